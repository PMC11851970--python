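"""Six-SVM voting ensemble over deep feature vectors.

Six RBF-kernel support vector machines are trained on overlapping subsets
of the training data and combined by averaging their binary outputs and
rounding::

    final = round((o_1 + o_2 + ... + o_6) / 6)

with the tie at exactly 0.5 rounded *up* to the preictal class, which
favors sensitivity.  Hard (binary) member outputs enter the vote; the mean
of the members' continuous decision scores is exposed separately for ROC
analysis.

Member diversity comes from bagged stratified leave-one-fold-out subsets
(the default: the data is split into six stratified folds and member *k*
trains on all folds except fold *k*), or alternatively from random 80 %
feature subspaces.  The member count is configurable so a single-SVM
ablation uses the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SvmConfig",
    "EnsembleModel",
    "EnsemblePrediction",
    "train_ensemble",
    "vote",
    "predict",
    "predict_batch",
]


@dataclass
class SvmConfig:
    """Hyperparameters of each member SVM."""

    C: float = 1.0
    kernel: str = "rbf"
    gamma: str | float = "scale"
    tol: float = 0.001
    decision_shape: str = "ovr"

    def __post_init__(self) -> None:
        if self.C <= 0 or self.tol <= 0:
            raise ValueError("C and tol must be positive")

    def make(self) -> Pipeline:
        # deep feature dimensions have widely varying scales, so each member
        # standardizes on its own training subset before the RBF kernel
        return Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "svc",
                    SVC(
                        C=self.C,
                        kernel=self.kernel,
                        gamma=self.gamma,
                        tol=self.tol,
                        decision_function_shape=self.decision_shape,
                    ),
                ),
            ]
        )


@dataclass
class EnsembleModel:
    members: list[Pipeline]  # StandardScaler + SVC per member
    member_assignments: list[np.ndarray]  # training row indices per member
    feature_subsets: list[np.ndarray] | None  # column indices, subspace mode
    cfg: SvmConfig
    seed: int
    n_features: int

    @property
    def n_members(self) -> int:
        return len(self.members)


@dataclass
class EnsemblePrediction:
    member_outputs: np.ndarray  # shape (n_members,), values in {0, 1}
    mean_vote: float
    final: int
    mean_score: float | None = None  # mean continuous decision score


def train_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    cfg: SvmConfig | None = None,
    seed: int = 0,
    n_members: int = 6,
    diversity: str = "folds",
) -> EnsembleModel:
    """Train the voting ensemble.

    ``diversity="folds"``: the training set is split into ``n_members``
    stratified folds (seeded); member *k* trains on the complement of fold
    *k*.  ``diversity="subspace"``: every member trains on all rows but a
    random 80 % subset of feature columns.
    """
    cfg = cfg or SvmConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if n_members > 1 and counts.min() < n_members:
        raise ValueError(
            f"need at least {n_members} samples per class for "
            f"{n_members} stratified folds; got {dict(zip(classes, counts))}"
        )

    members: list[SVC] = []
    assignments: list[np.ndarray] = []
    subsets: list[np.ndarray] | None = None
    if n_members == 1:
        clf = cfg.make()
        clf.fit(X, y)
        members.append(clf)
        assignments.append(np.arange(len(y)))
    elif diversity == "folds":
        skf = StratifiedKFold(n_splits=n_members, shuffle=True, random_state=seed)
        for train_idx, _holdout in skf.split(X, y):
            clf = cfg.make()
            clf.fit(X[train_idx], y[train_idx])
            members.append(clf)
            assignments.append(train_idx)
    elif diversity == "subspace":
        rng = np.random.default_rng(seed)
        n_cols = max(1, int(round(0.8 * X.shape[1])))
        subsets = []
        for _ in range(n_members):
            cols = np.sort(rng.choice(X.shape[1], size=n_cols, replace=False))
            clf = cfg.make()
            clf.fit(X[:, cols], y)
            members.append(clf)
            assignments.append(np.arange(len(y)))
            subsets.append(cols)
    else:
        raise ValueError(f"unknown diversity mode {diversity!r}")

    return EnsembleModel(
        members=members,
        member_assignments=assignments,
        feature_subsets=subsets,
        cfg=cfg,
        seed=seed,
        n_features=X.shape[1],
    )


def vote(member_outputs: np.ndarray | list[int]) -> EnsemblePrediction:
    """Combine binary member outputs by arithmetic mean and round-half-up.

    ``final = 1`` iff the mean vote is >= 0.5; a 3-3 tie therefore predicts
    preictal.  Symmetric in member order and monotone in each output.
    """
    out = np.asarray(member_outputs)
    if not np.isin(out, (0, 1)).all():
        raise ValueError(f"member outputs must be binary, got {out!r}")
    mean_vote = float(out.mean())
    return EnsemblePrediction(
        member_outputs=out.astype(int),
        mean_vote=mean_vote,
        final=int(mean_vote >= 0.5),
    )


def _member_inputs(model: EnsembleModel, X: np.ndarray, k: int) -> np.ndarray:
    if model.feature_subsets is not None:
        return X[:, model.feature_subsets[k]]
    return X


def predict_batch(
    model: EnsembleModel, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predict many epochs at once.

    Returns ``(finals, mean_votes, mean_scores)`` where ``mean_scores`` is
    the mean of the members' continuous decision-function values (used for
    ROC curves; the hard vote alone yields only ``n_members + 1`` operating
    points).
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension "
            f"{model.n_features}"
        )
    outs = np.stack(
        [m.predict(_member_inputs(model, X, k)) for k, m in enumerate(model.members)]
    )
    scores = np.stack(
        [
            m.decision_function(_member_inputs(model, X, k))
            for k, m in enumerate(model.members)
        ]
    )
    mean_votes = outs.mean(axis=0)
    finals = (mean_votes >= 0.5).astype(int)
    if model.n_members == 1:
        finals = outs[0].astype(int)
    return finals, mean_votes, scores.mean(axis=0)


def predict(model: EnsembleModel, feature: np.ndarray) -> EnsemblePrediction:
    """Predict a single epoch: apply every member, then the rounding vote."""
    X = np.atleast_2d(np.asarray(feature, dtype=np.float64))
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1]} != training dimension "
            f"{model.n_features}"
        )
    outs = np.array(
        [int(m.predict(_member_inputs(model, X, k))[0]) for k, m in enumerate(model.members)]
    )
    scores = [
        float(m.decision_function(_member_inputs(model, X, k))[0])
        for k, m in enumerate(model.members)
    ]
    if model.n_members == 1:
        pred = EnsemblePrediction(
            member_outputs=outs, mean_vote=float(outs[0]), final=int(outs[0])
        )
    else:
        pred = vote(outs)
    pred.mean_score = float(np.mean(scores))
    return pred
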