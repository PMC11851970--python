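"""Splitting, metric formulas, ROC/AUC and the experiment driver surface."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from preictal.evaluation import (
    ConfusionCounts,
    compute_metrics,
    roc_auc,
    split_dataset,
)


def fake_cohort(n_subjects=1, per_label=540):
    labels, subjects, t0 = [], [], []
    for s in range(n_subjects):
        for lab in (0, 1):
            labels += [lab] * per_label
            subjects += [f"s{s}"] * per_label
            t0 += list(np.arange(per_label) * 10.0 + lab * 1e5)
    return np.array(labels), np.array(subjects), np.array(t0)


def test_split_ratio_arithmetic():
    """1080 epochs per subject split 60/20/20 -> 648/216/216."""
    y, subj, t0 = fake_cohort()
    split = split_dataset(y, subj, t0)
    assert len(split["train"]) == 648
    assert len(split["val"]) == 216
    assert len(split["test"]) == 216
    # exact stratification: each split is half label 0, half label 1
    for idx in split.values():
        assert y[idx].mean() == 0.5


def test_split_deterministic_and_disjoint():
    y, subj, t0 = fake_cohort(n_subjects=2, per_label=30)
    s1 = split_dataset(y, subj, t0, seed=5, mode="random")
    s2 = split_dataset(y, subj, t0, seed=5, mode="random")
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])
    all_idx = np.concatenate(list(s1.values()))
    assert len(np.unique(all_idx)) == len(y)


def test_blocked_split_keeps_time_blocks_contiguous():
    """Within each (subject, label) group the three splits are consecutive
    time blocks — adjacent epochs never straddle a split boundary."""
    y, subj, t0 = fake_cohort(per_label=50)
    split = split_dataset(y, subj, t0)
    for lab in (0, 1):
        bounds = []
        for part in ("train", "val", "test"):
            times = t0[[i for i in split[part] if y[i] == lab]]
            bounds.append((times.min(), times.max()))
        assert bounds[0][1] < bounds[1][0] < bounds[1][1] < bounds[2][0]


def test_split_label_proportions_within_2pct_random_mode():
    y, subj, t0 = fake_cohort(n_subjects=3, per_label=100)
    split = split_dataset(y, subj, t0, seed=1, mode="random")
    overall = y.mean()
    for idx in split.values():
        assert abs(y[idx].mean() - overall) <= 0.02


def test_split_input_validation():
    y, subj, t0 = fake_cohort(per_label=2)
    with pytest.raises(ValueError, match="stratify"):
        split_dataset(y, subj, t0)
    y, subj, t0 = fake_cohort(per_label=10)
    with pytest.raises(ValueError, match="sum to 1"):
        split_dataset(y, subj, t0, ratios=(0.7, 0.2, 0.2))


# -- metrics ---------------------------------------------------------------


def test_perfect_classification_metrics():
    m = compute_metrics(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
    assert (m.accuracy, m.sensitivity, m.precision, m.f1) == (100.0, 100.0, 100.0, 100.0)


def test_symmetric_error_metrics():
    m = compute_metrics(ConfusionCounts(tp=9, fn=1, fp=1, tn=9))
    for v in (m.accuracy, m.sensitivity, m.precision, m.f1):
        assert v == pytest.approx(90.0)


def test_undefined_sensitivity_reported_absent():
    """No positive epochs: sensitivity is absent with a reason, not 0."""
    m = compute_metrics(ConfusionCounts(tp=0, fn=0, fp=2, tn=8))
    assert m.sensitivity is None
    assert "sensitivity" in m.undefined
    assert m.accuracy == pytest.approx(80.0)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ConfusionCounts(tp=-1, fp=0, tn=0, fn=1)


@given(
    st.tuples(
        st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500), st.integers(0, 500),
    ).filter(lambda t: sum(t) > 0)
)
def test_metric_formula_identities(t):
    """Accuracy, sensitivity, precision match their formulas exactly and F1
    is the harmonic mean of precision and sensitivity, to machine precision."""
    tp, fp, tn, fn = t
    m = compute_metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
    total = tp + fp + tn + fn
    assert m.accuracy == pytest.approx(100 * (tp + tn) / total, rel=1e-12)
    if tp + fn:
        assert m.sensitivity == pytest.approx(100 * tp / (tp + fn), rel=1e-12)
    if tp + fp:
        assert m.precision == pytest.approx(100 * tp / (tp + fp), rel=1e-12)
    if m.f1 is not None:
        assert m.f1 == pytest.approx(
            2 * m.precision * m.sensitivity / (m.precision + m.sensitivity), rel=1e-12
        )


# -- ROC -------------------------------------------------------------------


def pairwise_u_auc(scores, labels):
    """Brute-force oracle: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_perfectly_separated_scores_auc_one():
    auc, pts = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert auc == 1.0
    assert {"fpr", "tpr", "threshold"} <= set(pts.columns)


def test_random_scores_auc_near_half():
    rng = np.random.default_rng(0)
    scores = rng.uniform(size=2000)
    labels = rng.integers(0, 2, size=2000)
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(0.5, abs=0.05)


def test_auc_equals_pairwise_comparison_oracle():
    scores = [0.3, 0.1, 0.9, 0.4, 0.8, 0.4]
    labels = [0, 0, 1, 1, 1, 0]
    auc, _ = roc_auc(scores, labels)
    assert auc == pytest.approx(pairwise_u_auc(scores, labels), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    scores = rng.normal(size=300) + np.r_[np.zeros(150), np.ones(150)]
    labels = np.r_[np.zeros(150), np.ones(150)].astype(int)
    a1, _ = roc_auc(scores, labels)
    a2, _ = roc_auc(np.exp(3 * scores), labels)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc([0.1, 0.9], [1, 1])


# -- CLI surface -----------------------------------------------------------


def test_cli_report_formats_metrics(tmp_path):
    from click.testing import CliRunner

    from preictal.cli import main

    metrics = {
        "summary": {
            "test": {
                "accuracy": {"mean": 96.1, "sd": 1.0},
                "sensitivity": {"mean": 95.2, "sd": 1.1},
                "f1": {"mean": 95.1, "sd": 0.9},
            }
        },
        "pooled": {},
        "auc": 0.99,
    }
    p = tmp_path / "metrics.json"
    p.write_text(json.dumps(metrics))
    result = CliRunner().invoke(main, ["report", str(p)])
    assert result.exit_code == 0, result.output
    assert "96.10" in result.output
    assert "AUC: 0.9900" in result.output


def test_cli_synth_writes_edf_cohort(tmp_path):
    from click.testing import CliRunner

    from preictal.cli import main

    out = tmp_path / "cohort"
    result = CliRunner().invoke(
        main, ["synth", "--out", str(out), "--subjects", "1", "--seed", "3"]
    )
    assert result.exit_code == 0, result.output
    edfs = list(out.glob("*.edf"))
    assert len(edfs) == 1
    from preictal.edf_io import read_annotations, read_recording

    ann = read_annotations(out / "summary.txt", edfs[0].name)
    assert len(ann) == 1
    rec = read_recording(edfs[0], annotations=ann)
    assert rec.n_channels == 21
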