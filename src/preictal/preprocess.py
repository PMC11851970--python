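"""Filtering and epoching of EEG recordings.

Two stages:

* **Filtering** — narrow zero-phase notch filters at the mains frequencies
  (50 and 60 Hz) to suppress power-line interference, and an optional
  zero-phase low-pass FIR at 35 Hz.  The low-pass is skipped by default in
  the feature pipeline whenever the gamma band (30-80 Hz) is in use, since
  it would null that band.

* **Epoching** — cutting a recording into non-overlapping fixed-length
  (default 10 s) epochs labeled preictal (1) or baseline (0).  For each
  annotated seizure, the preictal window (default 10 min) ending at onset
  is tiled backwards from the onset; baseline epochs are drawn from spans
  at least a guard distance away from every seizure and outside every
  preictal window, then down-sampled (seeded) to match the preictal count
  so each subject contributes a balanced dataset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .edf_io import Recording

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "WindowingConfig",
    "Epoch",
    "apply_filters",
    "cut_epochs",
    "plan_epochs",
    "epoch_manifest",
]


@dataclass
class FilterConfig:
    """Notch + low-pass settings.

    ``fir_order`` is the low-pass FIR order (even, for linear phase); with
    ``zero_phase`` the filter runs forward and backward so the net group
    delay is zero.  ``lowpass_cutoff_hz=None`` disables the low-pass.
    """

    notch_freqs_hz: list[float] = field(default_factory=lambda: [50.0, 60.0])
    lowpass_cutoff_hz: float | None = 35.0
    fir_order: int = 50
    zero_phase: bool = True
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        nyq = fs / 2
        for f0 in self.notch_freqs_hz:
            if f0 >= nyq:
                raise ValueError(f"notch frequency {f0} Hz >= Nyquist {nyq} Hz")
        if self.lowpass_cutoff_hz is not None and self.lowpass_cutoff_hz >= nyq:
            raise ValueError(
                f"low-pass cutoff {self.lowpass_cutoff_hz} Hz >= Nyquist {nyq} Hz"
            )
        if self.fir_order % 2:
            raise ValueError("fir_order must be even for linear phase")


def apply_filters(rec: Recording, cfg: FilterConfig | None = None) -> Recording:
    """Return a filtered copy of ``rec`` (same shape, same metadata)."""
    cfg = cfg or FilterConfig()
    cfg.validate(rec.fs)
    x = rec.signal
    for f0 in cfg.notch_freqs_hz:
        b, a = sps.iirnotch(f0, cfg.notch_q, fs=rec.fs)
        if cfg.zero_phase:
            x = sps.filtfilt(b, a, x, axis=1)
        else:
            x = sps.lfilter(b, a, x, axis=1)
    if cfg.lowpass_cutoff_hz is not None:
        taps = sps.firwin(cfg.fir_order + 1, cfg.lowpass_cutoff_hz, fs=rec.fs)
        if cfg.zero_phase:
            x = sps.filtfilt(taps, [1.0], x, axis=1)
        else:
            x = sps.lfilter(taps, [1.0], x, axis=1)
    return Recording(
        signal=x,
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
        annotations=list(rec.annotations),
        subject_id=rec.subject_id,
    )


@dataclass
class WindowingConfig:
    """Epoch length, preictal window and baseline exclusion rule.

    ``baseline_min_gap_s`` keeps baseline epochs at least this far from any
    seizure interval, so the negative class is free of peri-ictal activity.
    """

    epoch_len_s: float = 10.0
    preictal_window_min: float = 10.0
    baseline_min_gap_s: float = 3600.0

    def __post_init__(self) -> None:
        if self.epoch_len_s <= 0 or self.preictal_window_min <= 0:
            raise ValueError("epoch length and preictal window must be positive")


@dataclass
class Epoch:
    """One fixed-length labeled EEG segment (a single classification sample)."""

    data: np.ndarray  # channels x (fs * epoch_len_s)
    label: int  # 0 baseline, 1 preictal
    subject_id: str
    t_start_s: float
    epoch_len_s: float
    fs: float

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        expected = int(round(self.fs * self.epoch_len_s))
        if self.data.shape[1] != expected:
            raise ValueError(
                f"epoch has {self.data.shape[1]} samples, expected {expected}"
            )


def plan_epochs(
    duration_s: float,
    annotations: list[tuple[float, float]],
    cfg: WindowingConfig,
) -> tuple[list[float], list[float], dict]:
    """Compute epoch start times without touching signal data.

    Returns ``(preictal_starts, baseline_candidate_starts, log)``.  Preictal
    epochs tile the ``preictal_window_min`` minutes ending at each onset,
    anchored at the onset and walking backwards, so the last epoch always
    abuts the seizure.  Baseline candidates tile every span that is at
    least ``baseline_min_gap_s`` from every seizure interval and outside
    every preictal window.  No epoch ever overlaps a seizure interval.
    """
    L = cfg.epoch_len_s
    window_s = cfg.preictal_window_min * 60.0
    log: dict = {"truncated_windows": 0, "dropped_overlap_ictal": 0}

    preictal_spans = []
    for onset, _end in annotations:
        lo = onset - window_s
        if lo < 0:
            log["truncated_windows"] += 1
            logger.info("preictal window before t=0 truncated (onset %.0f s)", onset)
            lo = 0.0
        preictal_spans.append((lo, onset))

    preictal_starts: list[float] = []
    for (lo, onset), (_s, _e) in zip(preictal_spans, annotations):
        n = int(np.floor((onset - lo) / L))
        starts = [onset - (k + 1) * L for k in range(n)][::-1]
        # a preictal window may run into an *earlier* seizure's ictal span
        kept = []
        for t in starts:
            if any(t < e and t + L > s for s, e in annotations):
                log["dropped_overlap_ictal"] += 1
            else:
                kept.append(t)
        preictal_starts.extend(kept)

    # baseline-eligible spans: away from seizures and preictal windows
    blocked = [(s - cfg.baseline_min_gap_s, e + cfg.baseline_min_gap_s)
               for s, e in annotations]
    blocked += preictal_spans
    baseline_starts: list[float] = []
    t = 0.0
    while t + L <= duration_s + 1e-9:
        if any(t < hi and t + L > lo for lo, hi in blocked):
            t += L
            continue
        baseline_starts.append(t)
        t += L
    log["n_preictal"] = len(preictal_starts)
    log["n_baseline_candidates"] = len(baseline_starts)
    return preictal_starts, baseline_starts, log


def cut_epochs(
    rec: Recording,
    cfg: WindowingConfig | None = None,
    seed: int = 0,
) -> list[Epoch]:
    """Cut a recording into balanced, labeled, non-overlapping epochs.

    Baseline candidates are down-sampled uniformly (seeded) to the preictal
    count; if fewer candidates exist than preictal epochs, all are kept and
    a warning is issued.
    """
    cfg = cfg or WindowingConfig()
    if rec.duration_s < cfg.epoch_len_s:
        warnings.warn(
            f"recording {rec.subject_id} shorter than one epoch; no epochs",
            stacklevel=2,
        )
        return []
    pre_starts, base_candidates, log = plan_epochs(
        rec.duration_s, rec.annotations, cfg
    )
    n_pre = len(pre_starts)
    rng = np.random.default_rng(seed)
    if len(base_candidates) > n_pre:
        keep = rng.choice(len(base_candidates), size=n_pre, replace=False)
        base_starts = [base_candidates[i] for i in sorted(keep)]
    else:
        if len(base_candidates) < n_pre:
            warnings.warn(
                f"{rec.subject_id}: only {len(base_candidates)} baseline "
                f"candidates for {n_pre} preictal epochs; classes unbalanced",
                stacklevel=2,
            )
        base_starts = base_candidates

    n_len = int(round(cfg.epoch_len_s * rec.fs))
    epochs: list[Epoch] = []
    for label, starts in ((1, pre_starts), (0, base_starts)):
        for t0 in starts:
            i0 = int(round(t0 * rec.fs))
            epochs.append(
                Epoch(
                    data=rec.signal[:, i0 : i0 + n_len],
                    label=label,
                    subject_id=rec.subject_id,
                    t_start_s=t0,
                    epoch_len_s=cfg.epoch_len_s,
                    fs=rec.fs,
                )
            )
    epochs.sort(key=lambda e: e.t_start_s)
    return epochs


def epoch_manifest(epochs: list[Epoch], seed: int | None = None) -> pd.DataFrame:
    """Tabulate epochs (subject, label, start time) for provenance records."""
    df = pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in epochs],
            "label": [e.label for e in epochs],
            "t_start_s": [e.t_start_s for e in epochs],
            "epoch_len_s": [e.epoch_len_s for e in epochs],
        }
    )
    if seed is not None:
        df.attrs["baseline_sampling_seed"] = seed
    return df
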