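"""Per-epoch feature extraction: band profiles and channel-correlation maps.

Two feature families are computed for every 10 s epoch:

* **Band profile** — a short-time Fourier transform (1 s Hann window, 50 %
  overlap) is reduced to a ``bands x frames`` matrix: the mean spectral
  magnitude over the bins of each canonical EEG band (delta 0.5-4, theta
  4-8, alpha 8-12, beta 13-30, gamma 30-80 Hz) at each time step, averaged
  over channels.  At 256 Hz and 10 s this is a 5 x 19 matrix.  Magnitude
  (not power) is used, so the profile is linear in signal amplitude.

* **Correlation map** — the ``channels x channels`` matrix of Pearson
  correlation coefficients over the epoch's samples, capturing spatial
  dependence between scalp regions.

Both are normalized per subject by element-wise division with the mean over
that subject's baseline epochs, so values express deviation from the
subject's own resting activity (a value of 1 means "no change").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .preprocess import Epoch

__all__ = [
    "BANDS",
    "StftConfig",
    "BandProfile",
    "CorrelationMap",
    "BaselineProfileSet",
    "band_profile",
    "correlation_map",
    "build_baseline_profiles",
    "normalize",
]

#: Canonical EEG frequency bands, Hz; each bin is assigned to [low, high).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


@dataclass
class StftConfig:
    window: str = "hann"
    nperseg: int = 256  # 1 s at 256 Hz
    noverlap: int = 128  # 50 % overlap


def validate_bands(bands: dict[str, tuple[float, float]], fs: float) -> None:
    prev_low = -np.inf
    for name, (low, high) in bands.items():
        if low >= high:
            raise ValueError(f"band {name}: low {low} >= high {high}")
        if low < prev_low:
            raise ValueError("bands must be ordered by frequency")
        if low >= fs / 2:
            raise ValueError(
                f"band {name} ({low}-{high} Hz) lies entirely above "
                f"Nyquist ({fs / 2} Hz)"
            )
        prev_low = low


@dataclass
class BandProfile:
    """Mean STFT magnitude per band per time step, averaged over channels."""

    values: np.ndarray  # n_bands x n_frames, >= 0
    band_order: list[str]
    time_step_s: float
    n_guarded: int = 0  # cells where baseline normalization was guarded


@dataclass
class CorrelationMap:
    """Pearson correlation between all channel pairs within one epoch."""

    values: np.ndarray  # C x C
    channel_order: list[str] = field(default_factory=list)
    n_zero_variance: int = 0
    n_guarded: int = 0


@dataclass
class BaselineProfileSet:
    """Per-subject element-wise means over baseline (label-0) epochs."""

    subject_id: str
    mean_band_profile: np.ndarray
    mean_correlation_map: np.ndarray
    n_profiles_used: int


def band_profile(
    epoch: Epoch,
    stft_cfg: StftConfig | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandProfile:
    """Compute the band-amplitude matrix of one epoch.

    Entry ``(b, t)`` is the mean STFT magnitude over the frequency bins of
    band ``b`` in frame ``t``, averaged over all channels.  Frames are
    taken without boundary padding, so a 10 s epoch with a 1 s window and
    50 % overlap yields 19 frames.
    """
    cfg = stft_cfg or StftConfig()
    bands = bands or BANDS
    validate_bands(bands, epoch.fs)
    if epoch.data.shape[1] < cfg.nperseg:
        raise ValueError("epoch shorter than one STFT window")
    freqs, _times, Z = sps.stft(
        epoch.data,
        fs=epoch.fs,
        window=cfg.window,
        nperseg=cfg.nperseg,
        noverlap=cfg.noverlap,
        boundary=None,
        padded=False,
        axis=1,
    )
    mag = np.abs(Z)  # channels x freqs x frames
    rows = []
    for name, (low, high) in bands.items():
        mask = (freqs >= low) & (freqs < high)
        if not mask.any():
            raise ValueError(f"band {name} contains no STFT bins at fs={epoch.fs}")
        rows.append(mag[:, mask, :].mean(axis=(0, 1)))
    hop = cfg.nperseg - cfg.noverlap
    return BandProfile(
        values=np.asarray(rows),
        band_order=list(bands),
        time_step_s=hop / epoch.fs,
    )


def correlation_map(
    epoch: Epoch, channel_order: list[str] | None = None
) -> CorrelationMap:
    """Pearson correlation over the epoch's samples for every channel pair.

    A zero-variance channel has undefined correlation; its off-diagonal
    row/column is set to 0 and the event counted in ``n_zero_variance``.
    """
    x = epoch.data
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples per channel")
    sd = x.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    r = np.where(np.isfinite(r), r, 0.0)
    if degenerate.any():
        r[degenerate, :] = 0.0
        r[:, degenerate] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return CorrelationMap(
        values=r,
        channel_order=list(channel_order or []),
        n_zero_variance=int(degenerate.sum()),
    )


def build_baseline_profiles(
    epochs: list[Epoch],
    n_profiles: int | None = None,
    stft_cfg: StftConfig | None = None,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BaselineProfileSet:
    """Average band profiles and correlation maps over baseline epochs.

    All epochs must carry label 0 and belong to one subject.  If
    ``n_profiles`` exceeds the number available, every epoch is used and
    ``n_profiles_used`` records the actual count.
    """
    if not epochs:
        raise ValueError("no baseline epochs supplied")
    subjects = {e.subject_id for e in epochs}
    if len(subjects) != 1:
        raise ValueError(f"epochs span multiple subjects: {sorted(subjects)}")
    if any(e.label != 0 for e in epochs):
        raise ValueError("baseline profiles must be built from label-0 epochs only")
    n_use = len(epochs) if n_profiles is None else min(n_profiles, len(epochs))
    if n_profiles is not None and n_profiles > len(epochs):
        import warnings

        warnings.warn(
            f"requested {n_profiles} baseline profiles, only "
            f"{len(epochs)} available; using all",
            stacklevel=2,
        )
    subset = epochs[:n_use]
    bp = np.mean([band_profile(e, stft_cfg, bands).values for e in subset], axis=0)
    cm = np.mean([correlation_map(e).values for e in subset], axis=0)
    return BaselineProfileSet(
        subject_id=subset[0].subject_id,
        mean_band_profile=bp,
        mean_correlation_map=cm,
        n_profiles_used=n_use,
    )


def _safe_divide(num: np.ndarray, den: np.ndarray, eps: float) -> tuple[np.ndarray, int]:
    guard = np.abs(den) < eps
    out = np.where(guard, 1.0, num / np.where(guard, 1.0, den))
    return out, int(guard.sum())


def normalize(
    profile: BandProfile | CorrelationMap,
    baseline: BaselineProfileSet,
    eps: float = 1e-8,
) -> BandProfile | CorrelationMap:
    """Divide a feature element-wise by the subject's baseline mean.

    Cells where the baseline mean has magnitude below ``eps`` are set to 1
    (the "no change" value) and counted in the result's ``n_guarded``.
    Normalized correlation values are passed through unchanged even when
    division pushes them outside [-1, 1].
    """
    if isinstance(profile, BandProfile):
        ref = baseline.mean_band_profile
        if profile.values.shape != ref.shape:
            raise ValueError(
                f"shape mismatch: profile {profile.values.shape} vs "
                f"baseline {ref.shape}"
            )
        vals, n_guard = _safe_divide(profile.values, ref, eps)
        return BandProfile(
            values=vals,
            band_order=list(profile.band_order),
            time_step_s=profile.time_step_s,
            n_guarded=n_guard,
        )
    if isinstance(profile, CorrelationMap):
        ref = baseline.mean_correlation_map
        if profile.values.shape != ref.shape:
            raise ValueError(
                f"shape mismatch: map {profile.values.shape} vs baseline {ref.shape}"
            )
        vals, n_guard = _safe_divide(profile.values, ref, eps)
        return CorrelationMap(
            values=vals,
            channel_order=list(profile.channel_order),
            n_zero_variance=profile.n_zero_variance,
            n_guarded=n_guard,
        )
    raise TypeError(f"cannot normalize {type(profile).__name__}")
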