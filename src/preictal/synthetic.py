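"""Synthetic multichannel EEG with known spectral and spatial structure.

The generator produces recordings in which every downstream quantity has a
known ground truth: per-band amplitude (delta through gamma) and the
inter-channel correlation matrix, each settable separately for the baseline
and preictal states.  A recording is laid out as baseline activity with one
or more annotated seizures; the window immediately preceding each onset
carries the preictal parameters.

Each band is realized as band-limited Gaussian noise (white noise band-pass
filtered to the band edges) rather than a pure tone, so that short-time
Fourier estimates and correlation maps are statistically non-degenerate.
Channel correlation is imposed by Cholesky mixing of independent sources,
which is exact in expectation; additive sensor noise dilutes the realized
correlation toward the identity, as it does in real recordings.

This module intentionally does not attempt physiological seizure morphology
or artifact (EMG/EOG) simulation — it provides *distinguishable, controlled*
structure, not realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .edf_io import Recording, write_edf, write_summary

__all__ = ["SynthSpec", "generate_recording", "default_band_amplitudes",
           "banded_correlation", "write_synth_dataset"]

#: Canonical EEG band edges in Hz (half-open intervals [low, high)).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 80.0),
}


def default_band_amplitudes() -> dict[str, float]:
    """Roughly 1/f-shaped resting scalp EEG band amplitudes, in microvolts."""
    return {"delta": 30.0, "theta": 15.0, "alpha": 12.0, "beta": 6.0, "gamma": 3.0}


def banded_correlation(n_channels: int, rho: float, floor: float = 0.2) -> np.ndarray:
    """Correlation matrix ``(1 - floor) * rho**|i-j| + floor``.

    Mimics the spatial structure of scalp EEG: neighbouring electrodes are
    more correlated than distant ones, but volume conduction and the shared
    reference keep even distant pairs weakly correlated (the ``floor``).
    A convex combination of two PSD matrices, so always PSD for |rho| < 1.
    """
    idx = np.arange(n_channels)
    decay = rho ** np.abs(idx[:, None] - idx[None, :])
    return (1.0 - floor) * decay + floor * np.ones((n_channels, n_channels))


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording.

    ``band_amplitudes`` and ``correlation`` are keyed by state
    (``"baseline"``, ``"preictal"``); a missing ``"preictal"`` entry falls
    back to the baseline value, giving a no-signal recording.
    """

    n_channels: int = 21
    fs: float = 256.0
    duration_s: float = 600.0
    band_amplitudes: dict[str, dict[str, float]] = field(default_factory=dict)
    correlation: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 3.0
    seizure_onsets_s: list[float] = field(default_factory=list)
    seizure_duration_s: float = 40.0
    preictal_window_s: float = 600.0
    seed: int = 0
    subject_id: str = "synth"

    def __post_init__(self) -> None:
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if not self.band_amplitudes:
            self.band_amplitudes = {"baseline": default_band_amplitudes()}
        if "baseline" not in self.band_amplitudes:
            raise ValueError("band_amplitudes must define the 'baseline' state")
        if not self.correlation:
            self.correlation = {"baseline": banded_correlation(self.n_channels, 0.3)}
        for state, mat in self.correlation.items():
            mat = np.asarray(mat, dtype=float)
            self.correlation[state] = mat
            if mat.shape != (self.n_channels, self.n_channels):
                raise ValueError(f"correlation[{state!r}] has shape {mat.shape}")
            if not np.allclose(mat, mat.T):
                raise ValueError(f"correlation[{state!r}] is not symmetric")
            if not np.allclose(np.diag(mat), 1.0):
                raise ValueError(f"correlation[{state!r}] diagonal is not 1")
            if np.linalg.eigvalsh(mat).min() < -1e-10:
                raise ValueError(
                    f"correlation[{state!r}] is not positive semidefinite"
                )
        top_edge = max(BAND_EDGES[b][1] for b in self.band_amplitudes["baseline"])
        if self.fs <= 2 * top_edge * 0.999:
            raise ValueError(
                f"fs={self.fs} too low for the highest band edge {top_edge} Hz"
            )

    def params(self, state: str) -> tuple[dict[str, float], np.ndarray]:
        amps = self.band_amplitudes.get(state, self.band_amplitudes["baseline"])
        corr = self.correlation.get(state, self.correlation["baseline"])
        return amps, corr


def _state_segments(spec: SynthSpec) -> list[tuple[float, float, str]]:
    """Partition [0, duration) into (start, end, state) runs.

    The ``preictal_window_s`` before each onset and the seizure itself carry
    the preictal parameters; everything else is baseline.
    """
    marks = []
    for onset in sorted(spec.seizure_onsets_s):
        lo = max(0.0, onset - spec.preictal_window_s)
        hi = min(spec.duration_s, onset + spec.seizure_duration_s)
        marks.append((lo, hi))
    segments: list[tuple[float, float, str]] = []
    t = 0.0
    for lo, hi in marks:
        if lo > t:
            segments.append((t, lo, "baseline"))
        segments.append((max(t, lo), hi, "preictal"))
        t = hi
    if t < spec.duration_s:
        segments.append((t, spec.duration_s, "baseline"))
    return segments


def _band_sos(low: float, high: float, fs: float):
    nyq = fs / 2
    high = min(high, nyq * 0.99)
    return sps.butter(4, [low / nyq, high / nyq], btype="bandpass", output="sos")


def _segment_signal(
    rng: np.random.Generator,
    n_samples: int,
    spec: SynthSpec,
    amps: dict[str, float],
    corr: np.ndarray,
) -> np.ndarray:
    """One stationary segment: Cholesky-mixed band-limited noise + white noise."""
    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(spec.n_channels))
    pad = int(2 * spec.fs)  # absorb band-pass filter transients
    n = n_samples + 2 * pad
    out = np.zeros((spec.n_channels, n_samples))
    for band, amp in amps.items():
        if amp == 0:
            continue
        low, high = BAND_EDGES[band]
        if low >= spec.fs / 2:
            continue
        src = rng.standard_normal((spec.n_channels, n))
        src = sps.sosfiltfilt(_band_sos(low, high, spec.fs), src, axis=1)
        sd = src.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        src /= sd
        out += amp * (chol @ src)[:, pad:-pad]
    if spec.noise_sd > 0:
        out += spec.noise_sd * rng.standard_normal((spec.n_channels, n_samples))
    return out


def generate_recording(spec: SynthSpec) -> Recording:
    """Generate a seeded synthetic Recording from a :class:`SynthSpec`.

    Identical specs (including seed) yield bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    n_total = int(round(spec.duration_s * spec.fs))
    signal = np.empty((spec.n_channels, n_total))
    cursor = 0
    for start, end, state in _state_segments(spec):
        n_seg = int(round(end * spec.fs)) - int(round(start * spec.fs))
        if n_seg <= 0:
            continue
        amps, corr = spec.params(state)
        signal[:, cursor : cursor + n_seg] = _segment_signal(
            rng, n_seg, spec, amps, corr
        )
        cursor += n_seg
    annotations = [
        (onset, min(spec.duration_s, onset + spec.seizure_duration_s))
        for onset in sorted(spec.seizure_onsets_s)
    ]
    labels = [f"CH{i:02d}-REF" for i in range(spec.n_channels)]
    if spec.n_channels == 21:
        from .edf_io import DEFAULT_CHANNELS

        labels = list(DEFAULT_CHANNELS)
    return Recording(
        signal=signal,
        fs=spec.fs,
        channel_labels=labels,
        annotations=annotations,
        subject_id=spec.subject_id,
    )


def write_synth_dataset(specs: list[SynthSpec], out_dir: str | Path) -> list[Path]:
    """Write each spec as an EDF file plus one shared CHB-MIT-style summary.

    Returns the EDF paths.  Re-reading these files exercises the same parser
    path as real CHB-MIT data.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    entries = []
    for spec in specs:
        rec = generate_recording(spec)
        path = out_dir / f"{spec.subject_id}.edf"
        write_edf(rec, path)
        entries.append((path.name, rec.annotations))
        paths.append(path)
    write_summary(out_dir / "summary.txt", entries, fs=specs[0].fs if specs else 256.0)
    return paths
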