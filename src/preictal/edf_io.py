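"""Reading and writing EEG recordings and seizure annotations.

Recordings live in EDF (European Data Format) files; seizure onset/offset
times live in plain-text summary files in the dialect used by the CHB-MIT
scalp EEG database (``chbXX-summary.txt``).  Everything downstream of this
module consumes only :class:`Recording` objects, so the container format is
fully encapsulated here.

EDF reading goes through MNE.  No installed library writes EDF, so a
minimal 16-bit EDF writer is implemented here; it produces files MNE (and
any other conformant reader) can open, which is what the synthetic-EEG
module uses to exercise the real reading path.
"""

from __future__ import annotations

import datetime
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Recording",
    "read_recording",
    "read_annotations",
    "write_edf",
    "write_summary",
    "DEFAULT_CHANNELS",
]

#: The 21-channel bipolar montage shared by most CHB-MIT files.  Which 21 of
#: the 23+ recorded channels to use is a configurable choice; this default
#: covers the standard longitudinal bipolar chains of the 10-20 system.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "FP1-F7", "F7-T7", "T7-P7", "P7-O1",
    "FP1-F3", "F3-C3", "C3-P3", "P3-O1",
    "FP2-F4", "F4-C4", "C4-P4", "P4-O2",
    "FP2-F8", "F8-T8", "T8-P8", "P8-O2",
    "FZ-CZ", "CZ-PZ",
    "T7-FT9", "FT9-FT10", "FT10-T8",
)


@dataclass
class Recording:
    """A multichannel EEG recording with seizure annotations.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitudes in microvolts.
    fs : float
        Sampling rate in Hz (256 for CHB-MIT).
    channel_labels : list of str
        Ordered channel names; row ``i`` of ``signal`` is
        ``channel_labels[i]``.
    annotations : list of (float, float)
        Seizure intervals as half-open ``[start_s, end_s)`` pairs, in
        seconds from recording start, sorted and non-overlapping.
    subject_id : str
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[tuple[float, float]] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} signal rows"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.annotations = sorted(tuple(a) for a in self.annotations)
        prev_end = 0.0
        for start, end in self.annotations:
            if start < prev_end:
                raise ValueError("annotations overlap or are unsorted")
            if end <= start or end > self.duration_s + 1.0 / self.fs:
                raise ValueError(f"annotation ({start}, {end}) out of range")
            prev_end = end

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


def read_recording(
    path: str | Path,
    channel_selection: list[str] | None = None,
    *,
    expected_fs: float | None = 256.0,
    annotations: list[tuple[float, float]] | None = None,
    subject_id: str | None = None,
    provenance: list[str] | None = None,
) -> Recording:
    """Read an EDF file, selecting and ordering channels.

    Parameters
    ----------
    path : path to an EDF file.
    channel_selection : list of channel labels, or None for all channels in
        file order.  The returned signal rows follow this order exactly.
    expected_fs : sampling rate the pipeline assumes; a mismatch is a
        warning (recorded in ``provenance``), not an error.
    annotations, subject_id : optional metadata to attach.
    provenance : optional list that collects human-readable notes about
        non-fatal irregularities (fs mismatch, duplicate labels).

    Raises
    ------
    KeyError
        If a requested label is not present in the file.
    """
    import mne

    path = Path(path)
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_fs is not None and fs != expected_fs:
        msg = f"{path.name}: sampling rate {fs} Hz != expected {expected_fs} Hz"
        warnings.warn(msg, stacklevel=2)
        if provenance is not None:
            provenance.append(msg)

    available = list(raw.ch_names)
    if channel_selection is None:
        picks = available
    else:
        picks = []
        for label in channel_selection:
            if label in available:
                picks.append(label)
            elif f"{label}-0" in available:
                # MNE disambiguates duplicate EDF labels with -0, -1, ...;
                # first occurrence wins.
                picks.append(f"{label}-0")
                note = f"{path.name}: duplicate label {label!r}, using first occurrence"
                if provenance is not None:
                    provenance.append(note)
            else:
                raise KeyError(
                    f"channel {label!r} not found in {path.name}; "
                    f"available: {available}"
                )
    data = raw.get_data(picks=picks)  # volts
    labels = channel_selection if channel_selection is not None else picks
    return Recording(
        signal=data * 1e6,
        fs=fs,
        channel_labels=list(labels),
        annotations=annotations or [],
        subject_id=subject_id if subject_id is not None else path.stem,
    )


# --------------------------------------------------------------------------
# CHB-MIT summary files

_FILE_RE = re.compile(r"^File Name:\s*(\S+)", re.IGNORECASE)
_COUNT_RE = re.compile(r"^Number of Seizures in File:\s*(\d+)", re.IGNORECASE)
_START_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+Start Time:\s*([\d.]+)\s*sec", re.IGNORECASE)
_END_RE = re.compile(r"^Seizure(?:\s+\d+)?\s+End Time:\s*([\d.]+)\s*sec", re.IGNORECASE)


def read_annotations(
    summary_path: str | Path, recording_name: str
) -> list[tuple[float, float]]:
    """Parse seizure intervals for one EDF file from a CHB-MIT summary.

    Returns every ``(start_s, end_s)`` pair declared for ``recording_name``,
    sorted ascending by start time.  A file block that declares a nonzero
    seizure count but lists fewer start/end pairs is a parse error.
    """
    summary_path = Path(summary_path)
    lines = summary_path.read_text().splitlines()

    in_block = False
    count: int | None = None
    starts: list[float] = []
    ends: list[float] = []
    for line in lines:
        line = line.strip()
        m = _FILE_RE.match(line)
        if m:
            if in_block:
                break  # next file block begins
            in_block = m.group(1) == recording_name
            continue
        if not in_block:
            continue
        m = _COUNT_RE.match(line)
        if m:
            count = int(m.group(1))
            continue
        m = _START_RE.match(line)
        if m:
            starts.append(float(m.group(1)))
            continue
        m = _END_RE.match(line)
        if m:
            ends.append(float(m.group(1)))

    if count is None and not starts:
        raise KeyError(f"{recording_name} not found in {summary_path.name}")
    declared = count if count is not None else len(starts)
    if len(starts) != declared or len(ends) != declared:
        raise ValueError(
            f"{summary_path.name}: {recording_name} declares {declared} "
            f"seizures but lists {len(starts)} start / {len(ends)} end times"
        )
    return sorted(zip(starts, ends))


def write_summary(
    path: str | Path,
    entries: list[tuple[str, list[tuple[float, float]]]],
    fs: float = 256.0,
) -> None:
    """Write a CHB-MIT-dialect summary file.

    ``entries`` maps EDF file names to their seizure interval lists.
    """
    out = [f"Data Sampling Rate: {fs:g} Hz", ""]
    for name, seizures in entries:
        out.append(f"File Name: {name}")
        out.append(f"Number of Seizures in File: {len(seizures)}")
        for k, (start, end) in enumerate(seizures, start=1):
            out.append(f"Seizure {k} Start Time: {start:g} seconds")
            out.append(f"Seizure {k} End Time: {end:g} seconds")
        out.append("")
    Path(path).write_text("\n".join(out) + "\n")


# --------------------------------------------------------------------------
# Minimal EDF writer (16-bit, one data record per second)


def _ascii(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> None:
    """Write a Recording to a 16-bit EDF file.

    The signal is quantized to the EDF container's 16-bit digital range with
    a per-channel physical scale, so a write/read round trip is exact up to
    that quantization.  The duration is padded to a whole number of seconds
    (one data record per second).
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs_i = int(round(fs))
    n_chan = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / fs_i))
    sig = np.zeros((n_chan, n_records * fs_i))
    sig[:, : recording.n_samples] = recording.signal

    phys_max = np.maximum(np.abs(sig).max(axis=1), 1.0)
    # keep the 8-char header field exact: 4 significant digits, with enough
    # margin that rounding never lands below the true signal maximum
    phys_max = np.array([float(f"{v * 1.001:.4g}") for v in phys_max])
    dig_max = 32767

    start = datetime.datetime(2000, 1, 1)
    header = b""
    header += _ascii("0", 8)
    header += _ascii(recording.subject_id or "X", 80)
    header += _ascii("Startdate 01-JAN-2000", 80)
    header += _ascii(start.strftime("%d.%m.%y"), 8)
    header += _ascii(start.strftime("%H.%M.%S"), 8)
    header += _ascii(str(256 * (1 + n_chan)), 8)
    header += _ascii("", 44)
    header += _ascii(str(n_records), 8)
    header += _ascii("1", 8)  # record duration, seconds
    header += _ascii(str(n_chan), 4)

    labels = recording.channel_labels
    header += b"".join(_ascii(lab, 16) for lab in labels)
    header += b"".join(_ascii("", 80) for _ in labels)  # transducer
    header += b"".join(_ascii("uV", 8) for _ in labels)
    header += b"".join(_ascii(f"{-p:.4g}", 8) for p in phys_max)
    header += b"".join(_ascii(f"{p:.4g}", 8) for p in phys_max)
    header += b"".join(_ascii(str(-dig_max), 8) for _ in labels)
    header += b"".join(_ascii(str(dig_max), 8) for _ in labels)
    header += b"".join(_ascii("", 80) for _ in labels)  # prefiltering
    header += b"".join(_ascii(str(fs_i), 8) for _ in labels)
    header += b"".join(_ascii("", 32) for _ in labels)

    digital = np.clip(
        np.round(sig / phys_max[:, None] * dig_max), -dig_max, dig_max
    ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * fs_i : (r + 1) * fs_i]
            fh.write(np.ascontiguousarray(block).tobytes())
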