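"""Reading, windowing and tabular I/O for single- and multi-channel EEG.

Two on-disk conventions are supported: the Bonn plain-text format (one
integer amplitude per line, one file per single-channel segment, nominally
sampled at 173.61 Hz) and standard 16-bit EDF as used by the CHB-MIT scalp
recordings (256 Hz, bipolar channel labels).  Feature tables travel as CSV
with a fixed column schema shared with :mod:`szdetect.fd_features`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

BONN_FS = 173.61
"""Default sampling rate (Hz) of the Bonn single-channel segments."""

#: Canonical feature column names, in the order every table uses.
FEATURE_NAMES = (
    "higuchi_fd",
    "katz_fd",
    "sevcik_fd",
    "inst_energy",
    "teager_energy",
    "petrosian_fd",
)

#: Full CSV schema for feature tables.
FEATURE_TABLE_COLUMNS = ("record_id", "channel", "window_start") + FEATURE_NAMES + ("label",)


class BonnParseError(ValueError):
    """A Bonn-format text file contained a line that does not parse as a number."""


class FeatureTableFormatError(ValueError):
    """A feature-table CSV does not match the canonical column schema."""


@dataclass
class Signal:
    """A uniformly sampled amplitude sequence with channel metadata.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in microvolts; finite, length >= 1.
    fs : float
        Sampling rate in Hz, > 0.
    channel : str
        Channel label (verbatim from the source file where applicable).
    record_id : str
        Identifier of the originating record (file stem for Bonn files).
    class_label : str or None
        Optional class annotation ("normal", "seizure", ...).
    """

    samples: np.ndarray
    fs: float
    channel: str = ""
    record_id: str = ""
    class_label: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite (no NaN/Inf)")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")

    def __len__(self) -> int:
        return int(self.samples.size)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry: ``length`` samples advanced by ``step``."""

    length: int
    step: int

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2 samples")
        if not 1 <= self.step <= self.length:
            raise ValueError("step must satisfy 1 <= step <= length")


@dataclass
class LabeledDataset:
    """Instances (feature vectors or signals) paired with class labels."""

    instances: list[tuple[object, str]]
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.class_names:
            self.class_names = sorted({lab for _, lab in self.instances})
        known = set(self.class_names)
        for _, lab in self.instances:
            if lab not in known:
                raise ValueError(f"label {lab!r} not in class_names {self.class_names}")

    def __len__(self) -> int:
        return len(self.instances)

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.instances]

    def feature_matrix(self) -> np.ndarray:
        """Stack instances into a 2-D float array (requires vector instances)."""
        return np.asarray([np.asarray(x, dtype=float).ravel() for x, _ in self.instances])


def read_bonn_segment(path: str | Path, fs: float = BONN_FS) -> Signal:
    """Read one Bonn-format text segment (one numeric amplitude per line).

    Raises
    ------
    BonnParseError
        If the file is empty or a non-empty line fails to parse; the error
        message names the 1-based line number.
    """
    path = Path(path)
    values: list[float] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError:
                raise BonnParseError(
                    f"{path}: line {lineno}: {text!r} is not a number"
                ) from None
    if not values:
        raise BonnParseError(f"{path}: no samples (empty file)")
    return Signal(np.array(values), fs=fs, channel="", record_id=path.stem)


def write_bonn_segment(signal: Signal, path: str | Path) -> None:
    """Write a signal in the Bonn one-amplitude-per-line text format."""
    with open(path, "w", encoding="utf-8") as fh:
        for v in signal.samples:
            fh.write(f"{v:.6f}\n" if v != int(v) else f"{int(v)}\n")


def read_edf_channels(path: str | Path, channels: Sequence[str] | str = "all") -> list[Signal]:
    """Read the requested channels of an EDF file as microvolt signals.

    The sampling rate comes from the EDF header and digital values are
    converted to physical units by the header scaling.  Channel labels are
    preserved verbatim.

    Raises
    ------
    KeyError
        If a requested channel label is absent; the message lists the
        labels the file does contain.
    """
    import mne  # heavy import kept local

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = list(raw.ch_names)
    if isinstance(channels, str) and channels == "all":
        wanted = available
    else:
        wanted = list(channels)
        missing = [c for c in wanted if c not in available]
        if missing:
            raise KeyError(
                f"channel(s) {missing} not in {path}; available: {available}"
            )
    fs = float(raw.info["sfreq"])
    data = raw.get_data(picks=wanted) * 1e6  # mne returns volts
    record_id = Path(path).stem
    return [
        Signal(row, fs=fs, channel=name, record_id=record_id)
        for name, row in zip(wanted, data)
    ]


def segment_windows(signal: Signal, spec: WindowSpec) -> list[Signal]:
    """Cut a signal into half-open windows ``[start, start + length)``.

    Windows start at offsets 0, step, 2*step, ... and are emitted only when
    they fit entirely, giving ``floor((n - length)/step) + 1`` windows.
    """
    n = len(signal)
    if spec.length > n:
        raise ValueError(f"window length {spec.length} exceeds signal length {n}")
    count = (n - spec.length) // spec.step + 1
    out = []
    for i in range(count):
        start = i * spec.step
        out.append(
            Signal(
                signal.samples[start : start + spec.length].copy(),
                fs=signal.fs,
                channel=signal.channel,
                record_id=signal.record_id,
                class_label=signal.class_label,
            )
        )
    return out


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a feature table to CSV, preserving values to full precision."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty feature table")
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FeatureTableFormatError(f"feature table missing column(s) {missing}")
    table = table.loc[:, list(FEATURE_TABLE_COLUMNS)]
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature-table CSV, validating the canonical header."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FeatureTableFormatError(f"{path}: missing column(s) {missing}")
    return df.loc[:, list(FEATURE_TABLE_COLUMNS)]
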