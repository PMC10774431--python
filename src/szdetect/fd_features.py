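"""Fractal-dimension and energy features of an EEG window.

Six features per window, always in this order: Higuchi FD, Katz FD,
Sevcik FD, log10 instantaneous energy, log10 Teager-Kaiser energy,
Petrosian FD.  Fractal dimensions are unitless complexity indices (1 for
a smooth line, toward 2 for plane-filling noise); the two energies are
log10 of mean squared amplitude and of the mean absolute Teager-Kaiser
operator output, respectively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import FEATURE_NAMES, FEATURE_TABLE_COLUMNS, Signal

_LOG_FLOOR = 1e-12  # floor on log10 arguments so features stay finite


@dataclass(frozen=True)
class FeatureVector:
    """The six per-window features, in canonical order."""

    higuchi_fd: float
    katz_fd: float
    sevcik_fd: float
    inst_energy: float
    teager_energy: float
    petrosian_fd: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass
class HiguchiCurve:
    """Mean curve length A(k) per delay k, the raw material of the FD slope."""

    k_values: np.ndarray
    lengths: np.ndarray


def higuchi_curve(x: np.ndarray, k_max: int = 8) -> HiguchiCurve:
    """Mean normalized curve length A(k) for k = 1 .. k_max.

    For each delay k and offset n = 1..k (1-based), the subsampled curve
    length is the sum of absolute increments times the normalization
    (N-1) / (floor((N-n)/k) * k), divided by k; A(k) averages over offsets.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if N < 2 * k_max:
        raise ValueError(f"need N >= 2*k_max, got N={N}, k_max={k_max}")
    ks = np.arange(1, k_max + 1)
    A = np.empty(k_max)
    for i, k in enumerate(ks):
        lengths = []
        for n in range(1, k + 1):          # 1-based offset
            m = (N - n) // k               # number of increments
            if m < 1:
                continue
            idx = n - 1 + np.arange(m + 1) * k
            seg = np.abs(np.diff(x[idx])).sum()
            lengths.append(seg * (N - 1) / (m * k) / k)
        A[i] = float(np.mean(lengths))
    return HiguchiCurve(k_values=ks, lengths=A)


def higuchi_fd(x: np.ndarray, k_max: int = 8) -> float:
    """Higuchi fractal dimension: OLS slope of ln A(k) against ln(1/k).

    A constant signal has zero curve lengths at every delay; by convention
    it returns 0 (there is no log-log line to fit).
    """
    curve = higuchi_curve(x, k_max)
    if np.any(curve.lengths <= 0):
        return 0.0
    lx = np.log(1.0 / curve.k_values)
    ly = np.log(curve.lengths)
    slope = np.polyfit(lx, ly, 1)[0]
    return float(slope)


def katz_fd(x: np.ndarray) -> float:
    """Katz fractal dimension of the planar waveform (i, x_i).

    With unit abscissa spacing: omega = total Euclidean curve length,
    d_1n = max Euclidean distance from the first point, the mean
    inter-point distance d_avg = omega/(N-1), h = omega/d_avg = N-1, and
    FD = log10(h) / (log10(d_1n/omega) + log10(h)).
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 3:
        raise ValueError("katz_fd needs at least 3 samples")
    dy = np.diff(x)
    omega = float(np.sum(np.hypot(1.0, dy)))
    i = np.arange(1, N)
    d1n = float(np.max(np.hypot(i, x[1:] - x[0])))
    h = N - 1  # omega / d_avg with d_avg = omega/(N-1)
    denom = np.log10(d1n / omega) + np.log10(h)
    return float(np.log10(h) / denom)


def sevcik_fd(x: np.ndarray) -> float:
    """Sevcik fractal dimension via normalization into the unit square.

    Abscissa mapped to i/(N-1) and ordinate min-max scaled; with L the
    curve length in the unit square, FD = 1 + (ln L - ln 2)/ln(2(N-1)).
    A flat signal (max == min) returns 1.0 by convention.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 3:
        raise ValueError("sevcik_fd needs at least 3 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return 1.0
    y = (x - lo) / (hi - lo)
    dx = 1.0 / (N - 1)
    L = float(np.sum(np.hypot(dx, np.diff(y))))
    return float(1.0 + (np.log(L) - np.log(2.0)) / np.log(2.0 * (N - 1)))


def instantaneous_energy(x: np.ndarray) -> float:
    """log10 of the mean squared amplitude, floored to stay finite."""
    x = np.asarray(x, dtype=float)
    if x.size < 1:
        raise ValueError("instantaneous_energy needs at least 1 sample")
    return float(np.log10(max(np.mean(x**2), _LOG_FLOOR)))


def teager_energy(x: np.ndarray) -> float:
    """log10 of the mean absolute Teager-Kaiser operator output.

    The operator x(t)^2 - x(t-1)*x(t+1) is evaluated over the N-2
    interior samples; the log argument is floored so a constant signal
    yields -12 rather than -inf.
    """
    x = np.asarray(x, dtype=float)
    N = x.size
    if N < 3:
        raise ValueError("teager_energy needs at least 3 samples")
    tk = np.abs(x[1:-1] ** 2 - x[:-2] * x[2:])
    return float(np.log10(max(tk.mean(), _LOG_FLOOR)))


def petrosian_fd(x: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference.

    Zero differences inherit the previous nonzero sign, so plateaus do not
    count as alternations.  N_i is the number of sign changes in the
    difference sequence; FD = log10(m) / (log10(m) + log10(m/(m + 0.4 N_i))).
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    if m < 3:
        raise ValueError("petrosian_fd needs at least 3 samples")
    d = np.diff(x)
    signs = np.sign(d)
    last = 0.0
    changes = 0
    for s in signs:
        if s == 0.0:
            continue
        if last != 0.0 and s != last:
            changes += 1
        last = s
    n_i = changes
    return float(np.log10(m) / (np.log10(m) + np.log10(m / (m + 0.4 * n_i))))


def extract_features(signal: Signal | np.ndarray, k_max: int = 8) -> FeatureVector:
    """All six features of one window, deterministic and always finite."""
    x = signal.samples if isinstance(signal, Signal) else np.asarray(signal, dtype=float)
    if x.size < 2 * k_max:
        raise ValueError(f"window of {x.size} samples too short for k_max={k_max}")
    return FeatureVector(
        higuchi_fd=higuchi_fd(x, k_max),
        katz_fd=katz_fd(x),
        sevcik_fd=sevcik_fd(x),
        inst_energy=instantaneous_energy(x),
        teager_energy=teager_energy(x),
        petrosian_fd=petrosian_fd(x),
    )


def feature_table(rows: list[tuple[Signal, int, FeatureVector]]) -> pd.DataFrame:
    """Assemble (signal, window_start, features) rows into the CSV schema."""
    records = []
    for sig, start, fv in rows:
        rec = {"record_id": sig.record_id, "channel": sig.channel,
               "window_start": start}
        rec.update({name: getattr(fv, name) for name in FEATURE_NAMES})
        rec["label"] = sig.class_label
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=list(FEATURE_TABLE_COLUMNS))
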