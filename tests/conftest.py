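"""Shared fixtures: synthetic Bonn files and a minimal EDF writer.

The EDF writer exists only to produce synthetic test fixtures for the
reader; it emits standard 16-bit EDF with one data record per second.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest


def write_edf_fixture(path, signals, fs, labels,
                      phys_min=-1000.0, phys_max=1000.0) -> None:
    """Write a synthetic 16-bit EDF file (fixture-only writer)."""
    ns = len(signals)
    n = len(signals[0])
    spr = int(fs)               # samples per record (1 s records)
    n_records = n // spr
    dig_min, dig_max = -32768, 32767

    def f(value, width):
        return str(value)[:width].ljust(width).encode("ascii")

    hdr = f("0", 8) + f("X X X X", 80) + f("Startdate 01-JAN-2020 X X X", 80)
    hdr += f("01.01.20", 8) + f("00.00.00", 8)
    hdr += f(256 * (ns + 1), 8) + f("", 44) + f(n_records, 8) + f(1, 8) + f(ns, 4)
    hdr += b"".join(f(lab, 16) for lab in labels)
    hdr += b"".join(f("", 80) for _ in range(ns))       # transducer
    hdr += b"".join(f("uV", 8) for _ in range(ns))
    hdr += b"".join(f(phys_min, 8) for _ in range(ns))
    hdr += b"".join(f(phys_max, 8) for _ in range(ns))
    hdr += b"".join(f(dig_min, 8) for _ in range(ns))
    hdr += b"".join(f(dig_max, 8) for _ in range(ns))
    hdr += b"".join(f("", 80) for _ in range(ns))       # prefiltering
    hdr += b"".join(f(spr, 8) for _ in range(ns))
    hdr += b"".join(f("", 32) for _ in range(ns))       # reserved
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_records):
            for sig in signals:
                seg = np.asarray(sig[r * spr:(r + 1) * spr], dtype=float)
                dig = np.round((seg - phys_min) * scale + dig_min).astype("<i2")
                fh.write(dig.tobytes())


@pytest.fixture()
def edf_fixture(tmp_path):
    """Two-channel 256 Hz EDF file with known sinusoidal content."""
    fs = 256
    t = np.arange(fs * 4) / fs
    ch1 = 100 * np.sin(2 * np.pi * 5 * t)
    ch2 = 50 * np.cos(2 * np.pi * 11 * t)
    path = tmp_path / "synthetic.edf"
    write_edf_fixture(path, [ch1, ch2], fs, ["FP1-F7", "C3-P3"])
    return path, fs, {"FP1-F7": ch1, "C3-P3": ch2}


@pytest.fixture()
def bonn_file(tmp_path):
    """A small Bonn-format text segment."""
    path = tmp_path / "Z001.txt"
    path.write_text("12\n-5\n0\n")
    return path
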