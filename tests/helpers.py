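"""Shared test utilities: AR signal factories and tiny EEG file writers."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
from scipy.signal import lfilter


def stable_ar_coefficients(rng: np.random.Generator, order: int,
                           max_reflection: float = 0.9) -> np.ndarray:
    """Random stable AR coefficients (A(z) = 1 + sum a_i z^-i convention).

    Built by the step-up recursion from reflection coefficients drawn in
    (-max_reflection, max_reflection), which guarantees all roots of
    A(z) lie inside the unit circle.
    """
    a = np.empty(0)
    for m in range(1, order + 1):
        k = rng.uniform(-max_reflection, max_reflection)
        a_new = np.empty(m)
        if m > 1:
            a_new[: m - 1] = a + k * a[::-1]
        a_new[m - 1] = k
        a = a_new
    return a


def simulate_ar(rng: np.random.Generator, a: np.ndarray, n: int,
                burn: int = 1000, noise_sd: float = 1.0) -> np.ndarray:
    """Simulate x(n) = e(n) - sum a_i x(n-i) with white Gaussian e."""
    e = noise_sd * rng.standard_normal(n + burn)
    x = lfilter([1.0], np.concatenate(([1.0], a)), e)
    return x[burn:]


def resonator_poly(freq: float, fs: float, pole: float) -> np.ndarray:
    """AR(2) coefficients (a_1, a_2) with complex poles at +-freq Hz."""
    theta = 2.0 * np.pi * freq / fs
    return np.array([-2.0 * pole * np.cos(theta), pole * pole])


def write_minimal_edf(path: Path, data: np.ndarray, fs: float,
                      labels: list[str]) -> None:
    """Write a minimal single-record EDF file (int16 samples).

    Covers just enough of the format for reader tests: one data record
    spanning the whole signal, physical range chosen so quantization is
    exact for integer inputs.
    """
    n_ch, n_samples = data.shape
    record_dur = n_samples / fs
    header = b""
    header += b"0".ljust(8)
    header += b"test patient".ljust(80)
    header += b"test recording".ljust(80)
    header += b"01.01.20".ljust(8)
    header += b"00.00.00".ljust(8)
    header += str(256 + 256 * n_ch).encode().ljust(8)
    header += b"".ljust(44)
    header += b"1".ljust(8)                       # number of data records
    header += f"{record_dur:g}".encode().ljust(8)
    header += str(n_ch).encode().ljust(4)
    for lab in labels:
        header += lab.encode().ljust(16)
    header += b"".ljust(80) * n_ch                # transducer
    header += b"uV".ljust(8) * n_ch
    header += b"-32768".ljust(8) * n_ch           # physical min
    header += b"32767".ljust(8) * n_ch            # physical max
    header += b"-32768".ljust(8) * n_ch           # digital min
    header += b"32767".ljust(8) * n_ch            # digital max
    header += b"".ljust(80) * n_ch                # prefiltering
    header += str(n_samples).encode().ljust(8) * n_ch
    header += b"".ljust(32) * n_ch
    body = b"".join(
        struct.pack(f"<{n_samples}h", *np.asarray(row, dtype=np.int16))
        for row in data)
    path.write_bytes(header + body)


def write_brainvision_ascii(directory: Path, stem: str, data: np.ndarray,
                            fs: float, labels: list[str]) -> Path:
    """Write an ASCII-format BrainVision trio (.vhdr/.vmrk/.eeg)."""
    directory = Path(directory)
    n_ch = data.shape[0]
    vhdr = directory / f"{stem}.vhdr"
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "[Common Infos]",
        f"DataFile={stem}.eeg",
        f"MarkerFile={stem}.vmrk",
        "DataFormat=ASCII",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / fs:g}",
        "[ASCII Infos]",
        "DecimalSymbol=.",
        "SkipLines=0",
        "SkipColumns=0",
        "[Channel Infos]",
    ]
    for i, lab in enumerate(labels, 1):
        lines.append(f"Ch{i}={lab},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")
    (directory / f"{stem}.vmrk").write_text(
        "Brain Vision Data Exchange Marker File, Version 1.0\n"
        "[Common Infos]\n"
        f"DataFile={stem}.eeg\n"
        "[Marker Infos]\n"
        "Mk1=New Segment,,1,1,0,00000000000000000000\n",
        encoding="utf-8")
    rows = "\n".join(" ".join(f"{v:.6f}" for v in col) for col in data.T)
    (directory / f"{stem}.eeg").write_text(rows + "\n", encoding="utf-8")
    return vhdr
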