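"""Reading and fixed preprocessing of resting-state EEG.

A :class:`Recording` holds one subject's multi-channel EEG time series.
The preprocessing applied once per recording is deliberately minimal, in
keeping with how the index is meant to be deployed (no manual cleaning):

1. :func:`normalize_energy` — divide each channel by the square root of
   its total energy, so amplitude scaling is uniform across electrodes;
2. :func:`remove_line_noise` — eliminate mains contamination (60 Hz and
   its recording-system artifacts at 180 and 200 Hz) by zeroing narrow
   FFT bins.

A zero-phase 6th-order Butterworth :func:`bandpass` is applied later,
per electrode configuration, to steer the spectral profiling toward a
chosen frequency region.

Supported on-disk dialects:

* BrainVision (``.vhdr``/``.vmrk``/``.eeg``) and EDF, read through MNE;
* a plain "matrix" dialect — delimited numeric text, samples x channels,
  with a JSON sidecar ``{"fs": ..., "channels": [...]}`` — used for
  synthetic cohorts and fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "Recording",
    "BandRange",
    "read_recording",
    "write_matrix_recording",
    "read_subject_table",
    "normalize_energy",
    "remove_line_noise",
    "bandpass",
    "preprocess_recording",
]

#: Mains frequency and recording-system artifacts removed from every recording.
DEFAULT_NOTCH_FREQS = (60.0, 180.0, 200.0)


@dataclass(frozen=True)
class BandRange:
    """A bandpass frequency range in Hz (0 < f_lo < f_hi < fs/2)."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0.0 < self.f_lo < self.f_hi):
            raise ValueError(f"invalid band ({self.f_lo}, {self.f_hi}) Hz")

    def validate(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz not below Nyquist ({fs / 2} Hz)"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo


@dataclass
class Recording:
    """One subject's multi-channel EEG time series.

    ``data`` is shaped (n_channels, n_samples); all channels share the
    sampling rate ``fs`` and the sample count.
    """

    subject_id: str
    fs: float
    channels: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{len(self.channels)} channel labels but data has "
                f"{self.data.shape[0]} rows"
            )
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel labels must be unique")
        if self.data.shape[1] == 0:
            raise ValueError("zero-length channels")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        try:
            idx = self.channels.index(label)
        except ValueError:
            raise KeyError(
                f"electrode {label!r} not present in recording "
                f"{self.subject_id!r}"
            ) from None
        return self.data[idx]

    def truncated(self, fraction: float) -> "Recording":
        """Keep the leading ``ceil(fraction * N)`` samples (the end is cut)."""
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        n_keep = ceil(fraction * self.n_samples)
        return Recording(self.subject_id, self.fs, self.channels,
                         self.data[:, :n_keep].copy())


def read_recording(
    path: str | Path,
    dialect: str = "matrix",
    *,
    fs: float | None = None,
    channels: list[str] | None = None,
    subject_id: str | None = None,
) -> Recording:
    """Read a single EEG recording.

    Parameters
    ----------
    path
        Header file (BrainVision ``.vhdr``), EDF file, or matrix text file.
    dialect
        ``"brainvision"``, ``"edf"`` or ``"matrix"``.
    fs, channels
        Matrix-dialect side-channel configuration; when omitted they are
        taken from the JSON sidecar next to ``path``.
    subject_id
        Defaults to the file stem.
    """
    path = Path(path)
    sid = subject_id if subject_id is not None else path.stem
    if dialect in ("brainvision", "edf"):
        import mne

        if dialect == "brainvision":
            raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data()
        return Recording(sid, float(raw.info["sfreq"]),
                         tuple(raw.ch_names), data)
    if dialect == "matrix":
        if fs is None or channels is None:
            sidecar = path.with_suffix(".json")
            if not sidecar.exists():
                raise ValueError(
                    "matrix dialect needs fs and channel labels, either as "
                    f"arguments or in a sidecar {sidecar.name}"
                )
            meta = json.loads(sidecar.read_text())
            fs = float(meta["fs"]) if fs is None else fs
            channels = list(meta["channels"]) if channels is None else channels
        arr = np.loadtxt(path, delimiter=_sniff_delimiter(path), ndmin=2)
        if arr.shape[1] != len(channels):
            raise ValueError(
                f"matrix has {arr.shape[1]} columns but {len(channels)} "
                "channel labels were supplied"
            )
        return Recording(sid, float(fs), tuple(channels), arr.T)
    raise ValueError(f"unknown dialect {dialect!r}")


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def write_matrix_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording in the matrix dialect (CSV + JSON sidecar)."""
    path = Path(path)
    np.savetxt(path, rec.data.T, delimiter=",", fmt="%.8g")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(
        {"fs": rec.fs, "channels": list(rec.channels),
         "subject_id": rec.subject_id}))


# -- subject table ----------------------------------------------------------

#: Continuous cognitive scores the index can be trained against.
SCORE_COLUMNS = ("MoCA", "PVT", "PCPST", "DCCST", "FICAT", "PSMT")


def read_subject_table(path: str | Path) -> pd.DataFrame:
    """Read the per-subject table (CSV/TSV; empty cells = missing).

    Requires ``id`` plus at least one cognitive-score column; validates
    id uniqueness and the 0-30 MoCA range.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=None, engine="python")
    if "id" not in table.columns:
        raise ValueError("subject table must have an 'id' column")
    table["id"] = table["id"].astype(str)
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    if not any(c in table.columns for c in SCORE_COLUMNS):
        raise ValueError(
            f"subject table needs at least one score column among {SCORE_COLUMNS}"
        )
    if "MoCA" in table.columns:
        moca = table["MoCA"].dropna()
        if ((moca < 0) | (moca > 30)).any():
            raise ValueError("MoCA scores must lie in [0, 30]")
    return table


# -- fixed preprocessing ----------------------------------------------------


def normalize_energy(x: np.ndarray) -> np.ndarray:
    """Scale a signal to unit total energy (sum of squared samples = 1)."""
    x = np.asarray(x, dtype=float)
    energy = float(np.sum(x * x))
    if energy == 0.0:
        raise ValueError("all-zero signal: cannot normalize a degenerate channel")
    return x / np.sqrt(energy)


def remove_line_noise(
    x: np.ndarray,
    fs: float,
    freqs=DEFAULT_NOTCH_FREQS,
    halfwidth: float = 0.5,
) -> np.ndarray:
    """Eliminate narrowband contamination in the frequency domain.

    All real-FFT bins within ``halfwidth`` Hz of each target frequency are
    zeroed and the signal inverse-transformed; conjugate symmetry is
    preserved by construction so the output is exactly real and the same
    length as the input.
    """
    x = np.asarray(x, dtype=float)
    nyq = fs / 2.0
    for f0 in freqs:
        if f0 >= nyq:
            raise ValueError(f"line frequency {f0} Hz is at or above Nyquist ({nyq} Hz)")
    spectrum = np.fft.rfft(x)
    grid = np.fft.rfftfreq(x.size, d=1.0 / fs)
    for f0 in freqs:
        spectrum[np.abs(grid - f0) <= halfwidth] = 0.0
    return np.fft.irfft(spectrum, n=x.size)


def bandpass(
    x: np.ndarray,
    fs: float,
    band: BandRange | tuple[float, float],
    order: int = 6,
) -> np.ndarray:
    """Zero-phase Butterworth bandpass.

    ``order`` is the full bandpass filter order (default 6); the filter is
    applied forward and backward (zero net phase shift, squared magnitude
    response), with reflective edge padding of length ``3 * (order + 1)``
    to suppress transients.
    """
    if not isinstance(band, BandRange):
        band = BandRange(*band)
    band.validate(fs)
    if order % 2:
        raise ValueError("bandpass order must be even")
    x = np.asarray(x, dtype=float)
    padlen = 3 * (order + 1)
    if x.size <= padlen:
        raise ValueError(
            f"signal too short ({x.size} samples) for stable zero-phase "
            f"filtering (needs > {padlen})"
        )
    sos = _signal.butter(order // 2, (band.f_lo, band.f_hi),
                         btype="bandpass", fs=fs, output="sos")
    return _signal.sosfiltfilt(sos, x, padtype="even", padlen=padlen)


def preprocess_recording(
    rec: Recording, notch_freqs=DEFAULT_NOTCH_FREQS
) -> Recording:
    """Apply the fixed per-recording pipeline: normalize, then de-noise.

    Energy normalization precedes line-noise removal; both act per
    channel. The per-configuration bandpass is *not* applied here — it
    belongs to scoring time, where the frequency range is a tunable
    parameter.
    """
    cleaned = np.empty_like(rec.data)
    for i in range(rec.data.shape[0]):
        cleaned[i] = remove_line_noise(
            normalize_energy(rec.data[i]), rec.fs, notch_freqs
        )
    return Recording(rec.subject_id, rec.fs, rec.channels, cleaned)
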