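"""Traditional spectral comparators: band powers and topographies.

Canonical EEG bands: delta (1-4 Hz), theta (4-8), alpha (8-13), beta
(13-30), gamma (31-100). Band power is the integral of a power
spectral density over ``[f_lo, f_hi)``. By default the PSD is the
full-length periodogram: integrating over a band already averages many
independent bins, and the unsegmented estimate partitions the total
signal power exactly (Parseval), which segment-averaged estimates only
do approximately. Welch averaging (Hann segments, 50% overlap) is
available through ``seg_seconds`` for callers who want smoothed
per-bin spectra. The alpha/theta log ratio is log10 of the power
quotient.
Correlation topographies report per-electrode age-adjusted partial
Spearman correlations between a spectral feature and a cognitive
score, flagged at p < 0.05 (uncorrected).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .evaluation import partial_spearman

__all__ = [
    "CANONICAL_BANDS",
    "band_power",
    "band_power_table",
    "alpha_theta_log_ratio",
    "correlation_topography",
]

CANONICAL_BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (31.0, 100.0),
}


def _psd(x: np.ndarray, fs: float, seg_seconds: float | None):
    if seg_seconds is None:
        return _signal.periodogram(x, fs=fs, window="boxcar",
                                   detrend=False, scaling="density")
    nperseg = min(int(round(seg_seconds * fs)), x.size)
    return _signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                         noverlap=nperseg // 2, detrend=False,
                         scaling="density")


def band_power(x: np.ndarray, fs: float, band: tuple[float, float],
               seg_seconds: float | None = None) -> float:
    """Integrated PSD over [f_lo, f_hi); scale-equivariant (c^2).

    ``seg_seconds=None`` (default) integrates the full-length
    periodogram; a value selects Welch averaging with that segment
    length in seconds.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"invalid band {band}")
    if f_hi >= fs / 2:
        raise ValueError(f"band upper edge {f_hi} Hz must be below Nyquist")
    x = np.asarray(x, dtype=float)
    freqs, psd = _psd(x, fs, seg_seconds)
    mask = (freqs >= f_lo) & (freqs < f_hi)
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def alpha_theta_log_ratio(x: np.ndarray, fs: float,
                          seg_seconds: float | None = None,
                          base: float = 10.0) -> float:
    """log_base of alpha over theta band power (base 10 by default)."""
    alpha = band_power(x, fs, CANONICAL_BANDS["alpha"], seg_seconds)
    theta = band_power(x, fs, CANONICAL_BANDS["theta"], seg_seconds)
    if theta <= 0 or alpha <= 0:
        raise ValueError("band powers must be positive for a log ratio")
    return float(np.log(alpha / theta) / np.log(base))


def band_power_table(recordings, electrodes=None,
                     bands: dict | None = None,
                     seg_seconds: float | None = None) -> pd.DataFrame:
    """Subjects x (electrode, band) feature matrix of band powers."""
    if bands is None:
        bands = CANONICAL_BANDS
    rows = {}
    for sid, rec in recordings.items():
        labels = electrodes if electrodes is not None else rec.channels
        row = {}
        for el in labels:
            x = rec.channel(el)
            for name, rng in bands.items():
                row[f"{el}_{name}"] = band_power(x, rec.fs, rng, seg_seconds)
        rows[sid] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def correlation_topography(features: pd.DataFrame, scores, ages=None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-electrode partial Spearman correlation of a feature with a score.

    ``features`` is subjects x electrodes (one feature per electrode,
    aligned to ``scores``/``ages`` by row order). Returns a frame with
    rho, p and a significance flag per electrode.
    """
    scores = np.asarray(scores, dtype=float)
    if len(features) != scores.size:
        raise ValueError("features and scores are misaligned")
    if ages is not None:
        ages = np.asarray(ages, dtype=float)
        if ages.size != scores.size:
            raise ValueError("features and ages are misaligned")
    rows = []
    for col in features.columns:
        rho, p = partial_spearman(features[col].to_numpy(dtype=float),
                                  scores, None if ages is None else ages)
        rows.append({"electrode": col, "rho": rho, "p": p,
                     "significant": p < alpha})
    return pd.DataFrame(rows).set_index("electrode")
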