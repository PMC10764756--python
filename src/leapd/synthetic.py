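"""Synthetic resting-state EEG cohorts with score-linked oscillations.

The generator emulates the statistical structure the cognitive index
assumes: each subject carries a latent cognition score (stored as MoCA)
and, on a configurable set of *informative* electrodes, the EEG
contains

* a theta-alpha AR resonance whose center frequency increases linearly
  with the score (spanning roughly 7-13 Hz over the score range by
  default),
* a beta AR resonance (~19 Hz) whose amplitude increases linearly with
  the score,
* a 1/f (pink) background, a 60 Hz mains sinusoid, and white noise.

Uninformative electrodes carry only background, mains and noise, so
electrode selection has a ground truth. All randomness flows from a
Philox counter-based generator keyed by the cohort seed, making
cohorts bit-reproducible across runs and platforms.

What this deliberately does not emulate: artifacts (blinks, movement),
nonstationarity, volume-conduction correlations between channels, and
the heavy-tailed score distributions of clinical samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Recording

__all__ = ["CohortSpec", "SyntheticCohort", "generate_cohort",
           "generate_worked_example", "write_cohort"]

#: 60-channel 10-10 montage used in the emulated study setup.
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8", "F7", "F5", "F3", "F1",
    "Fz", "F2", "F4", "F6", "F8", "FT7", "FC5", "FC3", "FC1", "FCz",
    "FC2", "FC4", "FC6", "FT8", "T7", "C5", "C3", "C1", "Cz", "C2",
    "C4", "C6", "T8", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4",
    "CP6", "TP8", "P7", "P5", "P3", "P1", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "F9", "F10",
)

#: Electrodes carrying the score-linked oscillations by default
#: (the central-parietal set where cognition effects concentrate).
DEFAULT_INFORMATIVE = ("P8", "PO7", "CP1", "CP2", "P6", "O2", "P4", "F4")


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings; the defaults emulate the study conditions.

    ``ta_base``/``ta_slope`` place the theta-alpha resonance at
    ``ta_base + ta_slope * (score - score_range[0])`` Hz;
    ``beta_amp_base``/``beta_amp_slope`` scale the beta resonance RMS
    the same way. Component levels are RMS values relative to the
    theta-alpha resonance (1.0).
    """

    n_subjects: int = 149
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    informative: tuple[str, ...] = DEFAULT_INFORMATIVE
    fs: float = 500.0
    duration: float = 160.0            # seconds (~2.6 min recordings)
    score_range: tuple[int, int] = (9, 30)
    age_mean: float = 68.0
    age_sd: float = 8.0
    ta_base: float = 7.0               # Hz at the lowest score
    ta_slope: float = 6.0 / 21.0       # Hz per score unit (7->13 over range)
    ta_pole: float = 0.97
    beta_freq: float = 19.0            # Hz, fixed
    beta_pole: float = 0.95
    beta_amp_base: float = 0.4         # RMS at the lowest score
    beta_amp_slope: float = 0.04       # RMS per score unit
    background_level: float = 1.0      # pink-noise RMS
    background_exponent: float = 1.0   # 1/f^exponent power slope
    line_amp: float = 0.5              # 60 Hz component RMS
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")
        if not set(self.informative) <= set(self.channels):
            raise ValueError("informative electrodes must be among channels")
        if not (0 < self.ta_pole < 1 and 0 < self.beta_pole < 1):
            raise ValueError("pole magnitudes must lie in (0, 1)")
        if self.duration * self.fs < 100:
            raise ValueError("recordings too short for any LPC fit")
        if self.score_range[0] >= self.score_range[1]:
            raise ValueError("invalid score range")


@dataclass
class SyntheticCohort:
    """Recordings, subject table, and the generating ground truth."""

    spec: CohortSpec
    recordings: dict[str, Recording] = field(repr=False)
    table: pd.DataFrame = field(repr=False)
    ground_truth: pd.DataFrame = field(repr=False)


def _ar_resonator(rng: np.random.Generator, n: int, freq: float, fs: float,
                  pole: float) -> np.ndarray:
    """Unit-RMS narrowband noise: white noise through a 2-pole AR filter."""
    from scipy.signal import lfilter

    theta = 2.0 * np.pi * freq / fs
    a = [1.0, -2.0 * pole * np.cos(theta), pole * pole]
    x = lfilter([1.0], a, rng.standard_normal(n))
    return x / np.sqrt(np.mean(x * x))


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-RMS 1/f^exponent noise by spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    return x / np.sqrt(np.mean(x * x))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a deterministic cohort from the spec's Philox-seeded stream."""
    rng = np.random.Generator(np.random.Philox(spec.seed))
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    lo, hi = spec.score_range
    records = []
    truth_rows = []
    recordings = {}
    for subj in range(spec.n_subjects):
        sid = f"S{subj + 1:03d}"
        score = int(rng.integers(lo, hi + 1))
        age = float(np.clip(rng.normal(spec.age_mean, spec.age_sd), 40, 95))
        sex = "M" if rng.random() < 0.5 else "F"
        group = "PD" if rng.random() < 0.67 else "control"
        f_ta = spec.ta_base + spec.ta_slope * (score - lo)
        beta_amp = spec.beta_amp_base + spec.beta_amp_slope * (score - lo)
        data = np.empty((len(spec.channels), n))
        for ch_idx, label in enumerate(spec.channels):
            sig = (spec.background_level
                   * _pink_noise(rng, n, spec.background_exponent))
            sig = sig + spec.line_amp * np.sqrt(2.0) * np.sin(
                2.0 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
            sig = sig + spec.noise_sd * rng.standard_normal(n)
            if label in spec.informative:
                sig = sig + _ar_resonator(rng, n, f_ta, spec.fs, spec.ta_pole)
                sig = sig + beta_amp * _ar_resonator(
                    rng, n, spec.beta_freq, spec.fs, spec.beta_pole)
            data[ch_idx] = sig
        recordings[sid] = Recording(sid, spec.fs, spec.channels, data)
        records.append({"id": sid, "age": round(age, 1), "sex": sex,
                        "group": group, "MoCA": score})
        truth_rows.append({"id": sid, "score": score,
                           "theta_alpha_freq": f_ta,
                           "beta_amplitude": beta_amp})
    table = pd.DataFrame(records)
    truth = pd.DataFrame(truth_rows).set_index("id")
    return SyntheticCohort(spec, recordings, table, truth)


def generate_worked_example() -> SyntheticCohort:
    """Small fixed cohort (8 subjects, 2 electrodes, 10 s) for fast tests."""
    spec = CohortSpec(
        n_subjects=8,
        channels=("P8", "PO7"),
        informative=("P8", "PO7"),
        duration=10.0,
        seed=11,  # gives a 5/3 impaired/normal split, LOOCV-safe
    )
    return generate_cohort(spec)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort in the matrix dialect plus a subject-table CSV."""
    from pathlib import Path

    from .io import write_matrix_recording

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, rec in cohort.recordings.items():
        write_matrix_recording(rec, out / f"{sid}.csv")
    cohort.table.to_csv(out / "subjects.csv", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.csv")
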