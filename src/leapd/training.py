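"""Training: group construction, parameter search, and the fitted model.

The trainable parameters, per electrode, are the bandpass range (2-34 Hz
search domain), the LPC order K (2-10), and the affine-subspace
dimension n (1..K-1). They are optimized by exhaustive search,
maximizing the Spearman rank correlation between out-of-fold
single-electrode indices (from a single round of subject-level
stratified 10-fold cross-validation) and the continuous cognitive
score. Electrodes are then ranked by their best cross-validated rho and
the top k (default 8) combined by geometric mean.

Group construction: for MoCA the impaired group is score < 26 and the
normal group score >= 26; for the NIH-Toolbox scores the cutoff is the
median across included subjects (score < median -> low group).

The grid search shares work aggressively: one zero-phase filter pass
per (subject, band), one Levinson-Durbin recursion per filtered signal
(yielding every order at once), and one SVD per (fold, group, K)
(yielding every subspace dimension at once via basis prefixes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import DEFAULT_NOTCH_FREQS, BandRange, Recording, bandpass
from .lpc import _autocorrelation, fit_lpc, levinson_durbin
from .subspace import (AffineSubspace, IndexResult, SubspacePair,
                       combine_indices, fit_affine_subspace, leapd_index)

__all__ = [
    "ElectrodeConfig",
    "GridSpec",
    "SearchEntry",
    "LEAPDModel",
    "split_groups",
    "stratified_folds",
    "single_electrode_index_cv",
    "grid_search_electrode",
    "grid_search",
    "select_electrodes",
    "fit_model",
]

MOCA_CUTOFF = 26.0


@dataclass(frozen=True)
class ElectrodeConfig:
    """Per-electrode tunables: band (Hz), LPC order K, subspace dim n."""

    electrode: str
    band: tuple[float, float]
    order: int
    dim: int

    def __post_init__(self) -> None:
        BandRange(*self.band)
        if not (1 <= self.dim < self.order):
            raise ValueError(f"need 1 <= n < K, got n={self.dim}, K={self.order}")

    def to_dict(self) -> dict:
        return {"electrode": self.electrode, "band": list(self.band),
                "order": self.order, "dim": self.dim}

    @classmethod
    def from_dict(cls, d: dict) -> "ElectrodeConfig":
        return cls(d["electrode"], tuple(d["band"]), d["order"], d["dim"])


@dataclass(frozen=True)
class GridSpec:
    """Search grid: candidate bands and LPC orders (n ranges over 1..K-1).

    The default grid uses integer-Hz band endpoints within 2-34 Hz with a
    minimum width of 2 Hz (496 bands) and orders 2-10.
    """

    bands: tuple[tuple[float, float], ...]
    orders: tuple[int, ...]

    @classmethod
    def default(cls, f_min: float = 2.0, f_max: float = 34.0,
                min_width: float = 2.0, step: float = 1.0,
                orders=range(2, 11)) -> "GridSpec":
        bands = []
        lo = f_min
        while lo + min_width <= f_max:
            hi = lo + min_width
            while hi <= f_max:
                bands.append((lo, hi))
                hi += step
            lo += step
        return cls(tuple(bands), tuple(orders))

    @classmethod
    def small(cls) -> "GridSpec":
        """A coarse grid (4-Hz steps, orders {3, 5, 7}) for quick runs."""
        return cls.default(step=4.0, min_width=4.0, orders=(3, 5, 7))


@dataclass
class SearchEntry:
    """Best configuration found for one electrode plus its CV score."""

    electrode: str
    config: ElectrodeConfig
    rho: float
    grid_scores: pd.DataFrame | None = field(default=None, repr=False)


# -- group construction -----------------------------------------------------


def _included(table: pd.DataFrame, score_name: str) -> pd.DataFrame:
    if score_name not in table.columns:
        raise ValueError(f"subject table has no column {score_name!r}")
    return table.loc[table[score_name].notna(), ["id", score_name]]


def score_cutoff(scores: pd.Series, cutoff_rule: str) -> float:
    if cutoff_rule == "fixed26":
        return MOCA_CUTOFF
    if cutoff_rule == "median":
        return float(np.median(scores.to_numpy(dtype=float)))
    raise ValueError(f"unknown cutoff rule {cutoff_rule!r}")


def default_cutoff_rule(score_name: str) -> str:
    return "fixed26" if score_name == "MoCA" else "median"


def split_groups(table: pd.DataFrame, score_name: str = "MoCA",
                 cutoff_rule: str | None = None) -> tuple[list[str], list[str]]:
    """Partition subjects into (impaired/low, normal/high) id lists.

    Subjects with a missing score are excluded. ``score < cutoff`` goes
    to the impaired (low) group, ``score >= cutoff`` to the normal
    (high) group; the cutoff is 26 for MoCA and the cohort median for
    the NIH-Toolbox scores.
    """
    if cutoff_rule is None:
        cutoff_rule = default_cutoff_rule(score_name)
    inc = _included(table, score_name)
    cutoff = score_cutoff(inc[score_name], cutoff_rule)
    low = inc.loc[inc[score_name] < cutoff, "id"].tolist()
    high = inc.loc[inc[score_name] >= cutoff, "id"].tolist()
    if not low or not high:
        raise ValueError(
            f"degenerate split for {score_name} at cutoff {cutoff}: "
            f"{len(low)} impaired vs {len(high)} normal")
    return low, high


def stratified_folds(ids: list[str], impaired: set[str], n_folds: int,
                     seed: int) -> list[list[str]]:
    """Shuffled subject-level folds, stratified by impaired/normal label.

    Each group is permuted with a Philox counter-based generator keyed
    by ``seed`` and dealt round-robin, so fold sizes differ by at most
    one within each group and the partition is reproducible.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > len(ids):
        raise ValueError(f"{n_folds} folds for only {len(ids)} subjects")
    rng = np.random.Generator(np.random.Philox(seed))
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    j = 0  # the deal continues across groups so no fold is left empty
    for group in (sorted(i for i in ids if i in impaired),
                  sorted(i for i in ids if i not in impaired)):
        order = rng.permutation(len(group))
        for idx in order:
            folds[j % n_folds].append(group[idx])
            j += 1
    return folds


# -- shared numerical core ---------------------------------------------------


def _band_coefficients(recordings: dict[str, Recording], ids: list[str],
                       electrode: str, band: tuple[float, float],
                       orders: tuple[int, ...]) -> dict[str, list[np.ndarray]]:
    """Per subject: LPC coefficient vectors for every requested order.

    One bandpass and one Levinson-Durbin recursion per subject; the
    recursion yields all orders up to max(orders) simultaneously.
    """
    max_order = max(orders)
    out = {}
    for sid in ids:
        rec = recordings[sid]
        x = bandpass(rec.channel(electrode), rec.fs, band)
        r = _autocorrelation(x, max_order)
        coeffs, _ = levinson_durbin(r, max_order)
        out[sid] = coeffs
    return out


def _group_projector(vectors: np.ndarray):
    """Mean, right singular vectors and numeric rank of a training group."""
    mean = vectors.mean(axis=0)
    centered = (vectors - mean) / np.sqrt(max(vectors.shape[0] - 1, 1))
    _, svals, vh = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > 1e-12 * svals[0])) if svals.size and svals[0] > 0 else 0
    return mean, vh, rank


def _distance_profile(a: np.ndarray, mean: np.ndarray, vh: np.ndarray,
                      rank: int, max_n: int) -> np.ndarray:
    """Distances to the affine subspace for every dimension n = 1..max_n.

    Exploits the prefix property of the SVD basis: the n-dimensional
    basis is the first n rows of vh, so squared residuals fall by the
    squared projection coefficients cumulatively. Dimensions beyond the
    numeric rank reuse the rank-limited distance.
    """
    resid = a - mean
    total = float(resid @ resid)
    coords = vh @ resid
    usable = min(max_n, rank, coords.size)
    cum = np.cumsum(coords[:usable] ** 2)
    prof = np.empty(max_n)
    prof[:usable] = np.sqrt(np.maximum(total - cum, 0.0))
    if usable < max_n:
        prof[usable:] = prof[usable - 1] if usable else np.sqrt(total)
    return prof


def _cv_index_profiles(recordings, ids, impaired_set, electrode,
                       band, orders, folds_part):
    """Out-of-fold index profiles for one band over all (K, n) pairs.

    Returns ``{K: array (n_subjects, K-1)}`` with the out-of-fold index
    of every subject for each subspace dimension n (columns), plus the
    maximum feasible n per K given fold group sizes.
    """
    coeffs = _band_coefficients(recordings, ids, electrode, band, orders)
    pos = {sid: i for i, sid in enumerate(ids)}
    min_group = min(
        min(sum(1 for s in ids if s not in fold and s in impaired_set),
            sum(1 for s in ids if s not in fold and s not in impaired_set))
        for fold in folds_part)
    profiles = {}
    n_max_by_order = {}
    for k_ord in orders:
        n_max = min(k_ord - 1, min_group - 1)
        if n_max < 1:
            raise ValueError(
                "a fold's training split leaves a group too small to fit "
                f"any subspace (min group size {min_group})")
        prof = np.empty((len(ids), n_max))
        for fold in folds_part:
            fold_set = set(fold)
            train = [s for s in ids if s not in fold_set]
            v_imp = np.vstack([coeffs[s][k_ord] for s in train
                               if s in impaired_set])
            v_norm = np.vstack([coeffs[s][k_ord] for s in train
                                if s not in impaired_set])
            m_i, vh_i, r_i = _group_projector(v_imp)
            m_n, vh_n, r_n = _group_projector(v_norm)
            for sid in fold:
                a = coeffs[sid][k_ord]
                d_imp = _distance_profile(a, m_i, vh_i, r_i, n_max)
                d_norm = _distance_profile(a, m_n, vh_n, r_n, n_max)
                tot = d_imp + d_norm
                row = np.where(tot > 0, d_imp / np.where(tot > 0, tot, 1.0), 0.5)
                prof[pos[sid]] = row
        profiles[k_ord] = prof
        n_max_by_order[k_ord] = n_max
    return profiles, n_max_by_order


# -- public training operations ---------------------------------------------


def single_electrode_index_cv(recordings: dict[str, Recording],
                              table: pd.DataFrame, electrode: str,
                              config: ElectrodeConfig, folds: int = 10,
                              seed: int = 0, score_name: str = "MoCA",
                              cutoff_rule: str | None = None) -> pd.Series:
    """Out-of-fold single-electrode indices for one fixed configuration.

    Subjects are partitioned at subject level (stratified, seeded); each
    subject is scored by subspaces fitted on the other folds only.
    """
    imp, norm = split_groups(table, score_name, cutoff_rule)
    ids = [s for s in table["id"] if s in set(imp + norm)]  # table order
    part = stratified_folds(ids, set(imp), folds, seed)
    profiles, n_max = _cv_index_profiles(
        recordings, ids, set(imp), electrode, config.band,
        (config.order,), part)
    n_eff = min(config.dim, n_max[config.order])
    values = profiles[config.order][:, n_eff - 1]
    return pd.Series(values, index=ids, name=electrode)


def grid_search_electrode(recordings: dict[str, Recording],
                          table: pd.DataFrame, electrode: str,
                          grid: GridSpec, folds: int = 10, seed: int = 0,
                          score_name: str = "MoCA",
                          cutoff_rule: str | None = None,
                          return_grid: bool = False) -> SearchEntry:
    """Exhaustive search over (band, K, n) maximizing cross-validated rho.

    The fold partition is drawn once from ``seed`` and shared by every
    configuration, making the search a single round of k-fold CV. Ties
    in rho are broken deterministically toward the narrower band, then
    smaller K, smaller n, and lower band edge, so the result does not
    depend on grid enumeration order.
    """
    if not grid.bands or not grid.orders:
        raise ValueError("empty search grid")
    imp, norm = split_groups(table, score_name, cutoff_rule)
    ids = [s for s in table["id"] if s in set(imp + norm)]
    score_map = _included(table, score_name).set_index("id")[score_name]
    scores = score_map.loc[ids].to_numpy(dtype=float)
    part = stratified_folds(ids, set(imp), folds, seed)

    best_key = None
    best: tuple[ElectrodeConfig, float] | None = None
    rows = []
    for band in grid.bands:
        profiles, n_max = _cv_index_profiles(
            recordings, ids, set(imp), electrode, band,
            tuple(grid.orders), part)
        for k_ord in grid.orders:
            prof = profiles[k_ord]
            for n in range(1, n_max[k_ord] + 1):
                rho = float(_stats.spearmanr(prof[:, n - 1], scores).statistic)
                if np.isnan(rho):
                    rho = 0.0
                if return_grid:
                    rows.append({"f_lo": band[0], "f_hi": band[1],
                                 "order": k_ord, "dim": n, "rho": rho})
                key = (rho, -(band[1] - band[0]), -k_ord, -n, -band[0])
                if best_key is None or key > best_key:
                    best_key = key
                    best = (ElectrodeConfig(electrode, band, k_ord, n), rho)
    config, rho = best
    grid_df = pd.DataFrame(rows) if return_grid else None
    return SearchEntry(electrode, config, rho, grid_df)


def grid_search(recordings: dict[str, Recording], table: pd.DataFrame,
                electrodes, grid: GridSpec, folds: int = 10, seed: int = 0,
                score_name: str = "MoCA",
                cutoff_rule: str | None = None) -> list[SearchEntry]:
    """Run :func:`grid_search_electrode` over a list of electrodes."""
    return [grid_search_electrode(recordings, table, el, grid, folds, seed,
                                  score_name, cutoff_rule)
            for el in electrodes]


def select_electrodes(results: list[SearchEntry], k: int = 8) -> list[SearchEntry]:
    """Top-k electrodes by best cross-validated rho (descending).

    Ties keep the earlier entry in the input (channel-list) order —
    ``sorted`` is stable, so equal-rho electrodes preserve their
    relative position.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(results):
        raise ValueError(f"k={k} exceeds the {len(results)} searched electrodes")
    ranked = sorted(results, key=lambda e: -e.rho)
    return ranked[:k]


# -- the fitted, serializable model -----------------------------------------


@dataclass
class LEAPDModel:
    """A trained index: per-electrode configs plus fitted subspace pairs.

    The classification threshold is fixed at 0.5 (index < 0.5 predicts
    cognitive impairment); ``fs`` and ``notch_freqs`` record the
    preprocessing provenance the model expects.
    """

    score_name: str
    cutoff_rule: str
    fs: float
    configs: list[ElectrodeConfig]
    pairs: dict[str, SubspacePair] = field(repr=False)
    notch_freqs: tuple[float, ...] = DEFAULT_NOTCH_FREQS
    threshold: float = 0.5
    seed: int | None = None

    @property
    def electrodes(self) -> list[str]:
        return [c.electrode for c in self.configs]

    def score_recording(self, rec: Recording) -> IndexResult:
        """Index a preprocessed recording (all model electrodes required)."""
        if rec.fs != self.fs:
            raise ValueError(
                f"recording sampled at {rec.fs} Hz but model expects {self.fs} Hz")
        per = {}
        for cfg in self.configs:
            x = bandpass(rec.channel(cfg.electrode), rec.fs, cfg.band)
            a = fit_lpc(x, cfg.order, rec.fs).coefficients
            per[cfg.electrode] = leapd_index(a, self.pairs[cfg.electrode])
        return IndexResult(per, combine_indices(list(per.values())))

    def to_json(self) -> str:
        doc = {
            "score_name": self.score_name,
            "cutoff_rule": self.cutoff_rule,
            "fs": self.fs,
            "notch_freqs": list(self.notch_freqs),
            "threshold": self.threshold,
            "seed": self.seed,
            "configs": [c.to_dict() for c in self.configs],
            "pairs": {label: p.to_dict() for label, p in self.pairs.items()},
        }
        return json.dumps(doc, sort_keys=True, indent=1)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def from_json(cls, text: str) -> "LEAPDModel":
        d = json.loads(text)
        return cls(
            score_name=d["score_name"], cutoff_rule=d["cutoff_rule"],
            fs=d["fs"],
            configs=[ElectrodeConfig.from_dict(c) for c in d["configs"]],
            pairs={k: SubspacePair.from_dict(v) for k, v in d["pairs"].items()},
            notch_freqs=tuple(d["notch_freqs"]), threshold=d["threshold"],
            seed=d["seed"])

    @classmethod
    def load(cls, path: str | Path) -> "LEAPDModel":
        return cls.from_json(Path(path).read_text())


def fit_subspace_pair(recordings: dict[str, Recording], cfg: ElectrodeConfig,
                      impaired: list[str], normal: list[str]) -> SubspacePair:
    """Fit the (impaired, normal) subspace pair for one configuration."""
    def group_fit(ids: list[str]) -> AffineSubspace:
        vecs = np.vstack([
            fit_lpc(bandpass(recordings[s].channel(cfg.electrode),
                             recordings[s].fs, cfg.band),
                    cfg.order, recordings[s].fs).coefficients
            for s in ids])
        return fit_affine_subspace(vecs, min(cfg.dim, len(ids) - 1))

    return SubspacePair(group_fit(impaired), group_fit(normal))


def fit_model(recordings: dict[str, Recording], table: pd.DataFrame,
              configs: list[ElectrodeConfig], score_name: str = "MoCA",
              cutoff_rule: str | None = None,
              seed: int | None = None) -> LEAPDModel:
    """Fit subspace pairs on all provided subjects for fixed configs."""
    if cutoff_rule is None:
        cutoff_rule = default_cutoff_rule(score_name)
    imp, norm = split_groups(table, score_name, cutoff_rule)
    fs = next(iter(recordings.values())).fs
    pairs = {cfg.electrode: fit_subspace_pair(recordings, cfg, imp, norm)
             for cfg in configs}
    return LEAPDModel(score_name=score_name, cutoff_rule=cutoff_rule, fs=fs,
                      configs=list(configs), pairs=pairs, seed=seed)
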