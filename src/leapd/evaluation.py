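"""Performance evaluation: cross-validation schemes and metrics.

Every scheme holds the electrode configurations fixed (they come from
training) and refits only the affine subspace pairs on each training
split, then scores held-out subjects. Metrics:

* correlation — age-adjusted partial Spearman rho between out-of-fold
  combined indices and the cognitive score;
* classification — index < 0.5 predicts cognitive impairment; accuracy,
  AUC (rank statistic with the impaired group as the low-index class),
  sensitivity/specificity/PPV/NPV in percent, odds ratio;
* regression — OLS of score on index (linear and quadratic): R^2, RMSE
  (raw scale and with both variables min-max scaled to [0, 1]),
  F-statistic vs the intercept-only model, Gaussian AIC, and a
  likelihood-ratio test of quadratic vs linear.

Robustness sweeps vary the number of combined electrodes and the
retained fraction of each recording (truncated from the end).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .io import DEFAULT_NOTCH_FREQS, Recording, preprocess_recording
from .subspace import (SubspacePair, combine_indices, fit_affine_subspace,
                       leapd_index)
from .training import (ElectrodeConfig, SearchEntry, _band_coefficients,
                       _included, default_cutoff_rule, score_cutoff,
                       stratified_folds)

__all__ = [
    "EvalReport",
    "loocv",
    "kfold_cv",
    "randomization_test",
    "partial_spearman",
    "classification_metrics",
    "regression_models",
    "electrode_sweep",
    "truncation_sweep",
]


@dataclass
class EvalReport:
    """Metrics bundle from one evaluation scheme."""

    scheme: str
    score_name: str
    indices: pd.Series = field(repr=False)
    rho: float
    rho_p: float
    classification: dict
    regression: dict
    seed: int | None = None

    @property
    def n(self) -> int:
        return len(self.indices)

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "score_name": self.score_name,
            "n": self.n,
            "seed": self.seed,
            "spearman_rho": self.rho,
            "spearman_p": self.rho_p,
            "classification": self.classification,
            "regression": self.regression,
            "indices": {k: float(v) for k, v in self.indices.items()},
        }


# -- statistics --------------------------------------------------------------


def partial_spearman(x, y, covariates=None) -> tuple[float, float]:
    """Spearman rank correlation, optionally partialling out covariates.

    All variables are rank-transformed (average ranks for ties); with
    covariates, x and y ranks are linearly adjusted for the covariate
    ranks (with intercept) and the Pearson correlation of the rank
    residuals is returned. The two-sided p value uses the t
    approximation with ``df = n - 2 - n_covariates``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input vector")
    rx = _stats.rankdata(x)
    ry = _stats.rankdata(y)
    n_cov = 0
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] == n and cov.shape[1] != n:
            cov = cov.T
        n_cov = cov.shape[0]
        design = np.column_stack(
            [np.ones(n)] + [_stats.rankdata(c) for c in cov])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise ValueError("residual rank variance is zero")
    rho = float(np.clip((rx @ ry) / denom, -1.0, 1.0))
    df = n - 2 - n_cov
    if df <= 0:
        raise ValueError("not enough observations for the covariate count")
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * _stats.t.sf(abs(t), df)
    return rho, float(p)


def classification_metrics(indices, labels, threshold: float = 0.5) -> dict:
    """Binary detection metrics with "impaired" as the positive class.

    ``labels`` is True for impaired subjects; ``index < threshold``
    predicts impairment (exactly 0.5 predicts normal). AUC is the
    Mann-Whitney rank statistic for the impaired group taking *lower*
    indices. A zero cell in the confusion table triggers the
    Haldane-Anscombe 0.5 correction for the odds ratio (flagged).
    """
    idx = np.asarray(indices, dtype=float)
    lab = np.asarray(labels, dtype=bool)
    if lab.all() or not lab.any():
        raise ValueError("AUC undefined: labels contain a single class")
    pred = idx < threshold
    tp = int(np.sum(pred & lab))
    fn = int(np.sum(~pred & lab))
    fp = int(np.sum(pred & ~lab))
    tn = int(np.sum(~pred & ~lab))
    n_imp, n_norm = tp + fn, fp + tn
    ranks = _stats.rankdata(idx)
    # probability a normal subject out-ranks an impaired one
    u_norm = float(np.sum(ranks[~lab])) - n_norm * (n_norm + 1) / 2.0
    auc = u_norm / (n_imp * n_norm)
    corrected = 0 in (tp, fn, fp, tn)
    if corrected:
        odds = ((tp + 0.5) * (tn + 0.5)) / ((fp + 0.5) * (fn + 0.5))
    else:
        odds = (tp * tn) / (fp * fn)

    def pct(a, b):
        return 100.0 * a / b if b else float("nan")

    return {
        "accuracy_pct": pct(tp + tn, len(idx)),
        "auc": auc,
        "sensitivity_pct": pct(tp, tp + fn),
        "specificity_pct": pct(tn, tn + fp),
        "ppv_pct": pct(tp, tp + fp),
        "npv_pct": pct(tn, tn + fn),
        "odds_ratio": float(odds),
        "odds_ratio_corrected": corrected,
        "confusion": {"tp": tp, "fn": fn, "fp": fp, "tn": tn},
    }


def _ols_block(y: np.ndarray, design: np.ndarray) -> dict:
    n = y.size
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    p_terms = design.shape[1] - 1  # slope terms beyond the intercept
    df_resid = n - design.shape[1]
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    if rss <= 0:
        f_stat, f_p = float("inf"), 0.0
    else:
        f_stat = ((tss - rss) / p_terms) / (rss / df_resid)
        f_p = float(_stats.f.sf(f_stat, p_terms, df_resid))
    aic = (n * np.log(rss / n) + 2.0 * (design.shape[1] + 1)
           if rss > 0 else -np.inf)
    return {"r2": r2, "rss": rss, "rmse": float(np.sqrt(rss / n)),
            "f_stat": float(f_stat), "f_p": f_p, "aic": float(aic),
            "coefficients": beta.tolist()}


def regression_models(index, score) -> dict:
    """Linear and quadratic OLS of score on index, plus an LRT.

    RMSE is reported both on the raw score scale and with both
    variables min-max scaled to [0, 1] (``rmse_scaled``); the scaling
    convention behind published index-RMSE magnitudes is not unique, so
    both are emitted. AIC uses the Gaussian profile form
    ``n ln(RSS/n) + 2 (n_params + 1)``.
    """
    x = np.asarray(index, dtype=float)
    y = np.asarray(score, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    lin = _ols_block(y, np.column_stack([np.ones(n), x]))
    quad = _ols_block(y, np.column_stack([np.ones(n), x, x * x]))
    for block in (lin, quad):
        block["rmse_scaled"] = (block["rmse"] / np.ptp(y)
                                if np.ptp(y) > 0 else float("nan"))
    if quad["rss"] <= 0:
        lrt_p = 0.0 if lin["rss"] > 0 else 1.0
    else:
        lrt = n * np.log(lin["rss"] / quad["rss"])
        lrt_p = float(_stats.chi2.sf(lrt, 1))
    return {"linear": lin, "quadratic": quad, "lrt_p": lrt_p}


# -- scheme plumbing ---------------------------------------------------------


def _config_vectors(recordings: dict[str, Recording], ids: list[str],
                    configs: list[ElectrodeConfig]) -> dict[str, dict[str, np.ndarray]]:
    """LPC coefficient vectors per electrode config, per subject."""
    out = {}
    for cfg in configs:
        coeffs = _band_coefficients(recordings, ids, cfg.electrode, cfg.band,
                                    (cfg.order,))
        out[cfg.electrode] = {sid: coeffs[sid][cfg.order] for sid in ids}
    return out


def _fit_pairs_from_vectors(vectors, configs, imp_ids, norm_ids):
    pairs = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rank truncation
        for cfg in configs:
            v = vectors[cfg.electrode]
            dim = min(cfg.dim, len(imp_ids) - 1, len(norm_ids) - 1)
            if dim < 1:
                raise ValueError(
                    "training split leaves a group with fewer than 2 subjects")
            pairs[cfg.electrode] = SubspacePair(
                fit_affine_subspace(np.vstack([v[s] for s in imp_ids]), dim),
                fit_affine_subspace(np.vstack([v[s] for s in norm_ids]), dim))
    return pairs


def _combined_index(vectors, configs, pairs, sid) -> float:
    per = [leapd_index(vectors[cfg.electrode][sid], pairs[cfg.electrode])
           for cfg in configs]
    return combine_indices(per)


def _metrics_report(scheme, indices, table, score_name, cutoff_rule,
                    seed=None) -> EvalReport:
    inc = _included(table, score_name).set_index("id")[score_name]
    scores = inc.loc[indices.index].to_numpy(dtype=float)
    ages = None
    if "age" in table.columns:
        age_map = table.set_index("id")["age"]
        if age_map.loc[indices.index].notna().all():
            ages = age_map.loc[indices.index].to_numpy(dtype=float)
    rho, rho_p = partial_spearman(indices.to_numpy(), scores, ages)
    cutoff = score_cutoff(inc, cutoff_rule)
    labels = scores < cutoff
    cls = classification_metrics(indices.to_numpy(), labels)
    reg = regression_models(indices.to_numpy(), scores)
    return EvalReport(scheme, score_name, indices, rho, rho_p, cls, reg,
                      seed=seed)


def loocv(recordings: dict[str, Recording], table: pd.DataFrame,
          configs: list[ElectrodeConfig], score_name: str = "MoCA",
          cutoff_rule: str | None = None) -> EvalReport:
    """Leave-one-out: each subject scored by subspaces refit without it.

    Electrode configurations stay fixed; only the subspace pairs are
    refit per held-out subject. The training-split cutoff (for the
    median rule) is recomputed on the training subjects to avoid
    leaking the held-out score.
    """
    if cutoff_rule is None:
        cutoff_rule = default_cutoff_rule(score_name)
    inc = _included(table, score_name).set_index("id")[score_name]
    ids = [s for s in table["id"] if s in inc.index]
    cutoff_full = score_cutoff(inc, cutoff_rule)
    n_imp = int((inc < cutoff_full).sum())
    if min(n_imp, len(ids) - n_imp) < 3:
        raise ValueError("leave-one-out needs at least 3 subjects per group")
    vectors = _config_vectors(recordings, ids, configs)
    values = []
    for sid in ids:
        train = [s for s in ids if s != sid]
        cutoff = score_cutoff(inc.loc[train], cutoff_rule)
        imp = [s for s in train if inc[s] < cutoff]
        norm = [s for s in train if inc[s] >= cutoff]
        if not imp or not norm:
            raise ValueError("leave-one-out emptied a training group")
        pairs = _fit_pairs_from_vectors(vectors, configs, imp, norm)
        values.append(_combined_index(vectors, configs, pairs, sid))
    series = pd.Series(values, index=ids, name="combined_index")
    return _metrics_report("loocv", series, table, score_name, cutoff_rule)


def kfold_cv(recordings: dict[str, Recording], table: pd.DataFrame,
             configs: list[ElectrodeConfig], k: int = 10, rounds: int = 100,
             seed: int = 0, score_name: str = "MoCA",
             cutoff_rule: str | None = None):
    """k-fold CV over independent stratified shuffles.

    Returns ``(reports, summary)`` where ``summary`` holds the mean and
    standard deviation of each scalar metric across rounds. Round r
    derives its fold seed deterministically from ``seed``.
    """
    if k < 2 or rounds < 1:
        raise ValueError("need k >= 2 and rounds >= 1")
    if cutoff_rule is None:
        cutoff_rule = default_cutoff_rule(score_name)
    inc = _included(table, score_name).set_index("id")[score_name]
    ids = [s for s in table["id"] if s in inc.index]
    vectors = _config_vectors(recordings, ids, configs)
    cutoff_all = score_cutoff(inc, cutoff_rule)
    impaired_all = {s for s in ids if inc[s] < cutoff_all}
    reports = []
    for rnd in range(rounds):
        fold_seed = (seed + 7919 * rnd) % (2 ** 31)
        part = stratified_folds(ids, impaired_all, k, fold_seed)
        values = pd.Series(index=ids, dtype=float, name="combined_index")
        for fold in part:
            fold_set = set(fold)
            train = [s for s in ids if s not in fold_set]
            cutoff = score_cutoff(inc.loc[train], cutoff_rule)
            imp = [s for s in train if inc[s] < cutoff]
            norm = [s for s in train if inc[s] >= cutoff]
            if not imp or not norm:
                raise ValueError("a fold's training split emptied a group")
            pairs = _fit_pairs_from_vectors(vectors, configs, imp, norm)
            for sid in fold:
                values[sid] = _combined_index(vectors, configs, pairs, sid)
        rep = _metrics_report(f"kfold(k={k})", values, table, score_name,
                              cutoff_rule, seed=fold_seed)
        reports.append(rep)
    summary = _summarize(reports)
    return reports, summary


def _summarize(reports: list[EvalReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        row = {"spearman_rho": rep.rho,
               "accuracy_pct": rep.classification["accuracy_pct"],
               "auc": rep.classification["auc"],
               "sensitivity_pct": rep.classification["sensitivity_pct"],
               "specificity_pct": rep.classification["specificity_pct"],
               "linear_r2": rep.regression["linear"]["r2"],
               "quadratic_r2": rep.regression["quadratic"]["r2"]}
        rows.append(row)
    df = pd.DataFrame(rows)
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})


def randomization_test(recordings: dict[str, Recording], table: pd.DataFrame,
                       configs: list[ElectrodeConfig], seed: int = 0,
                       score_name: str = "MoCA",
                       cutoff_rule: str | None = None,
                       identity: bool = False) -> EvalReport:
    """Shuffle cognitive scores among subjects, then run leave-one-out.

    The permutation (a bijection of the score multiset, drawn from a
    Philox generator keyed by ``seed``) feeds the full pipeline: groups
    are re-split from the shuffled scores at every training split. With
    ``identity=True`` the permutation is forced to the identity, which
    must reproduce the plain LOOCV report (a self-check hook).
    """
    shuffled = table.copy()
    mask = shuffled[score_name].notna().to_numpy()
    vals = shuffled.loc[mask, score_name].to_numpy()
    if not identity:
        rng = np.random.Generator(np.random.Philox(seed))
        vals = vals[rng.permutation(vals.size)]
    shuffled.loc[mask, score_name] = vals
    rep = loocv(recordings, shuffled, configs, score_name, cutoff_rule)
    rep.scheme = "randomization"
    rep.seed = seed
    return rep


# -- robustness sweeps -------------------------------------------------------


def electrode_sweep(recordings: dict[str, Recording], table: pd.DataFrame,
                    ranked: list[SearchEntry], counts=None,
                    score_name: str = "MoCA",
                    cutoff_rule: str | None = None) -> pd.DataFrame:
    """LOOCV metrics while combining the top-c electrodes, c in counts.

    ``ranked`` must list electrodes from best to worst single-electrode
    performance (as produced by training); each curve point combines
    the leading ``c`` entries.
    """
    if counts is None:
        counts = range(1, len(ranked) + 1)
    counts = list(counts)
    if max(counts) > len(ranked):
        raise ValueError("counts exceed the number of ranked electrodes")
    rows = []
    for c in counts:
        configs = [e.config for e in ranked[:c]]
        rep = loocv(recordings, table, configs, score_name, cutoff_rule)
        rows.append({"n_electrodes": c, "rho": rep.rho,
                     "accuracy_pct": rep.classification["accuracy_pct"],
                     "auc": rep.classification["auc"]})
    return pd.DataFrame(rows)


def truncation_sweep(raw_recordings: dict[str, Recording],
                     table: pd.DataFrame, configs: list[ElectrodeConfig],
                     fractions=tuple(range(10, 101, 5)),
                     notch_freqs=DEFAULT_NOTCH_FREQS,
                     score_name: str = "MoCA",
                     cutoff_rule: str | None = None) -> pd.DataFrame:
    """LOOCV metrics after truncating each recording from the end.

    ``fractions`` are retained percentages; each recording keeps its
    leading ``ceil(fraction * N)`` samples, the fixed preprocessing is
    re-run on the truncated signals, and the full LOOCV is repeated.
    """
    fractions = sorted(fractions)
    max_order = max(cfg.order for cfg in configs)
    rows = []
    for frac_pct in fractions:
        frac = frac_pct / 100.0
        trunc = {}
        for sid, rec in raw_recordings.items():
            cut = rec.truncated(frac)
            if cut.n_samples < 10 * max_order:
                raise ValueError(
                    f"truncation to {frac_pct}% leaves {cut.n_samples} samples, "
                    f"below the 10*K = {10 * max_order} minimum")
            trunc[sid] = preprocess_recording(cut, notch_freqs)
        rep = loocv(trunc, table, configs, score_name, cutoff_rule)
        rows.append({"fraction_pct": frac_pct, "rho": rep.rho,
                     "accuracy_pct": rep.classification["accuracy_pct"],
                     "auc": rep.classification["auc"]})
    return pd.DataFrame(rows)
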