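"""Cross-validation schemes, statistics, and robustness sweeps."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import roc_auc_score

import leapd
from conftest import make_table


def _separable_cohort(seed=0, n=60):
    """Cohort subset with a wide score gap (non-overlapping group spectra)."""
    spec = leapd.CohortSpec(n_subjects=n, channels=("P8", "PO7"),
                            informative=("P8", "PO7"), duration=20.0,
                            seed=seed)
    cohort = leapd.generate_cohort(spec)
    keep = cohort.table["MoCA"].le(13) | cohort.table["MoCA"].ge(28)
    table = cohort.table.loc[keep].reset_index(drop=True)
    pre = {s: leapd.preprocess_recording(cohort.recordings[s])
           for s in table["id"]}
    return pre, table


class TestPartialSpearman:
    def test_identity_gives_rho_one(self, rng):
        x = rng.standard_normal(30)
        rho, p = leapd.partial_spearman(x, x)
        assert rho == 1.0
        assert p == 0.0

    def test_matches_scipy_without_covariates(self, rng):
        for _ in range(5):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40) + 0.4 * x
            rho, _ = leapd.partial_spearman(x, y)
            assert rho == pytest.approx(
                stats.spearmanr(x, y).statistic, abs=1e-12)

    def test_constant_covariate_equals_plain_spearman(self, rng):
        x = rng.standard_normal(25)
        y = rng.standard_normal(25)
        plain, _ = leapd.partial_spearman(x, y)
        # a constant covariate has constant ranks, absorbed by the intercept
        adj, _ = leapd.partial_spearman(x, y, np.full(25, 3.0))
        assert adj == pytest.approx(plain, abs=1e-10)

    def test_confounder_is_removed(self):
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = rng.standard_normal(500)
            x = np.exp(z) + 0.05 * rng.standard_normal(500)
            y = z ** 3 + 0.05 * rng.standard_normal(500)
            rho, _ = leapd.partial_spearman(x, y, z)
            hits += abs(rho) < 0.1
        assert hits >= 4

    def test_rejects_constant_input(self):
        with pytest.raises(ValueError, match="constant"):
            leapd.partial_spearman(np.ones(10), np.arange(10.0))


class TestClassificationMetrics:
    def test_perfect_separation(self):
        m = leapd.classification_metrics([0.1, 0.2, 0.8, 0.9],
                                         [True, True, False, False])
        assert m["accuracy_pct"] == 100.0
        assert m["auc"] == 1.0

    def test_contingency_arithmetic(self):
        # impaired: 3 below threshold, 1 above; normal: 1 below, 3 above
        idx = [0.1, 0.2, 0.3, 0.6, 0.4, 0.7, 0.8, 0.9]
        lab = [True] * 4 + [False] * 4
        m = leapd.classification_metrics(idx, lab)
        assert m["confusion"] == {"tp": 3, "fn": 1, "fp": 1, "tn": 3}
        assert m["sensitivity_pct"] == 75.0
        assert m["specificity_pct"] == 75.0
        assert m["odds_ratio"] == 9.0
        assert not m["odds_ratio_corrected"]

    def test_boundary_index_predicts_normal(self):
        m = leapd.classification_metrics([0.5, 0.5, 0.5, 0.5],
                                         [True, True, False, False])
        assert m["sensitivity_pct"] == 0.0
        assert m["specificity_pct"] == 100.0

    def test_zero_cell_triggers_haldane_correction(self):
        m = leapd.classification_metrics([0.1, 0.2, 0.6, 0.9],
                                         [True, True, False, False])
        assert m["odds_ratio_corrected"]
        assert np.isfinite(m["odds_ratio"])

    def test_auc_matches_roc_integration(self, rng):
        for _ in range(10):
            idx = rng.random(30)
            lab = rng.random(30) < 0.4
            if lab.all() or not lab.any():
                continue
            m = leapd.classification_metrics(idx, lab)
            # sklearn integrates the ROC; normal is the high-index class
            oracle = roc_auc_score(~lab, idx)
            assert m["auc"] == pytest.approx(oracle, abs=1e-10)

    def test_label_swap_flips_auc_and_rates(self, rng):
        idx = rng.random(20)
        lab = np.arange(20) < 8
        m = leapd.classification_metrics(idx, lab)
        swapped = leapd.classification_metrics(1.0 - idx, ~lab)
        assert swapped["auc"] == pytest.approx(m["auc"], abs=1e-12)
        m2 = leapd.classification_metrics(idx, ~lab)
        assert m2["auc"] == pytest.approx(1.0 - m["auc"], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            leapd.classification_metrics([0.2, 0.8], [True, True])


class TestRegressionModels:
    def test_exact_linear_fit(self):
        x = np.linspace(0, 1, 20)
        r = leapd.regression_models(x, 5.0 + 2.0 * x)
        assert r["linear"]["r2"] == pytest.approx(1.0, abs=1e-12)
        assert r["linear"]["rmse"] == pytest.approx(0.0, abs=1e-10)

    def test_exact_quadratic_prefers_quadratic(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        y = 1.0 + 3.0 * x - 4.0 * x ** 2 + 0.01 * rng.standard_normal(50)
        r = leapd.regression_models(x, y)
        assert r["quadratic"]["r2"] > 0.999
        assert r["lrt_p"] < 0.001

    def test_quadratic_r2_never_below_linear(self, rng):
        x = rng.random(40)
        y = rng.standard_normal(40)
        r = leapd.regression_models(x, y)
        assert r["quadratic"]["r2"] >= r["linear"]["r2"] - 1e-12

    def test_aic_penalizes_spurious_quadratic_term(self):
        """On pure-linear Gaussian data the quadratic model usually has
        the larger (worse) AIC."""
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.random(149)
            y = 2.0 * x + rng.standard_normal(149)
            r = leapd.regression_models(x, y)
            worse += r["quadratic"]["aic"] > r["linear"]["aic"]
        assert worse >= 60

    def test_scaled_rmse_uses_score_span(self, rng):
        x = rng.random(30)
        y = 10.0 + 20.0 * x + rng.standard_normal(30)
        r = leapd.regression_models(x, y)
        assert r["linear"]["rmse_scaled"] == pytest.approx(
            r["linear"]["rmse"] / np.ptp(y))

    def test_rejects_constant_predictor(self):
        with pytest.raises(ValueError, match="constant"):
            leapd.regression_models(np.ones(10), np.arange(10.0))


class TestLOOCV:
    def test_one_index_per_subject(self, worked_pre, worked_cohort,
                                   worked_configs):
        rep = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        assert rep.n == len(worked_cohort.table)
        assert set(rep.indices.index) == set(worked_cohort.table["id"])
        assert ((rep.indices >= 0) & (rep.indices <= 1)).all()

    def test_separable_cohort_is_perfectly_classified(self):
        pre, table = _separable_cohort()
        # low model order: the groups sit far apart along a coarse
        # spectral axis, and small subspaces do not absorb noise
        cfgs = [leapd.ElectrodeConfig(el, (4.0, 30.0), 3, 1)
                for el in ("P8", "PO7")]
        rep = leapd.loocv(pre, table, cfgs)
        assert rep.classification["auc"] == 1.0
        assert rep.classification["accuracy_pct"] == 100.0

    def test_report_serializes(self, worked_pre, worked_cohort,
                               worked_configs):
        rep = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        doc = rep.to_dict()
        assert doc["scheme"] == "loocv"
        assert set(doc["classification"]) >= {
            "accuracy_pct", "auc", "sensitivity_pct", "specificity_pct",
            "ppv_pct", "npv_pct", "odds_ratio"}
        assert {"linear", "quadratic", "lrt_p"} <= set(doc["regression"])


class TestKFold:
    def test_deterministic_single_round(self, worked_pre, worked_cohort,
                                        worked_configs):
        a, _ = leapd.kfold_cv(worked_pre, worked_cohort.table,
                              worked_configs, k=4, rounds=1, seed=7)
        b, _ = leapd.kfold_cv(worked_pre, worked_cohort.table,
                              worked_configs, k=4, rounds=1, seed=7)
        pd.testing.assert_series_equal(a[0].indices, b[0].indices)

    def test_k_equals_n_reduces_to_loocv(self, worked_pre, worked_cohort,
                                         worked_configs):
        n = len(worked_cohort.table)
        reports, _ = leapd.kfold_cv(worked_pre, worked_cohort.table,
                                    worked_configs, k=n, rounds=1, seed=0)
        loo = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        pd.testing.assert_series_equal(
            reports[0].indices.sort_index(), loo.indices.sort_index())

    def test_metric_variability_shrinks_with_effect_size(self):
        """Across-round rho variability is smaller for a strong
        score-frequency link than for a weak one."""
        sds = []
        for slope in (0.02, 0.6):
            spec = leapd.CohortSpec(n_subjects=40, channels=("P8",),
                                    informative=("P8",), duration=10.0,
                                    ta_slope=slope, seed=5)
            cohort = leapd.generate_cohort(spec)
            pre = {s: leapd.preprocess_recording(r)
                   for s, r in cohort.recordings.items()}
            cfgs = [leapd.ElectrodeConfig("P8", (4.0, 30.0), 5, 2)]
            reports, _ = leapd.kfold_cv(pre, cohort.table, cfgs, k=5,
                                        rounds=10, seed=1)
            sds.append(np.std([r.rho for r in reports], ddof=1))
        assert sds[1] < sds[0]

    def test_rejects_bad_parameters(self, worked_pre, worked_cohort,
                                    worked_configs):
        with pytest.raises(ValueError):
            leapd.kfold_cv(worked_pre, worked_cohort.table, worked_configs,
                           k=1, rounds=1)


class TestRandomizationTest:
    def test_identity_permutation_equals_loocv(self, worked_pre,
                                               worked_cohort,
                                               worked_configs):
        loo = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        ident = leapd.randomization_test(worked_pre, worked_cohort.table,
                                         worked_configs, seed=3,
                                         identity=True)
        pd.testing.assert_series_equal(loo.indices, ident.indices)
        assert ident.rho == loo.rho

    def test_shuffle_preserves_group_sizes(self, worked_pre, worked_cohort,
                                           worked_configs):
        """The permutation is a bijection of the score multiset, so the
        impaired/normal counts survive shuffling."""
        loo = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        sh = leapd.randomization_test(worked_pre, worked_cohort.table,
                                      worked_configs, seed=3)
        conf = loo.classification["confusion"]
        conf_sh = sh.classification["confusion"]
        assert conf["tp"] + conf["fn"] == conf_sh["tp"] + conf_sh["fn"]
        assert conf["fp"] + conf["tn"] == conf_sh["fp"] + conf_sh["tn"]
        assert sh.scheme == "randomization"

    def test_deterministic_under_seed(self, worked_pre, worked_cohort,
                                      worked_configs):
        a = leapd.randomization_test(worked_pre, worked_cohort.table,
                                     worked_configs, seed=11)
        b = leapd.randomization_test(worked_pre, worked_cohort.table,
                                     worked_configs, seed=11)
        pd.testing.assert_series_equal(a.indices, b.indices)


class TestSweeps:
    def test_electrode_sweep_shape_and_first_point(
            self, worked_pre, worked_cohort, worked_configs):
        ranked = [leapd.SearchEntry(c.electrode, c, 0.5)
                  for c in worked_configs]
        curve = leapd.electrode_sweep(worked_pre, worked_cohort.table,
                                      ranked)
        assert len(curve) == 2
        single = leapd.loocv(worked_pre, worked_cohort.table,
                             worked_configs[:1])
        assert curve["auc"].iloc[0] == single.classification["auc"]
        assert curve["rho"].iloc[0] == single.rho

    def test_electrode_sweep_rejects_excess_counts(
            self, worked_pre, worked_cohort, worked_configs):
        ranked = [leapd.SearchEntry(c.electrode, c, 0.5)
                  for c in worked_configs]
        with pytest.raises(ValueError, match="counts"):
            leapd.electrode_sweep(worked_pre, worked_cohort.table, ranked,
                                  counts=[3])

    def test_truncated_length_convention(self):
        rec = leapd.Recording("s", 100.0, ("A",),
                              np.arange(1000.0).reshape(1, -1))
        assert rec.truncated(0.10).n_samples == 100
        assert rec.truncated(0.333).n_samples == 333
        assert rec.truncated(1.0).n_samples == 1000
        np.testing.assert_array_equal(rec.truncated(0.1).data[0],
                                      rec.data[0, :100])

    def test_full_fraction_matches_plain_loocv(self, worked_cohort,
                                               worked_pre, worked_configs):
        curve = leapd.truncation_sweep(worked_cohort.recordings,
                                       worked_cohort.table, worked_configs,
                                       fractions=(100,))
        loo = leapd.loocv(worked_pre, worked_cohort.table, worked_configs)
        assert curve["auc"].iloc[0] == loo.classification["auc"]
        assert curve["rho"].iloc[0] == pytest.approx(loo.rho, abs=1e-12)

    def test_truncation_below_minimum_length_rejected(self, worked_cohort,
                                                      worked_configs):
        with pytest.raises(ValueError, match="minimum"):
            leapd.truncation_sweep(worked_cohort.recordings,
                                   worked_cohort.table, worked_configs,
                                   fractions=(1,))
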