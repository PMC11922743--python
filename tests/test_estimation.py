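"""Effect estimation: weighted rates, sandwich variance, relative-difference
CIs, noninferiority verdicts, subgroups and category decomposition."""

import dataclasses

import numpy as np
import pytest

from screencausal.records import CohortTable
from screencausal.simulate import SimulationConfig, simulate_cohort
from screencausal.weighting import fit_propensity, overlap_weights
from screencausal.estimation import (EstimationError, analyze_endpoint,
                                     category_decomposition, effect_from_rates,
                                     model_ppv, noninferiority_decision,
                                     sandwich_covariance, subgroup_analysis,
                                     weighted_rates, make_scheme, age_band)

from conftest import make_table


class TestWeightedRates:
    def test_unit_weights_are_group_means(self):
        y = np.array([1, 0, 0, 1, 1, 0], dtype=float)
        z = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        mu1, mu0 = weighted_rates(y, z, np.ones(6))
        assert mu1 == pytest.approx(1 / 3)
        assert mu0 == pytest.approx(2 / 3)

    def test_doubling_weight_equals_duplicating_record(self):
        y = np.array([1, 0, 0, 1, 0], dtype=float)
        z = np.array([1, 1, 0, 0, 0], dtype=float)
        w = np.array([2.0, 1, 1, 1, 1])
        dup = weighted_rates(np.r_[y, y[0]], np.r_[z, z[0]], np.ones(6))
        assert weighted_rates(y, z, w) == pytest.approx(dup)

    def test_zero_group_weight_rejected(self):
        with pytest.raises(EstimationError):
            weighted_rates(np.array([1.0, 0.0]), np.array([1.0, 1.0]),
                           np.array([1.0, 1.0]))

    def test_equals_weighted_quasibinomial_glm(self, small_cohort):
        """The weighted group means equal the fitted rates of the weighted
        quasi-binomial group-only regression (statsmodels oracle, 1e-10)."""
        import statsmodels.api as sm
        fit = fit_propensity(small_cohort)
        z = (small_cohort.df["study_group"] == "ai").to_numpy(float)
        w = overlap_weights(fit.e, z).w
        for col in ("cancer_detected", "recall"):
            y = small_cohort.df[col].to_numpy(float)
            mu1, mu0 = weighted_rates(y, z, w)
            glm = sm.GLM(y, sm.add_constant(z), family=sm.families.Binomial(),
                         var_weights=w).fit()
            pred = glm.predict(np.array([[1.0, 1.0], [1.0, 0.0]]))
            assert abs(mu1 - pred[0]) < 1e-10
            assert abs(mu0 - pred[1]) < 1e-10


class TestSandwich:
    def test_fixed_half_propensity_reduces_to_binomial(self):
        """With known e = 0.5 the fixed-PS sandwich equals the classic
        two-sample binomial variance of the group proportions."""
        rng = np.random.default_rng(0)
        n = 4000
        z = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < np.where(z == 1, 0.06, 0.05)).astype(float)
        rows = [{"study_group": "ai" if zi else "control",
                 "reader1_used_ai": int(zi),
                 "cancer_detected": int(yi)} for zi, yi in zip(z, y)]
        table = make_table(rows)
        fit = fit_propensity(table, covariates=())
        fit = dataclasses.replace(fit, e=np.full(n, 0.5))
        ws = make_scheme(fit, z, "overlap")  # w = 0.5 everywhere
        cov = sandwich_covariance(table, fit, ws, y, ps="fixed")
        n1, n0 = z.sum(), n - z.sum()
        mu1, mu0 = y[z == 1].mean(), y[z == 0].mean()
        assert cov[0, 0] == pytest.approx(mu1 * (1 - mu1) / n1, rel=1e-6)
        assert cov[1, 1] == pytest.approx(mu0 * (1 - mu0) / n0, rel=1e-6)
        assert cov[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_stacked_close_to_bootstrap(self, small_cohort):
        """Stacked sandwich SE of the log rate ratio within 10% of a
        1,000-replicate woman-level bootstrap SE."""
        df = small_cohort.df
        z = (df["study_group"] == "ai").to_numpy(float)
        y = df["cancer_detected"].to_numpy(float)
        fit = fit_propensity(small_cohort)
        ws = make_scheme(fit, z, "overlap")
        mu1, mu0 = weighted_rates(y, z, ws.w)
        cov = sandwich_covariance(small_cohort, fit, ws, y)
        se_lr = np.sqrt(cov[0, 0] / mu1**2 + cov[1, 1] / mu0**2
                        - 2 * cov[0, 1] / (mu1 * mu0))
        rng = np.random.default_rng(123)
        boots = []
        for _ in range(1000):
            idx = rng.integers(0, len(df), len(df))
            sub = CohortTable(df.iloc[idx].reset_index(drop=True), "simulated")
            bfit = fit_propensity(sub)
            bz = (sub.df["study_group"] == "ai").to_numpy(float)
            bws = make_scheme(bfit, bz, "overlap")
            bmu1, bmu0 = weighted_rates(sub.df["cancer_detected"].to_numpy(float),
                                        bz, bws.w)
            if bmu0 > 0 and bmu1 > 0:
                boots.append(np.log(bmu1 / bmu0))
        se_boot = np.std(boots, ddof=1)
        assert abs(se_lr - se_boot) / se_boot < 0.10

    def test_covariance_symmetric_positive(self, small_cohort):
        fit = fit_propensity(small_cohort)
        z = (small_cohort.df["study_group"] == "ai").to_numpy(float)
        ws = make_scheme(fit, z, "overlap")
        y = small_cohort.df["cancer_detected"].to_numpy(float)
        for ps in ("stacked", "fixed"):
            cov = sandwich_covariance(small_cohort, fit, ws, y, ps=ps)
            assert cov[0, 1] == pytest.approx(cov[1, 0], rel=1e-8)
            assert cov[0, 0] > 0 and cov[1, 1] > 0
            assert np.all(np.isfinite(cov))
            assert np.linalg.eigvalsh(cov).min() > -1e-15


class TestEffectFromRates:
    def test_equal_rates_zero_differences(self):
        est = effect_from_rates(0.005, 0.005, np.eye(2) * 1e-8)
        assert est.diff == 0.0
        assert est.pct_diff == 0.0

    def test_zero_control_rate_flags_na(self):
        est = effect_from_rates(0.001, 0.0, np.eye(2) * 1e-8)
        assert not est.pct_defined
        assert np.isnan(est.pct_diff)

    def test_headline_arithmetic(self):
        est = effect_from_rates(0.0067, 0.0057, np.eye(2) * 1e-9)
        assert est.pct_diff == pytest.approx(17.54, abs=0.01)
        assert est.diff == pytest.approx(1.0, abs=1e-9)  # per 1,000

    def test_ci_ordering(self):
        cov = np.array([[2e-7, 0], [0, 2e-7]])
        est = effect_from_rates(0.0067, 0.0057, cov)
        assert est.ci_pct[0] < est.pct_diff < est.ci_pct[1]
        assert est.ci_diff[0] < est.diff < est.ci_diff[1]

    def test_negative_variance_rejected(self):
        with pytest.raises(EstimationError):
            effect_from_rates(0.01, 0.01, np.array([[-1e-8, 0], [0, 1e-8]]))


class TestNoninferiority:
    @pytest.mark.parametrize("ci, higher, verdict", [
        ((5.7, 30.8), True, "superior"),          # detection, CI all positive
        ((-6.5, 1.7), False, "noninferior"),      # recall, upper below +10
        ((-12.0, 5.0), True, "not_noninferior"),  # lower bound below margin
        ((-9.9, 11.6), True, "noninferior"),
        ((-5.0, 9.9), False, "noninferior"),
        ((-5.0, 10.1), False, "not_noninferior"),
        ((0.1, 5.0), True, "superior"),
        ((-0.1, 5.0), True, "noninferior"),
        ((-5.0, -0.1), False, "superior"),
        ((-5.0, 0.1), False, "noninferior"),
        ((-10.1, 5.0), True, "not_noninferior"),
        ((-9.9, 5.0), True, "noninferior"),
    ])
    def test_verdict_truth_table(self, ci, higher, verdict):
        dec = noninferiority_decision(ci, higher_is_better=higher)
        assert dec.verdict == verdict
        if dec.verdict == "superior":
            assert dec.noninferior  # superiority implies noninferiority


class TestAnalyzeEndpoint:
    def test_placebo_cohort_null_recovery(self):
        from screencausal.simulate import placebo_config
        cfg = placebo_config(SimulationConfig(n_women=60_000, n_reader_sets=40,
                                              n_readers=30))
        table = simulate_cohort(cfg, seed=17)
        est, _ = analyze_endpoint(table, "detection")
        assert est.ci_pct[0] < 0 < est.ci_pct[1]

    def test_configured_ratio_recovered(self):
        """Ratio-mode cohort with true detection ratio 1.18: the estimate's
        CI covers +18%."""
        cfg = SimulationConfig(n_women=400_000, effect_mode="ratio",
                               detection_ratio=1.18)
        table = simulate_cohort(cfg, seed=4)
        est, _ = analyze_endpoint(table, "detection")
        assert est.ci_pct[0] < 18.0 < est.ci_pct[1]
        assert abs(est.pct_diff - 18.0) < 15.0

    def test_unknown_outcome_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            analyze_endpoint(small_cohort, "interval_cancer")


class TestModelPPV:
    def test_equal_rates_hundred_percent(self):
        rows = []
        for z in (0, 1):
            rows += [{"study_group": "ai" if z else "control",
                      "reader1_used_ai": z, "consensus": 1, "recall": 1,
                      "biopsy": 1, "cancer_detected": 1,
                      "invasiveness": "dcis", "stage": "0"}] * 10
            rows += [{"study_group": "ai" if z else "control",
                      "reader1_used_ai": z}] * 40
        table = make_table(rows)
        out = model_ppv(table, "recall", n_boot=10, seed=0)
        assert out["ppv_ai"] == pytest.approx(100.0)
        assert out["ppv_control"] == pytest.approx(100.0)

    def test_ratio_matches_direct_weighted_computation(self, small_cohort):
        out = model_ppv(small_cohort, "recall", n_boot=5, seed=1)
        fit = fit_propensity(small_cohort)
        z = (small_cohort.df["study_group"] == "ai").to_numpy(float)
        w = overlap_weights(fit.e, z).w
        det1, _ = weighted_rates(small_cohort.df["cancer_detected"].to_numpy(float), z, w)
        rec1, _ = weighted_rates(small_cohort.df["recall"].to_numpy(float), z, w)
        assert out["ppv_ai"] == pytest.approx(100 * det1 / rec1, rel=1e-10)


class TestSubgroups:
    def test_single_level_equals_full_analysis(self, small_cohort):
        df = small_cohort.df.copy()
        df["one_level"] = "all"
        table = CohortTable(df, "simulated")
        sub = subgroup_analysis(table, "one_level", "detection")
        est_full, _ = analyze_endpoint(small_cohort, "detection")
        est_sub, _ = sub["all"]
        assert est_sub.pct_diff == pytest.approx(est_full.pct_diff, abs=1e-9)

    def test_age_band_levels_recover_uniform_ratio(self):
        cfg = SimulationConfig(n_women=150_000, n_reader_sets=60, n_readers=40,
                               effect_mode="ratio", detection_ratio=1.25)
        table = simulate_cohort(cfg, seed=9)
        sub = subgroup_analysis(table, "age_band", "detection")
        for level in ("50-59", "60-69"):
            est, _ = sub[level]
            assert est.ci_pct[0] < 25.0 < est.ci_pct[1], (level, est.ci_pct)

    def test_single_group_level_flagged_none(self, small_cohort):
        df = small_cohort.df.copy()
        df["weird"] = np.where(df["study_group"] == "ai", "lvl_a", "lvl_b")
        table = CohortTable(df, "simulated")
        sub = subgroup_analysis(table, "weird", "detection")
        assert sub["lvl_a"] is None and sub["lvl_b"] is None


class TestCategoryDecomposition:
    def test_two_equal_halves(self):
        rows = []
        for z in (0, 1):
            for inv, stage in (("dcis", "0"), ("invasive", "1")):
                extra = {"grade": "2", "size_class": "le10mm"} if inv == "invasive" else {}
                rows += [{"study_group": "ai" if z else "control",
                          "reader1_used_ai": z, "consensus": 1, "recall": 1,
                          "biopsy": 1, "cancer_detected": 1,
                          "invasiveness": inv, "stage": stage, **extra}] * 5
            rows += [{"study_group": "ai" if z else "control",
                      "reader1_used_ai": z}] * 90
        table = make_table(rows)
        out = category_decomposition(table, "invasiveness", covariates=())
        total, _ = analyze_endpoint(table, "detection", covariates=())
        assert out["dcis"].mu1 == pytest.approx(total.mu1 / 2, rel=1e-9)
        assert out["invasive"].mu1 == pytest.approx(total.mu1 / 2, rel=1e-9)

    def test_additivity_to_total_detection(self, small_cohort):
        """Per-category model-based rates sum exactly to the total rate."""
        out = category_decomposition(small_cohort, "invasiveness")
        est, _ = analyze_endpoint(small_cohort, "detection")
        assert sum(e.mu1 for e in out.values()) == pytest.approx(est.mu1, abs=1e-10)
        assert sum(e.mu0 for e in out.values()) == pytest.approx(est.mu0, abs=1e-10)

    def test_unknown_category_value_rejected(self, small_cohort):
        df = small_cohort.df.copy()
        det = df.index[df["cancer_detected"] == 1]
        df.loc[det[0], "invasiveness"] = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            category_decomposition(CohortTable(df, "simulated"), "invasiveness")


def test_age_band_derivation(small_cohort):
    bands = age_band(small_cohort)
    ages = small_cohort.df["age_years"]
    assert ((bands == "50-59") == (ages < 60)).all()
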