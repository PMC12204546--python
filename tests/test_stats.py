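import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from ppgq.io_formats import Condition, ValidationError
from ppgq.stats import (
    ModelSpec,
    boxplot_stats,
    covariate_model_spec,
    enumerate_direct_comparisons,
    fit_contrast,
    fit_lmm,
    holm_sidak,
    metric_r2,
    summarize_metric,
)
from ppgq.synthetic import CohortDesign, simulate_metric_cohort


def _cohort(n_subjects=60, sigma_subject=4.0, sigma_resid=4.0, seed=0, fixed=None):
    design = CohortDesign(
        n_subjects=n_subjects,
        intercept=10.0,
        fixed_effects=fixed or {},
        sigma_subject=sigma_subject,
        sigma_resid=sigma_resid,
        seed=seed,
    )
    return simulate_metric_cohort(design)


class TestFitLMM:
    def test_no_subject_variance_reduces_to_ols(self):
        tab = _cohort(n_subjects=40, sigma_subject=0.0, fixed={"posture_supine": 2.0, "age": 0.1})
        spec = ModelSpec("value", ("age", "posture_supine"))
        res = fit_lmm(tab, spec)
        X = sm.add_constant(tab[["age", "posture_supine"]].astype(float))
        ols = sm.OLS(tab["value"], X).fit()
        assert res.coef("age") == pytest.approx(ols.params["age"], abs=1e-6)
        assert res.coef("posture_supine") == pytest.approx(ols.params["posture_supine"], abs=1e-6)

    def test_intercept_only_on_balanced_data_is_grand_mean(self):
        tab = _cohort(n_subjects=30, seed=3)
        res = fit_lmm(tab, ModelSpec("value", ()))
        assert res.coef("intercept") == pytest.approx(tab["value"].mean(), abs=1e-8)

    def test_parameter_recovery_with_known_components(self):
        fixed = {"posture_supine": 3.0, "height_arm_up": 6.0, "age": 0.15}
        tab = _cohort(n_subjects=500, seed=1, fixed=fixed)
        res = fit_lmm(tab, ModelSpec("value", tuple(fixed)))
        for term, truth in fixed.items():
            est, se = res.coef(term), res.table.loc[term, "se"]
            assert abs(est - truth) < 3 * se
        assert res.var_subject == pytest.approx(16.0, rel=0.20)

    def test_ml_residual_variance_not_above_reml(self):
        # ML divides by n, REML corrects for estimated fixed effects
        tab = _cohort(n_subjects=20, seed=5, fixed={"posture_supine": 2.0})
        spec = ModelSpec("value", ("posture_supine",))
        res_ml = fit_lmm(tab, spec)
        X = pd.DataFrame({"intercept": 1.0, "posture_supine": tab["posture_supine"].astype(float)})
        reml = sm.MixedLM(tab["value"], X, groups=tab["subject_id"]).fit(reml=True)
        assert res_ml.var_resid <= reml.scale + 1e-9

    def test_singular_design_names_collinear_term(self):
        tab = _cohort(n_subjects=10)
        tab["age_copy"] = tab["age"]
        with pytest.raises(ValidationError, match="age_copy"):
            fit_lmm(tab, ModelSpec("value", ("age", "age_copy")))

    def test_missing_rows_dropped_listwise(self):
        tab = _cohort(n_subjects=20, seed=8)
        tab.loc[tab.index[:7], "age"] = np.nan
        res = fit_lmm(tab, ModelSpec("value", ("age",)))
        assert res.n_dropped == 7
        assert res.n_obs == len(tab) - 7

    def test_ci_consistent_with_se(self):
        tab = _cohort(n_subjects=50, seed=2, fixed={"age": 0.1})
        res = fit_lmm(tab, ModelSpec("value", ("age",)))
        row = res.table.loc["age"]
        assert row["ci_hi"] - row["ci_lo"] == pytest.approx(2 * 1.96 * row["se"], rel=0.01)


class TestDirectComparisons:
    def test_full_design_yields_30_tests(self):
        contrasts = enumerate_direct_comparisons(list(Condition))
        assert len(contrasts) == 30
        for metric in ("snr_db", "pi_percent", "tmcc"):
            assert sum(c.metric == metric for c in contrasts) == 10

    def test_standing_only_subset_single_contrast(self):
        subset = [Condition.STANDING_ARM_DOWN, Condition.STANDING_ARM_UP]
        contrasts = enumerate_direct_comparisons(subset, metrics=("snr_db",))
        assert len(contrasts) == 1

    def test_sitting_only_subset_three_contrasts(self):
        subset = [
            Condition.SITTING_ARM_DOWN,
            Condition.SITTING_ARM_LAP,
            Condition.SITTING_ARM_UP,
        ]
        contrasts = enumerate_direct_comparisons(subset, metrics=("tmcc",))
        assert len(contrasts) == 3

    def test_contrast_recovers_condition_effect(self):
        delta = 4.0
        design = CohortDesign(
            n_subjects=200,
            intercept=9.0,
            fixed_effects={"posture_supine": delta},
            sigma_subject=4.0,
            sigma_resid=2.0,
            response="snr_db",
            seed=6,
        )
        tab = simulate_metric_cohort(design)
        contrasts = enumerate_direct_comparisons(
            [Condition.STANDING_ARM_DOWN, Condition.SITTING_ARM_LAP, Condition.SUPINE],
            metrics=("snr_db",),
        )
        c = next(
            c
            for c in contrasts
            if {c.cond_a, c.cond_b} == {Condition.STANDING_ARM_DOWN, Condition.SUPINE}
        )
        est, p = fit_contrast(tab, c)
        assert est == pytest.approx(delta, abs=0.5)
        assert p < 1e-6


class TestHolmSidak:
    def test_hand_computed_step_down(self):
        fam = holm_sidak([0.04, 0.01, 0.02], alpha=0.05)
        assert fam.p_adjusted == pytest.approx([0.04, 0.029701, 0.0396], abs=1e-9)
        assert fam.reject.all()

    def test_single_test_identity(self):
        fam = holm_sidak([0.5])
        assert fam.p_adjusted[0] == 0.5 and not fam.reject[0]

    def test_all_zero_rejected(self):
        fam = holm_sidak([0.0, 0.0, 0.0])
        assert np.all(fam.p_adjusted == 0.0) and fam.reject.all()

    def test_matches_statsmodels_reference(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=25)
        fam = holm_sidak(p, alpha=0.05)
        reject_sm, p_adj_sm, _, _ = multipletests(p, alpha=0.05, method="holm-sidak")
        assert np.allclose(fam.p_adjusted, p_adj_sm, atol=1e-12)
        assert np.array_equal(fam.reject, reject_sm)

    def test_adjusted_dominates_raw_and_is_monotone(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        fam = holm_sidak(p)
        assert np.all(fam.p_adjusted >= fam.p_raw - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(fam.p_adjusted[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            holm_sidak([0.5, 1.2])

    def test_familywise_error_controlled_under_null(self):
        rng = np.random.default_rng(12345)
        fw_rejections = 0
        n_families = 500
        for _ in range(n_families):
            fam = holm_sidak(rng.uniform(size=10), alpha=0.05)
            fw_rejections += bool(fam.reject.any())
        assert fw_rejections / n_families <= 0.06


class TestDescriptives:
    def test_boxplot_constant_vector(self):
        s = boxplot_stats([4.2] * 9)
        assert s["median"] == s["q1"] == s["q3"] == 4.2
        assert s["outliers"] == []

    def test_boxplot_flags_outlier(self):
        s = boxplot_stats(list(range(1, 10)) + [100])
        assert s["outliers"] == [100]
        assert s["whisker_hi"] == 9

    def test_boxplot_symmetric_quartiles(self):
        x = np.concatenate([-np.arange(1, 50), [0], np.arange(1, 50)])
        s = boxplot_stats(x)
        assert s["median"] - s["q1"] == pytest.approx(s["q3"] - s["median"], abs=1e-9)

    @pytest.mark.parametrize("slope,intercept", [(2.0, 1.0), (-1.0, 0.0)])
    def test_r2_perfect_linear(self, slope, intercept):
        x = np.linspace(0, 1, 50)
        assert metric_r2(x, slope * x + intercept) == pytest.approx(1.0, abs=1e-12)

    def test_r2_independent_near_zero(self):
        rng = np.random.default_rng(0)
        assert metric_r2(rng.normal(size=10_000), rng.normal(size=10_000)) < 0.01

    def test_r2_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = 2 * x
        assert metric_r2(x, y) == pytest.approx(1.0)

    def test_summary_values(self):
        s = summarize_metric([1, 2, 3])
        assert (s["median"], s["mean"], s["sd"]) == (2, 2, 1)
        assert summarize_metric([5.0] * 4)["sd"] == 0.0
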