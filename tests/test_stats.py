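"""Crossover mixed model: identifiability, oracles, diagnostics, sensitivity."""

import numpy as np
import pandas as pd
import pytest

from pvshock import stats as st
from pvshock.errors import InsufficientDataError

from conftest import make_crossover_frame


class TestFitStageLmm:
    def test_zero_noise_recovers_injected_effects_exactly(self):
        df = make_crossover_frame(n_pigs=6, effects={"impella": 0.0, "drugA": 5.0,
                                                     "drugB": -2.0},
                                  pig_sd=0.0, noise_sd=0.0)
        effs = {e.stage: e for e in st.fit_stage_lmm(df, "y", "impella")}
        assert effs["drugA"].mean_difference == pytest.approx(5.0, abs=1e-6)
        assert effs["drugB"].mean_difference == pytest.approx(-2.0, abs=1e-6)
        assert effs["drugA"].p_value < 1e-10

    def test_reference_contrast_is_degenerate_zero(self):
        df = make_crossover_frame(seed=3)
        ref = [e for e in st.fit_stage_lmm(df, "y", "impella")
               if e.stage == "impella"][0]
        assert ref.mean_difference == 0.0
        assert (ref.ci_lo, ref.ci_hi) == (0.0, 0.0)
        assert ref.p_value == 1.0

    def test_contrasts_equal_paired_mean_differences_when_balanced(self):
        """Balanced design, homoscedastic model: GLS contrast == paired mean diff."""
        df = make_crossover_frame(n_pigs=9, effects={"impella": 0.0, "drugA": 4.0,
                                                     "drugB": 1.0},
                                  pig_sd=3.0, noise_sd=1.5, seed=21)
        effs = {e.stage: e for e in
                st.fit_stage_lmm(df, "y", "impella", heteroscedastic=False)}
        wide = df.pivot(index="pig_id", columns="stage", values="y")
        for stage in ("drugA", "drugB"):
            paired = (wide[stage] - wide["impella"]).mean()
            assert effs[stage].mean_difference == pytest.approx(paired, abs=1e-6)

    def test_matches_statsmodels_mixedlm_homoscedastic(self):
        """Independent oracle: MixedLM REML on the homoscedastic special case."""
        import statsmodels.formula.api as smf

        df = make_crossover_frame(n_pigs=8, effects={"impella": 0.0, "drugA": 5.0,
                                                     "drugB": -3.0},
                                  pig_sd=2.0, noise_sd=1.0, seed=7)
        fit = st.fit_lmm(df, "y", heteroscedastic=False)
        sm_fit = smf.mixedlm("y ~ C(stage, Treatment('impella'))", df,
                             groups=df["pig_id"]).fit(reml=True)
        assert fit.sigma_b2 == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]),
                                             rel=1e-3)
        assert fit.sigma_e2["drugA"] == pytest.approx(float(sm_fit.scale), rel=1e-3)
        effs = {e.stage: e for e in st.effects_vs_reference(fit, "impella")}
        for stage in ("drugA", "drugB"):
            key = f"C(stage, Treatment('impella'))[T.{stage}]"
            assert effs[stage].mean_difference == pytest.approx(
                float(sm_fit.params[key]), abs=1e-5)

    def test_heteroscedastic_variances_track_stage_noise(self):
        rng = np.random.default_rng(5)
        rows = []
        sds = {"impella": 0.5, "drugA": 4.0, "drugB": 1.0}
        for i in range(60):
            b = rng.normal(0, 1.0)
            for s_, sd_ in sds.items():
                rows.append({"pig_id": f"p{i:02d}", "stage": s_,
                             "y": 10.0 + b + rng.normal(0, sd_)})
        fit = st.fit_lmm(pd.DataFrame(rows), "y", heteroscedastic=True)
        assert fit.sigma_e2["drugA"] > 4 * fit.sigma_e2["impella"]
        assert fit.sigma_e2["drugA"] == pytest.approx(16.0, rel=0.5)

    def test_invariant_to_pig_relabeling_and_row_order(self):
        df = make_crossover_frame(n_pigs=7, seed=13)
        eff1 = st.fit_stage_lmm(df, "y", "impella")
        relabel = {p: f"z{i}" for i, p in enumerate(df["pig_id"].unique()[::-1])}
        df2 = df.assign(pig_id=df["pig_id"].map(relabel)).sample(
            frac=1.0, random_state=1)
        eff2 = st.fit_stage_lmm(df2, "y", "impella")
        for a, b in zip(eff1, eff2):
            assert a.mean_difference == pytest.approx(b.mean_difference, abs=1e-8)
            assert a.ci_lo == pytest.approx(b.ci_lo, abs=1e-6)

    def test_period_term_is_estimable_and_optional(self):
        df = make_crossover_frame(n_pigs=8, seed=2)
        # randomize drug positions so period and stage are not collinear
        rng = np.random.default_rng(0)
        for pig, grp in df.groupby("pig_id"):
            df.loc[grp.index, "period"] = rng.permutation([1, 2, 3])
        effs = st.fit_stage_lmm(df, "y", "impella", include_period=True)
        assert all(np.isfinite(e.mean_difference) for e in effs)

    def test_too_few_pigs_rejected(self):
        df = make_crossover_frame(n_pigs=2)
        with pytest.raises(InsufficientDataError, match="3 pigs"):
            st.fit_stage_lmm(df, "y", "impella")


class TestResidualNormality:
    def test_gaussian_residuals_rarely_flagged(self):
        flags = []
        for seed in range(12):
            df = make_crossover_frame(n_pigs=10, pig_sd=2.0, noise_sd=1.0,
                                      seed=seed)
            fit = st.fit_lmm(df, "y", heteroscedastic=False)
            flags.append(st.residual_normality(fit)["flagged"])
        assert np.mean(flags) <= 0.25

    def test_heavy_tailed_residuals_flagged(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(10):
            for j, s_ in enumerate(("impella", "drugA", "drugB")):
                rows.append({"pig_id": f"p{i}", "stage": s_,
                             "y": 10.0 + rng.standard_cauchy()})
        fit = st.fit_lmm(pd.DataFrame(rows), "y", heteroscedastic=False)
        assert st.residual_normality(fit)["flagged"]

    def test_constant_residuals_rejected(self):
        df = make_crossover_frame(n_pigs=5, pig_sd=0.0, noise_sd=0.0)
        fit = st.fit_lmm(df, "y", heteroscedastic=False)
        with pytest.raises(InsufficientDataError):
            st.residual_normality(fit)


class TestLeaveOneOut:
    def test_one_refit_per_pig(self):
        df = make_crossover_frame(n_pigs=6, seed=9)
        per_fit, summ = st.leave_one_out_sensitivity(df, "y", "impella")
        assert per_fit["excluded_pig"].nunique() == 6

    def test_signs_stable_without_outlier(self):
        df = make_crossover_frame(n_pigs=8, effects={"impella": 0.0, "drugA": 8.0,
                                                     "drugB": -8.0},
                                  pig_sd=1.0, noise_sd=0.5, seed=3)
        _, summ = st.leave_one_out_sensitivity(df, "y", "impella")
        assert summ["sign_stable"].all()

    def test_injected_outlier_dominates_effect_shift(self):
        df = make_crossover_frame(n_pigs=8, effects={"impella": 0.0, "drugA": 2.0,
                                                     "drugB": 0.0},
                                  pig_sd=1.0, noise_sd=0.5, seed=5)
        # one extreme pig inflates the drugA effect
        mask = (df["pig_id"] == "p00") & (df["stage"] == "drugA")
        df.loc[mask, "y"] += 40.0
        per_fit, _ = st.leave_one_out_sensitivity(df, "y", "impella")
        da = per_fit[per_fit.stage == "drugA"].set_index("excluded_pig")
        full_like = da["mean_difference"].drop("p00").mean()
        assert abs(da.loc["p00", "mean_difference"] - full_like) == pytest.approx(
            abs(da["mean_difference"] - full_like).max())

    def test_fewer_than_four_pigs_rejected(self):
        df = make_crossover_frame(n_pigs=3)
        with pytest.raises(InsufficientDataError):
            st.leave_one_out_sensitivity(df, "y", "impella")


class TestSummarizeBaseline:
    def test_closed_form_t_interval(self):
        df = pd.DataFrame({"pig_id": list("abc"), "stage": ["baseline"] * 3,
                           "y": [1.0, 2.0, 3.0]})
        s = st.summarize_baseline(df, "y")
        assert s["mean"] == pytest.approx(2.0)
        assert s["ci_lo"] == pytest.approx(2.0 - 4.302653 / np.sqrt(3), abs=1e-4)
        assert s["ci_hi"] == pytest.approx(2.0 + 4.302653 / np.sqrt(3), abs=1e-4)

    def test_identical_values_zero_width(self):
        df = pd.DataFrame({"pig_id": list("abcd"), "stage": ["baseline"] * 4,
                           "y": [5.0] * 4})
        s = st.summarize_baseline(df, "y")
        assert s["ci_lo"] == s["ci_hi"] == 5.0

    def test_single_value_rejected(self):
        df = pd.DataFrame({"pig_id": ["a"], "stage": ["baseline"], "y": [1.0]})
        with pytest.raises(InsufficientDataError):
            st.summarize_baseline(df, "y")

    def test_cohort_baseline_sw_matches_reference(self):
        from pvshock.validation import baseline_cohort_mean_sw

        assert baseline_cohort_mean_sw(seed=11) == pytest.approx(4853.0, rel=0.15)
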