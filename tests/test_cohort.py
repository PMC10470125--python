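"""Synthetic cohort generator: marginal calibration, copula dependence,
outcome model, batch effects and censoring."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp, spearmanr

import gestmix as gx
from gestmix.cohort import (
    apply_batch_effects,
    censor_and_missing,
    correlation_matrix,
    generate_cohort,
    lognormal_params_from_moments,
    simulate_population,
    spearman_to_pearson,
)
from gestmix.specs import (
    BatchEffectSpec,
    CorrelationSpec,
    MarginalSpec,
    MissingSpec,
    OutcomeModelSpec,
    SpecError,
    default_correlations,
    default_marginals,
)


class TestLognormalMoments:
    def test_degenerate_point_mass(self):
        mu, sigma = lognormal_params_from_moments(1.4, 0.0)
        assert mu == pytest.approx(math.log(1.4))
        assert sigma == 0.0

    def test_inverts_to_requested_moments(self):
        # closed-form values, cross-checked by Monte-Carlo moments
        mu, sigma = lognormal_params_from_moments(1.4, 0.9)
        assert sigma == pytest.approx(0.58812, abs=1e-4)
        assert mu == pytest.approx(0.16355, abs=1e-4)
        draws = np.exp(mu + sigma * np.random.default_rng(0).standard_normal(10**6))
        assert draws.mean() == pytest.approx(1.4, abs=0.005)
        assert draws.std() == pytest.approx(0.9, abs=0.01)

    def test_unit_sigma_closed_form(self):
        mean = math.exp(1.5)
        sd = mean * math.sqrt(math.e - 1.0)  # makes sigma exactly 1
        mu, sigma = lognormal_params_from_moments(mean, sd)
        assert sigma == pytest.approx(1.0, abs=1e-12)
        assert mu == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(SpecError):
            lognormal_params_from_moments(0.0, 1.0)


class TestSpearmanConversion:
    @pytest.mark.parametrize("rho", [0.0, 1.0, -1.0])
    def test_fixed_points(self, rho):
        assert spearman_to_pearson(rho) == pytest.approx(rho)

    def test_printed_correlation_value(self):
        assert spearman_to_pearson(0.59) == pytest.approx(0.60809, abs=1e-4)

    def test_simulated_spearman_matches_target(self):
        rho_p = spearman_to_pearson(0.59)
        rng = np.random.default_rng(1)
        z1 = rng.standard_normal(200_000)
        z2 = rho_p * z1 + math.sqrt(1 - rho_p**2) * rng.standard_normal(200_000)
        assert spearmanr(z1, z2).statistic == pytest.approx(0.59, abs=0.01)

    @given(st.floats(-1.0, 1.0))
    @settings(max_examples=50, derandomize=True)
    def test_magnitude_and_sign(self, rho):
        rp = spearman_to_pearson(rho)
        assert abs(rp) >= abs(rho) - 1e-12
        assert math.copysign(1, rp) == math.copysign(1, rho) or rho == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(SpecError):
            spearman_to_pearson(1.2)


class TestCorrelationMatrix:
    def test_default_matrix_is_psd_unit_diagonal(self):
        R = correlation_matrix(default_correlations())
        assert np.allclose(np.diag(R), 1.0)
        assert np.linalg.eigvalsh(R).min() > -1e-10

    def test_nonpsd_repair_and_error_modes(self):
        pairs = (("as", "hg", 0.95), ("hg", "pb", 0.95), ("as", "pb", -0.95))
        with pytest.warns(UserWarning):
            R = correlation_matrix(CorrelationSpec(pairs=pairs))
        assert np.linalg.eigvalsh(R).min() > -1e-10
        with pytest.raises(SpecError):
            correlation_matrix(CorrelationSpec(pairs=pairs, on_nonpsd="error"))


class TestPopulationCalibration:
    def test_spearman_within_sampling_error(self):
        null = OutcomeModelSpec(metal_betas={}, covariate_betas={})
        pop = simulate_population(10_000, outcome_spec=null, seed=5)
        assert spearmanr(pop["as"], pop["hg"]).statistic == pytest.approx(0.59, abs=0.03)
        assert spearmanr(pop["mg"], pop["zn"]).statistic == pytest.approx(0.53, abs=0.03)

    def test_null_betas_give_exchangeable_case_metal_distributions(self):
        null = OutcomeModelSpec(
            intercept=-2.0, metal_betas={}, covariate_betas={}
        )
        pop = simulate_population(20_000, outcome_spec=null, seed=6)
        cases = pop.loc[pop["case"] == 1, "hg"]
        ctrls = pop.loc[pop["case"] == 0, "hg"]
        assert ks_2samp(cases, ctrls).pvalue > 0.01

    def test_outcome_beta_recovered_as_or_per_iqr(self):
        import statsmodels.api as sm

        spec = OutcomeModelSpec(
            intercept=-2.0, metal_betas={"cu": 0.25}, covariate_betas={}
        )
        pop = simulate_population(150_000, outcome_spec=spec, seed=7)
        ln = np.log(pop["cu"])
        z = (ln - ln.mean()) / ln.std()
        fit = sm.GLM(
            pop["case"], sm.add_constant(np.asarray(z)), family=sm.families.Binomial()
        ).fit()
        iqr = np.percentile(ln, 75) - np.percentile(ln, 25)
        or_iqr = math.exp(fit.params.iloc[1] * iqr / ln.std())
        truth = math.exp(0.25 * iqr / ln.std())
        assert or_iqr == pytest.approx(truth, rel=0.05)

    def test_case_control_counts_exact_and_deterministic(self):
        a = generate_cohort(seed=3)
        b = generate_cohort(seed=3)
        assert int(a.truth["case"].sum()) == 144
        assert len(a.truth) == 1226
        pd.testing.assert_frame_equal(a.truth, b.truth)


class TestBatchEffects:
    def test_identity_when_unbiased_and_noiseless(self, monkeypatch):
        coh = generate_cohort(seed=9)
        spec = BatchEffectSpec(
            multipliers={"r1": 1.0, "r2": 1.0, "r3": 1.0, "lund": 1.0},
            qc_noise_cv=0.0,
            sample_noise_cv=0.0,
        )
        raw, qc = apply_batch_effects(coh, spec, seed=1)
        for m in gx.METALS:
            np.testing.assert_allclose(raw[m], coh.truth[m])
        assert (qc["qc_value"] > 0).all()

    def test_round_multiplier_applied_exactly(self):
        coh = generate_cohort(seed=9)
        spec = BatchEffectSpec(
            multipliers={"r1": 1.0, "r2": 2.0, "r3": 1.0, "lund": 1.0},
            qc_noise_cv=0.0,
            sample_noise_cv=0.0,
        )
        raw, _ = apply_batch_effects(coh, spec, seed=1)
        in_r2 = raw["round"] == "r2"
        np.testing.assert_allclose(raw.loc[in_r2, "hg"], 2.0 * coh.truth.loc[in_r2.to_numpy(), "hg"])
        np.testing.assert_allclose(raw.loc[~in_r2, "hg"], coh.truth.loc[(~in_r2).to_numpy(), "hg"])


class TestCensoring:
    def test_no_limits_no_censoring(self):
        coh = generate_cohort(seed=10)
        raw, _ = apply_batch_effects(coh, seed=1)
        marg = {
            m: MarginalSpec(metal=m, mean=s.mean, sd=s.sd)  # limits stripped
            for m, s in default_marginals().items()
        }
        obs, reasons = censor_and_missing(
            raw, marg, MissingSpec(not_analysed_metals=(), covariate_mcar={}), seed=2
        )
        for m in ("as", "cd", "co"):
            assert obs[m].notna().all()

    def test_lod_at_tenth_percentile_censors_ten_percent(self):
        coh = generate_cohort(seed=11)
        spec = BatchEffectSpec(
            multipliers={"r1": 1.0, "r2": 1.0, "r3": 1.0, "lund": 1.0},
            qc_noise_cv=0.0,
            sample_noise_cv=0.0,
        )
        raw, _ = apply_batch_effects(coh, spec, seed=1)
        p10 = float(np.percentile(raw["as"], 10))
        marg = dict(default_marginals())
        marg["as"] = MarginalSpec(metal="as", mean=2.4, sd=3.0, lod=p10, loq=3 * p10)
        obs, reasons = censor_and_missing(
            raw, marg, MissingSpec(not_analysed_metals=(), covariate_mcar={}), seed=2
        )
        frac = obs["as"].isna().mean()
        assert frac == pytest.approx(0.10, abs=0.01)
        assert (reasons.loc[obs["as"].isna(), "as"] == "below_lod").all()

    def test_external_round_missingness_matches_design(self, cohort):
        # ~105/1226 subjects analysed externally without Mg/Cs
        n_cs = int(cohort.observed["cs"].isna().sum())
        assert n_cs == 105
        assert (cohort.missing_reasons.loc[cohort.observed["cs"].isna(), "cs"] == "not_analysed").all()

    def test_simulate_is_seed_deterministic(self):
        a = gx.simulate(seed=21)
        b = gx.simulate(seed=21)
        pd.testing.assert_frame_equal(a.observed, b.observed)
        pd.testing.assert_frame_equal(a.qc, b.qc)
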