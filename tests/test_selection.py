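"""Elastic-net solver correctness, design construction, stability
selection, permutation p-values and BH-FDR."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from gestmix.enet import cv_enet_logistic, fit_enet_logistic, lambda_path
from gestmix.selection import (
    SelectionConfig,
    bh_thresholds,
    build_design,
    permutation_pvalues,
    stability_selection,
)


def _toy_logistic(n=400, p=6, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = beta if beta is not None else np.array([1.0, -0.6, 0.0, 0.0, 0.4, 0.0])
    eta = X @ beta - 0.3
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


class TestEnetSolver:
    def test_unpenalized_fit_matches_irls_oracle(self):
        X, y = _toy_logistic(seed=1)
        mask = np.array([True] * 4 + [False] * 2)
        fit = fit_enet_logistic(X, y, alpha=0.9, lam=0.0, penalty_mask=mask)
        mle = sm.GLM(y, sm.add_constant(X), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(
            np.r_[fit.intercept, fit.coef], mle.params, atol=1e-4
        )

    def test_infinite_penalty_zeroes_penalized_terms_only(self):
        X, y = _toy_logistic(seed=2)
        mask = np.array([True] * 4 + [False] * 2)
        fit = fit_enet_logistic(X, y, alpha=1.0, lam=1e6, penalty_mask=mask)
        assert np.all(fit.coef[mask] == 0.0)
        # unpenalized columns equal the covariate-only MLE
        mle = sm.GLM(y, sm.add_constant(X[:, ~mask]), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coef[~mask], mle.params[1:], atol=1e-4)

    def test_lambda_max_zeroes_all_penalized(self):
        X, y = _toy_logistic(seed=3)
        mask = np.ones(X.shape[1], dtype=bool)
        lam_max = lambda_path(X, y, 0.9, mask, nlam=2)[0]
        fit = fit_enet_logistic(X, y, alpha=0.9, lam=lam_max * 1.01, penalty_mask=mask)
        assert np.all(fit.coef == 0.0)

    def test_constant_column_rejected(self):
        X, y = _toy_logistic(seed=4)
        X = X.copy()
        X[:, 2] = 0.0
        with pytest.raises(ValueError, match="constant"):
            fit_enet_logistic(X, y, 0.9, 0.1, np.ones(X.shape[1], bool))

    def test_matches_glmnet_reference(self, tmp_path):
        """Independent oracle: R glmnet with penalty.factor on identical data.

        glmnet rescales penalty factors to sum to nvars, so the local lambda
        is scaled by nvars/sum(pf) to express the same objective.
        """
        X, y = _toy_logistic(n=300, seed=5)
        mask = np.array([True] * 4 + [False] * 2)
        lam_glmnet = 0.03
        lam_local = lam_glmnet * X.shape[1] / mask.sum()
        fit = fit_enet_logistic(
            X, y, alpha=0.9, lam=lam_local, penalty_mask=mask, tol=1e-10
        )
        np.savetxt(tmp_path / "X.csv", X, delimiter=",")
        np.savetxt(tmp_path / "y.csv", y, delimiter=",")
        rcode = textwrap.dedent(
            f"""
            suppressMessages(library(glmnet))
            X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE))
            y <- scan("{tmp_path}/y.csv", quiet=TRUE)
            pf <- c(1,1,1,1,0,0)
            f <- glmnet(X, y, family="binomial", alpha=0.9, lambda={lam_glmnet},
                        penalty.factor=pf, standardize=FALSE, thresh=1e-12)
            cat(c(as.numeric(f$a0), as.numeric(f$beta)), sep="\\n")
            """
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.split()])
        np.testing.assert_allclose(np.r_[fit.intercept, fit.coef], ref, atol=2e-4)

    def test_cv_selects_strong_signal(self):
        X, y = _toy_logistic(n=600, seed=6, beta=np.array([1.5, 0, 0, 0, 0, 0.0]))
        mask = np.ones(6, dtype=bool)
        fit = cv_enet_logistic(X, y, 0.9, mask, seed=0)
        assert fit.coef[0] != 0.0
        assert abs(fit.coef[0]) > np.abs(fit.coef[1:]).max()


class TestBuildDesign:
    def test_main_effect_term_counts(self, imputations):
        d = build_design(imputations.datasets[0])
        assert int(d.penalized_mask.sum()) == 11
        assert int((~d.penalized_mask).sum()) == 7
        sds = d.values.std(axis=0)
        np.testing.assert_allclose(sds[: 11 + 7], 1.0, atol=1e-8)

    def test_interaction_term_counts(self, imputations):
        d = build_design(imputations.datasets[0], include_interactions=True)
        # C(11,2)=55 metal x metal + 11 x sex + 11 x education
        assert d.n_terms == 18 + 77
        assert int(d.penalized_mask.sum()) == 11 + 77
        # interaction columns are products of their standardized parents
        i_as_hg = d.terms.index("hg:as")
        i_hg, i_as = d.terms.index("hg"), d.terms.index("as")
        np.testing.assert_allclose(
            d.values[:, i_as_hg], d.values[:, i_hg] * d.values[:, i_as]
        )

    def test_missing_cells_rejected(self, adjusted):
        with pytest.raises(ValueError, match="impute first"):
            build_design(adjusted.df)


class TestStabilitySelection:
    def test_perfect_predictor_has_selection_probability_one(self):
        from conftest import make_complete_null_table

        rng = np.random.default_rng(12)
        df = make_complete_null_table(60, 240, seed=12)
        # deterministic predictor: hg separates cases from controls
        df["hg"] = df["case"] * 4.0 + rng.normal(0, 0.05, len(df))
        cfg = SelectionConfig(B=4, M=2, nlam=8, nfolds=3)
        psel = stability_selection(df, config=cfg, seed=3)
        assert psel["hg"] == 1.0

    def test_pure_noise_exposures_rarely_selected(self):
        from conftest import make_complete_null_table

        df = make_complete_null_table(60, 240, seed=13)
        cfg = SelectionConfig(B=6, M=2, nlam=8, nfolds=3)
        psel = stability_selection(df, config=cfg, seed=4)
        assert psel.mean() < 0.5

    def test_psel_in_unit_interval_and_deterministic(self, adjusted):
        cfg = SelectionConfig(B=3, M=2, nlam=6, nfolds=3)
        a = stability_selection(adjusted.df, bounds=adjusted.bounds, config=cfg, seed=5)
        b = stability_selection(adjusted.df, bounds=adjusted.bounds, config=cfg, seed=5)
        assert ((a >= 0) & (a <= 1)).all()
        pd.testing.assert_series_equal(a, b)
        assert set(a.index) == set(
            ["hg", "as", "cd", "pb", "mn", "se", "co", "cs", "cu", "zn", "mg"]
        )


class TestPermutationPvalues:
    def test_minimum_attainable_p_and_monotonicity(self, adjusted):
        cfg = SelectionConfig(B=2, M=2, B_perm=2, M_perm=2, nlam=5, nfolds=3)
        psel = stability_selection(adjusted.df, bounds=adjusted.bounds, config=cfg, seed=1)
        forced = psel.copy()
        forced[:] = 1.1  # above any attainable null P_sel
        res = permutation_pvalues(
            adjusted.df, forced, bounds=adjusted.bounds, config=cfg, seed=2, K=19
        )
        assert np.allclose(res["p_perm"], 1.0 / 20.0)
        # p is monotone non-increasing in the observed P_sel
        lower = psel.copy()
        lower[:] = -0.1
        res2 = permutation_pvalues(
            adjusted.df, lower, bounds=adjusted.bounds, config=cfg, seed=2, K=19
        )
        assert (res2["p_perm"] >= res["p_perm"] - 1e-12).all()

    def test_k_too_small_rejected(self, adjusted):
        cfg = SelectionConfig(B=2, M=2)
        psel = pd.Series(0.5, index=["hg"])
        with pytest.raises(ValueError):
            permutation_pvalues(adjusted.df, psel, config=cfg, seed=0, K=5)


class TestBhThresholds:
    def test_worked_example(self):
        p = pd.Series({"a": 0.01, "b": 0.02, "c": 0.2})
        out = bh_thresholds(p, fdr_alpha=0.05)
        np.testing.assert_allclose(
            out.loc[["a", "b", "c"], "bh_threshold"], [0.05 / 3, 0.1 / 3, 0.05]
        )
        assert out.loc["a", "bh_pass"] and out.loc["b", "bh_pass"]
        assert not out.loc["c", "bh_pass"]

    def test_all_ones_pass_nothing(self):
        out = bh_thresholds(pd.Series([1.0, 1.0, 1.0]))
        assert not out["bh_pass"].any()

    def test_single_pvalue_reduces_to_alpha_rule(self):
        assert bh_thresholds(pd.Series([0.04]), 0.05)["bh_pass"].iloc[0]
        assert not bh_thresholds(pd.Series([0.06]), 0.05)["bh_pass"].iloc[0]

    def test_step_up_rescues_smaller_pvalues(self):
        # p2 passes at rank 2 and drags p1 in even though p1 > alpha/m
        p = pd.Series({"a": 0.024, "b": 0.025})
        out = bh_thresholds(p, fdr_alpha=0.05)
        assert out["bh_pass"].all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_thresholds(pd.Series([0.0, 0.5]))
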