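"""Firth-penalized logistic regression against closed forms and grid search."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.special import expit, logit

from ndd_burden import fit_firth, penalized_lrt, wald_inference
from ndd_burden.firth_glm import (
    RankDeficientDesignError,
    _penalized_loglik,
    build_design,
    clean_design,
)


def grid_search_2d(X, y, b0_range, b1_range, n=121):
    """Dense maximization of the penalized log-likelihood, refined twice."""
    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = None
    for _ in range(4):
        g0 = np.linspace(lo0, hi0, n)
        g1 = np.linspace(lo1, hi1, n)
        vals = np.array(
            [[_penalized_loglik(X, y, np.array([a, b])) for b in g1] for a in g0]
        )
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (g0[i], g1[j])
        w0, w1 = (hi0 - lo0) / n, (hi1 - lo1) / n
        lo0, hi0 = best[0] - 2 * w0, best[0] + 2 * w0
        lo1, hi1 = best[1] - 2 * w1, best[1] + 2 * w1
    return np.array(best)


class TestFitFirth:
    @pytest.mark.parametrize("k,n", [(0, 10), (3, 12), (5, 10), (20, 20)])
    def test_intercept_only_closed_form(self, k, n):
        # the Jeffreys penalty turns the intercept-only problem into
        # maximizing p^(k+1/2) (1-p)^(n-k+1/2), so p_hat = (k+1/2)/(n+1)
        y = np.array([1.0] * k + [0.0] * (n - k))
        fit = fit_firth(np.ones((n, 1)), y, ["intercept"], tol=1e-10)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(logit((k + 0.5) / (n + 1)), abs=1e-8)

    def test_balanced_outcome_gives_zero_intercept(self):
        y = np.array([1.0] * 5 + [0.0] * 5)
        fit = fit_firth(np.ones((10, 1)), y, tol=1e-10)
        assert fit.beta[0] == pytest.approx(0.0, abs=1e-8)

    def test_complete_separation_matches_grid_search(self):
        # all 4 carriers are cases: unpenalized MLE is infinite,
        # the penalized optimum is finite and positive
        y = np.array([1.0] * 8 + [0.0] * 12)
        x = np.array([1.0] * 4 + [0.0] * 16)
        X = np.column_stack([np.ones(20), x])
        fit = fit_firth(X, y, ["b0", "b1"], clean=False)
        assert fit.converged
        assert 0 < fit.beta[1] < 50
        ref = grid_search_2d(X, y, (-6, 6), (-2, 12))
        assert fit.beta == pytest.approx(ref, abs=1e-3)

    def test_two_parameter_problem_matches_grid_search(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = (rng.random(80) < expit(0.3 + 0.8 * x)).astype(float)
        X = np.column_stack([np.ones(80), x])
        fit = fit_firth(X, y)
        ref = grid_search_2d(X, y, (-4, 4), (-4, 4))
        assert fit.beta == pytest.approx(ref, abs=1e-3)

    def test_finite_estimates_on_many_random_separated_datasets(self):
        # sub-sample of the separation-robustness sweep; the full 1000-run
        # sweep is exercised by the acceptance suite
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(10, 101))
            n_case = int(rng.integers(1, n))
            y = np.array([1.0] * n_case + [0.0] * (n - n_case))
            n_carrier = int(rng.integers(1, n_case + 1))
            x = np.zeros(n)
            x[:n_carrier] = 1.0  # carriers are exclusively cases
            fit = fit_firth(np.column_stack([np.ones(n), x]), y)
            assert fit.converged and np.all(np.abs(fit.beta) < 50)

    def test_bias_reduction_vs_unpenalized_mle(self):
        # mean Firth estimate closer to the true beta=1 than the mean MLE
        # over the replicates where the MLE exists
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        true_beta = 1.0
        firth_est, mle_est = [], []
        for _ in range(300):
            x = rng.normal(size=60)
            y = (rng.random(60) < expit(true_beta * x)).astype(float)
            X = np.column_stack([np.ones(60), x])
            fit = fit_firth(X, y)
            firth_est.append(fit.beta[1])
            try:
                with np.errstate(all="ignore"):
                    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
                if np.all(np.abs(res.params) < 10):  # crude separation screen
                    mle_est.append(res.params[1])
            except Exception:
                pass
        assert abs(np.mean(firth_est) - true_beta) < abs(np.mean(mle_est) - true_beta)

    def test_covariate_rescaling_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        y = (rng.random(100) < expit(0.5 * x)).astype(float)
        X1 = np.column_stack([np.ones(100), x])
        X2 = np.column_stack([np.ones(100), 10.0 * x])
        f1 = fit_firth(X1, y, tol=1e-10)
        f2 = fit_firth(X2, y, tol=1e-10)
        assert f2.beta[1] == pytest.approx(f1.beta[1] / 10.0, rel=1e-6)
        p1 = wald_inference(f1)["p"].iloc[1]
        p2 = wald_inference(f2)["p"].iloc[1]
        assert p2 == pytest.approx(p1, abs=1e-8)

    def test_non_binary_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_firth(np.ones((3, 1)), np.array([0.0, 0.5, 1.0]))

    def test_rank_deficient_design_raises_without_cleaning(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficientDesignError):
            fit_firth(X, np.array([1.0] * 5 + [0.0] * 5), clean=False)

    def test_degenerate_columns_dropped_with_warning(self):
        y = np.array([1.0] * 5 + [0.0] * 5)
        X = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.warns(UserWarning, match="degenerate"):
            fit = fit_firth(X, y, ["intercept", "allzero"])
        assert fit.names == ["intercept"] and fit.dropped == ["allzero"]


class TestWaldInference:
    def test_direct_normal_formulas(self):
        from ndd_burden.firth_glm import FirthFit

        fit = FirthFit(
            beta=np.array([2.0]), cov=np.array([[0.25]]), names=["x"],
            converged=True, n_iter=1, max_score=0.0, loglik_pen=0.0,
        )
        row = wald_inference(fit).iloc[0]
        assert row["OR"] == pytest.approx(np.exp(2.0), rel=1e-9)
        assert row["ci_low"] == pytest.approx(np.exp(2.0 - 1.959963985 * 0.5), rel=1e-6)
        assert row["ci_high"] == pytest.approx(np.exp(2.0 + 1.959963985 * 0.5), rel=1e-6)
        assert row["p"] == pytest.approx(6.33e-5, rel=1e-2)
        assert row["ci_low"] < row["OR"] < row["ci_high"]

    def test_null_coefficient_has_p_one(self):
        from ndd_burden.firth_glm import FirthFit

        fit = FirthFit(
            beta=np.array([0.0]), cov=np.array([[1.0]]), names=["x"],
            converged=True, n_iter=1, max_score=0.0, loglik_pen=0.0,
        )
        row = wald_inference(fit).iloc[0]
        assert row["OR"] == 1.0 and row["p"] == pytest.approx(1.0)

    def test_requires_convergence(self):
        from ndd_burden.firth_glm import FirthFit

        fit = FirthFit(
            beta=np.array([0.0]), cov=np.array([[1.0]]), names=["x"],
            converged=False, n_iter=100, max_score=1.0, loglik_pen=0.0,
        )
        with pytest.raises(ValueError):
            wald_inference(fit)


class TestPenalizedLRT:
    def test_identical_designs_give_p_one(self):
        y = np.array([1.0] * 6 + [0.0] * 6)
        fit = fit_firth(np.ones((12, 1)), y)
        assert penalized_lrt(fit, fit) == 1.0

    def test_chi_square_quantile(self):
        from ndd_burden.firth_glm import FirthFit

        null = FirthFit(np.zeros(1), np.eye(1), ["a"], True, 1, 0.0, loglik_pen=-10.0)
        full = FirthFit(np.zeros(2), np.eye(2), ["a", "b"], True, 1, 0.0,
                        loglik_pen=-10.0 + 3.841 / 2)
        assert penalized_lrt(full, null) == pytest.approx(0.05, rel=1e-3)

    def test_separated_predictor_beats_wald(self):
        y = np.array([1.0] * 8 + [0.0] * 12)
        x = np.array([1.0] * 5 + [0.0] * 15)
        X = np.column_stack([np.ones(20), x])
        full = fit_firth(X, y, ["intercept", "x"])
        null = fit_firth(np.ones((20, 1)), y, ["intercept"])
        wald_p = wald_inference(full).loc["x", "p"]
        assert penalized_lrt(full, null) < wald_p

    def test_non_nested_rejected(self):
        y = np.array([1.0] * 6 + [0.0] * 6)
        f1 = fit_firth(np.ones((12, 1)), y, ["a"])
        f2 = fit_firth(np.ones((12, 1)), y, ["b"])
        with pytest.raises(ValueError):
            penalized_lrt(f1, f2)


class TestDesignHelpers:
    def test_build_design_standardizes_age(self):
        X, names = build_design(
            np.array([1, 0, 0, 0]), np.array([1, 1, 0, 0]),
            np.array([10.0, 20.0, 30.0, 40.0]), np.array([0, 0, 1, 0]),
        )
        assert names == ["intercept", "carrier", "sex_male", "age_std", "family_history"]
        assert X[:, 3].mean() == pytest.approx(0.0, abs=1e-12)
        assert X[:, 3].std() == pytest.approx(1.0, rel=1e-12)

    def test_clean_design_drops_collinear(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x, 2 * x])
        with pytest.warns(UserWarning):
            Xc, names, dropped = clean_design(X, ["i", "x", "x2"])
        assert names == ["i", "x"] and dropped == ["x2"]
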