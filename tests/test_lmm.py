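"""REML/ML engine: closed forms, dense-likelihood oracles, and LRTs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridmap.lmm import (
    RandomTerm,
    lrt,
    ml_loglik,
    reml_fit,
    restricted_loglik,
    rlrt_test,
)


@pytest.fixture(scope="module")
def kernel60():
    rng = np.random.default_rng(0)
    z = rng.standard_normal((60, 8))
    return z @ z.T / 8


class TestREMLFit:
    def test_no_random_terms_reduces_to_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(50), rng.standard_normal(50)])
        y = X @ [1.0, 2.0] + rng.standard_normal(50)
        fit = reml_fit(y, X, [])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        sse = float(((y - X @ beta) ** 2).sum())
        assert np.allclose(fit.beta, beta)
        assert fit.variance_components["residual"] == pytest.approx(sse / 48)

    def test_balanced_oneway_matches_anova_closed_form(self):
        rng = np.random.default_rng(2)
        groups = np.repeat(np.arange(12), 5)
        y = 2.0 + rng.normal(0, 1.5, 12)[groups] + rng.standard_normal(60)
        fit = reml_fit(y, np.ones((60, 1)),
                       [RandomTerm("grp", kind="grouping", labels=groups)])
        means = pd.Series(y).groupby(groups).mean()
        msb = 5 * ((means - means.mean()) ** 2).sum() / 11
        msw = ((y - means[groups].to_numpy()) ** 2).sum() / (60 - 12)
        assert fit.variance_components["grp"] == pytest.approx((msb - msw) / 5,
                                                               abs=1e-6)
        assert fit.variance_components["residual"] == pytest.approx(msw, abs=1e-6)

    def test_rank_deficient_design_rejected(self):
        X = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            reml_fit(np.zeros(20), X, [])

    def test_fitted_loglik_beats_grid_and_matches_dense(self, kernel60):
        rng = np.random.default_rng(3)
        X = np.ones((60, 1))
        root = np.linalg.cholesky(kernel60 + 1e-9 * np.eye(60))
        y = root @ rng.standard_normal(60) + rng.standard_normal(60)
        fit = reml_fit(y, X, [RandomTerm("k", matrix=kernel60)])
        c = fit.variance_components
        V = c["k"] * kernel60 + c["residual"] * np.eye(60)
        assert fit.loglik_reml == pytest.approx(restricted_loglik(y, X, V),
                                                abs=1e-8)
        grid = [
            restricted_loglik(y, X, a * kernel60 + b * np.eye(60))
            for a in np.logspace(-3, 3, 30)
            for b in np.logspace(-3, 3, 30)
        ]
        assert fit.loglik_reml >= max(grid) - 1e-8

    def test_invariant_to_fixed_design_reparameterisation(self, kernel60):
        rng = np.random.default_rng(4)
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        y = X @ [1.0, 0.5] + rng.standard_normal(60)
        A = np.array([[3.0, -1.0], [2.0, 5.0]])
        f1 = reml_fit(y, X, [RandomTerm("k", matrix=kernel60)])
        f2 = reml_fit(y, X @ A, [RandomTerm("k", matrix=kernel60)])
        assert f1.loglik_reml == pytest.approx(f2.loglik_reml, abs=1e-6)
        for key in f1.variance_components:
            assert f1.variance_components[key] == pytest.approx(
                f2.variance_components[key], abs=1e-6)

    def test_components_never_negative_boundary_flagged(self, kernel60):
        rng = np.random.default_rng(5)
        for rep in range(10):
            y = rng.standard_normal(60)  # no kernel signal
            fit = reml_fit(y, np.ones((60, 1)),
                           [RandomTerm("k", matrix=kernel60)])
            assert all(v >= 0 for v in fit.variance_components.values())
            if fit.variance_components["k"] == 0.0:
                assert "k" in fit.boundary

    def test_profile_matches_dense_at_random_points(self, kernel60):
        """Surface evaluations agree between rotation and dense routes."""
        from hybridmap.lmm import _profile_ll_single, _single_term_rotation

        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        y = rng.standard_normal(60)
        xi, U, lam = _single_term_rotation(X, kernel60)
        eta2 = (U.T @ y) ** 2
        q = 60 - 2
        for gamma in rng.uniform(0.05, 20.0, size=20):
            quad = float(np.sum(eta2 / (gamma * xi + 1.0)))
            s2 = quad / q
            fast = _profile_ll_single(eta2, xi, lam, 60, q, gamma, "reml")
            dense = restricted_loglik(y, X, s2 * (gamma * kernel60 + np.eye(60)))
            assert fast == pytest.approx(dense, abs=1e-8)


class TestLRT:
    def test_identical_models_give_p_one(self, kernel60):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(60)
        fit = reml_fit(y, np.ones((60, 1)), [RandomTerm("k", matrix=kernel60)],
                       method="ml")
        assert lrt(fit, fit, 1) == pytest.approx(1.0)

    def test_chi_square_quantile_identity(self):
        assert stats.chi2.sf(3.841458820694124, 1) == pytest.approx(0.05)

    def test_optimizer_failure_detected(self, kernel60):
        rng = np.random.default_rng(8)
        y = rng.standard_normal(60)
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        full = reml_fit(y, X, [RandomTerm("k", matrix=kernel60)], method="ml")
        null = reml_fit(y, X[:, :1], [RandomTerm("k", matrix=kernel60)],
                        method="ml")
        with pytest.raises(ValueError, match="optimizer failure"):
            lrt(null, full, 1)  # swapped: "full" has lower likelihood

    def test_null_pvalues_uniform(self, kernel60):
        """Fixed-effect LRT is calibrated on simulated null traits."""
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        term = RandomTerm("k", matrix=kernel60)
        pvals = []
        for _ in range(300):
            y = rng.standard_normal(60)  # covariate has no effect
            full = reml_fit(y, X, [term], method="ml")
            null = reml_fit(y, X[:, :1], [term], method="ml")
            pvals.append(lrt(full, null, 1))
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestRLRT:
    def test_too_few_simulations_rejected(self, kernel60):
        with pytest.raises(ValueError):
            rlrt_test(np.zeros(60), np.ones((60, 1)),
                      RandomTerm("k", matrix=kernel60), n_sim=50)

    def test_boundary_component_gives_null_stat(self, kernel60):
        rng = np.random.default_rng(10)
        y = rng.standard_normal(60)
        stat, p = rlrt_test(y, np.ones((60, 1)),
                            RandomTerm("k", matrix=kernel60), n_sim=200, seed=1)
        assert stat >= 0.0
        if stat == 0.0:
            assert p > 0.5

    def test_detects_strong_genetic_signal(self, kernel60):
        rng = np.random.default_rng(11)
        root = np.linalg.cholesky(kernel60 + 1e-9 * np.eye(60))
        y = 2.0 * (root @ rng.standard_normal(60)) + rng.standard_normal(60)
        stat, p = rlrt_test(y, np.ones((60, 1)),
                            RandomTerm("k", matrix=kernel60), n_sim=400, seed=2)
        assert p < 0.05

    def test_power_at_high_heritability(self, cohort320, grm320, grm_root320):
        """h2 = 0.6 polygenic traits are detected at n = 320."""
        rng = np.random.default_rng(12)
        term = RandomTerm("g", matrix=grm320.matrix)
        X = np.ones((320, 1))
        sg = 0.6 / 0.4
        hits = 0
        reps = 20
        for r in range(reps):
            y = np.sqrt(sg) * (grm_root320 @ rng.standard_normal(320))
            y += rng.standard_normal(320)
            _, p = rlrt_test(y, X, term, n_sim=200, seed=100 + r)
            hits += p < 0.05
        assert hits / reps > 0.8

    def test_general_path_with_nuisance_term(self, kernel60):
        """Nested bootstrap path runs and is sane with a grouping nuisance."""
        rng = np.random.default_rng(13)
        groups = np.repeat(np.arange(12), 5)
        y = rng.normal(0, 1, 12)[groups] + rng.standard_normal(60)
        nuisance = [RandomTerm("grp", kind="grouping", labels=groups)]
        stat, p = rlrt_test(y, np.ones((60, 1)),
                            RandomTerm("k", matrix=kernel60),
                            nuisance_terms=nuisance, n_sim=100, seed=3)
        assert stat >= 0.0
        assert 0.0 < p <= 1.0
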