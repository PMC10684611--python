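"""LMM engine: closed-form oracles, limits, and an independent implementation
cross-check (statsmodels MixedLM is used as a test oracle only)."""

import numpy as np
import pytest

from choughs.lmm import (
    RankDeficientError,
    collinearity_screen,
    fit_random_intercept_lmm,
    satterthwaite_f,
)


def _balanced_dataset(rng, g=6, m=5, sigma_b=1.2, sigma=0.8, beta0=3.0):
    groups = np.repeat(np.arange(g), m)
    b = rng.normal(0, sigma_b, g)
    y = beta0 + b[groups] + rng.normal(0, sigma, g * m)
    return y, np.ones((g * m, 1)), groups


class TestREMLFit:
    def test_balanced_anova_closed_form(self):
        """On a balanced one-way layout the REML variance components equal the
        ANOVA moment estimators: sigma^2 = MSE, sigma_b^2 = (MSB - MSE)/m."""
        rng = np.random.default_rng(7)
        g, m = 6, 5
        y, X, groups = _balanced_dataset(rng, g=g, m=m)
        fit = fit_random_intercept_lmm(y, X, groups)
        ym = y.reshape(g, m)
        mse = np.sum((ym - ym.mean(1, keepdims=True)) ** 2) / (g * (m - 1))
        msb = m * np.sum((ym.mean(1) - y.mean()) ** 2) / (g - 1)
        assert fit.sigma2_resid == pytest.approx(mse, abs=1e-6)
        assert fit.sigma2_group == pytest.approx(max(0.0, (msb - mse) / m), abs=1e-6)
        assert fit.beta[0] == pytest.approx(y.mean(), abs=1e-8)

    def test_singleton_groups_reduce_to_ols(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.normal(size=n)
        y = 1.0 + 0.3 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_random_intercept_lmm(y, X, np.arange(n))
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.lam == 0.0
        assert not fit.group_variance_identifiable
        np.testing.assert_allclose(fit.beta, beta_ols, rtol=1e-10)

    def test_duplication_weighting_property_vs_brute_force(self):
        """Replicating the whole dataset (groups cloned under fresh labels)
        doubles every GLS building block, so the profiled beta(lambda) is
        duplication-invariant at any fixed lambda — checked against a dense
        brute-force GLS refit.  (The REML lambda-hat itself is allowed to
        shift, and rows duplicated *within* groups would change the weights.)"""
        rng = np.random.default_rng(11)
        y, X, groups = _balanced_dataset(rng)
        x1 = rng.normal(size=len(y))
        X = np.column_stack([X, x1])
        from choughs.lmm import _encode_groups, _profiled_reml

        y2 = np.concatenate([y, y])
        X2 = np.vstack([X, X])
        g2 = np.concatenate([groups, groups + 1000])
        for lam in (0.0, 0.3, 2.0):
            gi, gs = _encode_groups(groups)
            beta1 = _profiled_reml(lam, X, y, gi, gs)[1]
            gi2, gs2 = _encode_groups(g2)
            beta2 = _profiled_reml(lam, X2, y2, gi2, gs2)[1]
            np.testing.assert_allclose(beta1, beta2, rtol=1e-10)
            # dense brute-force GLS at the same lambda
            Z = (g2[:, None] == np.unique(g2)[None, :]).astype(float)
            V = np.eye(len(y2)) + lam * Z @ Z.T
            Vi = np.linalg.inv(V)
            beta_bf = np.linalg.solve(X2.T @ Vi @ X2, X2.T @ Vi @ y2)
            np.testing.assert_allclose(beta2, beta_bf, rtol=1e-8)

    def test_reml_local_optimality_on_grid(self):
        """The criterion at the returned lambda beats 0 and 10*lambda."""
        rng = np.random.default_rng(5)
        y, X, groups = _balanced_dataset(rng, g=10, m=6)
        fit = fit_random_intercept_lmm(y, X, groups)
        from choughs.lmm import _profiled_reml, _encode_groups

        gi, gs = _encode_groups(groups)
        ll_hat = _profiled_reml(fit.lam, X, y, gi, gs)[0]
        assert ll_hat >= _profiled_reml(0.0, X, y, gi, gs)[0] - 1e-9
        assert ll_hat >= _profiled_reml(10.0 * max(fit.lam, 0.1), X, y, gi, gs)[0] - 1e-9

    def test_rank_deficiency_names_aliased_column(self):
        rng = np.random.default_rng(1)
        n = 30
        x = rng.normal(size=n)
        X = np.column_stack([np.ones(n), x, 2.0 * x])
        with pytest.raises(RankDeficientError, match="dup"):
            fit_random_intercept_lmm(
                rng.normal(size=n), X, np.repeat(np.arange(6), 5),
                column_names=["int", "x", "dup"],
            )

    def test_cross_check_against_statsmodels(self):
        """beta within 1e-4 relative of an established mixed-model fit on
        random unbalanced datasets (oracle used in tests only)."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(2024)
        for _ in range(10):
            g = int(rng.integers(8, 15))
            sizes = rng.integers(2, 9, g)
            groups = np.repeat(np.arange(g), sizes)
            n = len(groups)
            x = rng.normal(size=n)
            b = rng.normal(0, 0.9, g)
            y = 0.5 + 0.7 * x + b[groups] + rng.normal(0, 0.6, n)
            X = np.column_stack([np.ones(n), x])
            fit = fit_random_intercept_lmm(y, X, groups)
            mf = sm.regression.mixed_linear_model.MixedLM(y, X, groups).fit(reml=True)
            np.testing.assert_allclose(fit.beta, mf.fe_params, rtol=1e-4)
            assert fit.sigma2_resid == pytest.approx(mf.scale, rel=1e-2)


class TestSatterthwaite:
    def test_ols_limit_matches_residual_df(self):
        rng = np.random.default_rng(3)
        n = 40
        x = rng.normal(size=n)
        y = 1.0 + 0.3 * x + rng.normal(size=n)
        X = np.column_stack([np.ones(n), x])
        fit = fit_random_intercept_lmm(y, X, np.arange(n))
        res = satterthwaite_f(fit, [[0.0, 1.0]])
        assert res.ddf == pytest.approx(n - 2, rel=0.01)

    def test_rank_invariance_of_duplicated_contrast(self):
        rng = np.random.default_rng(9)
        y, X, groups = _balanced_dataset(rng, g=8, m=4)
        x1 = rng.normal(size=len(y))
        X = np.column_stack([X, x1])
        fit = fit_random_intercept_lmm(y, X, groups)
        r1 = satterthwaite_f(fit, [[0.0, 1.0]])
        r2 = satterthwaite_f(fit, [[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        assert r2.ndf == 1
        assert r1.f_value == pytest.approx(r2.f_value, rel=1e-9)
        assert r1.ddf == pytest.approx(r2.ddf, rel=1e-9)

    def test_group_level_contrast_ddf_near_group_df(self):
        """A between-group predictor's denominator df should track the number
        of groups, not the number of observations."""
        rng = np.random.default_rng(21)
        g, m = 20, 10
        groups = np.repeat(np.arange(g), m)
        z = np.repeat(rng.normal(size=g), m)  # group-level covariate
        b = rng.normal(0, 1.0, g)
        y = 1.0 + b[groups] + rng.normal(0, 0.5, g * m)
        X = np.column_stack([np.ones(g * m), z])
        fit = fit_random_intercept_lmm(y, X, groups)
        res = satterthwaite_f(fit, [[0.0, 1.0]])
        assert 10 < res.ddf < 30  # near g-2 = 18, far from n-2 = 198

    def test_all_zero_contrast_rejected(self):
        rng = np.random.default_rng(4)
        y, X, groups = _balanced_dataset(rng)
        fit = fit_random_intercept_lmm(y, X, groups)
        with pytest.raises(ValueError):
            satterthwaite_f(fit, [[0.0]])


class TestCollinearityScreen:
    def test_identical_columns_drop_second(self):
        x = np.arange(20.0)
        assert collinearity_screen({"a": x, "b": x.copy()}, 0.7) == ["a"]

    def test_all_below_threshold_all_retained(self, rng):
        cols = {f"c{i}": rng.normal(size=50) for i in range(4)}
        assert collinearity_screen(cols, 0.7) == list(cols)

    def test_greedy_matches_brute_force_on_constructed_ranks(self):
        """rho(1,2) ~ 0.9, rho(1,3) ~ 0.2, rho(2,3) ~ 0.3: drop column 2."""
        rng = np.random.default_rng(0)
        n = 200
        u = rng.normal(size=n)
        c1 = u
        c2 = u + 0.35 * rng.normal(size=n)          # strongly rank-correlated with c1
        c3 = 0.25 * u + rng.normal(size=n)          # weakly correlated with both
        from scipy import stats as st

        assert abs(st.spearmanr(c1, c2).statistic) >= 0.9
        assert abs(st.spearmanr(c1, c3).statistic) < 0.4
        assert abs(st.spearmanr(c2, c3).statistic) < 0.4
        retained = collinearity_screen({"c1": c1, "c2": c2, "c3": c3}, 0.7)
        assert retained == ["c1", "c3"]
        # brute force: every maximal admissible subset containing the earliest
        # columns equals the greedy result
        import itertools

        cols = {"c1": c1, "c2": c2, "c3": c3}
        admissible = [
            s for r in range(3, 0, -1) for s in itertools.combinations(cols, r)
            if all(
                abs(st.spearmanr(cols[a], cols[b]).statistic) < 0.7
                for a, b in itertools.combinations(s, 2)
            )
        ]
        assert list(admissible[0]) == retained

    def test_constant_column_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = collinearity_screen({"k": np.ones(10), "x": np.arange(10.0)}, 0.7)
        assert out == ["x"]
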