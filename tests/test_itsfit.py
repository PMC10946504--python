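"""Segmented-regression estimators: oracles, whitening, cascade."""

import numpy as np
import pytest

from itsmeta import (
    ITSSeries,
    ITSTrueParams,
    build_design,
    fit_cascade,
    fit_ols,
    fit_pw,
    fit_reml,
    generate_its_series,
)
from itsmeta.itsfit import reml_profile_loglik


def _series_from_y(y, TI):
    y = np.asarray(y, dtype=float)
    return ITSSeries(t=np.arange(1, len(y) + 1), y=y, T=len(y), TI=TI)


class TestDesign:
    def test_regressor_values_short_series(self):
        X = build_design(12, 7)
        # pre rows: indicator and interaction zero
        assert np.all(X[:6, 2] == 0) and np.all(X[:6, 3] == 0)
        # interruption row: indicator on, interaction still zero
        assert X[6, 2] == 1 and X[6, 3] == 0
        # last row: 12 - 7 = 5 steps after interruption
        assert X[11, 3] == 5
        np.testing.assert_array_equal(X[:, 1], np.arange(1, 13))

    @pytest.mark.parametrize("T,TI", [(12, 7), (48, 25), (100, 51)])
    def test_full_rank_and_balance(self, T, TI):
        X = build_design(T, TI)
        assert np.linalg.matrix_rank(X) == 4
        assert (X[:, 2] == 0).sum() == T - (T - TI + 1)

    def test_unestimable_design_raises(self):
        with pytest.raises(ValueError):
            build_design(10, 4)  # only 3 pre points


class TestOLS:
    def test_exact_interpolation_of_noiseless_line(self):
        t = np.arange(1, 13)
        D = (t >= 7).astype(float)
        y = 0 + 0 * t + 1 * D + 0.1 * (t - 7) * D
        fit = fit_ols(_series_from_y(y, 7))
        np.testing.assert_allclose(fit.beta_hat, [0, 0, 1, 0.1], atol=1e-12)
        assert fit.converged and fit.method_used == "OLS"

    def test_matches_normal_equations_oracle(self, ar_series):
        fit = fit_ols(ar_series)
        X = build_design(ar_series.T, ar_series.TI)
        beta = np.linalg.solve(X.T @ X, X.T @ ar_series.y)
        np.testing.assert_allclose(fit.beta_hat, beta, atol=1e-10)
        resid = ar_series.y - X @ beta
        s2 = resid @ resid / (ar_series.T - 4)
        se = np.sqrt(s2 * np.diag(np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(fit.se, se, atol=1e-10)

    def test_unbiased_level_change(self):
        rng = np.random.default_rng(42)
        truth = ITSTrueParams(beta2=1.0, beta3=0.1, rho=0.4)
        est = [fit_ols(generate_its_series(truth, 48, 25, rng)).level_change
               for _ in range(1000)]
        mcse = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - 1.0) < 3 * mcse


class TestPW:
    def test_zero_autocorrelation_equals_ols(self):
        # build noise lying in the orthogonal complement of the design
        # and with exactly zero lag-1 autocovariance, so the estimated
        # rho is 0 and the transform is the identity
        rng = np.random.default_rng(0)
        X = build_design(12, 7)
        proj = np.eye(12) - X @ np.linalg.solve(X.T @ X, X.T)
        z1, z2 = proj @ rng.normal(size=12), proj @ rng.normal(size=12)
        a = z1[1:] @ z1[:-1]
        b = z1[1:] @ z2[:-1] + z2[1:] @ z1[:-1]
        c = z2[1:] @ z2[:-1]
        alpha = (-b + np.sqrt(b**2 - 4 * a * c)) / (2 * c)
        z = z1 + alpha * z2
        assert z[1:] @ z[:-1] == pytest.approx(0.0, abs=1e-10)
        y = X @ np.array([0.0, 0.0, 1.0, 0.1]) + z
        fit_p = fit_pw(_series_from_y(y, 7))
        fit_o = fit_ols(_series_from_y(y, 7))
        np.testing.assert_allclose(fit_p.beta_hat, fit_o.beta_hat,
                                   atol=1e-8)
        np.testing.assert_allclose(fit_p.se, fit_o.se, atol=1e-8)
        assert fit_p.rho_hat == pytest.approx(0.0, abs=1e-6)

    def test_transform_whitens_residuals(self):
        rng = np.random.default_rng(3)
        truth = ITSTrueParams(rho=0.6)
        s = generate_its_series(truth, 10_000, 5_001, rng)
        fit = fit_pw(s)
        assert fit.converged
        X = build_design(s.T, s.TI)
        c = np.sqrt(1 - fit.rho_hat**2)
        Xs = np.vstack([c * X[0], X[1:] - fit.rho_hat * X[:-1]])
        ys = np.concatenate([[c * s.y[0]], s.y[1:] - fit.rho_hat * s.y[:-1]])
        resid = ys - Xs @ fit.beta_hat
        r1 = (resid[1:] @ resid[:-1]) / (resid @ resid)
        assert abs(r1) < 0.02

    def test_recovers_rho_on_long_series(self):
        rng = np.random.default_rng(4)
        s = generate_its_series(ITSTrueParams(rho=0.4), 5_000, 2_501, rng)
        fit = fit_pw(s)
        assert fit.rho_hat == pytest.approx(0.4, abs=0.05)

    def test_pw_converges_where_reml_fails(self):
        # across many short noisy series, every REML failure is caught by PW
        rng = np.random.default_rng(5)
        n_fail = 0
        for _ in range(300):
            s = generate_its_series(ITSTrueParams(rho=0.6), 12, 7, rng)
            if not fit_reml(s).converged:
                n_fail += 1
                assert fit_pw(s).converged
        assert n_fail > 0  # short, highly autocorrelated series do fail


class TestREML:
    def test_rho_zero_profile_equals_ols(self, ar_series):
        X = build_design(ar_series.T, ar_series.TI)
        fit_o = fit_ols(ar_series)
        # at rho = 0 the whitened model is the OLS model, so the profiled
        # criterion uses the OLS residual variance with T - 4 denominator
        ll0 = reml_profile_loglik(X, ar_series.y, 0.0)
        dof = ar_series.T - 4
        sign, logdet = np.linalg.slogdet(X.T @ X)
        expected = -0.5 * (dof * np.log(fit_o.sigma2_hat) + logdet)
        assert ll0 == pytest.approx(expected, abs=1e-10)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(6)
        step = 1e-4
        rhos = np.arange(-0.999, 0.999 + step / 2, step)
        for _ in range(10):
            truth = ITSTrueParams(beta2=1, beta3=0.1,
                                  rho=rng.uniform(0, 0.6))
            s = generate_its_series(truth, 48, 25, rng)
            fit = fit_reml(s)
            X = build_design(s.T, s.TI)
            ll = _batched_profile(X, s.y, rhos)
            assert abs(fit.rho_hat - rhos[np.argmax(ll)]) < 1e-3

    def test_nonconvergence_concentrates_in_short_series(self):
        rng = np.random.default_rng(7)
        rates = {}
        for T in (12, 48, 100):
            fails = 0
            for _ in range(150):
                s = generate_its_series(ITSTrueParams(rho=0.4), T,
                                        T // 2 + 1, rng)
                fails += not fit_reml(s).converged
            rates[T] = fails / 150
        assert rates[12] > rates[48] >= rates[100]

    def test_se_accounts_for_autocorrelation(self):
        # under strong autocorrelation the OLS model SE understates the
        # sampling SD of the level-change; the REML model SE does not
        rng = np.random.default_rng(8)
        truth = ITSTrueParams(beta2=1.0, beta3=0.1, rho=0.6)
        ols_est, ols_se, reml_se = [], [], []
        for _ in range(300):
            s = generate_its_series(truth, 100, 51, rng)
            fo = fit_ols(s)
            fr = fit_reml(s)
            ols_est.append(fo.level_change)
            ols_se.append(fo.se_level)
            reml_se.append(fr.se_level)
        emp_sd = np.std(ols_est, ddof=1)
        assert np.mean(ols_se) < 0.7 * emp_sd
        # REML ratios at this length sit in roughly (0.75, 1); the key
        # direction is that REML closes most of the OLS shortfall
        assert np.mean(reml_se) > 0.75 * emp_sd
        assert np.mean(reml_se) > 1.4 * np.mean(ols_se)


def _batched_profile(X, y, rhos):
    """Vectorised restricted profile log-likelihood over a rho grid."""
    T, p = X.shape
    c = np.sqrt(1 - rhos**2)
    Xs = np.empty((len(rhos), T, p))
    ys = np.empty((len(rhos), T))
    Xs[:, 0] = c[:, None] * X[0]
    ys[:, 0] = c * y[0]
    Xs[:, 1:] = X[1:] - rhos[:, None, None] * X[:-1]
    ys[:, 1:] = y[1:] - rhos[:, None] * y[:-1]
    G = np.einsum("rti,rtj->rij", Xs, Xs)
    b = np.linalg.solve(G, np.einsum("rti,rt->ri", Xs, ys)[..., None])[..., 0]
    resid = ys - np.einsum("rti,ri->rt", Xs, b)
    rss = np.einsum("rt,rt->r", resid, resid)
    dof = T - p
    logdet = np.linalg.slogdet(G)[1]
    return -0.5 * (dof * np.log(rss / dof) - np.log1p(-rhos**2) + logdet)


class TestCascade:
    def test_first_preference_used_when_it_converges(self, ar_series):
        fit = fit_cascade(ar_series)
        assert fit.method_used == "REML"

    def test_fallback_to_pw_on_reml_failure(self):
        rng = np.random.default_rng(9)
        seen_pw = False
        for _ in range(300):
            s = generate_its_series(ITSTrueParams(rho=0.6), 12, 7, rng)
            fit = fit_cascade(s)
            assert fit.converged
            if fit.method_used == "PW":
                seen_pw = True
        assert seen_pw

    def test_forced_ols_order(self, ar_series):
        fit = fit_cascade(ar_series, order=("OLS",))
        ref = fit_ols(ar_series)
        assert fit.method_used == "OLS"
        np.testing.assert_array_equal(fit.beta_hat, ref.beta_hat)

    def test_empty_order_rejected(self, ar_series):
        with pytest.raises(ValueError):
            fit_cascade(ar_series, order=())


class TestLocationEquivariance:
    @pytest.mark.parametrize("fitter", [fit_ols, fit_pw, fit_reml])
    def test_constant_shift_moves_only_intercept(self, fitter, ar_series):
        base = fitter(ar_series)
        shifted = ITSSeries(t=ar_series.t, y=ar_series.y + 10.0,
                            T=ar_series.T, TI=ar_series.TI)
        fit = fitter(shifted)
        assert fit.beta_hat[0] == pytest.approx(base.beta_hat[0] + 10.0,
                                                abs=1e-6)
        np.testing.assert_allclose(fit.beta_hat[1:], base.beta_hat[1:],
                                   atol=1e-6)
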