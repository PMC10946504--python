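"""Segmented-regression estimation for a single interrupted time series.

Three estimators of the model

    y_t = beta0 + beta1 * t + beta2 * D_t + beta3 * (t - TI) * D_t + e_t

with AR(1) errors ``e_t = rho * e_{t-1} + w_t`` are provided:

* :func:`fit_ols` — ordinary least squares, ignoring autocorrelation
  (rho fixed at 0); point estimates are unbiased but standard errors
  are biased when rho != 0.
* :func:`fit_pw` — iterated Prais-Winsten generalised least squares:
  estimate rho from the residuals, quasi-difference the data (keeping
  the first observation scaled by sqrt(1 - rho^2)), refit, and repeat
  to convergence.
* :func:`fit_reml` — restricted maximum likelihood for the linear model
  with AR(1) error correlation, profiling the restricted log-likelihood
  over rho with closed-form GLS coefficients at each candidate value.

:func:`fit_cascade` applies them in order of preference, falling back
when an estimator fails to converge; OLS always converges and so
terminates the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .datagen import ITSSeries

__all__ = [
    "ITSFit",
    "build_design",
    "fit_ols",
    "fit_pw",
    "fit_reml",
    "fit_cascade",
    "reml_profile_loglik",
]

N_PARAMS = 4
RHO_BOUND = 0.999
#: rho within this distance of the +/-0.999 bound counts as a boundary
#: solution, i.e. REML non-convergence.
BOUNDARY_TOL = 1e-3


@dataclass(frozen=True)
class ITSFit:
    """Estimated segmented-regression coefficients for one series.

    ``beta_hat`` and ``se`` are ordered (intercept, pre-slope,
    level-change, slope-change).  ``rho_hat`` is 0 by construction for
    OLS.  ``method_used`` records which estimator produced the fit —
    for a cascade, the first one that converged.
    """

    beta_hat: np.ndarray
    se: np.ndarray
    rho_hat: float
    sigma2_hat: float
    method_used: str
    converged: bool
    n_iter: int = 0

    @property
    def level_change(self) -> float:
        return float(self.beta_hat[2])

    @property
    def slope_change(self) -> float:
        return float(self.beta_hat[3])

    @property
    def se_level(self) -> float:
        return float(self.se[2])

    @property
    def se_slope(self) -> float:
        return float(self.se[3])


def build_design(T: int, TI: int) -> np.ndarray:
    """Design matrix [1, t, D_t, (t - TI) D_t] for t = 1..T.

    Raises if either segment has fewer than 4 points, in which case the
    four columns are not estimable.
    """
    n_pre, n_post = TI - 1, T - TI + 1
    if n_pre < N_PARAMS or n_post < N_PARAMS:
        raise ValueError(
            f"design not estimable: {n_pre} pre / {n_post} post points"
        )
    t = np.arange(1, T + 1, dtype=float)
    D = (t >= TI).astype(float)
    return np.column_stack([np.ones(T), t, D, (t - TI) * D])


def _whiten(X: np.ndarray, y: np.ndarray, rho: float):
    """Prais-Winsten transform removing AR(1) correlation at given rho."""
    c = np.sqrt(1.0 - rho**2)
    Xs = np.empty_like(X)
    ys = np.empty_like(y)
    Xs[0] = c * X[0]
    ys[0] = c * y[0]
    Xs[1:] = X[1:] - rho * X[:-1]
    ys[1:] = y[1:] - rho * y[:-1]
    return Xs, ys


def _gls_at_rho(X: np.ndarray, y: np.ndarray, rho: float):
    """GLS coefficients, RSS and Gram matrix after whitening at rho."""
    Xs, ys = _whiten(X, y, rho)
    G = Xs.T @ Xs
    beta = np.linalg.solve(G, Xs.T @ ys)
    resid = ys - Xs @ beta
    return beta, float(resid @ resid), G


def _lag1_autocorr(resid: np.ndarray, scale: float = 0.0) -> float:
    denom = float(resid @ resid)
    # residuals at rounding-error level (perfect fit) carry no signal
    if denom <= 1e-24 * max(scale, 1.0):
        return 0.0
    return float(resid[1:] @ resid[:-1]) / denom


def fit_ols(series: ITSSeries) -> ITSFit:
    """Ordinary least squares fit of the segmented model.

    Standard errors use the classical homoskedastic-independent
    covariance with residual degrees of freedom T - 4.
    """
    X = build_design(series.T, series.TI)
    y = series.y
    G = X.T @ X
    beta = np.linalg.solve(G, X.T @ y)
    resid = y - X @ beta
    dof = series.T - N_PARAMS
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(G)))
    return ITSFit(
        beta_hat=beta,
        se=se,
        rho_hat=0.0,
        sigma2_hat=sigma2,
        method_used="OLS",
        converged=True,
    )


def fit_pw(
    series: ITSSeries, tol: float = 1e-6, max_iter: int = 100
) -> ITSFit:
    """Iterated Prais-Winsten generalised least squares.

    Alternates between estimating rho from the lag-1 autocorrelation of
    the current (untransformed-scale) residuals and refitting on the
    quasi-differenced data, until successive rho estimates change by
    less than ``tol``.  Estimates of |rho| at or beyond 1 are clamped to
    +/-0.999 and iteration continues; failure to settle within
    ``max_iter`` iterations is flagged as non-convergence.
    """
    X = build_design(series.T, series.TI)
    y = series.y

    ssy = float(y @ y)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    rho = _lag1_autocorr(y - X @ beta, ssy)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        rho = float(np.clip(rho, -RHO_BOUND, RHO_BOUND))
        beta, _, _ = _gls_at_rho(X, y, rho)
        rho_new = _lag1_autocorr(y - X @ beta, ssy)
        if abs(rho_new - rho) < tol:
            rho = float(np.clip(rho_new, -RHO_BOUND, RHO_BOUND))
            converged = True
            break
        rho = rho_new

    beta, rss, G = _gls_at_rho(X, y, rho)
    dof = series.T - N_PARAMS
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(G)))
    return ITSFit(
        beta_hat=beta,
        se=se,
        rho_hat=rho,
        sigma2_hat=sigma2,
        method_used="PW",
        converged=converged,
        n_iter=n_iter,
    )


def reml_profile_loglik(
    X: np.ndarray, y: np.ndarray, rho: float
) -> float:
    """Restricted log-likelihood profiled over (beta, sigma^2) at rho.

    For y ~ N(X beta, sigma^2 V(rho)) with V the AR(1) correlation
    structure scaled so the whitened errors have variance sigma^2, the
    REML criterion with sigma^2 profiled out is (up to a constant)

        -1/2 [ (n - p) log(RSS / (n - p)) + log|V| + log|X' V^-1 X| ]

    where RSS is the whitened residual sum of squares and
    log|V| = -log(1 - rho^2).
    """
    n, p = X.shape
    _, rss, G = _gls_at_rho(X, y, rho)
    dof = n - p
    if rss <= 0:
        return np.inf  # degenerate (noiseless) input
    sign, logdet_G = np.linalg.slogdet(G)
    if sign <= 0:
        return -np.inf
    logdet_V = -np.log1p(-rho**2)
    return -0.5 * (dof * np.log(rss / dof) + logdet_V + logdet_G)


def fit_reml(series: ITSSeries) -> ITSFit:
    """REML fit of the segmented model with AR(1) errors.

    Maximises the restricted log-likelihood over rho in
    (-0.999, 0.999) by bounded scalar optimisation; beta and sigma^2
    have closed GLS forms at each rho.  Standard errors come from the
    GLS covariance sigma^2 (X' V^-1 X)^-1 at the optimum.  A boundary
    solution in rho, a non-finite objective or an optimiser failure is
    reported as non-convergence (the cascade then falls back).
    """
    X = build_design(series.T, series.TI)
    y = series.y

    res = optimize.minimize_scalar(
        lambda r: -reml_profile_loglik(X, y, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    converged = bool(res.success) and bool(np.isfinite(res.fun))
    if abs(rho) >= RHO_BOUND - BOUNDARY_TOL:
        converged = False

    beta, rss, G = _gls_at_rho(X, y, rho)
    dof = series.T - N_PARAMS
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(G)))
    return ITSFit(
        beta_hat=beta,
        se=se,
        rho_hat=rho,
        sigma2_hat=sigma2,
        method_used="REML",
        converged=converged,
        n_iter=int(getattr(res, "nfev", 0)),
    )


_FITTERS = {"OLS": fit_ols, "PW": fit_pw, "REML": fit_reml}


def fit_cascade(
    series: ITSSeries, order: tuple[str, ...] = ("REML", "PW", "OLS")
) -> ITSFit:
    """Fit by the first converging estimator in preference order.

    The default order is REML, then Prais-Winsten, then OLS.  The last
    attempted fit is returned even if none converged (this cannot occur
    when OLS, which always converges, is in the order).
    """
    if not order:
        raise ValueError("order must name at least one method")
    fit = None
    for name in order:
        try:
            fitter = _FITTERS[name.upper()]
        except KeyError:
            raise ValueError(f"unknown method {name!r}") from None
        fit = fitter(series)
        if fit.converged:
            return fit
    return fit
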