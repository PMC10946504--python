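"""Two-stage univariate meta-analysis of study-level effect estimates.

Given K estimates ``b_k`` with within-study variances ``v_k`` (treated
as known, the standard two-stage assumption), this module implements:

* fixed-effect (common-effect) inverse-variance pooling, weights 1/v_k;
* random-effects pooling with weights 1/(v_k + tau2);
* two between-study variance estimators — the moment-based
  DerSimonian-Laird estimator derived from Cochran's Q, and the
  iterative REML estimator — both truncated at zero;
* two confidence-interval methods — the Wald-type (WT) normal interval
  and the Hartung-Knapp/Sidik-Jonkman (HKSJ) interval, which rescales
  the pooled variance by the small-sample factor q and uses a
  t reference with K - 1 degrees of freedom.

The HKSJ q is used exactly as defined, without the common
``max(1, q)`` modification; with zero observed dispersion the interval
degenerates to zero width, which is a documented property of the
original estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetaInput",
    "MetaResult",
    "fixed_effect_pool",
    "dl_tau2",
    "reml_tau2",
    "random_effects_pool",
    "wt_ci",
    "hksj_ci",
    "meta_analyse",
    "META_METHODS",
]

#: The five (model, tau2 estimator, CI method) combinations evaluated.
META_METHODS: tuple[tuple[str, str | None, str], ...] = (
    ("fixed", None, "WT"),
    ("random", "DL", "WT"),
    ("random", "DL", "HKSJ"),
    ("random", "REML", "WT"),
    ("random", "REML", "HKSJ"),
)


@dataclass(frozen=True)
class MetaInput:
    """K study-level estimates with known within-study variances."""

    estimates: np.ndarray
    variances: np.ndarray
    effect_label: str = ""

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        var = np.asarray(self.variances, dtype=float)
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "variances", var)
        if est.shape != var.shape or est.ndim != 1:
            raise ValueError("estimates and variances must be equal-length 1-d")
        if len(est) < 2:
            raise ValueError("meta-analysis needs at least two studies")
        if not np.all(np.isfinite(est)) or not np.all(np.isfinite(var)):
            raise ValueError("estimates and variances must be finite")
        if np.any(var <= 0):
            raise ValueError("within-study variances must be positive")

    @property
    def K(self) -> int:
        return len(self.estimates)

    @classmethod
    def from_se(cls, estimates, se, effect_label: str = "") -> "MetaInput":
        se = np.asarray(se, dtype=float)
        return cls(np.asarray(estimates, dtype=float), se**2, effect_label)


@dataclass(frozen=True)
class MetaResult:
    """Pooled effect, uncertainty and heterogeneity for one effect measure."""

    model: str                 # "fixed" | "random"
    tau2_method: str | None    # None | "DL" | "REML"
    ci_method: str             # "WT" | "HKSJ"
    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    p_value: float
    tau2: float
    Q: float
    alpha: float = 0.05
    df: int | None = None      # K - 1 when HKSJ
    converged: bool = True     # REML tau2 iteration status
    effect_label: str = ""

    @property
    def method_label(self) -> str:
        if self.model == "fixed":
            return "Fixed"
        return f"{self.tau2_method}+{self.ci_method}"


def _pool(estimates: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    """Weighted mean and its base variance 1/sum(weights)."""
    wsum = weights.sum()
    return float((weights * estimates).sum() / wsum), float(1.0 / wsum)


def cochran_q(input: MetaInput) -> float:
    """Cochran's Q about the fixed-effect pooled estimate."""
    w = 1.0 / input.variances
    mu, _ = _pool(input.estimates, w)
    return float((w * (input.estimates - mu) ** 2).sum())


def wt_ci(
    pooled: float, variance: float, alpha: float = 0.05
) -> tuple[float, float, float]:
    """Wald-type normal interval and two-sided p-value."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    se = np.sqrt(variance)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    p = 2.0 * stats.norm.sf(abs(pooled) / se)
    return pooled - z * se, pooled + z * se, float(p)


def fixed_effect_pool(
    input: MetaInput, alpha: float = 0.05
) -> MetaResult:
    """Fixed-effect inverse-variance pooling with a WT interval."""
    w = 1.0 / input.variances
    pooled, var = _pool(input.estimates, w)
    lo, hi, p = wt_ci(pooled, var, alpha)
    return MetaResult(
        model="fixed",
        tau2_method=None,
        ci_method="WT",
        pooled=pooled,
        se_pooled=float(np.sqrt(var)),
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        tau2=0.0,
        Q=cochran_q(input),
        alpha=alpha,
        effect_label=input.effect_label,
    )


def dl_tau2(input: MetaInput) -> tuple[float, float]:
    """DerSimonian-Laird between-study variance and Cochran's Q.

    tau2 = max(0, (Q - (K - 1)) / (sum(w) - sum(w^2)/sum(w))) with
    fixed-effect weights w = 1/v_k.
    """
    w = 1.0 / input.variances
    Q = cochran_q(input)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (Q - (input.K - 1)) / denom)
    return tau2, Q


def _ml_tau2(input: MetaInput, start: float, max_iter: int = 20) -> float:
    """Maximum-likelihood tau2 fixed point, used to start the REML loop."""
    b, v = input.estimates, input.variances
    tau2 = start
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * b).sum() / w.sum()
        tau2 = max(0.0, float((w**2 * ((b - mu) ** 2 - v)).sum() / (w**2).sum()))
    return tau2

def reml_tau2(
    input: MetaInput, tol: float = 1e-8, max_iter: int = 100
) -> tuple[float, bool]:
    """Iterative REML between-study variance estimate.

    Repeats the fixed-point update

        tau2 <- max(0, sum(w^2 ((b - mu)^2 - v)) / sum(w^2) + 1/sum(w))

    with random-effects weights w = 1/(v + tau2) recomputed (and the
    pooled mean mu with them) at each step.  The extra 1/sum(w) term is
    the REML degrees-of-freedom correction absent from the ML update.
    Started from the ML estimate (itself started at DL); stops when the
    change falls below ``tol``, or flags non-convergence at
    ``max_iter``.
    """
    b, v = input.estimates, input.variances
    tau2 = _ml_tau2(input, start=dl_tau2(input)[0])
    converged = False
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = (w * b).sum() / w.sum()
        new = max(
            0.0,
            float((w**2 * ((b - mu) ** 2 - v)).sum() / (w**2).sum()
                  + 1.0 / w.sum()),
        )
        if abs(new - tau2) < tol:
            tau2 = new
            converged = True
            break
        tau2 = new
    return tau2, converged


def random_effects_pool(
    input: MetaInput, tau2: float
) -> tuple[float, float]:
    """Random-effects pooled estimate and base variance 1/sum(w_RE).

    Weights are 1/(v_k + tau2); tau2 = 0 reduces to fixed-effect
    pooling.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    w = 1.0 / (input.variances + tau2)
    return _pool(input.estimates, w)


def hksj_ci(
    input: MetaInput, tau2: float, alpha: float = 0.05
) -> tuple[float, float, float, float]:
    """HKSJ interval: (ci_low, ci_high, adjusted se, p-value).

    The pooled variance 1/sum(w_RE) is rescaled by

        q = sum(w_RE (b_k - mu)^2) / (K - 1)

    and the reference distribution is t with K - 1 df.  q is not
    truncated below 1, so identical estimates give a zero-width
    interval.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    b, v = input.estimates, input.variances
    K = input.K
    w = 1.0 / (v + tau2)
    mu = (w * b).sum() / w.sum()
    q = float((w * (b - mu) ** 2).sum() / (K - 1))
    var = q / float(w.sum())
    se = float(np.sqrt(var))
    tq = stats.t.ppf(1.0 - alpha / 2.0, K - 1)
    if se > 0:
        p = 2.0 * stats.t.sf(abs(mu) / se, K - 1)
    else:
        p = 0.0 if mu != 0 else 1.0  # degenerate zero-dispersion case
    return mu - tq * se, mu + tq * se, se, float(p)


def meta_analyse(
    input: MetaInput,
    model: str = "random",
    tau2_method: str | None = "REML",
    ci_method: str = "WT",
    alpha: float = 0.05,
) -> MetaResult:
    """Run one of the five evaluated meta-analysis method combinations.

    ``model="fixed"`` forces no heterogeneity estimation and a WT
    interval; ``model="random"`` requires ``tau2_method`` in
    {"DL", "REML"} and ``ci_method`` in {"WT", "HKSJ"}.
    """
    if model == "fixed":
        if tau2_method is not None or ci_method != "WT":
            raise ValueError(
                "fixed model uses no tau2 estimator and a WT interval"
            )
        return fixed_effect_pool(input, alpha)
    if model != "random":
        raise ValueError(f"unknown model {model!r}")
    if ci_method not in ("WT", "HKSJ"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    if tau2_method == "DL":
        tau2, Q = dl_tau2(input)
        converged = True
    elif tau2_method == "REML":
        tau2, converged = reml_tau2(input)
        Q = cochran_q(input)
    else:
        raise ValueError(f"unknown tau2_method {tau2_method!r}")

    pooled, var = random_effects_pool(input, tau2)
    if ci_method == "WT":
        lo, hi, p = wt_ci(pooled, var, alpha)
        se, df = float(np.sqrt(var)), None
    else:
        lo, hi, se, p = hksj_ci(input, tau2, alpha)
        df = input.K - 1
    return MetaResult(
        model="random",
        tau2_method=tau2_method,
        ci_method=ci_method,
        pooled=pooled,
        se_pooled=se,
        ci_low=lo,
        ci_high=hi,
        p_value=p,
        tau2=tau2,
        Q=Q,
        alpha=alpha,
        df=df,
        converged=converged,
        effect_label=input.effect_label,
    )
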