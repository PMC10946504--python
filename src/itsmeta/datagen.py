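"""Generation of interrupted time series (ITS) data with AR(1) errors.

A single ITS is drawn from the segmented linear model

    y_t = beta0 + beta1 * t + beta2 * D_t + beta3 * (t - TI) * D_t + e_t,
    e_t = rho * e_{t-1} + w_t,      w_t ~ N(0, 1) i.i.d.,

where ``D_t = 1`` for ``t >= TI`` (the post-interruption indicator) and
``TI`` is the interruption time point.  ``beta2`` is the immediate
level-change and ``beta3`` the slope-change — the two interruption
effects a meta-analysis later pools across studies.

Meta-analytic collections of K series are built by perturbing the
interruption effects with study-level random effects,
``beta2_k = beta2 + N(0, tau2_level)`` and
``beta3_k = beta3 + N(0, tau2_slope)``, so that ``tau2_* = 0``
corresponds to a common-effect (fixed-effect) generating model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

__all__ = [
    "ITSTrueParams",
    "ITSSeries",
    "ScenarioSpec",
    "MetaSample",
    "draw_autocorrelation",
    "generate_its_series",
    "generate_meta_sample",
    "default_interruption_time",
]

#: Minimum number of observations required on each side of the
#: interruption so that the four regression coefficients are estimable.
MIN_SEGMENT = 4


@dataclass(frozen=True)
class ITSTrueParams:
    """True generating parameters of one segmented AR(1) series.

    Parameters
    ----------
    beta0, beta1 : float
        Pre-interruption level intercept and slope (outcome units, and
        outcome units per time step).
    beta2 : float
        Immediate level-change at the interruption.
    beta3 : float
        Change in slope from the pre- to the post-interruption period.
    rho : float
        Lag-1 autocorrelation of the errors, in (-1, 1).
    sigma_w : float
        White-noise (innovation) standard deviation; 1 by construction
        for the simulation design.
    """

    beta0: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    rho: float = 0.0
    sigma_w: float = 1.0

    def __post_init__(self) -> None:
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"rho must lie in (-1, 1), got {self.rho}")
        if self.sigma_w <= 0:
            raise ValueError("sigma_w must be positive")


@dataclass(frozen=True)
class ITSSeries:
    """One interrupted time series with its (optional) generating truth."""

    t: np.ndarray
    y: np.ndarray
    T: int
    TI: int
    truth: ITSTrueParams | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if len(y) != self.T or len(t) != self.T:
            raise ValueError("t and y must have length T")
        _check_segments(self.T, self.TI)


def _check_segments(T: int, TI: int) -> None:
    """Both segments need >= MIN_SEGMENT points to fit 4 coefficients."""
    n_pre = TI - 1          # points with t < TI
    n_post = T - TI + 1     # points with t >= TI
    if n_pre < MIN_SEGMENT or n_post < MIN_SEGMENT:
        raise ValueError(
            f"segments too short for estimation: {n_pre} pre / {n_post} post "
            f"points (need >= {MIN_SEGMENT} each; T={T}, TI={TI})"
        )


def default_interruption_time(T: int) -> int:
    """Interruption index giving an equal pre/post split.

    With the post-period indicator ``D_t = 1`` for ``t >= TI``, setting
    ``TI = T/2 + 1`` puts exactly ``T/2`` points before and ``T/2``
    points after the interruption for even ``T``.
    """
    return T // 2 + 1


# Variable-autocorrelation distribution of the study design:
# rho* ~ N(0.4, 0.15^2), resampled when outside (-1, 1).
VARIABLE_RHO_MEAN = 0.4
VARIABLE_RHO_SD = 0.15


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the factorial simulation design.

    ``rho_mode`` is either ``"fixed"`` (every study in a meta-analysis
    shares the constant ``rho``) or ``"variable"`` (each study draws an
    independent autocorrelation from N(0.4, 0.15^2), truncated by
    rejection to (-1, 1)).
    """

    T: int
    beta2: float
    beta3: float
    rho_mode: str
    rho: float
    K: int
    tau2_level: float
    tau2_slope: float
    TI: int | None = None
    beta0: float = 0.0
    beta1: float = 0.0
    n_reps: int = 1000
    seed: int = 0
    scenario_id: str = ""

    def __post_init__(self) -> None:
        if self.rho_mode not in ("fixed", "variable"):
            raise ValueError(f"unknown rho_mode {self.rho_mode!r}")
        if self.K < 2:
            raise ValueError("K must be >= 2")
        if self.tau2_level < 0 or self.tau2_slope < 0:
            raise ValueError("between-study variances must be >= 0")
        if self.TI is None:
            object.__setattr__(self, "TI", default_interruption_time(self.T))
        _check_segments(self.T, self.TI)

    def with_id(self, scenario_id: str) -> "ScenarioSpec":
        return replace(self, scenario_id=scenario_id)


@dataclass(frozen=True)
class MetaSample:
    """K generated ITS studies plus their study-specific true effects."""

    series: tuple[ITSSeries, ...]
    true_level_effects: np.ndarray
    true_slope_effects: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.series) == len(self.true_level_effects)
                == len(self.true_slope_effects)):
            raise ValueError("per-study effects must match number of series")

    @property
    def K(self) -> int:
        return len(self.series)


def draw_autocorrelation(spec: ScenarioSpec, rng: np.random.Generator) -> float:
    """Draw one study-level autocorrelation for a scenario.

    In fixed mode the scenario constant is returned.  In variable mode a
    draw from N(0.4, 0.15^2) is taken and redrawn until it falls inside
    the stationarity region (-1, 1).
    """
    if spec.rho_mode == "fixed":
        return spec.rho
    while True:
        rho = rng.normal(VARIABLE_RHO_MEAN, VARIABLE_RHO_SD)
        if -1.0 < rho < 1.0:
            return rho


def generate_its_series(
    truth: ITSTrueParams,
    T: int,
    TI: int,
    rng: np.random.Generator,
) -> ITSSeries:
    """Simulate one segmented series with stationary AR(1) errors.

    The first error is drawn from the stationary distribution
    ``N(0, sigma_w^2 / (1 - rho^2))`` so that the error process has the
    same marginal law at every t; subsequent errors follow the recursion
    ``e_t = rho * e_{t-1} + w_t``.
    """
    _check_segments(T, TI)
    t = np.arange(1, T + 1)
    D = (t >= TI).astype(float)
    mean = (
        truth.beta0
        + truth.beta1 * t
        + truth.beta2 * D
        + truth.beta3 * (t - TI) * D
    )

    rho, sw = truth.rho, truth.sigma_w
    w = rng.normal(0.0, sw, size=T)
    w[0] = rng.normal(0.0, sw / np.sqrt(1.0 - rho**2))
    # e_t = rho e_{t-1} + w_t as a linear recursion, seeded with a
    # stationary first error in place of w_1
    e = signal.lfilter([1.0], [1.0, -rho], w)

    return ITSSeries(t=t, y=mean + e, T=T, TI=TI, truth=truth)


def generate_meta_sample(
    spec: ScenarioSpec, rng: np.random.Generator
) -> MetaSample:
    """Generate the K ITS studies of one replicate meta-analysis.

    Study-specific interruption effects are drawn about the scenario
    means with between-study SDs sqrt(tau2_level) and sqrt(tau2_slope).
    In fixed autocorrelation mode all studies share the scenario rho;
    in variable mode each study receives an independent draw.
    """
    level_effects = spec.beta2 + rng.normal(
        0.0, np.sqrt(spec.tau2_level), size=spec.K
    )
    slope_effects = spec.beta3 + rng.normal(
        0.0, np.sqrt(spec.tau2_slope), size=spec.K
    )

    series = []
    for k in range(spec.K):
        rho_k = draw_autocorrelation(spec, rng)
        truth = ITSTrueParams(
            beta0=spec.beta0,
            beta1=spec.beta1,
            beta2=level_effects[k],
            beta3=slope_effects[k],
            rho=rho_k,
        )
        series.append(generate_its_series(truth, spec.T, spec.TI, rng))

    return MetaSample(
        series=tuple(series),
        true_level_effects=level_effects,
        true_slope_effects=slope_effects,
    )
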