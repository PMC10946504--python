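"""Monte-Carlo performance measures for the simulation study.

For each scenario and analysis-method combination the replicate pooled
estimates, standard errors and confidence intervals are reduced to the
standard simulation-study measures: bias, empirical SE, model-based SE
(root-mean-square of the replicate model SEs), their ratio, confidence
interval coverage, and the rejection rate of the zero-effect test
(statistical power, or the type I error rate when the true effect is
zero).  Each headline measure carries its Monte Carlo standard error:

    MCSE(bias)     = empSE / sqrt(n)
    MCSE(coverage) = sqrt(cov% * (100 - cov%) / n)   (percentage points)

and likewise for power.  Replicates whose REML between-study-variance
iteration failed to converge are excluded from that method's summaries
and counted separately rather than silently replaced.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["ReplicateRecord", "PerformanceSummary", "summarize",
           "tally_convergence", "coverage_mcse"]


@dataclass(frozen=True)
class ReplicateRecord:
    """One meta-analysis outcome from one simulation replicate."""

    scenario_id: str
    replicate: int
    its_method: str        # "OLS" or "cascade" (REML -> PW -> OLS)
    meta_method: str       # "Fixed", "DL+WT", "DL+HKSJ", "REML+WT", "REML+HKSJ"
    effect_label: str      # "level" or "slope"
    pooled: float
    se_pooled: float
    ci_low: float
    ci_high: float
    tau2: float
    its_methods_used: tuple[str, ...] = ()
    meta_converged: bool = True


@dataclass(frozen=True)
class PerformanceSummary:
    """Performance measures for one (scenario, method, effect) cell."""

    scenario_id: str
    its_method: str
    meta_method: str
    effect_label: str
    truth: float
    n_reps: int
    n_used: int            # replicates after dropping non-converged meta fits
    bias: float
    bias_mcse: float
    emp_se: float
    mod_se: float
    mod_to_emp: float
    coverage: float        # percent
    coverage_mcse: float   # percentage points
    power_or_type1: float  # percent of CIs excluding zero
    power_mcse: float
    mean_tau2: float
    median_tau2: float
    prop_tau2_positive: float
    n_meta_nonconverged: int


def coverage_mcse(coverage_pct: float, n_reps: int) -> float:
    """Monte Carlo SE of a percentage over n_reps replicates."""
    return float(np.sqrt(coverage_pct * (100.0 - coverage_pct) / n_reps))


def _single_cell(records: Sequence[ReplicateRecord]) -> None:
    keys = {(r.scenario_id, r.its_method, r.meta_method, r.effect_label)
            for r in records}
    if len(keys) != 1:
        raise ValueError(
            "records must come from a single "
            f"(scenario, its_method, meta_method, effect) cell; got {keys}"
        )


def summarize(
    records: Sequence[ReplicateRecord], truth: float
) -> PerformanceSummary:
    """Reduce one cell's replicate records to its performance measures.

    ``truth`` is the estimand: the common effect under fixed-effect
    generation, or the mean of the random-effects distribution under
    heterogeneous generation.
    """
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least two replicates")
    _single_cell(records)
    r0 = records[0]

    n_total = len(records)
    used = [r for r in records if r.meta_converged]
    n_bad = n_total - len(used)
    if len(used) < 2:
        raise ValueError("fewer than two converged replicates")

    pooled = np.array([r.pooled for r in used])
    se = np.array([r.se_pooled for r in used])
    lo = np.array([r.ci_low for r in used])
    hi = np.array([r.ci_high for r in used])
    tau2 = np.array([r.tau2 for r in used])
    n = len(used)

    bias = float(pooled.mean() - truth)
    emp_se = float(pooled.std(ddof=1))
    mod_se = float(np.sqrt((se**2).mean()))
    cover = float(100.0 * ((lo <= truth) & (truth <= hi)).mean())
    reject = float(100.0 * ((lo > 0.0) | (hi < 0.0)).mean())

    return PerformanceSummary(
        scenario_id=r0.scenario_id,
        its_method=r0.its_method,
        meta_method=r0.meta_method,
        effect_label=r0.effect_label,
        truth=truth,
        n_reps=n_total,
        n_used=n,
        bias=bias,
        bias_mcse=emp_se / np.sqrt(n),
        emp_se=emp_se,
        mod_se=mod_se,
        mod_to_emp=mod_se / emp_se if emp_se > 0 else np.nan,
        coverage=cover,
        coverage_mcse=coverage_mcse(cover, n),
        power_or_type1=reject,
        power_mcse=coverage_mcse(reject, n),
        mean_tau2=float(tau2.mean()),
        median_tau2=float(np.median(tau2)),
        prop_tau2_positive=float((tau2 > 0).mean()),
        n_meta_nonconverged=n_bad,
    )


def tally_convergence(
    records: Iterable[ReplicateRecord],
) -> dict[str, dict[str, float]]:
    """Tabulate estimation-method fallback and non-convergence rates.

    Returns, per scenario, the number of study-level fits by each
    method in the cascade arm (REML whenever it converged, else PW,
    else OLS), the fraction of studies that fell back from REML, and
    the count and rate of REML between-study-variance non-convergence
    at the meta level.
    """
    out: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, int, str]] = set()
    for r in records:
        cell = out.setdefault(
            r.scenario_id,
            {"n_study_fits": 0, "n_reml": 0, "n_pw": 0, "n_ols": 0,
             "n_meta": 0, "n_meta_nonconverged": 0},
        )
        # the same study fits back every meta-method x effect record of a
        # replicate, so count them once per (replicate, analysis arm)
        fit_key = (r.scenario_id, r.replicate, r.its_method)
        if r.its_method != "OLS" and fit_key not in seen:
            seen.add(fit_key)
            for m in r.its_methods_used:
                cell["n_study_fits"] += 1
                key = {"REML": "n_reml", "PW": "n_pw", "OLS": "n_ols"}[m]
                cell[key] += 1
        cell["n_meta"] += 1
        if not r.meta_converged:
            cell["n_meta_nonconverged"] += 1
    for cell in out.values():
        n = cell["n_study_fits"]
        cell["reml_fallback_rate"] = (
            (cell["n_pw"] + cell["n_ols"]) / n if n else 0.0
        )
        cell["meta_nonconvergence_rate"] = (
            cell["n_meta_nonconverged"] / cell["n_meta"]
            if cell["n_meta"] else 0.0
        )
    return out
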