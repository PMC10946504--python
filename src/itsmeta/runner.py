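"""Factorial simulation driver.

Enumerates the scenario grid (the full study design is the Cartesian
product of series length, level- and slope-change, autocorrelation
level, number of studies, and the two between-study variances — 1620
cells), runs replicate meta-analyses in each cell, and reduces the
replicate records to performance summaries.

Each replicate draws its own independent random stream, derived from
the base seed, a stable hash of the scenario id, and the replicate
index; results are therefore reproducible and identical whether
replicates run serially or in parallel, and both analysis arms (OLS
and the REML->PW->OLS cascade) see the same generated data.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .datagen import MetaSample, ScenarioSpec, generate_meta_sample
from .itsfit import fit_cascade, fit_ols, fit_reml
from .meta import META_METHODS, MetaInput, meta_analyse
from .performance import ReplicateRecord, summarize, tally_convergence

__all__ = [
    "GridConfig",
    "enumerate_scenarios",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "run_sanity_check",
]

# Full factorial design of the study (levels in enumeration order).
PAPER_GRID = dict(
    T=[12, 48, 100],
    beta2=[0.0, 1.0],
    beta3=[0.0, 0.1],
    rho=[0.0, 0.2, 0.4, 0.6, "variable"],
    K=[3, 5, 20],
    tau2_level=[0.0, 0.1**2, 0.3**2],
    tau2_slope=[0.0, 0.01**2, 0.05**2],
)

ITS_ARMS = ("OLS", "cascade")


@dataclass(frozen=True)
class GridConfig:
    """Factor levels and execution settings for one simulation run."""

    T: Sequence[int] = (12, 48, 100)
    beta2: Sequence[float] = (0.0, 1.0)
    beta3: Sequence[float] = (0.0, 0.1)
    rho: Sequence = (0.0, 0.2, 0.4, 0.6, "variable")
    K: Sequence[int] = (3, 5, 20)
    tau2_level: Sequence[float] = (0.0, 0.1**2, 0.3**2)
    tau2_slope: Sequence[float] = (0.0, 0.01**2, 0.05**2)
    n_reps: int = 1000
    seed: int = 0
    its_methods: Sequence[str] = ITS_ARMS
    workers: int = 1

    def __post_init__(self) -> None:
        for name in ("T", "beta2", "beta3", "rho", "K",
                     "tau2_level", "tau2_slope"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"factor {name!r} has no levels")

    @classmethod
    def paper_grid(cls, n_reps: int = 1000, seed: int = 0,
                   **overrides) -> "GridConfig":
        return cls(n_reps=n_reps, seed=seed, **{**PAPER_GRID, **overrides})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GridConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _scenario_id(T, beta2, beta3, rho, K, tau2_level, tau2_slope) -> str:
    rho_tag = "var" if rho == "variable" else f"{float(rho):g}"
    return (
        f"T{T}_b2{float(beta2):g}_b3{float(beta3):g}_rho{rho_tag}"
        f"_K{K}_tl{float(tau2_level):g}_ts{float(tau2_slope):g}"
    )


def enumerate_scenarios(config: GridConfig) -> list[ScenarioSpec]:
    """Cartesian product of the factor levels, in a stable order."""
    specs = []
    for T in config.T:
        for beta2 in config.beta2:
            for beta3 in config.beta3:
                for rho in config.rho:
                    for K in config.K:
                        for tl in config.tau2_level:
                            for ts in config.tau2_slope:
                                if rho == "variable":
                                    mode, rho_val = "variable", np.nan
                                else:
                                    mode, rho_val = "fixed", float(rho)
                                specs.append(ScenarioSpec(
                                    T=int(T),
                                    beta2=float(beta2),
                                    beta3=float(beta3),
                                    rho_mode=mode,
                                    rho=rho_val,
                                    K=int(K),
                                    tau2_level=float(tl),
                                    tau2_slope=float(ts),
                                    n_reps=config.n_reps,
                                    seed=config.seed,
                                    scenario_id=_scenario_id(
                                        T, beta2, beta3, rho, K, tl, ts),
                                ))
    return specs


def replicate_rng(spec: ScenarioSpec, replicate: int) -> np.random.Generator:
    """Independent stream for one (scenario, replicate) pair."""
    scen_key = zlib.crc32(spec.scenario_id.encode())
    ss = np.random.SeedSequence([spec.seed, scen_key, replicate])
    return np.random.default_rng(ss)


def _fit_arm(sample: MetaSample, arm: str):
    if arm == "OLS":
        return [fit_ols(s) for s in sample.series]
    if arm == "cascade":
        return [fit_cascade(s) for s in sample.series]
    raise ValueError(f"unknown ITS analysis arm {arm!r}")


def run_replicate(
    spec: ScenarioSpec,
    replicate: int,
    its_methods: Sequence[str] = ITS_ARMS,
) -> list[ReplicateRecord]:
    """One replicate: generate K series, fit both arms, pool ten ways.

    Emits one record per (analysis arm x meta method x effect measure):
    with both arms and the five meta-analysis combinations that is 20
    records, all computed from the same generated data.
    """
    rng = replicate_rng(spec, replicate)
    sample = generate_meta_sample(spec, rng)

    records = []
    for arm in its_methods:
        fits = _fit_arm(sample, arm)
        methods_used = tuple(f.method_used for f in fits)
        inputs = {
            "level": MetaInput.from_se(
                [f.level_change for f in fits],
                [f.se_level for f in fits], "level"),
            "slope": MetaInput.from_se(
                [f.slope_change for f in fits],
                [f.se_slope for f in fits], "slope"),
        }
        for model, tau2_method, ci_method in META_METHODS:
            for label, mi in inputs.items():
                res = meta_analyse(mi, model, tau2_method, ci_method)
                records.append(ReplicateRecord(
                    scenario_id=spec.scenario_id,
                    replicate=replicate,
                    its_method=arm,
                    meta_method=res.method_label,
                    effect_label=label,
                    pooled=res.pooled,
                    se_pooled=res.se_pooled,
                    ci_low=res.ci_low,
                    ci_high=res.ci_high,
                    tau2=res.tau2,
                    its_methods_used=methods_used,
                    meta_converged=res.converged,
                ))
    return records


def run_scenario(
    spec: ScenarioSpec,
    its_methods: Sequence[str] = ITS_ARMS,
) -> list[ReplicateRecord]:
    records = []
    for rep in range(spec.n_reps):
        records.extend(run_replicate(spec, rep, its_methods))
    return records


def summarize_records(
    records: Iterable[ReplicateRecord],
    specs: Sequence[ScenarioSpec],
) -> pd.DataFrame:
    """Per-cell performance summaries as a tidy data frame.

    The estimand per cell is the scenario's mean level-change or
    slope-change (the centre of the random-effects distribution when
    heterogeneity is present).
    """
    truth_by_id = {
        s.scenario_id: {"level": s.beta2, "slope": s.beta3} for s in specs
    }
    cells: dict[tuple, list[ReplicateRecord]] = {}
    for r in records:
        key = (r.scenario_id, r.its_method, r.meta_method, r.effect_label)
        cells.setdefault(key, []).append(r)
    rows = []
    for (sid, arm, mm, label), recs in cells.items():
        summ = summarize(recs, truth_by_id[sid][label])
        rows.append(vars(summ))
    return pd.DataFrame(rows)


def records_frame(records: Iterable[ReplicateRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in records])
    if len(df):
        df["its_methods_used"] = df["its_methods_used"].map("|".join)
    return df


def run_grid(
    config: GridConfig,
    out_dir: str | Path | None = None,
    resume: bool = True,
    progress=None,
) -> dict[str, pd.DataFrame]:
    """Run every scenario of a grid and write tidy CSV outputs.

    Writes ``replicates.csv`` (one row per replicate x arm x meta
    method x effect), ``summary.csv`` (performance measures with Monte
    Carlo SEs per cell) and ``convergence.csv``.  When ``out_dir``
    already holds a ``replicates.csv`` and ``resume`` is set, scenarios
    present there are skipped and their stored records reused, so an
    interrupted run can be restarted without duplicating work.
    """
    specs = enumerate_scenarios(config)
    out = Path(out_dir) if out_dir is not None else None

    done_frames = []
    done_ids: set[str] = set()
    rep_path = out / "replicates.csv" if out else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        if resume and rep_path.exists():
            prev = pd.read_csv(rep_path)
            if len(prev):
                done_frames.append(prev)
                done_ids = set(prev["scenario_id"].unique())

    todo = [s for s in specs if s.scenario_id not in done_ids]
    if config.workers > 1 and len(todo) > 1:
        from concurrent.futures import ProcessPoolExecutor
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            scenario_results = list(pool.map(
                _run_scenario_task,
                [(s, tuple(config.its_methods)) for s in todo],
            ))
    else:
        scenario_results = []
        for s in todo:
            scenario_results.append(run_scenario(s, config.its_methods))
            if progress is not None:
                progress(s.scenario_id)

    new_records = [r for recs in scenario_results for r in recs]
    frames = done_frames + ([records_frame(new_records)]
                            if new_records else [])
    replicates = pd.concat(frames, ignore_index=True) if frames else (
        records_frame([]))

    # rebuild record objects from the full frame so resumed runs
    # summarize old and new scenarios alike
    all_records = [
        ReplicateRecord(
            scenario_id=row.scenario_id,
            replicate=int(row.replicate),
            its_method=row.its_method,
            meta_method=row.meta_method,
            effect_label=row.effect_label,
            pooled=row.pooled,
            se_pooled=row.se_pooled,
            ci_low=row.ci_low,
            ci_high=row.ci_high,
            tau2=row.tau2,
            its_methods_used=tuple(str(row.its_methods_used).split("|")),
            meta_converged=bool(row.meta_converged),
        )
        for row in replicates.itertuples()
    ]
    summary = summarize_records(all_records, specs)
    conv = pd.DataFrame(
        [{"scenario_id": sid, **cell}
         for sid, cell in tally_convergence(all_records).items()]
    )

    if out is not None:
        replicates.to_csv(rep_path, index=False)
        summary.to_csv(out / "summary.csv", index=False)
        conv.to_csv(out / "convergence.csv", index=False)
    return {"replicates": replicates, "summary": summary,
            "convergence": conv}


def _run_scenario_task(args):
    spec, its_methods = args
    return run_scenario(spec, its_methods)


def export_sample_csv(
    spec: ScenarioSpec, replicate: int, path: str | Path
) -> pd.DataFrame:
    """Write one replicate's generated series as tidy CSV."""
    rng = replicate_rng(spec, replicate)
    sample = generate_meta_sample(spec, rng)
    rows = []
    for k, s in enumerate(sample.series, start=1):
        for t, y in zip(s.t, s.y):
            rows.append({"scenario_id": spec.scenario_id,
                         "replicate": replicate, "study": k,
                         "t": int(t), "y": y})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def run_sanity_check(
    T: int = 100_000,
    K: int = 50,
    rho: float = 0.4,
    beta2: float = 1.0,
    beta3: float = 0.1,
    tau2_level: float = 0.3**2,
    tau2_slope: float = 0.05**2,
    n_reps: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Large-sample consistency check of the data-generating process.

    Simulates very long series and large meta-analyses, fits each
    series by REML, and averages the recovered level-change,
    slope-change, autocorrelation and REML between-study variances over
    replicates.  With consistent estimators every recovered value
    should match its input.
    """
    spec = ScenarioSpec(
        T=T, beta2=beta2, beta3=beta3, rho_mode="fixed", rho=rho,
        K=K, tau2_level=tau2_level, tau2_slope=tau2_slope,
        n_reps=n_reps, seed=seed, scenario_id="sanity",
    )
    from .meta import reml_tau2

    b2, b3, rhos, t2l, t2s = [], [], [], [], []
    for rep in range(n_reps):
        rng = replicate_rng(spec, rep)
        sample = generate_meta_sample(spec, rng)
        fits = [fit_reml(s) for s in sample.series]
        b2.append(np.mean([f.level_change for f in fits]))
        b3.append(np.mean([f.slope_change for f in fits]))
        rhos.append(np.mean([f.rho_hat for f in fits]))
        lvl = MetaInput.from_se([f.level_change for f in fits],
                                [f.se_level for f in fits])
        slp = MetaInput.from_se([f.slope_change for f in fits],
                                [f.se_slope for f in fits])
        t2l.append(reml_tau2(lvl)[0])
        t2s.append(reml_tau2(slp)[0])
    return {
        "beta2_hat": float(np.mean(b2)),
        "beta3_hat": float(np.mean(b3)),
        "rho_hat": float(np.mean(rhos)),
        "tau2_level_hat": float(np.mean(t2l)),
        "tau2_slope_hat": float(np.mean(t2s)),
        "beta2": beta2, "beta3": beta3, "rho": rho,
        "tau2_level": tau2_level, "tau2_slope": tau2_slope,
        "n_reps": n_reps,
    }
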