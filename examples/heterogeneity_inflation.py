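"""Spurious heterogeneity from unmodelled autocorrelation.

With no true between-study variance, pooling OLS-fitted series still
yields positive between-study variance estimates whenever the OLS
standard errors are too small (short series, or autocorrelation left
unmodelled).  This script measures, at autocorrelation 0 vs 0.6, the
percentage of replicate meta-analyses with a positive REML
between-study variance for the level-change — the inflation grows
sharply with autocorrelation.
"""

from itsmeta import MetaInput, ScenarioSpec, fit_ols, generate_meta_sample, reml_tau2
from itsmeta.runner import replicate_rng

for rho in (0.0, 0.6):
    spec = ScenarioSpec(
        T=100, beta2=1.0, beta3=0.1, rho_mode="fixed", rho=rho, K=3,
        tau2_level=0.0, tau2_slope=0.0, seed=11,
        scenario_id=f"demo_rho{rho}",
    )
    n_pos = 0
    n_reps = 300
    for rep in range(n_reps):
        rng = replicate_rng(spec, rep)
        sample = generate_meta_sample(spec, rng)
        fits = [fit_ols(s) for s in sample.series]
        mi = MetaInput.from_se([f.level_change for f in fits],
                               [f.se_level for f in fits])
        tau2, _ = reml_tau2(mi)
        n_pos += tau2 > 0
    print(f"rho = {rho}: tau2 > 0 in {100 * n_pos / n_reps:.1f}% of "
          f"{n_reps} replicate meta-analyses (true tau2 = 0)")
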