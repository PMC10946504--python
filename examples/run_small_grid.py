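"""Run a small corner of the factorial simulation.

Two scenarios (series length 12 vs 100 at autocorrelation 0.4, three
studies per meta-analysis, no heterogeneity), 50 replicates each, both
analysis arms and all five pooling methods.  The printed coverage rows
show the pattern the full study reports: fixed-effect meta-analysis of
OLS-fitted series under-covers, while random-effects methods stay near
the nominal 95%.
"""

from itsmeta import GridConfig, run_grid

config = GridConfig(
    T=[12, 100], beta2=[1.0], beta3=[0.1], rho=[0.4], K=[3],
    tau2_level=[0.0], tau2_slope=[0.0], n_reps=50, seed=7,
)
out = run_grid(config)
summary = out["summary"]
level = summary[summary.effect_label == "level"]
cols = ["scenario_id", "its_method", "meta_method", "bias", "coverage",
        "coverage_mcse", "mod_to_emp", "mean_tau2"]
print(level[cols].round(3).to_string(index=False))
print("\ncascade-arm convergence tallies:")
print(out["convergence"].to_string(index=False))
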