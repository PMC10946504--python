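# Methods

## Data-generating model

A single interrupted time series (ITS) of length `T` is drawn from the
segmented linear model

    y_t = β0 + β1 t + β2 D_t + β3 (t − T_I) D_t + e_t,
    e_t = ρ e_{t−1} + w_t,   w_t ~ N(0, 1) i.i.d.,

with `D_t = 1{t ≥ T_I}`.  The innovation SD is fixed at 1, so all
effect sizes are in residual-SD units.  Two choices deserve comment.

**Stationary initial error.**  `e_1` is drawn from the stationary AR(1)
marginal `N(0, 1/(1−ρ²))` rather than starting at zero with a burn-in.
This is equivalent in distribution to an infinite burn-in and removes
start-up transients that would otherwise distort the shortest series
(T = 12).

**Interruption index.**  `T_I = T/2 + 1`, so that exactly `T/2` points
precede and `T/2` points follow the interruption.  With the convention
`D_t = 1` for `t ≥ T_I`, placing the interruption at `T/2` itself would
give an unbalanced `T/2 − 1` / `T/2 + 1` split; the balanced split is
the design property we preserve.

A replicate meta-analysis of `K` studies shares (β0, β1) and draws
study effects `β2k ~ N(β2, τ²_level)` and `β3k ~ N(β3, τ²_slope)`.
Autocorrelation is either one constant shared by all `K` studies
("fixed" mode) or drawn independently per study from `N(0.4, 0.15²)`
("variable" mode), rejected and redrawn outside (−1, 1).  The factor
levels of the full design — T ∈ {12, 48, 100}; β2 ∈ {0, 1};
β3 ∈ {0, 0.1}; ρ ∈ {0, 0.2, 0.4, 0.6, variable}; K ∈ {3, 5, 20};
τ²_level ∈ {0, 0.1², 0.3²}; τ²_slope ∈ {0, 0.01², 0.05²} — form the
1620-cell grid in `runner.PAPER_GRID`, with 1000 replicates per cell by
default.  1000 replicates keep the Monte Carlo SE of a coverage
estimate near the nominal 95% level below 0.7 percentage points,
√(95·5/1000) ≈ 0.69.

What the generator deliberately does not emulate: unequal pre/post
segments, varying series lengths within one meta-analysis, lags beyond
1, seasonality, negative autocorrelation levels in the fixed grid, and
non-continuous outcomes.  Performance conclusions from this generator
therefore speak to balanced continuous-outcome ITS collections only.

## Study-level estimation

All three estimators fit the same four-coefficient design
`[1, t, D_t, (t − T_I) D_t]`, which requires at least four points per
segment.

- **OLS** solves the normal equations; SEs use the classical
  independent-error covariance with denominator `T − 4`.  Point
  estimates are unbiased under autocorrelation; SEs are not.
- **Prais-Winsten** iterates: estimate ρ by the lag-1 moment estimator
  `r = Σ ê_t ê_{t−1} / Σ ê_t²` on the current untransformed-scale
  residuals, quasi-difference the data (first row scaled by
  `√(1−ρ̂²)`), refit, and stop when successive ρ̂ change by < 1e-6
  (cap 100 iterations).  ρ̂ escaping [−1, 1] is clamped to ±0.999.
  Residual sums of squares at rounding-error level (a perfect fit)
  are treated as zero autocorrelation rather than divided through.
- **REML** maximises the restricted log-likelihood of the AR(1)-error
  linear model.  σ² and β have closed forms at fixed ρ, so the
  criterion is profiled to one dimension:

      ℓ_R(ρ) ∝ −½[(T−4) log(RSS(ρ)/(T−4)) − log(1−ρ²) + log|X'V⁻¹X|]

  maximised by bounded scalar search over ρ ∈ (−0.999, 0.999)
  (tolerance 1e-8).  SEs come from the GLS covariance
  `σ̂² (X'V⁻¹X)⁻¹` at the optimum, with no small-sample
  degrees-of-freedom correction — only the point estimate and SE feed
  the meta-analysis, and this keeps the three estimators' SEs
  directly comparable.  Non-convergence is declared on optimiser
  failure, a non-finite criterion, or a boundary solution
  (|ρ̂| within 1e-3 of 0.999); boundary solutions are how short,
  strongly autocorrelated series typically fail.  Failure rates are
  implementation-specific and are not expected to match any
  particular software's rate numerically; what is reproduced is the
  ordering (T = 12 ≫ 48 ≥ 100) and that Prais-Winsten rescues
  essentially all failures.

The **cascade** applies REML, then PW, then OLS, returning the first
converged fit and recording which method was used — OLS cannot fail on
an estimable design, so the cascade always terminates.

## Meta-analysis

Within-study variances are treated as known (the standard two-stage
assumption).  Fixed-effect pooling uses weights `1/σ²_k`; random-effects
pooling `1/(σ²_k + τ̂²)`.

- **DerSimonian-Laird τ²**: `max(0, (Q − (K−1)) / (ΣW − ΣW²/ΣW))` with
  fixed-effect weights and Cochran's Q about the fixed-effect pooled
  estimate.  Non-iterative.
- **REML τ²**: fixed-point iteration of
  `τ² ← max(0, Σ w²[(β̂_k − β̂*)² − σ²_k]/Σ w² + 1/Σ w)` with
  random-effects weights recomputed each step; the final `1/Σw` term
  is the restricted-likelihood degrees-of-freedom correction.  The
  iteration starts from the maximum-likelihood fixed point (itself
  started at DL, capped at 20 iterations), stops at |Δτ²| < 1e-8, and
  flags non-convergence at 100 iterations.  Non-convergence is
  surfaced, never silently replaced; the performance layer excludes
  and counts such replicates.
- **Wald-type interval**: `pooled ± z_{0.975}·se`, p-value from the
  normal.
- **HKSJ interval**: variance `q/ΣW` with
  `q = Σ W_k (β̂_k − β̂*)²/(K−1)`, reference t with K−1 df.  `q` is
  used exactly as defined — the common `max(1, q)` modification is
  *not* applied, so with zero observed dispersion the interval
  degenerates to zero width.  This follows the original estimator;
  users wanting the modified variant can clamp `q` upstream.

The five evaluated combinations are Fixed, DL+WT, DL+HKSJ, REML+WT and
REML+HKSJ (`meta.META_METHODS`).

## Simulation execution and reproducibility

Each (scenario, replicate) pair seeds an independent `numpy`
`SeedSequence([base_seed, crc32(scenario_id), replicate])` stream, so
results are bit-identical across runs, across serial/parallel
execution, and both analysis arms (all-OLS and the cascade) analyse the
identical generated data — the paired design that makes within-replicate
method comparisons sharp.  `run_grid` writes tidy replicate-level,
summary-level and convergence CSVs and can resume an interrupted run by
skipping scenarios already present in `replicates.csv`.

Performance measures follow the standard simulation-study definitions:
bias = mean(pooled) − truth; empirical SE = SD of pooled estimates;
model SE = root-mean-square of replicate model SEs; coverage and
zero-rejection percentages; MCSE(bias) = empSE/√n and
MCSE(percentage) = √(p(100−p)/n).  Under random-effects generation the
coverage truth is the mean of the effect distribution, not the
replicate-specific realised mean.  The model-SE summary uses the
root-mean-square (rather than the arithmetic mean) so that it estimates
the square root of the mean reported variance.

A pre-run consistency check (`run_sanity_check`, also
`itsmeta sanity`) simulates series of 100,000 points and meta-analyses
of 50 studies, fits by REML and confirms that level-change,
slope-change, autocorrelation and both between-study variances are
recovered.  Because a 50-study sample variance has relative sampling SD
√(2/49) ≈ 20%, the check averages over 10 replicate meta-analyses by
default, bringing the Monte Carlo error on the recovered τ² near 6% so
that a 10% agreement band is informative.

## Worked example

The packaged fixture holds the published study-level level- and
slope-change estimates (OLS and REML columns) and REML autocorrelation
estimates for the 11-state analysis of recreational-cannabis
legalisation and traffic fatality rates (Lane et al. 2019; 96 monthly
points per state).  Only these summary statistics are embedded; the
underlying monthly series are external and not redistributed, so the
study-level regressions themselves are out of scope here.  Inputs are
printed to two decimals (one SE to a single decimal, read as 0.60), so
reproduction of the published pooled results carries a documented
tolerance of about ±0.01 on estimates and interval limits and ±0.003 on
τ².

## Test and acceptance problem sizes

The packaged checks run reduced versions of the study design chosen to
keep Monte Carlo error well inside the tolerances they assert: the
heterogeneity-overestimation rates use the 45-scenario presentation
subgrid at 200 (K = 3) and 100 (K = 20) replicates per scenario;
unbiasedness and the REML-oracle comparison use 500-replicate and
100-series runs; the coverage contrast uses 2000 replicates because the
DL+WT coverage sits within half a percentage point of the asserted
band edge.  All are ordinary library calls — nothing in the checks is
special-cased in the implementation.
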