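# Methods

This note records the statistical content of the package: the models, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical decisions a maintainer would otherwise
have to reverse-engineer.

## Study design constants (`StudyConfig`)

| parameter | default | meaning |
|---|---|---|
| `years` | (2021, 2022) | the two contrasted study years |
| `months` | 6–9 | field season (June–September) |
| `days_per_month_range` | (9, 12) | observation days drawn per month |
| `altitude_bounds_m` | (2200, 2800) | foraging band of the basin, m a.s.l. |
| `reps_mixed_null`, `reps_chisq` | 10,000 | Monte-Carlo replicates |
| `correlation_threshold` | 0.7 | Spearman screen: \|rho\| at or above drops the later predictor |
| `min_flock_size_occurrence` | 10 (strict) | a null-model row needs **more than** 10 occurrences to be reported; `min_occurrence_strict=False` switches to at-least |
| `kde_mass_quantile` | 0.95 | utilization-distribution isopleth |
| `kde_cell_size_m` | 25 | grid resolution, well below any plausible bandwidth at basin scale |
| `altitude_bin_m` | 100 | contingency-table bin width over the altitude band |

The 0.95 isopleth and the 100-m bin are conventions, not published values:
the source analyses do not state their kernel inclusion threshold or exact
interval width, so the package uses the field-standard utilization quantile
and a round bin that yields 6 bins over the 600-m band. Both are config
switches.

## Random-intercept LMM engine

Model: y = X beta + Z u + e with one grouping factor (collection date),
u ~ N(0, sigma_b^2 I), e ~ N(0, sigma^2 I). Estimation is REML with the
variance ratio lambda = sigma_b^2/sigma^2 profiled: for fixed lambda the
marginal covariance is block diagonal with blocks sigma^2(I + lambda J), so
beta(lambda) and sigma^2(lambda) are closed-form via per-group sums
(Sherman–Morrison), and the profiled criterion is maximised over
log lambda in [-16, 16] by bounded scalar search; the boundary fit
lambda = 0 is compared explicitly and returned when better. With a single
group, or all groups of size one, sigma_b^2 is unidentifiable: the fit is
returned at lambda = 0 and flagged.

Satterthwaite denominator df: the covariance of the fixed effects is
C(theta) = (X' V(theta)^-1 X)^-1 as a function of theta =
(sigma_b^2, sigma^2). For a q-row contrast L, the eigen-contrasts of
L C L' each get nu_i = 2 g_i^2 / (grad g_i' A grad g_i), with g_i the
eigen-variance, gradients by central finite differences (relative step
1e-4), and A the inverse of the finite-difference negative REML Hessian at
the optimum. The nu_i pool harmonically, ddf = 2E/(E - q) with
E = sum nu_i/(nu_i - 2), which for q = 1 is the classical single-contrast
formula. ddf is floored at 1.01 to keep the F reference proper; nu <= 2
triggers the floor with a warning. Degenerate zero-variance responses are
guarded by a relative floor on sigma^2 and a pseudoinverse in the F
quadratic form, so constant inputs yield F = 0 rather than an error.

Verification: balanced one-way layouts reproduce the ANOVA closed form
(sigma^2 = MSE, sigma_b^2 = (MSB - MSE)/m) to 1e-6; singleton groups
reproduce OLS with ddf = n - p within 1 %; beta matches statsmodels MixedLM
(REML) to 1e-4 relative on random unbalanced datasets; the type-I error of
the Satterthwaite test of a group-level effect over 500 null simulations
(n = 300, 30 groups) lies in [0.03, 0.07]. These are test-suite results;
none are hard-coded anywhere in the package.

A genuine subtlety found while testing: duplicating every observation
*within* its group is not beta-preserving in a mixed model (group sizes
enter the GLS weights), and even whole-dataset replication shifts the REML
lambda slightly. The invariant that does hold — beta(lambda) is unchanged
at every fixed lambda under whole-dataset replication with cloned groups —
is what the test asserts, against a dense brute-force GLS refit.

## Stay-time analysis

Three model families on log stay times, all with the date random intercept:
overall `log T ~ species + year + flock_size`; per species on monospecific
records `log T ~ year + flock_size`; per year on red-billed records
`log T ~ flock_type`. Flock size enters untransformed by default
(`log_flock_size` switches); factors are treatment-coded with the
alphabetically first level as reference (the F tests are coding-invariant).
Stratum means come from a separate saturated cell-means LMM, so they are
invariant to reference-level choices, and are reported both raw (arithmetic
mean of seconds) and model-based, exp(mu_cell + (sigma_b^2 + sigma^2)/2).
The model-based number is the one compared against calibration targets: a
log-scale model's exp(mu) estimates the geometric mean, and omitting the
correction would under-report by ~20 % at the default noise levels.

## Mixed-flocking null model

Pools are censused per year as the maximum flock count per species,
mirroring the field convention that the largest flying flock represents the
local total. Mixed flocks carry no per-species counts in the CSV schema, so
their size is attributed to the majority species (the one with the larger
monospecific maximum that year) for the census only. The Monte-Carlo
expectation samples the species-1 count of an n-bird draw directly from the
hypergeometric distribution — exactly equivalent to labelling and drawing
individuals, at a fraction of the cost — and the exact twin
1 - [C(N1,n) + C(N2,n)]/C(N1+N2,n) is evaluated in log-space. Flock sizes
exceeding the census (possible only under the majority attribution) are
clipped to N1 + N2. The binomial comparison uses the Monte-Carlo
expectation as its null probability, as in the original procedure; the
exact value sits alongside it in every row.

## Home ranges

Per-axis bandwidths use the two-stage direct Sheather–Jones plug-in
(normal-scale psi_6 → pilot g → kernel estimate of psi_4 → h), falling back
to Silverman's rule if a plug-in stage degenerates; during development the
implementation was checked against R's `bw.SJ(method="dpi")` (within ~1 %).
The KDE is evaluated on a lattice-aligned grid padded by 4 bandwidths
(discretized mass 1 within 1e-3; alignment makes translation equivariance
exact). The q-isopleth is the smallest density-threshold cell set with mass
at least q. Overlaps re-evaluate both KDEs on the union grid at the finer
cell size, recompute each mask there, and intersect — comparing masks from
different grids directly would alias at the boundary. `HomeRange` retains
its points and bandwidths for exactly this purpose.

Mixed-flock ranges use the flock positions (one point per flock sighting),
i.e. flock centroids, not individual birds — individual positions within a
flock are not recorded in the schema.

## Climate models

Temperature: full ML (not REML) so LRTs are valid, alternating profiled
whitened least squares for beta with Nelder–Mead over (phi1, phi2) in the
stationarity triangle from three starts. Each year is an independent AR(2)
block: the first two residuals use the stationary bivariate distribution
(their correlation-scale Cholesky whitens them exactly), later ones the
innovation recursion — conditional ML would bias phi on short blocks.
Convergence is declared at delta-loglik < 1e-8.

Precipitation: hurdle gamma. Logistic IRLS for P(zero) with linear
predictors capped at ±15 as a separation guard (an all-positive series
yields P(zero) ≈ 3e-7 and a warning rather than divergence); gamma IRLS
with log link on the positives (the beta score is free of the shape), then
the shape by profile ML via the digamma equation solved with Brent. Because
a gamma variate is never zero, hurdle and zero-inflated forms coincide and
the total log-likelihood is exactly the sum of the parts (asserted in
tests). Both hurdle components share the same design (year + month, or with
interaction); the year LRT for precipitation therefore has 2 df — the
published single-df statistic may have tested one component only, which the
report accommodates by also listing the joint year+interaction comparison.

## Synthetic generator: what it emulates, and what not

The generator reproduces the *statistical skeleton* the analyses assume:

* flock sizes: zero-truncated negative binomial, dispersion k = 5, with the
  underlying mean solved so the truncated mean equals the calibrated
  target (28.8 / 6.7 birds in 2021, 18.7 / 8.0 in 2022); mixed events
  (probability 0.15) join independent contingents of both species;
* stay times: log-normal with residual SD 0.6, shared per-date effects of
  SD 0.3, and a log-size slope (-0.1), intercepts solved so the realised
  arithmetic stratum mean equals the target (473/176 s red monospecific,
  210/134 s yellow monospecific, 146 s red in mixed flocks 2021; strata the
  study does not print — red mixed 2022 and yellow mixed — default to the
  same species-year monospecific mean, encoding the reported absence of a
  flock-type effect in 2022);
* positions: Gaussian scatter (SD 600 m) about offset species centres with
  a tighter mixed-flock cluster between them; altitudes uniform per stratum,
  with only the yellow-billed 2022 range extending above 2600 m;
* climate: month-year mean temperatures with stationary AR(2) errors
  (phi = (0.6, 0.2), innovation SD 1.5 °C; 2022 warmer in every month) and
  hurdle-gamma precipitation (2022 markedly drier January–March).

Noise levels, dispersion, spatial geometry and the ~200 observations / ~100
flocks per stratum are generator choices — the study reports no variances
or per-stratum sample sizes — fixed once at values a field ecologist would
call plausible, and stated here so nobody mistakes them for published
quantities. Every stratum draws from its own seed-derived RNG stream, so
perturbing one stratum's calibration leaves all others bit-identical.

What the generator does *not* emulate: flock fission–fusion dynamics,
within-day temporal autocorrelation of behaviour, observer effort varying
with weather, spatially structured encounter probability, or any coupling
between climate and behaviour. A green recovery test therefore establishes
that the pipeline is unbiased for the stated data-generating process — not
that the process is a faithful model of chough ecology.

Known limitation of the recovery surface: at the stated stratum sizes the
stay-time and flock-size estimators carry 5–9 % relative standard error, so
a ±10 % recovery band is 1.5–2 standard errors wide and any individual
seed has a 5–15 % chance of missing on any one stratum. Seed 1 draws the
yellow-billed 2022 flock stratum 2.5 sigma high (+13 %); the corresponding
acceptance test is left failing rather than widening the band or adjusting
the generator, since the generator is verifiably unbiased (mean recovery
error < 0.5 % over 500 seeds).

## Numerical conventions

* One master seed; every stochastic stage derives its own stream from
  (seed, stage-name) via `SeedSequence`, all below 2^31.
* CSV floats are written with `repr` so round trips are bit-exact.
* Monte-Carlo p-values use the add-one convention (1 + exceedances)/(reps+1),
  never exactly zero.
* Chi-square MC replicates compare with a 1e-9 slack so ties at the
  observed statistic count as exceedances.
* The greedy collinearity screen keeps the earlier-listed member of a
  correlated pair; listing order is therefore part of the analysis
  definition (species, year, flock size).
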