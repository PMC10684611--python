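# choughs

An analysis pipeline for the foraging ecology of two coexisting alpine
corvids — the yellow-billed chough (*Pyrrhocorax graculus*) and the
red-billed chough (*Pyrrhocorax pyrrhocorax*) — observed in a high-alpine
basin over two climatically contrasting summers (2021, a typical year, and
2022, an exceptionally hot and dry one). It is written for behavioural
ecologists who have field data in simple CSV form (focal stay times, flock
censuses, daily weather) and want the complete statistical treatment as one
reproducible run, and for methodologists who want each statistical engine
individually testable.

Because the original field data are not publicly deposited, the package also
ships a calibrated synthetic-data generator that emulates the study design
(two species, June–September, 9–12 observation days a month, 2200–2800 m
a.s.l.) with stratum means set to the published group averages. The pipeline
is validated by recovering those means from its own synthetic data and by
checking every engine against an analytic or brute-force oracle.

## The models

**Stay times.** The seconds a focal bird forages on a patch, from landing to
take-off. Modelled on the natural-log scale with a random-intercept linear
mixed model, collection date *d* as the grouping factor:

    log T_i = x_i' beta + u_{d(i)} + e_i,   u_d ~ N(0, sigma_b^2),  e_i ~ N(0, sigma^2)

fitted by REML with the variance ratio lambda = sigma_b^2/sigma^2 profiled
out (closed-form GLS at each lambda, one-dimensional search on log lambda).
Fixed-effect tests are F statistics with Satterthwaite denominator degrees
of freedom, obtained by the eigen-contrast squeeze against the
finite-difference REML curvature. Stratum means are back-transformed with
the log-normal correction exp(mu + (sigma_b^2 + sigma^2)/2), which estimates
the *arithmetic* mean implied by a log-scale model. Candidate predictors
pass a Spearman collinearity screen (|rho| >= 0.7 drops the later-listed
variable) first.

**Flock sizes.** The same LMM machinery on the raw size scale: per species,
size ~ year; per year, size ~ species; monospecific flocks only.

**Propensity to mixed flocking.** A null model of random assortment: with
per-year species pools N1, N2 censused as the largest flock count observed
for each species, a flock of size n is mixed with probability

    P(mixed | n) = 1 - [C(N1, n) + C(N2, n)] / C(N1 + N2, n),

estimated both by Monte Carlo (n birds sampled without replacement, 10,000
replicates) and by this exact hypergeometric form. Observed mixing
frequencies are compared to the expectation with an exact two-sided binomial
test; flock sizes occurring 10 times or fewer are computed but flagged
unreported.

**Foraging home ranges.** A product-Gaussian kernel density estimate of
flock positions with a per-axis plug-in (Sheather–Jones direct) bandwidth;
the home range is the smallest density-threshold set of grid cells holding
95 % of the probability mass (the conventional utilization-distribution
isopleth). Pairwise overlaps re-evaluate both densities on a shared grid.

**Altitudinal distributions.** Per species, a year × 100-m-bin contingency
table tested by Pearson chi-square with a Monte-Carlo p-value over tables
drawn with both margins fixed (sequential multivariate-hypergeometric
construction).

**Climate.** Daily mean temperature: Gaussian regression on month, year and
their interaction with AR(2) errors restarted each year (exact stationary
treatment of each year's first two days), fitted by full maximum likelihood
so that nested models compare by likelihood-ratio tests. Daily
precipitation: a hurdle model — logistic regression for P(dry) plus a
log-link gamma regression on the positive amounts — whose likelihood
factorizes exactly.

## Worked example

```sh
choughs run --seed 1 --out results/
```

runs generate → analyse end to end (about one second) and prints one status
line per section. `results/report.json` then holds, among much else
(numbers from this exact run):

* stay-time stratum means (s), model-based with the log-normal correction:
  red-billed monospecific 479 (2021) vs 190 (2022); yellow-billed 215 vs
  143; red-billed in mixed flocks 152 (2021) — against calibration targets
  473/176, 210/134 and 146;
* the per-year flock-type contrast for the red-billed chough:
  F(1, 382) = 296.6, p < 1e-40 in 2021 (mixed flocks shorten stays), but
  F(1, 391) = 0.01, p = 0.91 in 2022 — the generator encodes exactly this
  collapse of the interference effect;
* mixed-flocking rows such as flock size 3: observed frequency 0/11 against
  an expected 0.61 (exact 0.611, Monte-Carlo 0.607), binomial p = 3.5e-05 —
  mixing far rarer than random assortment;
* home ranges 2021: species areas 7.9 and 8.1 km², shared fraction 0.65 and
  0.63, mixed-flock range 1.3 km² (much smaller than either species');
* altitude: yellow-billed year effect chi² = 33.4, MC p ≈ 1e-04 (its 2022
  range extends above 2600 m), red-billed chi² = 3.0, p = 0.40;
* climate: year LRT on temperature chi²(1) = 15.1, p = 1e-04; on
  precipitation chi²(2) = 8.5, p = 0.014 (2022 hotter throughout, drier
  early in the year).

`choughs generate` emits the dataset bundle only; `choughs analyse --data
DIR` runs the analyses on any bundle in the documented CSV schemas, so real
field data can be substituted for the synthetic study.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default synthetic study from the packaged calibration with
the given seed, runs the pipeline, and writes the nine recovered quantities
(five model-based stay-time stratum means in seconds, four monospecific
flock-size means in birds) as JSON, each tagged with the stratum sample size
used.
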