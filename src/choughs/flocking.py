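"""Flock-size models and the mixed-species flocking null model.

The null model asks: if the two species' individuals assorted at random, how
often would a flock of size *n* contain both species?  Per year, each species'
population is taken as the largest flock count observed for it ("the maximum
number of individuals found during the field activity").  For each observed
flock size *n* the expected mixing probability is computed both by Monte
Carlo (sampling *n* individuals without replacement from the pooled
population, 10,000 replicates by default) and by the exact hypergeometric
closed form

    P(mixed) = 1 - [C(N1, n) + C(N2, n)] / C(N1 + N2, n),

and the observed mixing frequency is compared with the expectation by an
exact two-sided binomial test (minimum-likelihood method).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core_io import FlockRecord, StudyConfig, flocks_frame
from .lmm import FTestResult, fit_random_intercept_lmm, satterthwaite_f

logger = logging.getLogger(__name__)


@dataclass
class MixedFlockNullRow:
    """Observed vs expected mixed-flocking probability for one flock size."""

    flock_size: int
    occurrences: int
    observed_mixed: int
    p_observed: float
    p_expected_mc: float
    p_expected_exact: float
    reps: int
    binomial_p: float
    reported: bool  # False when occurrences fail the minimum-count filter

    def to_dict(self) -> dict:
        return {
            "flock_size": self.flock_size,
            "occurrences": self.occurrences,
            "observed_mixed": self.observed_mixed,
            "p_observed": self.p_observed,
            "p_expected_mc": self.p_expected_mc,
            "p_expected_exact": self.p_expected_exact,
            "reps": self.reps,
            "binomial_p": self.binomial_p,
            "reported": self.reported,
        }


@dataclass
class FlockSizeResults:
    per_year_species_test: dict[int, FTestResult]
    per_species_year_test: dict[str, FTestResult]
    group_means: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "per_year_species_test": {str(y): t.to_dict() for y, t in self.per_year_species_test.items()},
            "per_species_year_test": {s: t.to_dict() for s, t in self.per_species_year_test.items()},
            "group_means": self.group_means.to_dict(orient="records"),
        }


def _log_choose(a: np.ndarray | int, b: int) -> np.ndarray:
    """log C(a, b) elementwise, -inf where b > a."""
    a = np.asarray(a, dtype=float)
    with np.errstate(invalid="ignore"):
        out = gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)
    return np.where(a >= b, out, -np.inf)


def mixed_flock_prob_exact(N1: int, N2: int, n: int) -> float:
    """Exact probability that n individuals sampled without replacement from
    pools of N1 and N2 contain both species; log-space for large arguments."""
    if N1 < 0 or N2 < 0:
        raise ValueError("pool sizes must be nonnegative")
    if not (1 <= n <= N1 + N2):
        raise ValueError(f"flock size n={n} outside [1, N1+N2={N1 + N2}]")
    if n == 1:
        return 0.0  # a single bird cannot be mixed
    if n > max(N1, N2):
        return 1.0  # n exceeds both pools: every draw holds both species
    log_total = _log_choose(N1 + N2, n)
    p_pure = 0.0
    for N in (N1, N2):
        lc = _log_choose(N, n)
        if np.isfinite(lc):
            p_pure += float(np.exp(lc - log_total))
    return float(min(max(1.0 - p_pure, 0.0), 1.0))


def mixed_flock_prob_mc(N1: int, N2: int, n: int, reps: int, seed: int) -> float:
    """Monte-Carlo estimate: draw n birds without replacement from the pooled
    N1 + N2, ``reps`` times; return the fraction of draws containing both
    species.  The per-draw species-1 count is hypergeometric, which is the
    exact distribution of label counts under sampling without replacement."""
    if N1 < 0 or N2 < 0:
        raise ValueError("pool sizes must be nonnegative")
    if not (1 <= n <= N1 + N2):
        raise ValueError(f"flock size n={n} outside [1, N1+N2={N1 + N2}]")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    k1 = rng.hypergeometric(N1, N2, n, size=reps)
    mixed = (k1 > 0) & (k1 < n)
    return float(np.mean(mixed))


def binomial_test_two_sided(k: int, m: int, p: float) -> float:
    """Exact two-sided binomial p-value by the minimum-likelihood method (the
    convention of the classical ``binom.test``)."""
    if not (0 <= k <= m):
        raise ValueError("need 0 <= k <= m")
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must lie in [0, 1]")
    if m == 0:
        return 1.0
    if p == 0.0:
        return 1.0 if k == 0 else 0.0
    if p == 1.0:
        return 1.0 if k == m else 0.0
    return float(stats.binomtest(k, m, p).pvalue)


def propensity_analysis(
    flocks: list[FlockRecord] | pd.DataFrame,
    study: StudyConfig,
    seed: int,
) -> dict[int, list[MixedFlockNullRow]]:
    """Per-year mixed-flocking null-model table.

    Population sizes are censused per year: for each species, the maximum
    flock count attributed to it (mixed flocks, whose per-species counts are
    unrecorded in the flock schema, are attributed wholly to the majority
    species — the species with the larger monospecific maximum that year).
    Rows whose flock size occurs too rarely (``min_flock_size_occurrence``,
    strict by default) are computed but flagged unreported.
    """
    df = flocks if isinstance(flocks, pd.DataFrame) else flocks_frame(flocks)
    out: dict[int, list[MixedFlockNullRow]] = {}
    for yi, year in enumerate(sorted(df["year"].unique())):
        sub = df[df["year"] == year]
        mono = sub[~sub["mixed"]]
        species_seen = {sp for tup in sub["species_present"] for sp in tup}
        if len(species_seen) < 2:
            logger.warning("year %s has a single species; propensity analysis skipped", year)
            continue
        max_mono = {
            sp: int(mono[mono["species_present"].apply(lambda t: t[0] == sp)]["size"].max())
            for sp in sorted(species_seen)
        }
        majority = max(max_mono, key=lambda sp: max_mono[sp])
        pools = dict(max_mono)
        mixed_sizes = sub[sub["mixed"]]["size"]
        if len(mixed_sizes):
            pools[majority] = max(pools[majority], int(mixed_sizes.max()))
        (sp1, N1), (sp2, N2) = sorted(pools.items())
        rows: list[MixedFlockNullRow] = []
        for ni, n in enumerate(sorted(sub["size"].unique())):
            size_sub = sub[sub["size"] == n]
            m = int(len(size_sub))
            k = int(size_sub["mixed"].sum())
            n_eff = min(int(n), N1 + N2)  # a flock cannot exceed the census
            p_exact = mixed_flock_prob_exact(N1, N2, n_eff)
            p_mc = mixed_flock_prob_mc(
                N1, N2, n_eff, study.reps_mixed_null,
                seed=(seed + 1000 * yi + ni) % (2**31 - 1),
            )
            min_m = study.min_flock_size_occurrence
            reported = m > min_m if study.min_occurrence_strict else m >= min_m
            rows.append(
                MixedFlockNullRow(
                    flock_size=int(n), occurrences=m, observed_mixed=k,
                    p_observed=k / m, p_expected_mc=p_mc, p_expected_exact=p_exact,
                    reps=study.reps_mixed_null,
                    binomial_p=binomial_test_two_sided(k, m, p_mc),
                    reported=bool(reported),
                )
            )
        out[int(year)] = rows
    return out


def flock_size_analysis(
    flocks: list[FlockRecord] | pd.DataFrame,
    log_scale: bool = False,
) -> FlockSizeResults:
    """Flock-size LMMs on monospecific flocks with a date random intercept:
    per species, size ~ year; per year, size ~ species.  Group means are
    reported on the raw scale (birds per flock)."""
    df = flocks if isinstance(flocks, pd.DataFrame) else flocks_frame(flocks)
    mono = df[~df["mixed"]].copy()
    if mono.empty:
        raise ValueError("no monospecific flocks")
    mono["species"] = mono["species_present"].apply(lambda t: t[0])
    resp = np.log(mono["size"].to_numpy(dtype=float)) if log_scale else mono["size"].to_numpy(dtype=float)
    mono = mono.assign(_resp=resp)

    per_species: dict[str, FTestResult] = {}
    for sp in sorted(mono["species"].unique()):
        sub = mono[mono["species"] == sp]
        if sub["year"].nunique() < 2 or sub["date"].nunique() < 2:
            logger.warning("year test skipped for %s: insufficient data", sp)
            continue
        X = np.column_stack(
            [np.ones(len(sub))] +
            [(sub["year"] == y).to_numpy(dtype=float) for y in sorted(sub["year"].unique())[1:]]
        )
        fit = fit_random_intercept_lmm(sub["_resp"], X, sub["date"].to_numpy())
        L = np.zeros((X.shape[1] - 1, X.shape[1]))
        for r in range(L.shape[0]):
            L[r, r + 1] = 1.0
        per_species[sp] = satterthwaite_f(fit, L)

    per_year: dict[int, FTestResult] = {}
    for year in sorted(mono["year"].unique()):
        sub = mono[mono["year"] == year]
        if sub["species"].nunique() < 2 or sub["date"].nunique() < 2:
            logger.warning("species test skipped for %s: insufficient data", year)
            continue
        X = np.column_stack(
            [np.ones(len(sub))] +
            [(sub["species"] == s).to_numpy(dtype=float) for s in sorted(sub["species"].unique())[1:]]
        )
        fit = fit_random_intercept_lmm(sub["_resp"], X, sub["date"].to_numpy())
        L = np.zeros((X.shape[1] - 1, X.shape[1]))
        for r in range(L.shape[0]):
            L[r, r + 1] = 1.0
        per_year[int(year)] = satterthwaite_f(fit, L)

    means = (
        mono.groupby(["species", "year"])["size"]
        .agg(mean_size="mean", n="count")
        .reset_index()
    )
    return FlockSizeResults(
        per_year_species_test=per_year,
        per_species_year_test=per_species,
        group_means=means,
    )
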