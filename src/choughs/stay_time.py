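"""Stay-time analyses on natural-log stay times.

Three model families, all random-intercept LMMs with collection date as the
grouping factor and Satterthwaite F tests:

1. overall:      log(stay) ~ species + year + flock_size   (all records)
2. per species:  log(stay) ~ year + flock_size             (monospecific only)
3. per year:     log(stay) ~ flock_type                    (red-billed only)

Stratum means are reported both raw (arithmetic mean of the seconds) and
model-based: the saturated stratum-cell LMM mean back-transformed with the
log-normal correction exp(mu + (sigma_b^2 + sigma^2)/2), which estimates the
arithmetic mean a log-scale model implies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ForagingObservation, StudyConfig, observations_frame
from .lmm import FTestResult, collinearity_screen, fit_random_intercept_lmm, satterthwaite_f

logger = logging.getLogger(__name__)


@dataclass
class StayTimeResults:
    overall: dict[str, FTestResult]
    per_species: dict[str, dict[str, FTestResult]]
    per_year_flock_type: dict[int, FTestResult]
    stratum_means_s: pd.DataFrame
    retained_predictors: list[str]

    def to_dict(self) -> dict:
        return {
            "overall": {k: v.to_dict() for k, v in self.overall.items()},
            "per_species": {
                sp: {k: v.to_dict() for k, v in terms.items()}
                for sp, terms in self.per_species.items()
            },
            "per_year_flock_type": {
                str(y): v.to_dict() for y, v in self.per_year_flock_type.items()
            },
            "stratum_means_s": self.stratum_means_s.to_dict(orient="records"),
            "retained_predictors": self.retained_predictors,
        }


def _design(df: pd.DataFrame, factors: list[str], covariates: list[str]):
    """Treatment-coded design matrix with intercept; the alphabetically first
    level of each factor is the reference.  Returns (X, names, term_columns)."""
    n = len(df)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    term_columns: dict[str, list[int]] = {}
    for f in factors:
        levels = sorted(df[f].astype(str).unique())
        idx = []
        for lev in levels[1:]:
            cols.append((df[f].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
            idx.append(len(names) - 1)
        term_columns[f] = idx
    for c in covariates:
        cols.append(df[c].to_numpy(dtype=float))
        names.append(c)
        term_columns[c] = [len(names) - 1]
    return np.column_stack(cols), names, term_columns


def _term_tests(df: pd.DataFrame, response: np.ndarray, factors, covariates):
    X, names, term_columns = _design(df, factors, covariates)
    fit = fit_random_intercept_lmm(response, X, df["date"].to_numpy(), column_names=names)
    tests: dict[str, FTestResult] = {}
    p = X.shape[1]
    for term, col_idx in term_columns.items():
        if not col_idx:
            continue  # single-level factor: no contrast
        L = np.zeros((len(col_idx), p))
        for r, j in enumerate(col_idx):
            L[r, j] = 1.0
        tests[term] = satterthwaite_f(fit, L)
    return fit, tests


def _flock_size_column(df: pd.DataFrame, cfg: StudyConfig) -> pd.DataFrame:
    df = df.copy()
    df["flock_size_pred"] = (
        np.log(df["flock_size"].to_numpy(dtype=float))
        if cfg.log_flock_size
        else df["flock_size"].to_numpy(dtype=float)
    )
    return df


def stratum_means(obs_df: pd.DataFrame) -> pd.DataFrame:
    """Raw and model-based arithmetic stay-time means per
    (species, year, flock_type) stratum.

    The model-based mean comes from one saturated cell-means LMM on log stay
    times with a date random intercept, back-transformed with the log-normal
    correction; it is invariant to factor reference-level choices because the
    stratum cells are estimated directly.
    """
    df = obs_df.copy()
    df["stratum"] = (
        df["species"].astype(str) + "/" + df["year"].astype(str) + "/" + df["flock_type"].astype(str)
    )
    strata = sorted(df["stratum"].unique())
    # cell-means coding: one indicator per stratum, no intercept
    X = np.column_stack([(df["stratum"] == s).to_numpy(dtype=float) for s in strata])
    logy = np.log(df["stay_time_s"].to_numpy(dtype=float))
    fit = fit_random_intercept_lmm(logy, X, df["date"].to_numpy(), column_names=strata)
    correction = 0.5 * (fit.sigma2_group + fit.sigma2_resid)
    rows = []
    for i, s in enumerate(strata):
        species, year, ftype = s.split("/")
        sub = df[df["stratum"] == s]["stay_time_s"]
        mu = fit.beta[i]
        se = float(np.sqrt(fit.beta_cov[i, i]))
        model_mean = float(np.exp(mu + correction))
        rows.append(
            {
                "species": species,
                "year": int(year),
                "flock_type": ftype,
                "n": int(len(sub)),
                "raw_mean_s": float(sub.mean()),
                "model_mean_s": model_mean,
                "model_mean_lo_s": float(np.exp(mu - 1.96 * se + correction)),
                "model_mean_hi_s": float(np.exp(mu + 1.96 * se + correction)),
            }
        )
    return pd.DataFrame(rows)


def stay_time_analysis(
    obs: list[ForagingObservation] | pd.DataFrame, cfg: StudyConfig
) -> StayTimeResults:
    """Run the full stay-time analysis suite.

    Models whose stratum is absent from the data are skipped with a logged
    warning; the remaining models still run.
    """
    df = obs if isinstance(obs, pd.DataFrame) else observations_frame(obs)
    if df["date"].nunique() < 2:
        raise ValueError("need at least two collection dates")
    df = _flock_size_column(df, cfg)
    logy = np.log(df["stay_time_s"].to_numpy(dtype=float))

    # collinearity screen on the candidate predictors (numeric codings for
    # the factors so Spearman rank correlation is defined)
    candidates = pd.DataFrame(
        {
            "species": pd.factorize(df["species"])[0],
            "year": df["year"].to_numpy(),
            "flock_size": df["flock_size_pred"].to_numpy(),
        }
    )
    retained = collinearity_screen(candidates, cfg.correlation_threshold)

    factors = [c for c in ("species", "year") if c in retained and df[c].nunique() > 1]
    covariates = ["flock_size_pred"] if "flock_size" in retained else []

    _, overall = _term_tests(df, logy, factors, covariates)
    overall = {k.replace("flock_size_pred", "flock_size"): v for k, v in overall.items()}

    per_species: dict[str, dict[str, FTestResult]] = {}
    mono = df[df["flock_type"] == "monospecific"]
    for species in sorted(df["species"].unique()):
        sub = mono[mono["species"] == species]
        if sub.empty or sub["year"].nunique() < 2 or sub["date"].nunique() < 2:
            logger.warning("per-species model skipped for %s: insufficient strata", species)
            continue
        sub_logy = np.log(sub["stay_time_s"].to_numpy(dtype=float))
        sub_factors = ["year"] if "year" in retained else []
        _, tests = _term_tests(sub, sub_logy, sub_factors, covariates)
        per_species[species] = {
            k.replace("flock_size_pred", "flock_size"): v for k, v in tests.items()
        }

    per_year: dict[int, FTestResult] = {}
    red = df[df["species"] == "red_billed"]
    for year in sorted(df["year"].unique()):
        sub = red[red["year"] == year]
        if sub.empty or sub["flock_type"].nunique() < 2 or sub["date"].nunique() < 2:
            logger.warning("flock-type model skipped for %s: insufficient strata", year)
            continue
        sub_logy = np.log(sub["stay_time_s"].to_numpy(dtype=float))
        _, tests = _term_tests(sub, sub_logy, ["flock_type"], [])
        per_year[int(year)] = tests["flock_type"]

    return StayTimeResults(
        overall=overall,
        per_species=per_species,
        per_year_flock_type=per_year,
        stratum_means_s=stratum_means(df),
        retained_predictors=retained,
    )
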