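"""Climate models: AR(2)-GLS for temperature, hurdle-gamma for precipitation.

Temperature is modelled as a Gaussian regression on year, month and their
interaction with AR(2) errors nested within year: the error recursion
restarts at each January 1st and the first two residuals of each year are
treated exactly via the stationary AR(2) distribution.  Estimation is full
maximum likelihood (so fits are comparable by likelihood-ratio tests),
alternating a whitened least-squares step for the regression coefficients
with a bounded search for (phi1, phi2) over the stationarity triangle.

Precipitation is a hurdle model: a logistic regression for P(dry day) and a
gamma regression with log link on the positive amounts.  Because the gamma
distribution has no mass at zero the hurdle and zero-inflated forms coincide
and the likelihood factorizes exactly into the two parts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .core_io import ClimateDay, climate_frame

logger = logging.getLogger(__name__)

MAX_LINPRED = 15.0  # separation guard for the logistic part


class ConvergenceError(RuntimeError):
    def __init__(self, message, last=None):
        super().__init__(message)
        self.last = last


@dataclass
class GLSFit:
    beta: np.ndarray
    column_names: list[str]
    phi: tuple[float, float]
    sigma2_innov: float
    loglik: float
    n: int
    n_params: int  # beta + phi1 + phi2 + sigma2

    def to_dict(self) -> dict:
        return {
            "beta": dict(zip(self.column_names, map(float, self.beta))),
            "phi": [float(p) for p in self.phi],
            "sigma2_innov": float(self.sigma2_innov),
            "loglik": float(self.loglik),
            "n": int(self.n),
        }


@dataclass
class HurdleFit:
    zero_beta: np.ndarray
    zero_names: list[str]
    pos_beta: np.ndarray
    pos_names: list[str]
    gamma_shape: float
    loglik: float
    loglik_zero: float
    loglik_pos: float
    n: int
    n_params: int

    def to_dict(self) -> dict:
        return {
            "zero_beta": dict(zip(self.zero_names, map(float, self.zero_beta))),
            "pos_beta": dict(zip(self.pos_names, map(float, self.pos_beta))),
            "gamma_shape": float(self.gamma_shape),
            "loglik": float(self.loglik),
            "n": int(self.n),
        }


@dataclass
class LRTResult:
    statistic: float
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"chisq": float(self.statistic), "df": int(self.df), "p": float(self.p_value)}


def _ar2_stationary(phi1: float, phi2: float) -> bool:
    return (abs(phi2) < 1.0) and (phi1 + phi2 < 1.0) and (phi2 - phi1 < 1.0)


def _whiten_blocks(resid_blocks, phi1, phi2):
    """Whiten per-year residual blocks under the exact AR(2) likelihood.

    Returns (whitened residual vector u, logdet_K) where Var(resid) =
    sigma2 * K and u = W resid with Var(u) = sigma2 * I.  The first two
    observations of each block are transformed by the inverse Cholesky factor
    of the stationary correlation-scaled covariance; later observations are
    the AR innovations.
    """
    k0 = (1.0 - phi2) / ((1.0 + phi2) * ((1.0 - phi2) ** 2 - phi1**2))
    k1 = phi1 * k0 / (1.0 - phi2)
    K2 = np.array([[k0, k1], [k1, k0]])
    L2 = np.linalg.cholesky(K2)
    L2_inv = np.linalg.inv(L2)
    logdet_K2 = 2.0 * float(np.sum(np.log(np.diag(L2))))
    us = []
    logdet = 0.0
    for e in resid_blocks:
        T = len(e)
        if T < 3:
            raise ValueError("each yearly series must have length >= 3")
        u = np.empty(T)
        u[:2] = L2_inv @ e[:2]
        u[2:] = e[2:] - phi1 * e[1:-1] - phi2 * e[:-2]
        us.append(u)
        logdet += logdet_K2
    return np.concatenate(us), logdet


def _whiten_matrix_blocks(M_blocks, phi1, phi2):
    k0 = (1.0 - phi2) / ((1.0 + phi2) * ((1.0 - phi2) ** 2 - phi1**2))
    k1 = phi1 * k0 / (1.0 - phi2)
    L2_inv = np.linalg.inv(np.linalg.cholesky(np.array([[k0, k1], [k1, k0]])))
    out = []
    for M in M_blocks:
        W = np.empty_like(M)
        W[:2] = L2_inv @ M[:2]
        W[2:] = M[2:] - phi1 * M[1:-1] - phi2 * M[:-2]
        out.append(W)
    return np.vstack(out)


def _profile_loglik(phi, y_blocks, X_blocks):
    """ML log-likelihood at phi, profiled over beta and sigma2."""
    phi1, phi2 = phi
    if not _ar2_stationary(phi1, phi2):
        return -np.inf, None, None
    try:
        Xw = _whiten_matrix_blocks(X_blocks, phi1, phi2)
        yw, logdet = _whiten_blocks(y_blocks, phi1, phi2)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = len(yw)
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0:
        return -np.inf, None, None
    ll = -0.5 * (n * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet)
    return float(ll), beta, sigma2


def fit_gls_ar2(y, X, year_index, column_names=None, tol=1e-8, max_iter=200) -> GLSFit:
    """Maximum-likelihood GLS with AR(2) errors restarting per year.

    Parameters
    ----------
    y : (n,) response, contiguous daily values within each year
    X : (n, p) design matrix
    year_index : (n,) labels splitting the series into contiguous blocks
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if column_names is None:
        column_names = [f"x{j}" for j in range(X.shape[1])]
    years, idx = np.unique(np.asarray(year_index), return_inverse=True)
    y_blocks = [y[idx == i] for i in range(len(years))]
    X_blocks = [X[idx == i] for i in range(len(years))]
    for b in y_blocks:
        if len(b) < 3:
            raise ValueError("each yearly series must have length >= 3")

    # iterate: bounded Nelder-Mead over phi with profiled (beta, sigma2)
    def neg(phi):
        ll, *_ = _profile_loglik(phi, y_blocks, X_blocks)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for start in [(0.0, 0.0), (0.5, 0.2), (-0.3, 0.1)]:
        res = optimize.minimize(neg, start, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": tol, "maxiter": max_iter * 10})
        if best is None or res.fun < best.fun:
            best = res
    phi1, phi2 = best.x
    ll, beta, sigma2 = _profile_loglik((phi1, phi2), y_blocks, X_blocks)
    if not np.isfinite(ll):
        raise ConvergenceError("AR(2) GLS failed to converge", last=best)
    return GLSFit(
        beta=beta, column_names=list(column_names), phi=(float(phi1), float(phi2)),
        sigma2_innov=float(sigma2), loglik=float(ll), n=len(y),
        n_params=X.shape[1] + 3,
    )


def _irls_logistic(z, X, max_iter=100, tol=1e-10):
    """Logistic regression by IRLS with a separation guard: linear predictors
    are capped at +/-MAX_LINPRED."""
    n, p = X.shape
    beta = np.zeros(p)
    separated = False
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -MAX_LINPRED, MAX_LINPRED)
        mu = special.expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        zwork = eta + (z - mu) / w
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, WX.T @ zwork)
        if np.max(np.abs(X @ beta_new)) > MAX_LINPRED:
            separated = True
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    if separated:
        warnings.warn("quasi-separation in the hurdle zero model; "
                      "linear predictor capped", stacklevel=3)
    eta = np.clip(X @ beta, -MAX_LINPRED, MAX_LINPRED)
    mu = special.expit(eta)
    ll = float(np.sum(z * np.log(mu) + (1.0 - z) * np.log1p(-mu)))
    return beta, ll


def _irls_gamma_log(y, X, max_iter=200, tol=1e-10):
    """Gamma regression with log link by IRLS (the score for beta does not
    involve the shape, which is fitted afterwards by profile ML)."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log(np.mean(y))
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.exp(np.clip(eta, -30, 30))
        zwork = eta + (y - mu) / mu
        beta_new, *_ = np.linalg.lstsq(X, zwork, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(X @ beta, -30, 30))
    # profile ML for the shape alpha: log(alpha) - digamma(alpha) = mean(d)
    d = float(np.mean(np.log(mu) - np.log(y) + y / mu - 1.0))
    if d <= 0:
        shape = 1e6
    else:
        f = lambda a: np.log(a) - special.digamma(a) - d
        lo, hi = 1e-6, 1e6
        shape = float(optimize.brentq(f, lo, hi))
    ll = float(np.sum(stats.gamma.logpdf(y, a=shape, scale=mu / shape)))
    return beta, shape, ll


def fit_hurdle_gamma(y, X_zero, X_pos, zero_names=None, pos_names=None) -> HurdleFit:
    """Hurdle (zero-inflated) gamma fit.

    ``y`` is daily precipitation (>= 0).  The logistic part models
    P(y > 0); the gamma part, with log link, models the mean of the positive
    amounts.  The total log-likelihood is exactly the sum of the two parts.
    """
    y = np.asarray(y, dtype=float)
    X_zero = np.asarray(X_zero, dtype=float)
    X_pos = np.asarray(X_pos, dtype=float)
    if zero_names is None:
        zero_names = [f"z{j}" for j in range(X_zero.shape[1])]
    if pos_names is None:
        pos_names = [f"p{j}" for j in range(X_pos.shape[1])]
    positive = y > 0
    zero_beta, ll_zero = _irls_logistic((~positive).astype(float), X_zero)
    if positive.sum() >= 2 and len(np.unique(y[positive])) >= 2:
        pos_beta, shape, ll_pos = _irls_gamma_log(y[positive], X_pos[positive])
    else:
        logger.warning("insufficient positive precipitation; gamma part skipped")
        pos_beta = np.full(X_pos.shape[1], np.nan)
        shape, ll_pos = np.nan, 0.0
    return HurdleFit(
        zero_beta=zero_beta, zero_names=list(zero_names),
        pos_beta=pos_beta, pos_names=list(pos_names),
        gamma_shape=float(shape), loglik=float(ll_zero + ll_pos),
        loglik_zero=float(ll_zero), loglik_pos=float(ll_pos),
        n=len(y), n_params=X_zero.shape[1] + X_pos.shape[1] + 1,
    )


def lr_test(full, reduced) -> LRTResult:
    """Likelihood-ratio test of nested fits (chi-square reference)."""
    df = full.n_params - reduced.n_params
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    return LRTResult(statistic=stat, df=df, p_value=float(stats.chi2.sf(stat, df)))


def _climate_design(df: pd.DataFrame, with_year: bool, with_interaction: bool):
    """Treatment-coded design on month (factor) and optionally year."""
    months = sorted(df["month"].unique())
    years = sorted(df["year"].unique())
    cols = [np.ones(len(df))]
    names = ["(Intercept)"]
    for m in months[1:]:
        cols.append((df["month"] == m).to_numpy(dtype=float))
        names.append(f"month[{m}]")
    if with_year and len(years) > 1:
        for yv in years[1:]:
            cols.append((df["year"] == yv).to_numpy(dtype=float))
            names.append(f"year[{yv}]")
        if with_interaction:
            for yv in years[1:]:
                for m in months[1:]:
                    cols.append(
                        ((df["year"] == yv) & (df["month"] == m)).to_numpy(dtype=float)
                    )
                    names.append(f"year[{yv}]:month[{m}]")
    return np.column_stack(cols), names


def climate_analysis(series: list[ClimateDay] | pd.DataFrame, reduced_months_only=True) -> dict:
    """Year/month climate comparison.

    Temperature: AR(2)-GLS fits of (a) month only, (b) month + year,
    (c) month * year; likelihood-ratio tests of year (b vs a) and of
    year + interaction jointly (c vs a).  Precipitation: hurdle-gamma fits
    with the same designs in both components, compared the same way.
    Per-month-year means are reported alongside.
    """
    df = series if isinstance(series, pd.DataFrame) else climate_frame(series)
    df = df.sort_values("date").reset_index(drop=True)

    temp = df["temperature_c"].to_numpy(dtype=float)
    yearix = df["year"].to_numpy()

    X_red, names_red = _climate_design(df, with_year=False, with_interaction=False)
    X_year, names_year = _climate_design(df, with_year=True, with_interaction=False)
    X_full, names_full = _climate_design(df, with_year=True, with_interaction=True)

    fit_red = fit_gls_ar2(temp, X_red, yearix, names_red)
    fit_year = fit_gls_ar2(temp, X_year, yearix, names_year)
    fit_full = fit_gls_ar2(temp, X_full, yearix, names_full)

    out: dict = {
        "temperature": {
            "fit_month_only": fit_red.to_dict(),
            "fit_year_additive": fit_year.to_dict(),
            "fit_year_interaction": fit_full.to_dict(),
            "lrt_year": lr_test(fit_year, fit_red).to_dict(),
            "lrt_year_and_interaction": lr_test(fit_full, fit_red).to_dict(),
        }
    }

    precip = df["precipitation_mm"].to_numpy(dtype=float)
    h_red = fit_hurdle_gamma(precip, X_red, X_red, names_red, names_red)
    h_year = fit_hurdle_gamma(precip, X_year, X_year, names_year, names_year)
    h_full = fit_hurdle_gamma(precip, X_full, X_full, names_full, names_full)
    out["precipitation"] = {
        "fit_month_only": h_red.to_dict(),
        "fit_year_additive": h_year.to_dict(),
        "fit_year_interaction": h_full.to_dict(),
        "lrt_year": lr_test(h_year, h_red).to_dict(),
        "lrt_year_and_interaction": lr_test(h_full, h_red).to_dict(),
    }

    means = (
        df.groupby(["year", "month"])
        .agg(mean_temp_c=("temperature_c", "mean"), mean_precip_mm=("precipitation_mm", "mean"))
        .reset_index()
    )
    out["monthly_means"] = means.to_dict(orient="records")
    return out
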