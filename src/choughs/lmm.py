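"""Random-intercept linear mixed model engine.

Fits the model

    y = X beta + Z b + e,    b ~ N(0, sigma_b^2 I_g),   e ~ N(0, sigma^2 I_n)

with a single grouping factor (here, the collection date) by REML.  The
variance ratio lambda = sigma_b^2 / sigma^2 is profiled: for any lambda the
GLS solution for beta and the residual variance are available in closed form
because the marginal covariance is block diagonal with blocks
sigma^2 (I + lambda J).  The profiled REML criterion is then maximised by a
one-dimensional golden-section search on log(lambda), with the boundary
lambda = 0 handled explicitly.

Hypothesis tests use F statistics with Satterthwaite denominator degrees of
freedom: the covariance of the fixed effects is treated as a function of the
variance components theta = (sigma_b^2, sigma^2), each eigen-contrast of the
term gets a moment-matched df from the delta method against the asymptotic
covariance of theta (finite-difference REML Hessian), and the per-contrast
dfs are pooled harmonically so that single contrasts reduce to the classical
Satterthwaite formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

DDF_FLOOR = 1.01


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; the message names aliased columns."""


@dataclass
class LMMFit:
    """A fitted random-intercept LMM at the REML optimum."""

    beta: np.ndarray
    beta_cov: np.ndarray
    sigma2_resid: float
    sigma2_group: float
    lam: float
    reml_loglik: float
    theta_cov: np.ndarray
    n_obs: int
    n_groups: int
    rank_X: int
    column_names: list[str]
    group_variance_identifiable: bool
    # retained for downstream covariance recomputation at perturbed theta
    _X: np.ndarray = None
    _group_idx: np.ndarray = None
    _group_sizes: np.ndarray = None

    def beta_cov_at(self, sigma2_group: float, sigma2_resid: float) -> np.ndarray:
        """Fixed-effect covariance (X' V(theta)^-1 X)^-1 at given components."""
        lam = max(sigma2_group, 0.0) / sigma2_resid
        xtvx, _, _ = _gls_pieces(self._X, None, self._group_idx, self._group_sizes, lam)
        return sigma2_resid * np.linalg.inv(xtvx)


@dataclass
class FTestResult:
    """An F test with Satterthwaite denominator degrees of freedom."""

    f_value: float
    ndf: int
    ddf: float
    p_value: float

    def to_dict(self) -> dict:
        return {
            "F": float(self.f_value),
            "ndf": int(self.ndf),
            "ddf": float(self.ddf),
            "p": float(self.p_value),
        }


def _encode_groups(groups) -> tuple[np.ndarray, np.ndarray]:
    codes, _ = pd_factorize(groups)
    sizes = np.bincount(codes)
    return codes, sizes


def pd_factorize(groups):
    arr = np.asarray(groups)
    uniq, codes = np.unique(arr, return_inverse=True)
    return codes.astype(np.int64), uniq


def _gls_pieces(X, y, group_idx, group_sizes, lam):
    """Return (X' V0^-1 X, X' V0^-1 y, log|V0|) for V0 = I + lam * Z Z'.

    Uses the Sherman-Morrison form per block: V0_j^-1 = I - c_j J with
    c_j = lam / (1 + lam * m_j), so only group sums are needed.
    """
    shrink = lam / (1.0 + lam * group_sizes)  # c_j per group
    Xg = np.zeros((len(group_sizes), X.shape[1]))
    np.add.at(Xg, group_idx, X)
    xtvx = X.T @ X - (Xg * shrink[:, None]).T @ Xg
    logdet = float(np.sum(np.log1p(lam * group_sizes)))
    if y is None:
        return xtvx, None, logdet
    yg = np.zeros(len(group_sizes))
    np.add.at(yg, group_idx, y)
    xtvy = X.T @ y - Xg.T @ (shrink * yg)
    return xtvx, xtvy, logdet


def _profiled_reml(lam, X, y, group_idx, group_sizes):
    """REML log-likelihood profiled over beta and sigma^2 at fixed lambda."""
    n, p = X.shape
    xtvx, xtvy, logdet_v = _gls_pieces(X, y, group_idx, group_sizes, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - X @ beta
    shrink = lam / (1.0 + lam * group_sizes)
    rg = np.zeros(len(group_sizes))
    np.add.at(rg, group_idx, resid)
    quad = float(resid @ resid - rg @ (shrink * rg))
    # floor guards the degenerate zero-residual case (e.g. constant response)
    sigma2 = max(quad / (n - p), 1e-12 * (1.0 + float(y @ y) / n))
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    ll = -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0) + logdet_v + logdet_xtvx
    )
    return ll, beta, sigma2, xtvx


def reml_loglik_at_theta(fit: LMMFit, sigma2_group: float, sigma2_resid: float, y: np.ndarray) -> float:
    """Unprofiled REML log-likelihood at arbitrary (sigma_b^2, sigma^2)."""
    X, gi, gs = fit._X, fit._group_idx, fit._group_sizes
    n, p = X.shape
    lam = max(sigma2_group, 0.0) / sigma2_resid
    xtvx, xtvy, logdet_v0 = _gls_pieces(X, y, gi, gs, lam)
    beta = np.linalg.solve(xtvx, xtvy)
    resid = y - X @ beta
    shrink = lam / (1.0 + lam * gs)
    rg = np.zeros(len(gs))
    np.add.at(rg, gi, resid)
    quad = float(resid @ resid - rg @ (shrink * rg)) / sigma2_resid
    _, logdet_xtvx = np.linalg.slogdet(xtvx / sigma2_resid)
    logdet_v = logdet_v0 + n * np.log(sigma2_resid)
    return -0.5 * ((n - p) * np.log(2.0 * np.pi) + logdet_v + logdet_xtvx + quad)


def fit_random_intercept_lmm(y, X, groups, column_names=None) -> LMMFit:
    """REML fit of a random-intercept LMM by profiling the variance ratio.

    Parameters
    ----------
    y : (n,) response vector
    X : (n, p) fixed-effect design, full column rank
    groups : (n,) group labels for the random intercept
    column_names : optional names for the columns of X (used in errors)

    Returns the boundary fit lambda = 0 when the REML optimum lies there.
    With a single group, ``sigma2_group`` is not identifiable; the fit is
    returned with ``group_variance_identifiable=False`` and lambda = 0.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if column_names is None:
        column_names = [f"x{j}" for j in range(p)]
    if len(y) != n or len(np.asarray(groups)) != n:
        raise ValueError("y, X and groups must have matching lengths")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the aliased columns: those whose removal does not lower the rank
        aliased = []
        for j in range(p):
            keep = [k for k in range(p) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                aliased.append(column_names[j])
        raise RankDeficientError(f"design matrix rank deficient; aliased columns: {aliased}")
    if n <= p:
        raise ValueError("need more observations than fixed-effect columns")

    group_idx, group_sizes = _encode_groups(groups)
    g = len(group_sizes)

    identifiable = g >= 2 and np.any(group_sizes > 1)

    def neg_crit(loglam):
        ll, *_ = _profiled_reml(np.exp(loglam), X, y, group_idx, group_sizes)
        return -ll

    ll0, beta0, sigma2_0, xtvx0 = _profiled_reml(0.0, X, y, group_idx, group_sizes)
    if identifiable:
        res = optimize.minimize_scalar(
            neg_crit, bounds=(-16.0, 16.0), method="bounded",
            options={"xatol": 1e-10},
        )
        lam_hat = float(np.exp(res.x))
        ll_hat = -res.fun
        if ll0 >= ll_hat - 1e-12:
            lam_hat, ll_hat = 0.0, ll0
    else:
        lam_hat, ll_hat = 0.0, ll0

    ll, beta, sigma2, xtvx = _profiled_reml(lam_hat, X, y, group_idx, group_sizes)
    sigma2_b = lam_hat * sigma2
    beta_cov = sigma2 * np.linalg.inv(xtvx)

    fit = LMMFit(
        beta=beta,
        beta_cov=beta_cov,
        sigma2_resid=sigma2,
        sigma2_group=sigma2_b,
        lam=lam_hat,
        reml_loglik=ll,
        theta_cov=np.zeros((2, 2)),
        n_obs=n,
        n_groups=g,
        rank_X=p,
        column_names=list(column_names),
        group_variance_identifiable=bool(identifiable),
        _X=X,
        _group_idx=group_idx,
        _group_sizes=group_sizes,
    )
    fit.theta_cov = _theta_cov(fit, y)
    return fit


def _theta_cov(fit: LMMFit, y: np.ndarray) -> np.ndarray:
    """Asymptotic covariance of (sigma_b^2, sigma^2) from the negative REML
    Hessian, by central finite differences (relative step 1e-4)."""
    theta = np.array([fit.sigma2_group, fit.sigma2_resid])
    steps = 1e-4 * np.maximum(np.abs(theta), fit.sigma2_resid)

    def ll(t):
        sb = max(t[0], 0.0)
        return reml_loglik_at_theta(fit, sb, t[1], y)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(i, 2):
            ei = np.zeros(2); ei[i] = steps[i]
            ej = np.zeros(2); ej[j] = steps[j]
            if i == j:
                H[i, i] = (ll(theta + ei) - 2.0 * ll(theta) + ll(theta - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    ll(theta + ei + ej) - ll(theta + ei - ej)
                    - ll(theta - ei + ej) + ll(theta - ei - ej)
                ) / (4.0 * steps[i] * steps[j])
    neg_H = -H
    # at a boundary (lambda = 0) or a flat direction the Hessian can be
    # singular; fall back to the identifiable sub-block
    try:
        cov = np.linalg.inv(neg_H)
        if not np.all(np.isfinite(cov)) or cov[0, 0] < 0 or cov[1, 1] < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.zeros((2, 2))
        if neg_H[1, 1] > 0:
            cov[1, 1] = 1.0 / neg_H[1, 1]
        if neg_H[0, 0] > 0:
            cov[0, 0] = 1.0 / neg_H[0, 0]
    return cov


def satterthwaite_f(fit: LMMFit, L) -> FTestResult:
    """F test of H0: L beta = 0 with Satterthwaite denominator df.

    F = (L beta)' [L C L']^{-1} (L beta) / q with C the REML fixed-effect
    covariance and q = rank(L).  The denominator df comes from the
    eigen-decomposition squeeze: each eigen-contrast l of L C L' gets
    nu(l) = 2 g(l)^2 / (grad g' A grad g) where g(theta) = l' C(theta) l,
    gradients are central finite differences in (sigma_b^2, sigma^2) and A is
    the asymptotic covariance of theta; the nu(l) are pooled harmonically.
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    if not np.any(L):
        raise ValueError("contrast matrix L is all zero")
    # reduce to independent rows
    q = np.linalg.matrix_rank(L)
    if q < L.shape[0]:
        # orthonormal row basis keeps the test invariant
        _, _, vt = np.linalg.svd(L, full_matrices=False)
        L = vt[:q]  # F depends only on the row space of L
    C = fit.beta_cov
    Lb = L @ fit.beta
    M = L @ C @ L.T
    # pinv handles the degenerate zero-variance fit (constant response)
    f_value = float(Lb @ np.linalg.pinv(M) @ Lb) / q

    # eigen-contrasts of L C L'
    evals, evecs = np.linalg.eigh(M)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]

    theta = np.array([fit.sigma2_group, fit.sigma2_resid])
    steps = 1e-4 * np.maximum(np.abs(theta), fit.sigma2_resid)
    A = fit.theta_cov

    def g_all(t):
        Ct = fit.beta_cov_at(max(t[0], 0.0), t[1])
        Mt = L @ Ct @ L.T
        return np.array([evecs[:, i] @ Mt @ evecs[:, i] for i in range(q)])

    grads = np.zeros((q, 2))
    for k in range(2):
        e = np.zeros(2); e[k] = steps[k]
        grads[:, k] = (g_all(theta + e) - g_all(theta - e)) / (2.0 * steps[k])

    nus = np.empty(q)
    for i in range(q):
        g_i = float(evecs[:, i] @ M @ evecs[:, i])
        denom = float(grads[i] @ A @ grads[i])
        if denom <= 0 or not np.isfinite(denom):
            nus[i] = np.inf
        else:
            nus[i] = 2.0 * g_i**2 / denom

    finite = nus[np.isfinite(nus)]
    usable = finite[finite > 2.0]
    if len(usable) < q and len(finite) == len(nus):
        # some contrast has nu <= 2: floor the pooled df
        warnings.warn("Satterthwaite df <= 2 for a contrast; flooring ddf", stacklevel=2)
        ddf = max(float(np.min(nus)), DDF_FLOOR)
    elif np.all(np.isinf(nus)):
        ddf = float(fit.n_obs - fit.rank_X)
    else:
        E = float(np.sum(nus[np.isfinite(nus)] / (nus[np.isfinite(nus)] - 2.0)))
        E += int(np.sum(np.isinf(nus)))  # inf contributes nu/(nu-2) -> 1
        ddf = 2.0 * E / (E - q) if E > q else DDF_FLOOR
    ddf = max(ddf, DDF_FLOOR)
    p_value = float(stats.f.sf(f_value, q, ddf))
    return FTestResult(f_value=f_value, ndf=int(q), ddf=float(ddf), p_value=p_value)


def collinearity_screen(X_candidates, threshold: float = 0.7) -> list[str]:
    """Greedy Spearman collinearity screen.

    ``X_candidates`` is a mapping/DataFrame of named predictor columns.  Pairs
    with |rho| >= threshold lose their later-listed member; constant columns
    have undefined rank correlation and are dropped with a warning.  The
    retained set has all pairwise |rho| below the threshold.
    """
    import pandas as pd

    df = pd.DataFrame(X_candidates)
    if df.shape[1] < 1:
        raise ValueError("need at least one candidate predictor")
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    names = list(df.columns)
    retained: list[str] = []
    for name in names:
        col = df[name].to_numpy(dtype=float)
        if np.all(col == col[0]):
            warnings.warn(f"constant column {name!r}: Spearman undefined, dropped", stacklevel=2)
            continue
        ok = True
        for kept in retained:
            rho = stats.spearmanr(df[kept], col).statistic
            if np.abs(rho) >= threshold:
                ok = False
                break
        if ok:
            retained.append(name)
    return retained
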