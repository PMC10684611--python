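"""Foraging home ranges and altitudinal comparisons.

Home ranges are utilization distributions: a product Gaussian kernel density
estimate of the flock positions, with a per-axis plug-in (Sheather-Jones
direct, two-stage) bandwidth and Silverman's rule as fallback.  The home
range at mass quantile q is the smallest density-threshold set of grid cells
capturing at least a fraction q of the total probability mass — the
conventional utilization-distribution isopleth (q = 0.95 by default).

Altitudinal distributions are compared by Pearson chi-square on year-by-bin
contingency tables, with the p-value computed by Monte Carlo over tables
sampled with both margins fixed (sequential multivariate-hypergeometric
construction, as in the classical r x c randomization test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import FlockRecord, flocks_frame

logger = logging.getLogger(__name__)


class DegenerateBandwidthError(ValueError):
    """All points identical (or a zero-variance axis): no bandwidth exists."""


@dataclass
class HomeRange:
    """A gridded kernel-density foraging range."""

    grid_origin: tuple[float, float]
    cell_size_m: float
    density: np.ndarray  # (ny, nx), integrates (x cell area) to ~1
    mass_quantile: float
    inclusion_mask: np.ndarray  # boolean (ny, nx)
    area_m2: float
    n_points: int
    bandwidth_m: tuple[float, float]
    points: np.ndarray  # retained so overlaps can re-evaluate on a shared grid

    @property
    def x_edges(self) -> np.ndarray:
        nx = self.density.shape[1]
        return self.grid_origin[0] + self.cell_size_m * np.arange(nx + 1)

    @property
    def y_edges(self) -> np.ndarray:
        ny = self.density.shape[0]
        return self.grid_origin[1] + self.cell_size_m * np.arange(ny + 1)


@dataclass
class OverlapResult:
    frac_A_in_B: float
    frac_B_in_A: float
    shared_area_m2: float

    def to_dict(self) -> dict:
        return {
            "frac_A_in_B": self.frac_A_in_B,
            "frac_B_in_A": self.frac_B_in_A,
            "shared_area_m2": self.shared_area_m2,
        }


def _normal_scale_psi(r: int, sd: float) -> float:
    """Normal-scale estimate of the density functional psi_r = int f^(r) f."""
    from scipy.special import factorial

    half = r // 2
    return float(
        (-1) ** half * factorial(r) / ((2 * sd) ** (r + 1) * factorial(half) * np.sqrt(np.pi))
    )


def _phi_deriv(x: np.ndarray, r: int) -> np.ndarray:
    """r-th derivative of the standard normal pdf via Hermite polynomials."""
    from numpy.polynomial.hermite_e import hermeval

    coef = np.zeros(r + 1)
    coef[r] = 1.0
    he = hermeval(x, coef)
    return (-1) ** r * he * stats.norm.pdf(x)


def _psi_hat(x: np.ndarray, r: int, g: float) -> float:
    d = (x[:, None] - x[None, :]) / g
    n = len(x)
    return float(np.sum(_phi_deriv(d, r)) / (n**2 * g ** (r + 1)))


def sheather_jones_bandwidth(x: np.ndarray) -> float:
    """Two-stage direct plug-in bandwidth for a 1-D Gaussian KDE.

    Stage 0 estimates psi_6 at normal scale, stage 1 estimates psi_4 with a
    kernel functional estimator at the pilot bandwidth implied by psi_6, and
    the final bandwidth is h = [1 / (2 sqrt(pi) n psi_4)]^(1/5).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise DegenerateBandwidthError("zero-variance sample")
    psi6 = _normal_scale_psi(6, scale)
    # pilot bandwidth for estimating psi_4: g = [2 phi^(4)(0) / (-psi_6 n)]^(1/7)
    phi4_0 = float(_phi_deriv(np.array([0.0]), 4)[0])
    g = (2.0 * phi4_0 / (-psi6 * n)) ** (1.0 / 7.0)
    psi4 = _psi_hat(x, 4, g)
    if psi4 <= 0:
        raise DegenerateBandwidthError("plug-in functional estimate non-positive")
    return float((1.0 / (2.0 * np.sqrt(np.pi) * n * psi4)) ** 0.2)


def silverman_bandwidth(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    n = len(x)
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 0:
        raise DegenerateBandwidthError("zero-variance sample")
    return float(0.9 * scale * n ** (-0.2))


def _axis_bandwidth(x: np.ndarray) -> float:
    try:
        h = sheather_jones_bandwidth(x)
        if not np.isfinite(h) or h <= 0:
            raise ValueError("non-finite plug-in bandwidth")
        return h
    except DegenerateBandwidthError as exc:
        if "zero-variance" in str(exc):
            raise
        return silverman_bandwidth(x)
    except (ValueError, FloatingPointError, ZeroDivisionError):
        return silverman_bandwidth(x)


def _eval_product_kde(points: np.ndarray, hx: float, hy: float,
                      xc: np.ndarray, yc: np.ndarray) -> np.ndarray:
    """Evaluate the product-Gaussian KDE on the grid (yc x xc)."""
    gx = stats.norm.pdf((xc[None, :] - points[:, 0][:, None]) / hx) / hx
    gy = stats.norm.pdf((yc[None, :] - points[:, 1][:, None]) / hy) / hy
    return (gy.T @ gx) / len(points)


def kde_home_range(points, q: float = 0.95, cell_size_m: float = 25.0) -> HomeRange:
    """Gaussian-KDE utilization distribution and its q-mass home range.

    Parameters
    ----------
    points : (n, 2) array of planar positions in metres
    q : mass quantile of the inclusion isopleth, in (0, 1)
    cell_size_m : grid resolution

    The grid is padded by 4 bandwidths on each side so that the discretized
    density integrates to 1 within 1e-3.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(points)
    if n < 10:
        raise ValueError(f"need at least 10 points, got {n}")
    if np.allclose(points, points[0]):
        raise DegenerateBandwidthError("all points identical")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")

    hx = _axis_bandwidth(points[:, 0])
    hy = _axis_bandwidth(points[:, 1])

    pad = 4.0
    x0 = float(points[:, 0].min() - pad * hx)
    x1 = float(points[:, 0].max() + pad * hx)
    y0 = float(points[:, 1].min() - pad * hy)
    y1 = float(points[:, 1].max() + pad * hy)
    # snap the origin to the cell lattice so translation equivariance is exact
    x0 = np.floor(x0 / cell_size_m) * cell_size_m
    y0 = np.floor(y0 / cell_size_m) * cell_size_m
    nx = int(np.ceil((x1 - x0) / cell_size_m))
    ny = int(np.ceil((y1 - y0) / cell_size_m))
    xc = x0 + cell_size_m * (np.arange(nx) + 0.5)
    yc = y0 + cell_size_m * (np.arange(ny) + 0.5)

    density = _eval_product_kde(points, hx, hy, xc, yc)
    cell_area = cell_size_m**2

    mask = _isopleth_mask(density, cell_area, q)
    area = float(mask.sum() * cell_area)
    return HomeRange(
        grid_origin=(x0, y0),
        cell_size_m=cell_size_m,
        density=density,
        mass_quantile=q,
        inclusion_mask=mask,
        area_m2=area,
        n_points=n,
        bandwidth_m=(hx, hy),
        points=points.copy(),
    )


def _isopleth_mask(density: np.ndarray, cell_area: float, q: float) -> np.ndarray:
    """Smallest density-threshold cell set capturing mass >= q."""
    flat = density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) * cell_area
    total = cum[-1]
    k = int(np.searchsorted(cum, q * total) + 1)
    mask = np.zeros(flat.shape, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(density.shape)


def overlap_fraction(A: HomeRange, B: HomeRange) -> OverlapResult:
    """Pairwise overlap of two home ranges on a shared grid.

    Both KDEs are re-evaluated on the union bounding box at the finer of the
    two cell sizes, their q-isopleths recomputed there, and the shared area is
    the area of the mask intersection."""
    cell = min(A.cell_size_m, B.cell_size_m)
    x0 = min(A.grid_origin[0], B.grid_origin[0])
    y0 = min(A.grid_origin[1], B.grid_origin[1])
    x1 = max(A.x_edges[-1], B.x_edges[-1])
    y1 = max(A.y_edges[-1], B.y_edges[-1])
    nx = int(np.ceil((x1 - x0) / cell))
    ny = int(np.ceil((y1 - y0) / cell))
    if nx * ny > 40_000_000:
        raise ValueError("grids too far apart to unify at this resolution")
    xc = x0 + cell * (np.arange(nx) + 0.5)
    yc = y0 + cell * (np.arange(ny) + 0.5)
    cell_area = cell**2

    masks = []
    areas = []
    for hr in (A, B):
        dens = _eval_product_kde(hr.points, *hr.bandwidth_m, xc, yc)
        mask = _isopleth_mask(dens, cell_area, hr.mass_quantile)
        masks.append(mask)
        areas.append(float(mask.sum() * cell_area))
    shared = float(np.logical_and(*masks).sum() * cell_area)
    return OverlapResult(
        frac_A_in_B=shared / areas[0],
        frac_B_in_A=shared / areas[1],
        shared_area_m2=shared,
    )


def altitude_contingency(
    flocks: list[FlockRecord] | pd.DataFrame,
    bin_m: float = 100.0,
    bounds_m: tuple[float, float] = (2200.0, 2800.0),
) -> dict[str, pd.DataFrame]:
    """Per-species year-by-altitude-bin contingency tables.

    Bins are right-open [a, a + bin_m) spanning the configured bounds (the
    last bin absorbs the upper boundary).  A flock counts for every species
    present in it.  Bins empty in every year are dropped; totals are
    conserved."""
    if bin_m <= 0:
        raise ValueError("bin_m must be positive")
    df = flocks if isinstance(flocks, pd.DataFrame) else flocks_frame(flocks)
    lo, hi = bounds_m
    edges = np.arange(lo, hi + bin_m, bin_m)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_m)
    out: dict[str, pd.DataFrame] = {}
    for species in ("red_billed", "yellow_billed"):
        sub = df[df["species_present"].apply(lambda t: species in t)]
        if sub.empty:
            logger.warning("no flocks for %s; altitude table skipped", species)
            continue
        rows = {}
        for year in sorted(sub["year"].unique()):
            alts = sub[sub["year"] == year]["altitude_m"].to_numpy(dtype=float)
            counts, _ = np.histogram(np.clip(alts, lo, np.nextafter(hi, lo)), bins=edges)
            rows[int(year)] = counts
        table = pd.DataFrame(
            rows, index=[f"[{int(edges[i])},{int(edges[i + 1])})" for i in range(len(edges) - 1)]
        ).T
        table = table.loc[:, table.sum(axis=0) > 0]  # drop bins empty in all years
        out[species] = table
    return out


@dataclass
class ChisqMCResult:
    statistic: float
    p_value: float
    reps: int

    def to_dict(self) -> dict:
        return {"chisq": self.statistic, "p": self.p_value, "reps": self.reps}


def chisq_mc_pvalue(table, reps: int = 10_000, seed: int = 0) -> ChisqMCResult:
    """Pearson chi-square with a Monte-Carlo p-value under fixed margins.

    Null tables are drawn by the sequential construction: each row in turn is
    a multivariate-hypergeometric draw of its row total from the remaining
    column totals.  p = (1 + #{chi2_rep >= chi2_obs}) / (reps + 1).
    """
    obs = np.asarray(table, dtype=np.int64)
    if obs.ndim != 2:
        raise ValueError("table must be 2-D")
    row_tot = obs.sum(axis=1)
    col_tot = obs.sum(axis=0)
    if np.any(row_tot == 0) or np.any(col_tot == 0):
        raise ValueError("all row and column margins must be positive")
    total = obs.sum()
    expected = np.outer(row_tot, col_tot) / total
    chi2_obs = float(np.sum((obs - expected) ** 2 / expected))

    rng = np.random.default_rng(seed)
    r = obs.shape[0]
    exceed = 0
    for _ in range(reps):
        remaining = col_tot.copy()
        chi2 = 0.0
        for i in range(r - 1):
            draw = rng.multivariate_hypergeometric(remaining, int(row_tot[i]))
            chi2 += float(np.sum((draw - expected[i]) ** 2 / expected[i]))
            remaining = remaining - draw
        chi2 += float(np.sum((remaining - expected[r - 1]) ** 2 / expected[r - 1]))
        if chi2 >= chi2_obs - 1e-9:
            exceed += 1
    p = (1.0 + exceed) / (reps + 1.0)
    return ChisqMCResult(statistic=chi2_obs, p_value=float(p), reps=reps)


def altitude_analysis(
    flocks: list[FlockRecord] | pd.DataFrame,
    bin_m: float = 100.0,
    bounds_m: tuple[float, float] = (2200.0, 2800.0),
    reps: int = 10_000,
    seed: int = 0,
) -> dict:
    """Per-species Monte-Carlo chi-square comparison of yearly altitude
    distributions, plus the underlying contingency tables."""
    tables = altitude_contingency(flocks, bin_m=bin_m, bounds_m=bounds_m)
    out = {}
    for i, (species, table) in enumerate(sorted(tables.items())):
        entry = {
            "table": {
                "years": [int(y) for y in table.index],
                "bins": list(table.columns),
                "counts": table.to_numpy().tolist(),
            }
        }
        if table.shape[0] < 2 or table.shape[1] < 2:
            entry["test"] = None
            entry["skipped"] = "needs at least two years and two occupied bins"
        else:
            res = chisq_mc_pvalue(table.to_numpy(), reps=reps, seed=(seed + i) % (2**31 - 1))
            entry["test"] = res.to_dict()
        out[species] = entry
    return out
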