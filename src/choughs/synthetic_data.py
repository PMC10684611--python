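"""Synthetic study generator.

No field data are deposited for this study, so the pipeline ships a generator
that emulates its statistical structure: two chough species foraging in an
alpine basin over two summers, with

* flock sizes from an overdispersed (negative-binomial) count distribution,
  truncated at 1 bird (2 for mixed flocks), with stratum means set by the
  calibration;
* mixed-species flocks occurring with a fixed per-event probability;
* log-normal stay times with a shared per-date random effect and a (log)
  flock-size slope, calibrated so the *arithmetic* stratum mean matches the
  target (the log-normal mean correction exp(mu + s^2/2) is applied, plus an
  empirical correction for the realised flock-size spread);
* daily temperature as month-by-year means plus a stationary AR(2) error;
* daily precipitation as a hurdle process: zero with a month-by-year
  probability, otherwise gamma-distributed.

Every generator takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .core_io import (
    ClimateDay,
    ConfigurationError,
    FlockRecord,
    ForagingObservation,
    StudyConfig,
    derive_seed,
)

__all__ = [
    "CalibrationConfig",
    "default_calibration",
    "generate_study_days",
    "generate_flocks",
    "generate_stay_times",
    "generate_climate",
    "generate_bundle",
]


@dataclass
class CalibrationConfig:
    """Generator parameters: stratum means and noise levels.

    ``stay_mean_s[species][year][flock_type]`` are arithmetic means in
    seconds; ``flock_mean[species][year]`` are mean flock sizes in birds.
    """

    stay_mean_s: dict
    stay_log_sd: float
    stay_flock_slope: float
    day_intercept_sd: float
    obs_per_stratum: int
    flock_mean: dict
    flock_dispersion: float
    mixed_flock_prob: float
    flocks_per_stratum: int
    spatial_centres: dict
    altitude_range_m: dict
    temp_month_mean_c: dict
    temp_ar: tuple[float, float]
    temp_innov_sd: float
    precip_zero_prob: dict
    precip_gamma_shape: float
    precip_gamma_mean_mm: dict

    def __post_init__(self) -> None:
        phi1, phi2 = self.temp_ar
        if not _ar2_stationary(phi1, phi2):
            raise ConfigurationError(f"AR(2) coefficients {self.temp_ar} are non-stationary")
        if not (0.0 <= self.mixed_flock_prob <= 1.0):
            raise ConfigurationError("mixed_flock_prob must lie in [0, 1]")
        if self.flock_dispersion <= 0 or self.stay_log_sd < 0 or self.day_intercept_sd < 0:
            raise ConfigurationError("dispersion must be > 0 and SDs >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        raw["temp_ar"] = tuple(raw["temp_ar"])
        return cls(**raw)

    def stay_mean(self, species: str, year: int, flock_type: str) -> float:
        try:
            return float(self.stay_mean_s[species][year][flock_type])
        except KeyError:
            raise ConfigurationError(
                f"calibration missing stay mean for ({species}, {year}, {flock_type})"
            ) from None

    def flock_mean_for(self, species: str, year: int) -> float:
        try:
            return float(self.flock_mean[species][year])
        except KeyError:
            raise ConfigurationError(
                f"calibration missing flock mean for ({species}, {year})"
            ) from None


def _ar2_stationary(phi1: float, phi2: float) -> bool:
    return (abs(phi2) < 1.0) and (phi1 + phi2 < 1.0) and (phi2 - phi1 < 1.0)


def default_calibration() -> CalibrationConfig:
    """The packaged calibration encoding the study's printed group means."""
    with resources.files("choughs.data").joinpath("calibration.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    raw["temp_ar"] = tuple(raw["temp_ar"])
    return CalibrationConfig(**raw)


def generate_study_days(study: StudyConfig, seed: int) -> list[_dt.date]:
    """Draw the observation calendar: for each study month, 9-12 (configurable)
    distinct days, uniformly placed."""
    rng = np.random.default_rng(seed)
    lo, hi = study.days_per_month_range
    days: list[_dt.date] = []
    for year in study.years:
        for month in study.months:
            n_days = int(rng.integers(lo, hi + 1))
            month_len = (_dt.date(year + month // 12, month % 12 + 1, 1) - _dt.date(year, month, 1)).days
            chosen = rng.choice(month_len, size=min(n_days, month_len), replace=False)
            days.extend(_dt.date(year, month, int(d) + 1) for d in np.sort(chosen))
    return days


def _truncated_negbin(rng: np.random.Generator, mean: float, dispersion: float,
                      size: int, minimum: int) -> np.ndarray:
    """Zero-truncated negative binomial with *truncated* mean ``mean``.

    The underlying NB mean mu is solved so that mu / (1 - P(X=0)) equals the
    target, then draws below ``minimum`` (1 for monospecific contingents) are
    resampled.  Without the adjustment the truncation would bias small-flock
    strata upward."""
    from scipy import optimize as _opt

    k = dispersion

    def truncated_mean(mu):
        p0 = (k / (k + mu)) ** k
        return mu / (1.0 - p0)

    if minimum <= 0 or truncated_mean(1e-9) >= mean:
        mu = mean
    else:
        mu = _opt.brentq(lambda m: truncated_mean(m) - mean, 1e-9, mean)
    p = k / (k + mu)
    out = rng.negative_binomial(k, p, size=size)
    while np.any(out < minimum):
        bad = out < minimum
        out[bad] = rng.negative_binomial(k, p, size=int(bad.sum()))
    return out


def generate_flocks(study: StudyConfig, calib: CalibrationConfig, seed: int) -> list[FlockRecord]:
    """Generate flock sightings for every (species, year) stratum.

    Each stratum contributes ``flocks_per_stratum`` events; an event is mixed
    with probability ``mixed_flock_prob``, in which case a red-billed and a
    yellow-billed contingent (each drawn from its own size distribution) share
    one flock.  Coordinates are Gaussian around the stratum centre; altitudes
    are uniform within the stratum's range, clipped to the study bounds.
    """
    days = generate_study_days(study, derive_seed(seed, "study_days"))
    lo_b, hi_b = study.altitude_bounds_m
    records: list[FlockRecord] = []
    counter = 0
    for year in study.years:
        year_days = [d for d in days if d.year == year]
        for species in ("red_billed", "yellow_billed"):
            # one stream per stratum: perturbing one stratum's calibration
            # leaves every other stratum's output bit-identical; the partner
            # contingent of a mixed event draws from its own stream so the
            # other species' calibration cannot desynchronize this one
            rng = np.random.default_rng(derive_seed(seed, f"flocks/{species}/{year}"))
            rng_partner = np.random.default_rng(
                derive_seed(seed, f"flocks/{species}/{year}/partner")
            )
            centre = calib.spatial_centres[species]
            alt_lo, alt_hi = calib.altitude_range_m[species][year]
            alt_lo, alt_hi = max(alt_lo, lo_b), min(alt_hi, hi_b)
            n = calib.flocks_per_stratum
            mixed_flags = rng.random(n) < calib.mixed_flock_prob
            sizes_own = _truncated_negbin(
                rng, calib.flock_mean_for(species, year), calib.flock_dispersion, n, 1
            )
            dates = rng.choice(len(year_days), size=n)
            for i in range(n):
                counter += 1
                fid = f"F{counter:05d}"
                date = year_days[int(dates[i])]
                if mixed_flags[i]:
                    other = "yellow_billed" if species == "red_billed" else "red_billed"
                    size_other = int(
                        _truncated_negbin(
                            rng_partner, calib.flock_mean_for(other, year),
                            calib.flock_dispersion, 1, 1,
                        )[0]
                    )
                    size = int(sizes_own[i]) + size_other
                    cm = calib.spatial_centres["mixed"]
                    x = rng.normal(cm["x_m"], cm["spread_m"])
                    y = rng.normal(cm["y_m"], cm["spread_m"])
                    o_lo, o_hi = calib.altitude_range_m[other][year]
                    a_lo = max(alt_lo, max(o_lo, lo_b))
                    a_hi = min(alt_hi, min(o_hi, hi_b))
                    if a_hi <= a_lo:  # disjoint ranges: fall back to own range
                        a_lo, a_hi = alt_lo, alt_hi
                    alt = rng.uniform(a_lo, a_hi)
                    present: tuple[str, ...] = ("yellow_billed", "red_billed")
                else:
                    size = int(sizes_own[i])
                    x = rng.normal(centre["x_m"], centre["spread_m"])
                    y = rng.normal(centre["y_m"], centre["spread_m"])
                    alt = rng.uniform(alt_lo, alt_hi)
                    present = (species,)
                records.append(
                    FlockRecord(
                        flock_id=fid, date=date, species_present=present,
                        size=size, x_m=float(x), y_m=float(y), altitude_m=float(alt),
                    )
                )
    return records


def generate_stay_times(
    flocks: list[FlockRecord], calib: CalibrationConfig, seed: int
) -> list[ForagingObservation]:
    """Sample focal-individual stay times from the generated flocks.

    For a focal bird of species *s* in a flock of size *n* on date *d*:

        log T = a_stratum + slope * (log n - mean log n) + u_d + e,
        u_d ~ N(0, day_sd^2),  e ~ N(0, log_sd^2)

    The stratum intercept ``a`` is set so the arithmetic mean of T over the
    stratum's realised flock sizes equals the calibrated ``stay_mean_s``:
    a = log(target) - log mean[exp(slope * centred log n)] - (day_sd^2 + log_sd^2)/2.
    """
    if not flocks:
        raise ValueError("flocks must be nonempty")
    day_rng = np.random.default_rng(derive_seed(seed, "day_effects"))
    dates = sorted({f.date for f in flocks})
    day_effect = dict(zip(dates, day_rng.normal(0.0, calib.day_intercept_sd, len(dates))))

    observations: list[ForagingObservation] = []
    strata: dict[tuple[str, int, str], list[FlockRecord]] = {}
    for f in flocks:
        ftype = "mixed" if len(f.species_present) == 2 else "monospecific"
        for sp in f.species_present:
            strata.setdefault((sp, f.date.year, ftype), []).append(f)

    var_noise = calib.day_intercept_sd**2 + calib.stay_log_sd**2
    for (species, year, ftype), members in sorted(strata.items()):
        rng = np.random.default_rng(derive_seed(seed, f"stay/{species}/{year}/{ftype}"))
        target = calib.stay_mean(species, year, ftype)
        n_obs = calib.obs_per_stratum
        idx = rng.choice(len(members), size=n_obs)
        logsize = np.array([np.log(members[i].size) for i in idx])
        centred = logsize - logsize.mean()
        slope_term = calib.stay_flock_slope * centred
        # empirical correction: E[T] = exp(a) * mean(exp(slope_term)) * exp(var/2)
        a = np.log(target) - np.log(np.mean(np.exp(slope_term))) - var_noise / 2.0
        resid = rng.normal(0.0, calib.stay_log_sd, n_obs)
        for j, i in enumerate(idx):
            fl = members[int(i)]
            log_t = a + slope_term[j] + day_effect[fl.date] + resid[j]
            observations.append(
                ForagingObservation(
                    date=fl.date, species=species, flock_type=ftype,
                    flock_size=fl.size, stay_time_s=float(np.exp(log_t)),
                    flock_id=fl.flock_id,
                )
            )
    return observations


def generate_climate(study: StudyConfig, calib: CalibrationConfig, seed: int) -> list[ClimateDay]:
    """Daily climate for January-September of both study years.

    Temperature is the month-by-year mean plus a stationary AR(2) error
    (restarted each year, initialised from the stationary distribution);
    precipitation is zero with a month-by-year probability, else gamma.
    """
    phi1, phi2 = calib.temp_ar
    if not _ar2_stationary(phi1, phi2):
        raise ConfigurationError(f"AR(2) coefficients {calib.temp_ar} are non-stationary")
    rng = np.random.default_rng(seed)
    sd = calib.temp_innov_sd
    # stationary variance of AR(2): gamma0 = sd^2 (1-phi2) / ((1+phi2)((1-phi2)^2 - phi1^2))
    if sd > 0:
        gamma0 = sd**2 * (1 - phi2) / ((1 + phi2) * ((1 - phi2) ** 2 - phi1**2))
        rho1 = phi1 / (1 - phi2)
    else:
        gamma0, rho1 = 0.0, 0.0
    out: list[ClimateDay] = []
    for year in study.years:
        start = _dt.date(year, 1, 1)
        end = _dt.date(year, 9, 30)
        n = (end - start).days + 1
        e = np.zeros(n)
        if sd > 0:
            # exact stationary start for (e0, e1)
            cov = gamma0 * np.array([[1.0, rho1], [rho1, 1.0]])
            e[:2] = rng.multivariate_normal([0.0, 0.0], cov)
            innov = rng.normal(0.0, sd, n)
            for t in range(2, n):
                e[t] = phi1 * e[t - 1] + phi2 * e[t - 2] + innov[t]
        for i in range(n):
            date = start + _dt.timedelta(days=i)
            month = date.month
            temp = calib.temp_month_mean_c[year][month] + e[i]
            if rng.random() < calib.precip_zero_prob[year][month]:
                precip = 0.0
            else:
                shape = calib.precip_gamma_shape
                scale = calib.precip_gamma_mean_mm[year][month] / shape
                precip = float(rng.gamma(shape, scale))
            out.append(ClimateDay(date=date, temperature_c=float(temp), precipitation_mm=precip))
    return out


def generate_bundle(study: StudyConfig, calib: CalibrationConfig, seed: int):
    """Generate the full dataset bundle (flocks, observations, climate) from a
    single master seed, with per-stage derived seeds."""
    flocks = generate_flocks(study, calib, derive_seed(seed, "flocks"))
    obs = generate_stay_times(flocks, calib, derive_seed(seed, "stay_times"))
    climate = generate_climate(study, calib, derive_seed(seed, "climate"))
    return flocks, obs, climate
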