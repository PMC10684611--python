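"""Domain types, CSV readers/writers with validation, configuration, reporting.

The pipeline works on three tabular inputs:

* ``observations.csv`` — focal-individual foraging stay times with flock context,
* ``flocks.csv``       — flock sightings (composition, size, position, altitude),
* ``climate.csv``      — daily mean temperature and precipitation.

All files are comma-separated UTF-8 with a mandatory header, ISO-8601 dates
(``YYYY-MM-DD``) and ``.`` as the decimal mark.  Coordinates are planar metres
(easting/northing); no geodesy is performed.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

SPECIES = ("red_billed", "yellow_billed")
MIXED_LABEL = "yellow_billed+red_billed"
FLOCK_TYPES = ("monospecific", "mixed")

OBSERVATION_COLUMNS = ["date", "species", "flock_type", "flock_size", "stay_time_s", "flock_id"]
FLOCK_COLUMNS = ["flock_id", "date", "species_present", "size", "x_m", "y_m", "altitude_m"]
CLIMATE_COLUMNS = ["date", "temperature_c", "precipitation_mm"]


class SchemaError(ValueError):
    """A file is missing required columns."""


class ValidationError(ValueError):
    """A row violates a domain invariant; the message names the row."""


class ConfigurationError(ValueError):
    """A configuration value is missing or out of its legal range."""


@dataclass(frozen=True)
class ForagingObservation:
    """One focal-individual stay-time record: the seconds a bird spent
    foraging on a patch from landing to take-off, with its flock context."""

    date: _dt.date
    species: str
    flock_type: str
    flock_size: int
    stay_time_s: float
    flock_id: str


@dataclass(frozen=True)
class FlockRecord:
    """One flock sighting: composition, size, planar position and altitude."""

    flock_id: str
    date: _dt.date
    species_present: tuple[str, ...]
    size: int
    x_m: float
    y_m: float
    altitude_m: float


@dataclass(frozen=True)
class ClimateDay:
    """One day of weather: mean temperature (degC) and precipitation
    (mm water equivalent, rainfall + snowfall)."""

    date: _dt.date
    temperature_c: float
    precipitation_mm: float


@dataclass
class StudyConfig:
    """Study-design constants shared by the generator and the analyses.

    Defaults encode the study design: two years, June-September field months
    with 9-12 observation days each, a 2200-2800 m a.s.l. foraging band,
    10,000-replicate Monte-Carlo procedures, a Spearman |rho| >= 0.7
    collinearity screen, and the "more than 10 occurrences" reporting filter
    for the mixed-flocking null model.
    """

    years: tuple[int, int] = (2021, 2022)
    months: tuple[int, ...] = (6, 7, 8, 9)
    days_per_month_range: tuple[int, int] = (9, 12)
    altitude_bounds_m: tuple[float, float] = (2200.0, 2800.0)
    rng_seed: int = 0
    reps_mixed_null: int = 10_000
    reps_chisq: int = 10_000
    correlation_threshold: float = 0.7
    min_flock_size_occurrence: int = 10
    min_occurrence_strict: bool = True
    kde_mass_quantile: float = 0.95
    kde_cell_size_m: float = 25.0
    altitude_bin_m: float = 100.0
    log_flock_size: bool = False
    log_flock_size_in_size_models: bool = False

    def __post_init__(self) -> None:
        if self.reps_mixed_null < 1 or self.reps_chisq < 1:
            raise ConfigurationError("replicate counts must be >= 1")
        if not (0.0 < self.kde_mass_quantile < 1.0):
            raise ConfigurationError("kde_mass_quantile must lie in (0, 1)")
        if not (0.0 < self.correlation_threshold <= 1.0):
            raise ConfigurationError("correlation_threshold must lie in (0, 1]")
        if self.altitude_bin_m <= 0:
            raise ConfigurationError("altitude_bin_m must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("years", "months", "days_per_month_range", "altitude_bounds_m"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d


def derive_seed(master_seed: int, operation: str) -> int:
    """Deterministic per-operation seed below 2**31, derived from the master
    seed and the operation name so independent stages draw independent streams."""
    ss = np.random.SeedSequence([master_seed, *operation.encode()])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: str | Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _parse_date(value: object, row: int, path: str | Path) -> _dt.date:
    try:
        return _dt.date.fromisoformat(str(value))
    except ValueError as exc:
        raise ValidationError(f"{path} row {row}: bad date {value!r} ({exc})") from None


def read_observations(path: str | Path) -> list[ForagingObservation]:
    """Read and validate ``observations.csv``.

    The whole file is rejected on the first invalid row; the error names the
    row (1-based, counting the header as row 1) and the reason.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, OBSERVATION_COLUMNS, path)
    out: list[ForagingObservation] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2
        species = rec.species
        if species not in SPECIES:
            raise ValidationError(f"{path} row {row}: unknown species label {species!r}")
        flock_type = rec.flock_type
        if flock_type not in FLOCK_TYPES:
            raise ValidationError(f"{path} row {row}: unknown flock_type {flock_type!r}")
        try:
            flock_size = int(rec.flock_size)
            stay = float(rec.stay_time_s)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {row}: non-numeric flock_size or stay_time_s") from None
        if stay <= 0:
            raise ValidationError(f"{path} row {row}: stay_time_s must be > 0, got {stay}")
        if flock_size < 1:
            raise ValidationError(f"{path} row {row}: flock_size must be >= 1, got {flock_size}")
        if flock_type == "mixed" and flock_size < 2:
            raise ValidationError(f"{path} row {row}: mixed flock needs flock_size >= 2")
        out.append(
            ForagingObservation(
                date=_parse_date(rec.date, row, path),
                species=species,
                flock_type=flock_type,
                flock_size=flock_size,
                stay_time_s=stay,
                flock_id=str(rec.flock_id),
            )
        )
    return out


def write_observations(records: Iterable[ForagingObservation], path: str | Path) -> None:
    rows = [
        {
            "date": r.date.isoformat(),
            "species": r.species,
            "flock_type": r.flock_type,
            "flock_size": r.flock_size,
            "stay_time_s": repr(r.stay_time_s),
            "flock_id": r.flock_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=OBSERVATION_COLUMNS).to_csv(path, index=False)


def read_flocks(path: str | Path) -> list[FlockRecord]:
    """Read and validate ``flocks.csv``.

    ``species_present`` is one of ``red_billed``, ``yellow_billed`` or
    ``yellow_billed+red_billed`` (a mixed flock).
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, FLOCK_COLUMNS, path)
    out: list[FlockRecord] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2
        label = rec.species_present
        if label == MIXED_LABEL or label == "red_billed+yellow_billed":
            present: tuple[str, ...] = ("yellow_billed", "red_billed")
        elif label in SPECIES:
            present = (label,)
        else:
            raise ValidationError(f"{path} row {row}: unknown species_present {label!r}")
        try:
            size = int(rec.size)
            x = float(rec.x_m)
            y = float(rec.y_m)
            alt = float(rec.altitude_m)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {row}: non-numeric size or coordinates") from None
        if size < len(present):
            raise ValidationError(
                f"{path} row {row}: size {size} smaller than number of species present"
            )
        out.append(
            FlockRecord(
                flock_id=str(rec.flock_id),
                date=_parse_date(rec.date, row, path),
                species_present=present,
                size=size,
                x_m=x,
                y_m=y,
                altitude_m=alt,
            )
        )
    return out


def write_flocks(records: Iterable[FlockRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        label = MIXED_LABEL if len(r.species_present) == 2 else r.species_present[0]
        rows.append(
            {
                "flock_id": r.flock_id,
                "date": r.date.isoformat(),
                "species_present": label,
                "size": r.size,
                "x_m": repr(r.x_m),
                "y_m": repr(r.y_m),
                "altitude_m": repr(r.altitude_m),
            }
        )
    pd.DataFrame(rows, columns=FLOCK_COLUMNS).to_csv(path, index=False)


def read_climate(path: str | Path) -> list[ClimateDay]:
    """Read and validate ``climate.csv``; records are returned sorted by date."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, CLIMATE_COLUMNS, path)
    out: list[ClimateDay] = []
    seen: dict[_dt.date, int] = {}
    for i, rec in enumerate(df.itertuples(index=False)):
        row = i + 2
        date = _parse_date(rec.date, row, path)
        if date in seen:
            raise ValidationError(
                f"{path} row {row}: duplicate date {date} (first at row {seen[date]})"
            )
        seen[date] = row
        try:
            temp = float(rec.temperature_c)
            precip = float(rec.precipitation_mm)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {row}: non-numeric temperature or precipitation") from None
        if precip < 0:
            raise ValidationError(f"{path} row {row}: precipitation_mm must be >= 0, got {precip}")
        out.append(ClimateDay(date=date, temperature_c=temp, precipitation_mm=precip))
    return sorted(out, key=lambda r: r.date)


def write_climate(records: Iterable[ClimateDay], path: str | Path) -> None:
    rows = [
        {
            "date": r.date.isoformat(),
            "temperature_c": repr(r.temperature_c),
            "precipitation_mm": repr(r.precipitation_mm),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=CLIMATE_COLUMNS).to_csv(path, index=False)


def observations_frame(records: Sequence[ForagingObservation]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=OBSERVATION_COLUMNS)
    df["year"] = [r.date.year for r in records]
    return df


def flocks_frame(records: Sequence[FlockRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        d["mixed"] = len(r.species_present) == 2
        d["year"] = r.date.year
        rows.append(d)
    return pd.DataFrame(rows)


def climate_frame(records: Sequence[ClimateDay]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df["year"] = [r.date.year for r in records]
    df["month"] = [r.date.month for r in records]
    return df


class _ReportEncoder(json.JSONEncoder):
    def default(self, o):  # noqa: D102
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (_dt.date, _dt.datetime)):
            return o.isoformat()
        return super().default(o)


def write_report(report: dict, path: str | Path) -> None:
    """Write the pipeline report as deterministic, human-diffable JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True, cls=_ReportEncoder) + "\n")
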