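"""Internal data model.

All spatial coordinates are WGS84 longitude/latitude in that order
(GeoSPARQL CRS84 convention). All dates are calendar dates — the linkage
operates at daily resolution and sub-daily inputs are rejected at read
time rather than resampled. Missing environmental values are represented
by one internal flag (NaN) everywhere, never dropped, so that coverage
accounting downstream sees them.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .errors import GeometryError, GridError, NestingError, ValidationError

#: Tolerance on grid-axis spacing regularity, in degrees.
GRID_SPACING_TOL = 1e-9

OBS_COLUMNS = ["source_id", "date", "variable", "value"]


@dataclass(frozen=True)
class Variable:
    """An environmental variable with its unit and a human definition."""

    name: str
    unit: str = ""
    definition: str = ""


@dataclass(frozen=True)
class Station:
    station_id: str
    lon: float
    lat: float


def _check_axis(name: str, axis: np.ndarray) -> None:
    if axis.ndim != 1 or axis.size < 1:
        raise GridError(f"{name} axis must be a non-empty 1-D array")
    if axis.size > 1:
        steps = np.diff(axis)
        if np.any(steps <= 0):
            raise GridError(f"{name} axis must be strictly increasing")
        if np.ptp(steps) > GRID_SPACING_TOL:
            raise GridError(
                f"{name} axis spacing irregular: varies by {np.ptp(steps):g} degrees"
            )


@dataclass
class EnvDatasetGrid:
    """Gridded daily environmental variables on a regular lon/lat lattice.

    ``values`` has shape (n_variables, n_times, n_lats, n_lons); NaN marks
    a missing value. Axis values are cell *origins*: cell (i, j) is the
    half-open rectangle [lon_j, lon_j + dlon) x [lat_i, lat_i + dlat), so
    any point maps to exactly one cell.
    """

    dataset_id: str
    variables: list[Variable]
    lon_axis: np.ndarray
    lat_axis: np.ndarray
    time_axis: list[dt.date]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lon_axis = np.asarray(self.lon_axis, dtype=float)
        self.lat_axis = np.asarray(self.lat_axis, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        _check_axis("lon", self.lon_axis)
        _check_axis("lat", self.lat_axis)
        if len(self.time_axis) != len(set(self.time_axis)):
            raise GridError("duplicate dates on the time axis")
        if any(
            b <= a for a, b in zip(self.time_axis, self.time_axis[1:])
        ):
            raise GridError("time axis must be strictly increasing")
        expected = (
            len(self.variables),
            len(self.time_axis),
            self.lat_axis.size,
            self.lon_axis.size,
        )
        if self.values.shape != expected:
            raise GridError(
                f"values shape {self.values.shape} != (var, time, lat, lon) {expected}"
            )
        if np.isinf(self.values).any():
            raise GridError("non-missing values must be finite")

    @property
    def dlon(self) -> float:
        return float(self.lon_axis[1] - self.lon_axis[0]) if self.lon_axis.size > 1 else 1.0

    @property
    def dlat(self) -> float:
        return float(self.lat_axis[1] - self.lat_axis[0]) if self.lat_axis.size > 1 else 1.0

    def cell_id(self, ilat: int, ilon: int) -> str:
        return f"cell-{ilat:03d}-{ilon:03d}"

    def cell_index(self, cell_id: str) -> tuple[int, int]:
        _, ilat, ilon = cell_id.split("-")
        return int(ilat), int(ilon)

    def cell_containing(self, lon: float, lat: float) -> str | None:
        """Id of the half-open cell containing a point, or None if outside."""
        ilon = math.floor((lon - self.lon_axis[0]) / self.dlon)
        ilat = math.floor((lat - self.lat_axis[0]) / self.dlat)
        if 0 <= ilon < self.lon_axis.size and 0 <= ilat < self.lat_axis.size:
            return self.cell_id(ilat, ilon)
        return None

    def cell_origin(self, cell_id: str) -> tuple[float, float]:
        ilat, ilon = self.cell_index(cell_id)
        return float(self.lon_axis[ilon]), float(self.lat_axis[ilat])

    def obs_table(self) -> pd.DataFrame:
        """Long-form observation table (source_id, date, variable, value).

        Missing (NaN) values are omitted from the table; they remain in
        ``values`` and are counted by coverage logic via the time axis.
        """
        rows: list[tuple[str, dt.date, str, float]] = []
        for vi, var in enumerate(self.variables):
            for ti, date in enumerate(self.time_axis):
                plane = self.values[vi, ti]
                for ilat in range(self.lat_axis.size):
                    for ilon in range(self.lon_axis.size):
                        v = plane[ilat, ilon]
                        if not np.isnan(v):
                            rows.append(
                                (self.cell_id(ilat, ilon), date, var.name, float(v))
                            )
        return pd.DataFrame(rows, columns=OBS_COLUMNS)

    @property
    def date_range(self) -> tuple[dt.date, dt.date]:
        return self.time_axis[0], self.time_axis[-1]


@dataclass
class EnvDatasetStations:
    """Point-station daily observations (single-location time series).

    ``observations`` is a long-form DataFrame with columns
    (station_id, date, variable, value); value NaN marks a reported
    missing observation.
    """

    dataset_id: str
    stations: list[Station]
    observations: pd.DataFrame
    variables: list[Variable]

    def __post_init__(self) -> None:
        ids = [s.station_id for s in self.stations]
        if len(ids) != len(set(ids)):
            raise ValidationError("station_id values must be unique")
        obs = self.observations
        missing_cols = {"station_id", "date", "variable", "value"} - set(obs.columns)
        if missing_cols:
            raise ValidationError(f"observations missing columns {sorted(missing_cols)}")
        unknown = set(obs["station_id"]) - set(ids)
        if unknown:
            raise ValidationError(f"observations reference unknown stations {sorted(unknown)}")
        if obs.duplicated(["station_id", "date", "variable"]).any():
            raise ValidationError("(station_id, date, variable) must be unique")
        if not all(isinstance(d, dt.date) and not isinstance(d, dt.datetime) for d in obs["date"]):
            raise ValidationError("observation dates must be calendar dates")
        finite = obs["value"].astype(float)
        if np.isinf(finite).any():
            raise ValidationError("non-missing values must be finite")

    def station(self, station_id: str) -> Station:
        for s in self.stations:
            if s.station_id == station_id:
                return s
        raise KeyError(station_id)

    def obs_table(self) -> pd.DataFrame:
        obs = self.observations.dropna(subset=["value"])
        out = obs.rename(columns={"station_id": "source_id"})[OBS_COLUMNS]
        return out.reset_index(drop=True)

    @property
    def date_range(self) -> tuple[dt.date, dt.date]:
        dates = self.observations["date"]
        return min(dates), max(dates)


EnvDataset = EnvDatasetGrid | EnvDatasetStations


@dataclass
class AdminArea:
    """An administrative area polygon, optionally nested under a parent."""

    area_id: str
    label: str
    geometry: BaseGeometry
    parent_area_id: str | None = None

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise GeometryError(f"area {self.area_id!r}: invalid (self-intersecting?) geometry")
        if self.geometry.area <= 0:
            raise GeometryError(f"area {self.area_id!r}: zero-area geometry")


def check_area_forest(areas: list[AdminArea]) -> None:
    """Raise NestingError unless parent links form a forest (no cycles)."""
    parent = {a.area_id: a.parent_area_id for a in areas}
    for start in parent:
        seen = {start}
        cur = parent.get(start)
        while cur is not None:
            if cur in seen:
                raise NestingError(f"cyclic parent chain through area {cur!r}")
            seen.add(cur)
            cur = parent.get(cur)


@dataclass(frozen=True)
class HealthEvent:
    """A pseudonymous health event located by a point or an area code."""

    event_id: str
    event_date: dt.date
    point: tuple[float, float] | None = None  # (lon, lat)
    area_id: str | None = None

    def __post_init__(self) -> None:
        if (self.point is None) == (self.area_id is None):
            raise ValidationError(
                f"event {self.event_id!r}: exactly one of point or area_id required"
            )


SPATIAL_METHODS = ("area_contains", "nearest_station", "proximity_polygon", "buffer")
AGG_FUNCTIONS = ("mean", "min", "max", "sum", "count", "sd")
AGG_LEVELS = ("window", "daily")


@dataclass
class LinkageSpec:
    """How events are linked: spatial method + lag/window + aggregation.

    The exposure window covers ``window_days`` dates ending ``lag_days``
    before the event; the event day itself is always excluded.
    """

    spatial_method: str = "nearest_station"
    buffer_km: float | None = None
    lag_days: int = 0
    window_days: int = 7
    agg_functions: tuple[str, ...] = ("mean",)
    agg_level: str = "window"
    min_coverage: float = 0.0
    exclude_low_coverage: bool = False

    def __post_init__(self) -> None:
        if self.spatial_method not in SPATIAL_METHODS:
            raise ValidationError(
                f"spatial_method {self.spatial_method!r} not in {SPATIAL_METHODS}"
            )
        if (self.spatial_method == "buffer") != (self.buffer_km is not None):
            raise ValidationError("buffer_km must be given iff spatial_method='buffer'")
        if self.buffer_km is not None and self.buffer_km <= 0:
            raise ValidationError("buffer_km must be > 0")
        if self.lag_days < 0 or self.window_days < 1:
            raise ValidationError("need lag_days >= 0 and window_days >= 1")
        self.agg_functions = tuple(self.agg_functions)
        if not self.agg_functions:
            raise ValidationError("agg_functions must be non-empty")
        bad = set(self.agg_functions) - set(AGG_FUNCTIONS)
        if bad:
            raise ValidationError(f"unknown agg functions {sorted(bad)}")
        if self.agg_level not in AGG_LEVELS:
            raise ValidationError(f"agg_level {self.agg_level!r} not in {AGG_LEVELS}")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ValidationError("min_coverage must be in [0, 1]")


@dataclass(frozen=True)
class Source:
    """One environmental source feeding an event's exposure."""

    source_kind: str  # station | grid_cell | area
    source_id: str
    distance_km: float | None = None

    def __post_init__(self) -> None:
        if self.distance_km is not None and self.distance_km < 0:
            raise ValidationError("distance_km must be >= 0")


@dataclass
class SpatialContext:
    """The sources selected for one event x dataset pair."""

    event_id: str
    dataset_id: str
    sources: list[Source]

    @property
    def source_ids(self) -> list[str]:
        return [s.source_id for s in self.sources]


@dataclass(frozen=True)
class ExposureWindow:
    """Half-open span of dates [start_date, end_date_exclusive) before an event."""

    event_id: str
    start_date: dt.date
    end_date_exclusive: dt.date

    @property
    def window_days(self) -> int:
        return (self.end_date_exclusive - self.start_date).days

    def dates(self) -> list[dt.date]:
        return [
            self.start_date + dt.timedelta(days=i) for i in range(self.window_days)
        ]

    def __contains__(self, date: dt.date) -> bool:
        return self.start_date <= date < self.end_date_exclusive


@dataclass
class ExposureRecord:
    """One aggregated exposure value per event x dataset x variable x function."""

    event_id: str
    dataset_id: str
    variable: str
    window_start: dt.date
    window_end_exclusive: dt.date
    agg_function: str
    value: float  # NaN when coverage == 0
    coverage: float
    n_sources: int
    source_ids: list[str] = field(default_factory=list)
    flagged: bool = False


@dataclass
class Agent:
    name: str
    role: str  # researcher | software | entity


@dataclass
class Activity:
    """A provenance activity: which inputs were used, what was generated."""

    started: dt.datetime
    ended: dt.datetime
    used: list[str]
    generated: str


@dataclass
class MetadataBundle:
    """Dataset descriptors for the FAIR metadata graph (catalog + provenance)."""

    title: str
    licence: str | None
    version: str
    temporal_extent: tuple[dt.date, dt.date]
    spatial_extent: tuple[float, float, float, float] | str  # bbox or area ref
    distribution_url: str
    agents: list[Agent]
    activity: Activity

    def __post_init__(self) -> None:
        start, end = self.temporal_extent
        if start > end:
            raise ValidationError("temporal_extent start must be <= end")
        if self.activity.generated and not self.activity.used:
            raise ValidationError("a derived dataset's activity must use >= 1 input")
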