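"""Seeded synthetic fixtures emulating the study's dataset shapes.

Three generators mirror the kinds of inputs the linkage operates on:
a gridded daily weather-like field, point-station pollution-like time
series, and daily pseudonymous health events. Grids and stations share
one value model

    value(var, t, lat, lon) = base_level
                              + daily_amplitude * sin(2*pi*t / 365)
                              + spatial_gradient * (lat - lat_south)
                              + Normal(0, noise_sd)

so grid-vs-station linkage comparisons are meaningful. Every generator
is a pure function of its spec: the random stream is derived from
(seed, generator name), so adding a generator never perturbs another.

This emulates the broad shape of real data — seasonal cycle, north-south
gradient, observation noise, missingness — not meteorology or pollution
chemistry.
"""
from __future__ import annotations

import datetime as dt
import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ValidationError
from .types import (
    AdminArea,
    EnvDatasetGrid,
    EnvDatasetStations,
    HealthEvent,
    Station,
    Variable,
)

log = logging.getLogger(__name__)

#: Default pre-event margin so default exposure windows fit inside coverage.
EVENT_MARGIN_DAYS = 60


@dataclass(frozen=True)
class SynthVariable:
    name: str
    base_level: float = 10.0
    daily_amplitude: float = 5.0
    noise_sd: float = 1.0
    spatial_gradient: float = 0.5  # per degree latitude
    unit: str = ""


@dataclass
class SynthSpec:
    """Parameters for all three generators; defaults give a small, dense study."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (-1.0, 50.0, 1.0, 52.0)  # lon0, lat0, lon1, lat1
    n_days: int = 120
    start_date: dt.date = dt.date(2021, 1, 1)
    grid_shape: tuple[int, int] = (4, 4)  # (n_lat, n_lon)
    n_stations: int = 10
    n_events: int = 20
    variables: tuple[SynthVariable, ...] = (
        SynthVariable("temperature", 10.0, 8.0, 1.5, 0.5, "degC"),
        SynthVariable("pm10", 20.0, 5.0, 3.0, -0.8, "ug/m3"),
    )
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_days < 1 or self.grid_shape[0] < 1 or self.grid_shape[1] < 1:
            raise ValidationError("counts must be positive")
        if self.n_stations < 1 or self.n_events < 1:
            raise ValidationError("counts must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValidationError("missing_rate must be in [0, 1)")
        lon0, lat0, lon1, lat1 = self.extent
        if lon1 <= lon0 or lat1 <= lat0:
            raise ValidationError("extent must have positive width and height")


def _rng(spec: SynthSpec, name: str) -> np.random.Generator:
    # independent stream per generator: (seed, crc32(name)) seeds a Philox key
    return np.random.default_rng([spec.seed, zlib.crc32(name.encode())])


def _value_field(
    spec: SynthSpec,
    var: SynthVariable,
    lats: np.ndarray,
    n_points: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Shared value model, shape (n_days, n_points); lats aligned with points."""
    t = np.arange(spec.n_days)[:, None]
    seasonal = var.base_level + var.daily_amplitude * np.sin(2 * np.pi * t / 365.0)
    gradient = var.spatial_gradient * (lats - spec.extent[1])[None, :]
    noise = rng.normal(0.0, var.noise_sd, size=(spec.n_days, n_points)) if var.noise_sd > 0 else 0.0
    return seasonal + gradient + noise


def _dates(spec: SynthSpec) -> list[dt.date]:
    return [spec.start_date + dt.timedelta(days=i) for i in range(spec.n_days)]


def gen_grid(spec: SynthSpec, dataset_id: str = "synth_grid") -> EnvDatasetGrid:
    """Gridded daily series over the extent; missing cells flagged at missing_rate."""
    rng = _rng(spec, "grid")
    n_lat, n_lon = spec.grid_shape
    lon0, lat0, lon1, lat1 = spec.extent
    lon_axis = np.linspace(lon0, lon1, n_lon, endpoint=False)
    lat_axis = np.linspace(lat0, lat1, n_lat, endpoint=False)
    values = np.empty((len(spec.variables), spec.n_days, n_lat, n_lon))
    lat_flat = np.repeat(lat_axis, n_lon)
    for vi, var in enumerate(spec.variables):
        field_vals = _value_field(spec, var, lat_flat, n_lat * n_lon, rng)
        values[vi] = field_vals.reshape(spec.n_days, n_lat, n_lon)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values[mask] = np.nan
    return EnvDatasetGrid(
        dataset_id=dataset_id,
        variables=[Variable(v.name, v.unit, "synthetic") for v in spec.variables],
        lon_axis=lon_axis,
        lat_axis=lat_axis,
        time_axis=_dates(spec),
        values=values,
    )


def gen_stations_dataset(
    spec: SynthSpec, dataset_id: str = "synth_stations"
) -> EnvDatasetStations:
    """Point stations uniform in the extent; same value model sampled there."""
    rng = _rng(spec, "stations")
    lon0, lat0, lon1, lat1 = spec.extent
    lons = rng.uniform(lon0, lon1, spec.n_stations)
    lats = rng.uniform(lat0, lat1, spec.n_stations)
    stations = [
        Station(f"st{i:03d}", float(lons[i]), float(lats[i]))
        for i in range(spec.n_stations)
    ]
    dates = _dates(spec)
    frames = []
    for var in spec.variables:
        vals = _value_field(spec, var, lats, spec.n_stations, rng)
        if spec.missing_rate > 0:
            vals[rng.random(vals.shape) < spec.missing_rate] = np.nan
        frames.append(
            pd.DataFrame(
                {
                    "station_id": np.tile([s.station_id for s in stations], spec.n_days),
                    "date": np.repeat(dates, spec.n_stations),
                    "variable": var.name,
                    "value": vals.ravel(),
                }
            )
        )
    observations = (
        pd.concat(frames, ignore_index=True)
        .sort_values(["station_id", "date", "variable"])
        .reset_index(drop=True)
    )
    return EnvDatasetStations(
        dataset_id=dataset_id,
        stations=stations,
        observations=observations,
        variables=[Variable(v.name, v.unit, "synthetic") for v in spec.variables],
    )


def gen_events(
    spec: SynthSpec, areas: list[AdminArea] | None = None
) -> list[HealthEvent]:
    """Daily pseudonymous events; dates leave a pre-event margin so default
    windows fit inside environmental coverage."""
    rng = _rng(spec, "events")
    margin = EVENT_MARGIN_DAYS
    if spec.n_days <= margin:
        margin = max(spec.n_days - 1, 0)
        log.warning(
            "n_days=%d too short for the %d-day pre-event margin; shrunk to %d",
            spec.n_days, EVENT_MARGIN_DAYS, margin,
        )
    day_offsets = rng.integers(margin, spec.n_days, size=spec.n_events)
    lon0, lat0, lon1, lat1 = spec.extent
    events = []
    for i in range(spec.n_events):
        date = spec.start_date + dt.timedelta(days=int(day_offsets[i]))
        if areas:
            aid = areas[int(rng.integers(0, len(areas)))].area_id
            events.append(HealthEvent(f"ev{i:04d}", date, area_id=aid))
        else:
            lon = float(rng.uniform(lon0, lon1))
            lat = float(rng.uniform(lat0, lat1))
            events.append(HealthEvent(f"ev{i:04d}", date, point=(lon, lat)))
    return events


def gen_areas(spec: SynthSpec, n_split: int = 2) -> list[AdminArea]:
    """Nested rectangular areas: one parent covering the extent, split into
    an n_split x n_split child lattice. Deterministic; no randomness used."""
    lon0, lat0, lon1, lat1 = spec.extent
    areas = [AdminArea("region", "Synthetic region", box(lon0, lat0, lon1, lat1))]
    dlon = (lon1 - lon0) / n_split
    dlat = (lat1 - lat0) / n_split
    for i in range(n_split):
        for j in range(n_split):
            areas.append(
                AdminArea(
                    f"district-{i}{j}",
                    f"District {i}{j}",
                    box(lon0 + j * dlon, lat0 + i * dlat,
                        lon0 + (j + 1) * dlon, lat0 + (i + 1) * dlat),
                    parent_area_id="region",
                )
            )
    return areas
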