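"""Readers and writers for environmental datasets, areas, and events.

Formats accepted mirror the offline-distribution conventions of the tool:
NetCDF (``.nc``) for gridded daily series, CSV/TSV for station series
(long form: station_id, lon, lat, date, variable, value), ``.grid`` as a
TSV alias with that fixed header, GeoJSON or WKT-bearing CSV for
administrative areas, and a small CSV schema for health events. All
coordinates WGS84 lon/lat; all dates ISO 8601 calendar dates.

Missing values (NetCDF fill values / NaN, empty tabular cells) map to the
internal missing flag (NaN) and are never silently dropped.
"""
from __future__ import annotations

import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import xarray as xr
from shapely.geometry import mapping, shape

from .errors import (
    AmbiguityError,
    FormatError,
    SchemaError,
    ValidationError,
)
from .types import (
    AdminArea,
    EnvDataset,
    EnvDatasetGrid,
    EnvDatasetStations,
    HealthEvent,
    Station,
    Variable,
    check_area_forest,
)

TABULAR_COLUMNS = ["station_id", "lon", "lat", "date", "variable", "value"]

_EXT_FORMAT = {
    ".nc": "netcdf",
    ".csv": "csv",
    ".tsv": "tsv",
    ".grid": "grid",
}


def _parse_date(text: str, where: str) -> dt.date:
    """Strict ISO-8601 calendar date; sub-daily timestamps are rejected."""
    s = str(text).strip()
    try:
        return dt.date.fromisoformat(s)
    except ValueError:
        raise ValidationError(f"unparseable date {s!r} at {where}") from None


def infer_format(path: str | Path) -> str:
    ext = Path(path).suffix.lower()
    try:
        return _EXT_FORMAT[ext]
    except KeyError:
        raise FormatError(
            f"unsupported extension {ext!r}; accepted: .nc, .grid, .csv, .tsv"
        ) from None


def read_env_dataset(
    path: str | Path,
    format: str | None = None,
    schema: dict | None = None,
    dataset_id: str | None = None,
) -> EnvDataset:
    """Read an environmental dataset into the internal model.

    Parameters
    ----------
    path
        File to read. Extension decides the format unless ``format`` is given.
    format
        One of ``netcdf``, ``csv``, ``tsv``, ``grid``.
    schema
        For tabular input, a mapping from the internal column roles
        (``station_id``, ``lon``, ``lat``, ``date``, ``variable``,
        ``value``) to the file's column names; omitted roles default to
        the role name itself. For gridded input, optional keys
        ``variables`` (subset to load), ``lon``/``lat``/``time`` (axis
        variable names) and ``units`` (variable name -> unit string).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or infer_format(path)
    if fmt not in ("netcdf", "csv", "tsv", "grid"):
        raise FormatError(f"unknown format {fmt!r}")
    dataset_id = dataset_id or path.stem
    if fmt == "netcdf":
        return _read_grid_netcdf(path, schema or {}, dataset_id)
    sep = "," if fmt == "csv" else "\t"
    return _read_stations_tabular(path, sep, schema or {}, dataset_id)


def _read_grid_netcdf(path: Path, schema: dict, dataset_id: str) -> EnvDatasetGrid:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds = ds.load()
    lon_name = schema.get("lon", "lon")
    lat_name = schema.get("lat", "lat")
    time_name = schema.get("time", "time")
    for name in (lon_name, lat_name, time_name):
        if name not in ds.coords and name not in ds.variables:
            raise SchemaError(f"coordinate {name!r} not found in {path.name}")
    var_names = schema.get("variables") or [
        v for v in ds.data_vars if set(ds[v].dims) >= {lat_name, lon_name}
    ]
    unknown = [v for v in var_names if v not in ds.data_vars]
    if unknown:
        raise SchemaError(f"variables {unknown} not found in {path.name}")
    units = schema.get("units", {})
    times = pd.to_datetime(ds[time_name].values)
    if (times != times.normalize()).any():
        raise ValidationError("sub-daily time steps are not supported")
    time_axis = [t.date() for t in times]
    variables = []
    planes = []
    for v in var_names:
        da = ds[v].transpose(time_name, lat_name, lon_name)
        unit = units.get(v, str(da.attrs.get("units", "")))
        variables.append(Variable(v, unit, str(da.attrs.get("long_name", ""))))
        planes.append(np.asarray(da.values, dtype=float))
    return EnvDatasetGrid(
        dataset_id=dataset_id,
        variables=variables,
        lon_axis=np.asarray(ds[lon_name].values, dtype=float),
        lat_axis=np.asarray(ds[lat_name].values, dtype=float),
        time_axis=time_axis,
        values=np.stack(planes),
    )


def _read_stations_tabular(
    path: Path, sep: str, schema: dict, dataset_id: str
) -> EnvDatasetStations:
    df = pd.read_csv(path, sep=sep, dtype=str)
    colmap = {role: schema.get(role, role) for role in TABULAR_COLUMNS}
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"columns {missing} named by the schema are absent from {path.name} "
            f"(found: {list(df.columns)})"
        )
    units = schema.get("units", {})
    out = pd.DataFrame(
        {
            "station_id": df[colmap["station_id"]].astype(str),
            "lon": df[colmap["lon"]].astype(float),
            "lat": df[colmap["lat"]].astype(float),
            "variable": df[colmap["variable"]].astype(str),
        }
    )
    out["date"] = [
        _parse_date(v, f"row {i + 2}") for i, v in enumerate(df[colmap["date"]])
    ]
    # empty cells -> NaN (internal missing flag), kept as observations
    out["value"] = pd.to_numeric(df[colmap["value"]], errors="coerce")
    bad = df[colmap["value"]].notna() & df[colmap["value"]].str.strip().ne("") & out["value"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.values)[0]) + 2
        raise ValidationError(f"non-numeric value at row {row} of {path.name}")
    stations = [
        Station(sid, float(g["lon"].iloc[0]), float(g["lat"].iloc[0]))
        for sid, g in out.groupby("station_id", sort=True)
    ]
    var_names = sorted(out["variable"].unique())
    variables = [Variable(v, units.get(v, "")) for v in var_names]
    observations = out[["station_id", "date", "variable", "value"]].reset_index(drop=True)
    return EnvDatasetStations(dataset_id, stations, observations, variables)


def read_events(path: str | Path) -> list[HealthEvent]:
    """Read health events from CSV (event_id, date, lon/lat or area_id)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"event_id", "date"}
    if not required <= set(df.columns):
        raise SchemaError(f"events file must have columns {sorted(required)}")
    has_point_cols = {"lon", "lat"} <= set(df.columns)
    has_area_col = "area_id" in df.columns
    if not has_point_cols and not has_area_col:
        raise SchemaError("events file needs (lon, lat) or area_id columns")
    events: list[HealthEvent] = []
    for i, row in df.iterrows():
        where = f"row {i + 2}"
        if pd.isna(row.get("date")) or str(row["date"]).strip() == "":
            raise ValidationError(f"missing date at {where}")
        date = _parse_date(row["date"], where)
        lon = row.get("lon") if has_point_cols else None
        lat = row.get("lat") if has_point_cols else None
        area = row.get("area_id") if has_area_col else None
        have_point = pd.notna(lon) and pd.notna(lat)
        have_area = pd.notna(area) and str(area).strip() != ""
        if have_point and have_area:
            raise AmbiguityError(f"both point and area_id populated at {where}")
        if not have_point and not have_area:
            raise ValidationError(f"no location at {where}")
        events.append(
            HealthEvent(
                event_id=str(row["event_id"]),
                event_date=date,
                point=(float(lon), float(lat)) if have_point else None,
                area_id=str(area) if have_area else None,
            )
        )
    return events


def read_areas(path: str | Path, format: str | None = None) -> list[AdminArea]:
    """Read administrative areas from GeoJSON or a WKT-bearing CSV."""
    path = Path(path)
    if format is None:
        format = "geojson" if path.suffix.lower() in (".geojson", ".json") else "wkt-csv"
    if format == "geojson":
        areas = _read_areas_geojson(path)
    elif format == "wkt-csv":
        areas = _read_areas_wkt_csv(path)
    else:
        raise FormatError(f"unknown areas format {format!r}")
    check_area_forest(areas)
    return areas


def _read_areas_geojson(path: Path) -> list[AdminArea]:
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    feats = gj["features"] if gj.get("type") == "FeatureCollection" else [gj]
    areas = []
    for feat in feats:
        props = feat.get("properties") or {}
        parent = props.get("parent_area_id") or props.get("parent")
        areas.append(
            AdminArea(
                area_id=str(props["area_id"]),
                label=str(props.get("label", props["area_id"])),
                geometry=shape(feat["geometry"]),
                parent_area_id=str(parent) if parent else None,
            )
        )
    return areas


def _read_areas_wkt_csv(path: Path) -> list[AdminArea]:
    df = pd.read_csv(path, dtype=str)
    missing = {"area_id", "wkt"} - set(df.columns)
    if missing:
        raise SchemaError(f"WKT-CSV areas need columns {sorted(missing)}")
    areas = []
    for _, row in df.iterrows():
        parent = row.get("parent") if "parent" in df.columns else None
        areas.append(
            AdminArea(
                area_id=str(row["area_id"]),
                label=str(row.get("label", row["area_id"])),
                geometry=shapely.from_wkt(row["wkt"]),
                parent_area_id=str(parent) if pd.notna(parent) and parent else None,
            )
        )
    return areas


# ---------------------------------------------------------------- writers


def write_grid_netcdf(ds: EnvDatasetGrid, path: str | Path) -> None:
    data_vars = {}
    for vi, var in enumerate(ds.variables):
        da = xr.DataArray(
            ds.values[vi],
            dims=("time", "lat", "lon"),
            attrs={"units": var.unit, "long_name": var.definition},
        )
        data_vars[var.name] = da
    xds = xr.Dataset(
        data_vars,
        coords={
            "time": pd.to_datetime([d.isoformat() for d in ds.time_axis]),
            "lat": ds.lat_axis,
            "lon": ds.lon_axis,
        },
    )
    xds.to_netcdf(Path(path), engine="scipy")


def write_stations_tabular(ds: EnvDatasetStations, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".grid") else ","
    coords = {s.station_id: s for s in ds.stations}
    obs = ds.observations
    out = pd.DataFrame(
        {
            "station_id": obs["station_id"],
            "lon": [coords[s].lon for s in obs["station_id"]],
            "lat": [coords[s].lat for s in obs["station_id"]],
            "date": [d.isoformat() for d in obs["date"]],
            "variable": obs["variable"],
            "value": [
                "" if pd.isna(v) else repr(float(v)) for v in obs["value"]
            ],
        }
    )
    out.to_csv(path, sep=sep, index=False)


def write_events_csv(events: list[HealthEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        rows.append(
            {
                "event_id": e.event_id,
                "date": e.event_date.isoformat(),
                "lon": "" if e.point is None else repr(e.point[0]),
                "lat": "" if e.point is None else repr(e.point[1]),
                "area_id": e.area_id or "",
            }
        )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_areas_geojson(areas: list[AdminArea], path: str | Path) -> None:
    feats = []
    for a in areas:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(a.geometry),
                "properties": {
                    "area_id": a.area_id,
                    "label": a.label,
                    "parent_area_id": a.parent_area_id,
                },
            }
        )
    with open(Path(path), "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
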