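"""The linkage engine: spatial context + pre-event exposure window.

For every event x dataset pair the engine selects a *spatial context*
(which stations, grid cells or areas are relevant to the event location)
and a *temporal window* (a half-open span of dates strictly before the
event), then materializes the raw observations falling in both. Two
interchangeable backends produce the links:

``direct``
    Pure tabular filtering over the dataset observation tables.
``graph``
    A SPARQL query over the uplifted QB observation graph. Spatial
    relations are pre-materialized as event->source link triples
    (computed by the same spatial assignment), and the query itself does
    the temporal reasoning via date-literal comparisons — the contract is
    that both backends return identical row multisets.

Spatial methods
---------------
area_contains
    The most specific (smallest-area) administrative polygon containing
    the event point — or the event's own area code — expanded to the
    stations inside it or the grid cells whose origins fall inside it.
nearest_station
    The single station minimizing great-circle (haversine) distance.
proximity_polygon
    The station whose planar Voronoi (Thiessen) cell contains the event,
    computed in an equirectangular projection centred on the stations.
buffer
    All stations within ``buffer_km`` great-circle kilometres.

Ties are always broken toward the lexicographically smallest source id.
Grid datasets under the three point methods resolve to the single
half-open grid cell containing the point.
"""
from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from rdflib import Graph, URIRef
from shapely.geometry import MultiPoint, Point, box

from .errors import ConfigurationError, DisambiguationError, EnvLinkError, ValidationError
from .kg import mint_iri, uplift_dataset
from .types import (
    AdminArea,
    EnvDataset,
    EnvDatasetGrid,
    EnvDatasetStations,
    ExposureWindow,
    HealthEvent,
    LinkageSpec,
    Source,
    SpatialContext,
)

EARTH_RADIUS_KM = 6371.0088

SKIP_NO_CONTEXT = "no_spatial_context"
SKIP_OUTSIDE = "window_outside_coverage"
SKIP_NO_OBS = "no_observations_in_window"

DEFAULT_BASE = "https://example.org/envlink"


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 lon/lat points."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))


def temporal_window(event_date: dt.date, lag_days: int, window_days: int) -> ExposureWindow:
    """The exposure window: ``window_days`` dates ending ``lag_days`` before the event.

    Covers dates d with
    ``event_date - lag_days - window_days <= d < event_date - lag_days``
    (half-open upper bound). The event day itself is always excluded, so
    with lag 0 the window ends on the day before the event — exposures
    never peek at or past the event and reverse-causation leakage is
    impossible by construction.
    """
    if lag_days < 0:
        raise ValidationError("lag_days must be >= 0")
    if window_days < 1:
        raise ValidationError("window_days must be >= 1")
    end_exclusive = event_date - dt.timedelta(days=lag_days)
    start = end_exclusive - dt.timedelta(days=window_days)
    return ExposureWindow("", start, end_exclusive)


# ------------------------------------------------------------ spatial part


class _VoronoiCells:
    """Planar Voronoi (Thiessen) partition of a station set.

    Coordinates are projected with an equirectangular projection centred
    on the station centroid (x = dlon * cos(lat0), y = dlat), so cell
    membership equals nearest-station under that planar metric. The
    diagram is clipped to a generously padded envelope; points on shared
    edges are resolved to the lexicographically smallest station id.
    """

    def __init__(self, stations):
        self.station_ids = [s.station_id for s in stations]
        lons = np.array([s.lon for s in stations])
        lats = np.array([s.lat for s in stations])
        self.lon0 = float(lons.mean())
        self.lat0 = float(lats.mean())
        xs, ys = self._project(lons, lats)
        pts = MultiPoint(list(zip(xs, ys)))
        span = max(np.ptp(xs), np.ptp(ys), 1.0)
        pad = 50.0 * span
        env = box(xs.min() - pad, ys.min() - pad, xs.max() + pad, ys.max() + pad)
        cells = shapely.voronoi_polygons(pts, extend_to=env, ordered=True)
        self.cells = list(cells.geoms)
        if len(self.cells) != len(stations):
            raise EnvLinkError("voronoi construction lost a station cell")

    def _project(self, lon, lat):
        k = math.cos(math.radians(self.lat0))
        return (np.asarray(lon) - self.lon0) * k, np.asarray(lat) - self.lat0

    def assign(self, lon: float, lat: float) -> str | None:
        x, y = self._project(lon, lat)
        p = Point(float(x), float(y))
        hits = [
            sid
            for sid, cell in zip(self.station_ids, self.cells)
            if cell.covers(p)
        ]
        return min(hits) if hits else None


def _stations_required(ds: EnvDataset):
    if isinstance(ds, EnvDatasetStations) and not ds.stations:
        raise ConfigurationError(f"dataset {ds.dataset_id!r} has zero stations")


def _grid_point_context(event, ds: EnvDatasetGrid) -> list[Source]:
    cell = ds.cell_containing(*event.point)
    return [Source("grid_cell", cell)] if cell else []


def _containing_area(point: Point, areas: list[AdminArea]) -> AdminArea | None:
    hits = [a for a in areas if a.geometry.covers(point)]
    if not hits:
        return None
    # most specific = smallest enclosing polygon; ties by area_id
    return min(hits, key=lambda a: (a.geometry.area, a.area_id))


def assign_spatial(
    event: HealthEvent,
    ds: EnvDataset,
    areas: list[AdminArea] | None,
    method: str,
    buffer_km: float | None = None,
    _voronoi_cache: dict | None = None,
) -> SpatialContext | None:
    """Select the environmental sources relevant to one event.

    Returns ``None`` when the event has no spatial context under the
    requested method (e.g. a point outside every administrative area) —
    callers turn this into a skip-log entry, never a crash.
    """
    _stations_required(ds)
    is_grid = isinstance(ds, EnvDatasetGrid)

    if method == "area_contains":
        areas = areas or []
        if event.area_id is not None:
            area = next((a for a in areas if a.area_id == event.area_id), None)
        else:
            area = _containing_area(Point(*event.point), areas)
        if area is None:
            return None
        sources: list[Source] = []
        if is_grid:
            for ilat in range(ds.lat_axis.size):
                for ilon in range(ds.lon_axis.size):
                    origin = Point(float(ds.lon_axis[ilon]), float(ds.lat_axis[ilat]))
                    if area.geometry.covers(origin):
                        sources.append(Source("grid_cell", ds.cell_id(ilat, ilon)))
        else:
            for s in ds.stations:
                if area.geometry.covers(Point(s.lon, s.lat)):
                    sources.append(Source("station", s.station_id))
        sources.sort(key=lambda s: s.source_id)
        if not sources:
            return None
        return SpatialContext(event.event_id, ds.dataset_id, sources)

    if event.point is None:
        raise ValidationError(
            f"method {method!r} needs a point-located event ({event.event_id!r} has an area)"
        )

    if is_grid:
        sources = _grid_point_context(event, ds)
        return (
            SpatialContext(event.event_id, ds.dataset_id, sources) if sources else None
        )

    lons = np.array([s.lon for s in ds.stations])
    lats = np.array([s.lat for s in ds.stations])
    ids = [s.station_id for s in ds.stations]
    dists = haversine_km(event.point[0], event.point[1], lons, lats)

    if method == "nearest_station":
        dmin = dists.min()
        best = min(sid for sid, d in zip(ids, dists) if d == dmin)
        return SpatialContext(
            event.event_id,
            ds.dataset_id,
            [Source("station", best, float(dmin))],
        )

    if method == "proximity_polygon":
        cache = _voronoi_cache if _voronoi_cache is not None else {}
        if ds.dataset_id not in cache:
            cache[ds.dataset_id] = _VoronoiCells(ds.stations)
        sid = cache[ds.dataset_id].assign(*event.point)
        if sid is None:
            return None
        d = float(dists[ids.index(sid)])
        return SpatialContext(
            event.event_id, ds.dataset_id, [Source("station", sid, d)]
        )

    if method == "buffer":
        if buffer_km is None or buffer_km <= 0:
            raise ValidationError("buffer method needs buffer_km > 0")
        sources = sorted(
            (
                Source("station", sid, float(d))
                for sid, d in zip(ids, dists)
                if d <= buffer_km
            ),
            key=lambda s: s.source_id,
        )
        if not sources:
            return None
        return SpatialContext(event.event_id, ds.dataset_id, sources)

    raise ValidationError(f"unknown spatial method {method!r}")


# ------------------------------------------------------------ query part

QUERY_TEMPLATE = """\
PREFIX qb: <http://purl.org/linked-data/cube#>
PREFIX sdmx-dimension: <http://purl.org/linked-data/sdmx/2009/dimension#>
PREFIX rdfs: <http://www.w3.org/2000/01/rdf-schema#>
PREFIX xsd: <http://www.w3.org/2001/XMLSchema#>

SELECT ?source ?date ?variable ?value
WHERE {
  $event $spatial_relation ?sourceNode .
  ?obs a qb:Observation ;
       qb:dataSet $dataset ;
       sdmx-dimension:refArea ?sourceNode ;
       sdmx-dimension:refPeriod ?date ;
       ?measure ?value .
  ?measure a qb:MeasureProperty ;
           rdfs:label ?variable .
  ?sourceNode rdfs:label ?source .
  FILTER(?date >= $window_start && ?date < $window_end)
}
ORDER BY ?source ?date ?variable
"""

PLACEHOLDERS = ("$event", "$dataset", "$spatial_relation", "$window_start", "$window_end")


def link_predicate(base: str) -> URIRef:
    return mint_iri(base, ["def", "linkedSource"])


def build_query_template(spec: LinkageSpec) -> str:
    """SPARQL 1.1 template for the graph backend, with named placeholders.

    ``$event``, ``$dataset`` and ``$spatial_relation`` are bound to IRIs;
    ``$window_start``/``$window_end`` to xsd:date literals exactly
    ``window_days`` apart. The spatial relation is consumed as
    pre-materialized link triples; temporal selection is genuine
    xsd:date-comparison reasoning in the FILTER clause.
    """
    if spec.spatial_method not in ("area_contains", "nearest_station", "proximity_polygon", "buffer"):
        raise ValidationError(f"unsupported spatial method {spec.spatial_method!r}")
    return QUERY_TEMPLATE


def bind_query_template(
    template: str,
    event_iri: URIRef,
    dataset_iri: URIRef,
    window: ExposureWindow,
    spatial_relation: URIRef,
) -> str:
    """Substitute concrete IRIs and window bounds into the template."""
    return (
        template.replace("$event", f"<{event_iri}>")
        .replace("$dataset", f"<{dataset_iri}>")
        .replace("$spatial_relation", f"<{spatial_relation}>")
        .replace("$window_start", f'"{window.start_date.isoformat()}"^^xsd:date')
        .replace("$window_end", f'"{window.end_date_exclusive.isoformat()}"^^xsd:date')
    )


# ------------------------------------------------------------ link driver


@dataclass
class LinkedEvent:
    """Raw linked observations for one event x dataset pair."""

    event_id: str
    dataset_id: str
    context: SpatialContext
    window: ExposureWindow
    rows: pd.DataFrame  # columns: source_id, date, variable, value


@dataclass
class LinkageResult:
    links: list[LinkedEvent] = field(default_factory=list)
    skips: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def skip_log(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.skips, columns=["event_id", "dataset_id", "reason_code"]
        )

    def row_multiset(self) -> list[tuple]:
        """All (event, source, date, variable, value) tuples, sorted."""
        out = []
        for le in self.links:
            for r in le.rows.itertuples(index=False):
                out.append(
                    (le.event_id, r.source_id, r.date.isoformat(), r.variable, r.value)
                )
        return sorted(out)


def _check_variable_overlap(datasets: list[EnvDataset], rename: dict | None) -> dict:
    """Return per-dataset variable rename maps; raise on unresolved overlap."""
    rename = rename or {}
    seen: dict[str, str] = {}
    maps: dict[str, dict[str, str]] = {}
    for ds in datasets:
        dsmap = dict(rename.get(ds.dataset_id, {}))
        maps[ds.dataset_id] = dsmap
        for var in ds.variables:
            name = dsmap.get(var.name, var.name)
            if name in seen and seen[name] != ds.dataset_id:
                raise DisambiguationError(
                    f"variable {name!r} appears in datasets {seen[name]!r} and "
                    f"{ds.dataset_id!r}; supply a rename map"
                )
            seen[name] = ds.dataset_id
    return maps


def _skip_reason(window: ExposureWindow, ds: EnvDataset) -> str:
    first, last = ds.date_range
    if window.end_date_exclusive <= first or window.start_date > last:
        return SKIP_OUTSIDE
    return SKIP_NO_OBS


def link_events(
    events: list[HealthEvent],
    datasets: list[EnvDataset],
    areas: list[AdminArea] | None,
    spec: LinkageSpec,
    *,
    rename: dict | None = None,
    backend: str = "direct",
    base: str = DEFAULT_BASE,
    graphs: dict[str, Graph] | None = None,
) -> LinkageResult:
    """Link every event to every dataset under the spec.

    Events with no spatial context or no observations in the window are
    recorded in the skip log with a reason code, never dropped silently.
    """
    if backend not in ("direct", "graph"):
        raise ValidationError(f"unknown backend {backend!r}")
    renames = _check_variable_overlap(datasets, rename)
    result = LinkageResult()
    vcache: dict = {}

    if backend == "graph":
        graphs = graphs or {
            ds.dataset_id: uplift_dataset(ds, areas, base) for ds in datasets
        }

    obs_tables = {ds.dataset_id: ds.obs_table() for ds in datasets} if backend == "direct" else {}

    for ds in datasets:
        dsmap = renames[ds.dataset_id]
        for event in events:
            ctx = assign_spatial(
                event, ds, areas, spec.spatial_method, spec.buffer_km, vcache
            )
            if ctx is None or not ctx.sources:
                result.skips.append((event.event_id, ds.dataset_id, SKIP_NO_CONTEXT))
                continue
            window = temporal_window(event.event_date, spec.lag_days, spec.window_days)
            window = ExposureWindow(event.event_id, window.start_date, window.end_date_exclusive)
            if backend == "direct":
                rows = _direct_rows(obs_tables[ds.dataset_id], ctx, window)
            else:
                rows = _graph_rows(graphs[ds.dataset_id], event, ds, ctx, window, spec, base)
            if rows.empty:
                result.skips.append(
                    (event.event_id, ds.dataset_id, _skip_reason(window, ds))
                )
                continue
            if dsmap:
                rows = rows.assign(variable=rows["variable"].map(lambda v: dsmap.get(v, v)))
            result.links.append(LinkedEvent(event.event_id, ds.dataset_id, ctx, window, rows))
    return result


def _direct_rows(obs: pd.DataFrame, ctx: SpatialContext, window: ExposureWindow) -> pd.DataFrame:
    ids = set(ctx.source_ids)
    mask = (
        obs["source_id"].isin(ids)
        & (obs["date"] >= window.start_date)
        & (obs["date"] < window.end_date_exclusive)
    )
    rows = obs.loc[mask]
    return rows.sort_values(["source_id", "date", "variable"]).reset_index(drop=True)


def _graph_rows(
    g: Graph,
    event: HealthEvent,
    ds: EnvDataset,
    ctx: SpatialContext,
    window: ExposureWindow,
    spec: LinkageSpec,
    base: str,
) -> pd.DataFrame:
    from .kg import dataset_iri, source_iri

    event_iri = mint_iri(base, ["event", event.event_id])
    pred = link_predicate(base)
    kind = "cell" if isinstance(ds, EnvDatasetGrid) else "station"
    link_triples = [
        (event_iri, pred, source_iri(base, kind, s.source_id)) for s in ctx.sources
    ]
    for t in link_triples:
        g.add(t)
    try:
        query = bind_query_template(
            build_query_template(spec), event_iri, dataset_iri(base, ds.dataset_id),
            window, pred,
        )
        rows = [
            (str(src), dt.date.fromisoformat(str(date)), str(var), float(value))
            for src, date, var, value in g.query(query)
        ]
    finally:
        for t in link_triples:
            g.remove(t)
    df = pd.DataFrame(rows, columns=["source_id", "date", "variable", "value"])
    return df.sort_values(["source_id", "date", "variable"]).reset_index(drop=True)
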