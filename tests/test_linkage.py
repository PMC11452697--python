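"""Linkage engine: windows, spatial assignment, backends, skip log."""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from envlink import (
    AdminArea,
    EnvDatasetStations,
    HealthEvent,
    LinkageSpec,
    Station,
    SynthSpec,
    Variable,
    assign_spatial,
    bind_query_template,
    build_query_template,
    gen_grid,
    gen_stations_dataset,
    link_events,
    temporal_window,
)
from envlink.errors import ConfigurationError, DisambiguationError
from envlink.linkage import (
    SKIP_NO_CONTEXT,
    SKIP_OUTSIDE,
    _VoronoiCells,
)


class TestTemporalWindow:
    def test_week_before_event_with_no_lag(self):
        w = temporal_window(dt.date(2021, 3, 10), 0, 7)
        assert w.dates() == [dt.date(2021, 3, d) for d in range(3, 10)]
        assert w.window_days == 7

    def test_lag_30_window_14(self):
        # enumerated by hand backwards from the event date
        w = temporal_window(dt.date(2021, 3, 10), 30, 14)
        assert w.start_date == dt.date(2021, 1, 25)
        assert w.dates()[-1] == dt.date(2021, 2, 7)

    def test_window_one_is_the_day_before(self):
        w = temporal_window(dt.date(2022, 7, 1), 0, 1)
        assert w.dates() == [dt.date(2022, 6, 30)]

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        date=st.dates(dt.date(1990, 1, 1), dt.date(2030, 12, 31)),
        lag=st.integers(0, 60),
        window=st.integers(1, 90),
    )
    def test_window_law(self, date, lag, window):
        """|covered dates| = window_days; latest = event - lag - 1; event
        day always excluded."""
        w = temporal_window(date, lag, window)
        days = w.dates()
        assert len(days) == window
        assert max(days) == date - dt.timedelta(days=lag + 1)
        assert all(d < date for d in days)


def two_station_ds():
    obs = pd.DataFrame(
        {
            "station_id": ["A", "B"],
            "date": [dt.date(2021, 1, 1)] * 2,
            "variable": ["x"] * 2,
            "value": [1.0, 2.0],
        }
    )
    return EnvDatasetStations(
        "two", [Station("A", 0.0, 0.0), Station("B", 1.0, 0.0)], obs, [Variable("x")]
    )


class TestAssignSpatial:
    def test_nearest_station(self):
        ev = HealthEvent("e", dt.date(2021, 2, 1), point=(0.4, 0.0))
        ctx = assign_spatial(ev, two_station_ds(), [], "nearest_station")
        assert ctx.source_ids == ["A"]
        assert ctx.sources[0].distance_km == pytest.approx(
            0.4 * 111.19, rel=1e-2
        )  # ~111 km per degree at the equator

    def test_equidistant_tie_breaks_lexicographically(self):
        ev = HealthEvent("e", dt.date(2021, 2, 1), point=(0.5, 0.0))
        ctx = assign_spatial(ev, two_station_ds(), [], "nearest_station")
        assert ctx.source_ids == ["A"]

    def test_zero_stations_is_a_configuration_error(self):
        ds = EnvDatasetStations(
            "empty", [], pd.DataFrame(columns=["station_id", "date", "variable", "value"]),
            [Variable("x")],
        )
        ev = HealthEvent("e", dt.date(2021, 2, 1), point=(0.0, 0.0))
        with pytest.raises(ConfigurationError):
            assign_spatial(ev, ds, [], "nearest_station")

    def test_buffer_monotonicity(self):
        ds = gen_stations_dataset(SynthSpec(seed=21, n_stations=20))
        ev = HealthEvent("e", dt.date(2021, 3, 1), point=(0.0, 51.0))
        sizes = []
        for km in (10, 30, 60, 120, 400):
            ctx = assign_spatial(ev, ds, [], "buffer", buffer_km=km)
            sizes.append(0 if ctx is None else len(ctx.sources))
        assert sizes == sorted(sizes)

    def test_grid_point_method_selects_single_containing_cell(self):
        grid = gen_grid(SynthSpec(seed=1, grid_shape=(4, 4)))
        ev = HealthEvent("e", dt.date(2021, 3, 1), point=(-0.9, 50.1))
        ctx = assign_spatial(ev, grid, [], "nearest_station")
        assert [s.source_id for s in ctx.sources] == ["cell-000-000"]
        # a cell-boundary point belongs to exactly one (the half-open) cell
        ev2 = HealthEvent("e2", dt.date(2021, 3, 1), point=(-0.5, 50.5))
        ctx2 = assign_spatial(ev2, grid, [], "nearest_station")
        assert [s.source_id for s in ctx2.sources] == ["cell-001-001"]


class TestAreaContains:
    areas = [
        AdminArea("outer", "Outer", box(0.0, 50.0, 2.0, 52.0)),
        AdminArea("inner", "Inner", box(0.5, 50.5, 1.5, 51.5), "outer"),
    ]

    def test_most_specific_area_wins_and_nesting_holds(self):
        ev = HealthEvent("e", dt.date(2021, 2, 1), point=(1.0, 51.0))
        # one station inside the inner rectangle, one only in the outer
        ds2 = EnvDatasetStations(
            "d2",
            [Station("in1", 1.0, 51.0), Station("out1", 0.1, 50.1)],
            pd.DataFrame(
                {
                    "station_id": ["in1"],
                    "date": [dt.date(2021, 1, 1)],
                    "variable": ["x"],
                    "value": [1.0],
                }
            ),
            [Variable("x")],
        )
        ctx2 = assign_spatial(ev, ds2, self.areas, "area_contains")
        # the inner (smaller) area wins, so the outer-only station is excluded
        assert ctx2.source_ids == ["in1"]
        # nesting rule: the selected polygon sits inside every ancestor
        # polygon that also contains the point
        assert self.areas[0].geometry.contains(self.areas[1].geometry)

    def test_point_outside_every_area_gives_no_context(self):
        ev = HealthEvent("e", dt.date(2021, 2, 1), point=(10.0, 10.0))
        assert assign_spatial(ev, two_station_ds(), self.areas, "area_contains") is None

    def test_area_coded_event_uses_its_own_area(self):
        ds = EnvDatasetStations(
            "d2",
            [Station("in1", 1.0, 51.0)],
            pd.DataFrame(
                {
                    "station_id": ["in1"],
                    "date": [dt.date(2021, 1, 1)],
                    "variable": ["x"],
                    "value": [1.0],
                }
            ),
            [Variable("x")],
        )
        ev = HealthEvent("e", dt.date(2021, 2, 1), area_id="inner")
        ctx = assign_spatial(ev, ds, self.areas, "area_contains")
        assert ctx.source_ids == ["in1"]


def brute_force_planar_nearest(cells, stations, lon, lat):
    """Independent oracle: nearest station in the same projected metric."""
    k = math.cos(math.radians(cells.lat0))
    best = None
    for s in stations:
        d = ((s.lon - lon) * k) ** 2 + (s.lat - lat) ** 2
        key = (d, s.station_id)
        if best is None or key < best:
            best = key
    return best[1]


def test_voronoi_assignment_equals_brute_force_nearest_seed7():
    """Proximity-polygon assignment agrees with brute-force planar nearest
    for 200 random events over 50 random stations."""
    spec = SynthSpec(seed=7, n_stations=50)
    ds = gen_stations_dataset(spec)
    cells = _VoronoiCells(ds.stations)
    rng = np.random.default_rng(7)
    lon0, lat0, lon1, lat1 = spec.extent
    mismatches = 0
    for _ in range(200):
        lon = rng.uniform(lon0, lon1)
        lat = rng.uniform(lat0, lat1)
        want = brute_force_planar_nearest(cells, ds.stations, lon, lat)
        if cells.assign(lon, lat) != want:
            mismatches += 1
    assert mismatches == 0


class TestLinkEvents:
    def test_full_coverage_week_gives_seven_rows_per_variable(self, standard_fixture):
        ds, events = standard_fixture
        res = link_events(events[:1], [ds], [], LinkageSpec(window_days=7))
        assert len(res.links) == 1
        rows = res.links[0].rows
        assert all(len(g) == 7 for _, g in rows.groupby("variable"))

    def test_event_before_coverage_is_skipped_with_reason(self, standard_fixture):
        ds, _ = standard_fixture
        early = HealthEvent("early", dt.date(2020, 6, 1), point=(0.0, 51.0))
        res = link_events([early], [ds], [], LinkageSpec())
        assert res.links == []
        assert res.skips == [("early", ds.dataset_id, SKIP_OUTSIDE)]

    def test_no_context_is_skipped_not_crashed(self, standard_fixture):
        ds, events = standard_fixture
        res = link_events(
            events, [ds],
            [AdminArea("far", "Far", box(30, 30, 31, 31))],
            LinkageSpec(spatial_method="area_contains"),
        )
        assert res.links == []
        assert all(s[2] == SKIP_NO_CONTEXT for s in res.skips)

    def test_overlapping_variables_require_rename(self, standard_fixture):
        ds, events = standard_fixture
        grid = gen_grid(SynthSpec(seed=11))
        with pytest.raises(DisambiguationError):
            link_events(events, [ds, grid], [], LinkageSpec())
        rename = {grid.dataset_id: {"temperature": "t_grid", "pm10": "pm10_grid"}}
        res = link_events(events, [ds, grid], [], LinkageSpec(), rename=rename)
        variables = {v for le in res.links for v in le.rows["variable"]}
        assert {"t_grid", "pm10_grid", "temperature", "pm10"} == variables

    def test_backend_equivalence_on_standard_fixture(self, standard_fixture, base_iri):
        ds, events = standard_fixture
        spec = LinkageSpec(window_days=7)
        direct = link_events(events, [ds], [], spec, backend="direct", base=base_iri)
        graph = link_events(events, [ds], [], spec, backend="graph", base=base_iri)
        assert direct.row_multiset() == graph.row_multiset()
        assert len(direct.row_multiset()) == 3 * 2 * 7  # events x variables x days


class TestQueryTemplate:
    def test_placeholders_present_before_binding(self):
        t = build_query_template(LinkageSpec())
        for ph in ("$event", "$dataset", "$spatial_relation", "$window_start", "$window_end"):
            assert ph in t

    def test_bound_dates_are_window_days_apart(self, base_iri):
        from envlink.kg import dataset_iri, mint_iri
        from envlink.linkage import link_predicate

        spec = LinkageSpec(lag_days=0, window_days=7)
        w = temporal_window(dt.date(2021, 3, 10), spec.lag_days, spec.window_days)
        q = bind_query_template(
            build_query_template(spec),
            mint_iri(base_iri, ["event", "e1"]),
            dataset_iri(base_iri, "air"),
            w,
            link_predicate(base_iri),
        )
        assert "$" not in q
        assert '"2021-03-03"^^xsd:date' in q and '"2021-03-10"^^xsd:date' in q
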