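"""Aggregation rules, coverage accounting, export triad, determinism."""
import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest
from rdflib import RDF, Graph

from envlink import (
    Activity,
    Agent,
    LinkageSpec,
    MetadataBundle,
    SynthSpec,
    SynthVariable,
    aggregate,
    export_bundle,
    gen_grid,
    link_events,
    records_frame,
    temporal_window,
)
from envlink.kg import PROV, QB
from envlink.linkage import LinkedEvent, LinkageResult
from envlink.types import SpatialContext, Source


def make_link(values_by_date, window_days=3, event_date=dt.date(2021, 3, 10),
              source="st1", variable="x"):
    """A LinkedEvent with given {date: value-or-list} raw rows."""
    rows = []
    for date, vals in values_by_date.items():
        vals = vals if isinstance(vals, list) else [vals]
        for i, v in enumerate(vals):
            src = source if len(vals) == 1 else f"{source}{i}"
            rows.append({"source_id": src, "date": date, "variable": variable, "value": v})
    df = pd.DataFrame(rows, columns=["source_id", "date", "variable", "value"])
    w = temporal_window(event_date, 0, window_days)
    ctx = SpatialContext("e1", "d1", [Source("station", source)])
    return LinkedEvent("e1", "d1", ctx, w, df)


def days_before(event_date, n):
    return [event_date - dt.timedelta(days=i) for i in range(1, n + 1)]


class TestAggregate:
    def test_mean_over_full_three_day_window(self):
        d = days_before(dt.date(2021, 3, 10), 3)
        link = make_link(dict(zip(d, [2.0, 4.0, 6.0])), window_days=3)
        (rec,) = aggregate([link], LinkageSpec(agg_functions=("mean",), window_days=3))
        assert rec.value == 4.0 and rec.coverage == 1.0

    def test_partial_coverage_fraction(self):
        d = days_before(dt.date(2021, 3, 20), 8)
        link = make_link({x: 1.0 for x in d}, window_days=10)
        (rec,) = aggregate([link], LinkageSpec(agg_functions=("mean",), window_days=10))
        assert rec.coverage == pytest.approx(0.8)

    def test_multi_source_day_averages_first_daily_level(self):
        day = dt.date(2021, 3, 9)
        link = make_link({day: [1.0, 3.0]}, window_days=3)
        (rec,) = aggregate([link], LinkageSpec(agg_level="daily", window_days=3))
        assert rec.value == 2.0 and rec.agg_function == "daily_mean"
        assert rec.window_start == day
        assert rec.n_sources == 2

    def test_spatial_before_temporal_order_for_max(self):
        # max over daily means, not over raw rows
        d1, d2 = days_before(dt.date(2021, 3, 10), 2)
        link = make_link({d1: [0.0, 10.0], d2: [4.0, 4.0]}, window_days=2)
        (rec,) = aggregate([link], LinkageSpec(agg_functions=("max",), window_days=2))
        assert rec.value == 5.0  # daily means are 5 and 4; raw max would be 10

    def test_sd_uses_sample_denominator_and_count_counts_dates(self):
        d = days_before(dt.date(2021, 3, 10), 4)
        vals = [1.0, 5.0, 3.0, 7.0]
        link = make_link(dict(zip(d, vals)), window_days=4)
        recs = aggregate([link], LinkageSpec(agg_functions=("sd", "count"), window_days=4))
        by_fn = {r.agg_function: r.value for r in recs}
        assert by_fn["sd"] == pytest.approx(np.std(vals, ddof=1))
        assert by_fn["count"] == 4

    def test_missing_variable_yields_flagged_zero_coverage_record(self):
        d = days_before(dt.date(2021, 3, 10), 3)
        link = make_link(dict(zip(d, [1.0] * 3)), window_days=3)
        recs = aggregate(
            [link],
            LinkageSpec(agg_functions=("mean",), window_days=3, min_coverage=0.5),
            dataset_variables={"d1": ["x", "y"]},
        )
        by_var = {r.variable: r for r in recs}
        assert by_var["x"].coverage == 1.0 and not by_var["x"].flagged
        y = by_var["y"]
        assert y.coverage == 0.0 and y.flagged and math.isnan(y.value) and y.n_sources == 0

    def test_conservation_sum_equals_raw_sum_exactly(self, standard_fixture):
        ds, events = standard_fixture
        spec = LinkageSpec(agg_functions=("sum",), window_days=7)
        res = link_events(events, [ds], [], spec)
        recs = aggregate(res.links, spec)
        for le in res.links:
            for var, g in le.rows.groupby("variable"):
                rec = next(
                    r for r in recs
                    if r.event_id == le.event_id and r.variable == var
                )
                assert rec.value == float(g["value"].sum())


def run_md():
    return MetadataBundle(
        title="t", licence=None, version="1",
        temporal_extent=(dt.date(2021, 1, 1), dt.date(2021, 4, 1)),
        spatial_extent=(-1, 50, 1, 52), distribution_url="file://x",
        agents=[Agent("envlink", "software")],
        activity=Activity(dt.datetime(2021, 4, 1), dt.datetime(2021, 4, 1),
                          ["synth_stations"], "linked"),
    )


class TestExportBundle:
    @pytest.fixture
    def run_outputs(self, standard_fixture, tmp_path):
        ds, events = standard_fixture
        spec = LinkageSpec(agg_functions=("mean",), window_days=7)
        res = link_events(events, [ds], [], spec)
        recs = aggregate(res.links, spec)
        paths = export_bundle(recs, res, [], run_md(), tmp_path / "out", spec)
        return recs, res, paths

    def test_export_triad_plus_skip_log_present(self, run_outputs):
        _, _, paths = run_outputs
        for key, name in [("csv", "linked_data.csv"), ("ttl", "linked_data.ttl"),
                          ("html", "report.html"), ("skip_log", "skip_log.csv")]:
            assert paths[key].name == name and paths[key].exists()

    def test_csv_cardinality_events_times_variables_times_functions(self, run_outputs):
        recs, res, paths = run_outputs
        df = pd.read_csv(paths["csv"])
        assert len(df) == 3 * 2 * 1  # events x variables x agg functions
        assert list(df.columns) == [
            "event_id", "dataset_id", "variable", "window_start",
            "window_end", "agg", "value", "coverage", "n_sources",
        ]

    def test_turtle_reparses_with_provenance_shape(self, run_outputs):
        _, _, paths = run_outputs
        g = Graph().parse(paths["ttl"], format="turtle")
        act = next(g.subjects(RDF.type, PROV.Activity))
        used = set(g.objects(act, PROV.used))
        assert any(str(u).endswith("synth_stations") for u in used)
        assert len(list(g.objects(act, PROV.generated))) == 1
        assert len(list(g.subjects(RDF.type, QB.Observation))) == 6

    def test_determinism_byte_identical_outputs(self, standard_fixture, tmp_path):
        ds, events = standard_fixture
        spec = LinkageSpec(window_days=7)
        outs = []
        for name in ("a", "b"):
            res = link_events(events, [ds], [], spec)
            recs = aggregate(res.links, spec)
            paths = export_bundle(recs, res, [], run_md(), tmp_path / name, spec)
            outs.append(paths)
        assert outs[0]["csv"].read_bytes() == outs[1]["csv"].read_bytes()
        assert outs[0]["ttl"].read_bytes() == outs[1]["ttl"].read_bytes()


def test_constant_field_every_stat_equals_the_constant():
    const_var = SynthVariable("flat", base_level=7.25, daily_amplitude=0.0,
                              noise_sd=0.0, spatial_gradient=0.0)
    spec_s = SynthSpec(seed=13, variables=(const_var,), n_days=90)
    grid = gen_grid(spec_s)
    from envlink import gen_events

    events = gen_events(spec_s)[:5]
    lspec = LinkageSpec(agg_functions=("mean", "min", "max"), window_days=7)
    res = link_events(events, [grid], [], lspec)
    recs = aggregate(res.links, lspec)
    assert len(recs) == 5 * 1 * 3
    assert all(r.value == 7.25 for r in recs)


def test_flagged_records_stay_in_graph_but_leave_csv(tmp_path):
    d = days_before(dt.date(2021, 3, 20), 2)
    link = make_link({x: 1.0 for x in d}, window_days=10)
    spec = LinkageSpec(agg_functions=("mean",), window_days=10,
                       min_coverage=0.5, exclude_low_coverage=True)
    recs = aggregate([link], spec)
    assert recs[0].flagged
    res = LinkageResult(links=[link])
    paths = export_bundle(recs, res, [], run_md(), tmp_path, spec)
    assert len(pd.read_csv(paths["csv"])) == 0  # excluded from the table
    g = Graph().parse(paths["ttl"], format="turtle")
    low = [o for s, p, o in g if str(p).endswith("lowCoverage")]
    assert low  # quality annotation kept in the graph
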