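"""Aggregate linked observations into exposure records and export them.

Aggregation order is fixed: *spatial first* — observations from multiple
sources on the same day are averaged into one daily value — *then
temporal*, applying each aggregation function over the daily series.
The order matters for nonlinear statistics (min/max/sd) and is therefore
pinned and documented rather than configurable.

Coverage is the fraction of window dates with at least one observation
from the assigned sources. Records under ``min_coverage`` are flagged;
they stay in the RDF graph with a quality annotation and are excluded
from the CSV analysis table only when the spec asks for it.

The export bundle is the tool's three-format contract: an analysis table
(CSV), a linked-data graph (Turtle; exposure records as derived QB
observations plus the full metadata graph), and a self-contained HTML
report — plus the skip-log CSV.
"""
from __future__ import annotations

import datetime as dt
import html
import math
from pathlib import Path

import numpy as np
import pandas as pd
from rdflib import RDF, XSD, Graph, Literal

from .errors import EnvLinkError
from .kg import (
    PROV,
    QB,
    SDMX_DIM,
    canonical_turtle,
    dataset_iri,
    decimal_literal,
    measure_iri,
    merge_graphs,
    mint_iri,
    new_graph,
)
from .linkage import DEFAULT_BASE, LinkageResult, LinkedEvent
from .types import ExposureRecord, LinkageSpec, MetadataBundle

CSV_COLUMNS = [
    "event_id",
    "dataset_id",
    "variable",
    "window_start",
    "window_end",
    "agg",
    "value",
    "coverage",
    "n_sources",
]


def _daily_series(rows: pd.DataFrame) -> pd.Series:
    """Per-day mean over sources (the spatial step)."""
    return rows.groupby("date")["value"].mean()


def _apply(fn: str, daily: pd.Series) -> float:
    if fn == "mean":
        return float(daily.mean())
    if fn == "min":
        return float(daily.min())
    if fn == "max":
        return float(daily.max())
    if fn == "sum":
        return float(daily.sum())
    if fn == "count":
        return float(daily.size)
    if fn == "sd":
        return float(daily.std(ddof=1)) if daily.size > 1 else float("nan")
    raise EnvLinkError(f"unknown aggregation function {fn!r}")


def aggregate(
    links: list[LinkedEvent],
    spec: LinkageSpec,
    dataset_variables: dict[str, list[str]] | None = None,
) -> list[ExposureRecord]:
    """Aggregate raw linked rows into one exposure record per group.

    window level: one record per event x dataset x variable x function.
    daily level: one record per event x dataset x variable x observed
    window date (emitted as a one-day window with agg "daily_mean").

    When ``dataset_variables`` names the variables each dataset should
    report, a variable with zero observed dates still yields a record —
    coverage 0, missing value, flagged — so the analysis table accounts
    for every expected exposure.
    """
    records: list[ExposureRecord] = []
    for le in links:
        n_window = le.window.window_days
        groups = {str(k): v for k, v in le.rows.groupby("variable", sort=True)}
        expected = (
            dataset_variables.get(le.dataset_id, sorted(groups))
            if dataset_variables
            else sorted(groups)
        )
        empty = le.rows.iloc[0:0]
        for var in expected:
            var_rows = groups.get(var, empty)
            if var_rows.empty and spec.agg_level == "window":
                for fn in spec.agg_functions:
                    records.append(
                        ExposureRecord(
                            event_id=le.event_id,
                            dataset_id=le.dataset_id,
                            variable=var,
                            window_start=le.window.start_date,
                            window_end_exclusive=le.window.end_date_exclusive,
                            agg_function=fn,
                            value=float("nan"),
                            coverage=0.0,
                            n_sources=0,
                            source_ids=[],
                            flagged=True,
                        )
                    )
                continue
            if var_rows.empty:
                continue
            daily = _daily_series(var_rows)
            coverage = len(daily) / n_window
            flagged = coverage < spec.min_coverage
            used_sources = sorted(var_rows["source_id"].unique())
            if spec.agg_level == "daily":
                for date, value in daily.items():
                    records.append(
                        ExposureRecord(
                            event_id=le.event_id,
                            dataset_id=le.dataset_id,
                            variable=str(var),
                            window_start=date,
                            window_end_exclusive=date + dt.timedelta(days=1),
                            agg_function="daily_mean",
                            value=float(value),
                            coverage=1.0,
                            n_sources=int(var_rows[var_rows["date"] == date]["source_id"].nunique()),
                            source_ids=used_sources,
                            flagged=flagged,
                        )
                    )
                continue
            for fn in spec.agg_functions:
                value = _apply(fn, daily) if len(daily) else float("nan")
                records.append(
                    ExposureRecord(
                        event_id=le.event_id,
                        dataset_id=le.dataset_id,
                        variable=str(var),
                        window_start=le.window.start_date,
                        window_end_exclusive=le.window.end_date_exclusive,
                        agg_function=fn,
                        value=value,
                        coverage=coverage,
                        n_sources=len(used_sources),
                        source_ids=used_sources,
                        flagged=flagged,
                    )
                )
    return records


def records_frame(records: list[ExposureRecord]) -> pd.DataFrame:
    rows = [
        {
            "event_id": r.event_id,
            "dataset_id": r.dataset_id,
            "variable": r.variable,
            "window_start": r.window_start.isoformat(),
            "window_end": r.window_end_exclusive.isoformat(),
            "agg": r.agg_function,
            "value": "" if math.isnan(r.value) else np.format_float_positional(r.value, unique=True, trim="0"),
            "coverage": np.format_float_positional(r.coverage, unique=True, trim="0"),
            "n_sources": r.n_sources,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df.sort_values(
        ["event_id", "dataset_id", "variable", "window_start", "agg"]
    ).reset_index(drop=True)


def uplift_records(records: list[ExposureRecord], base: str, linked_id: str) -> Graph:
    """Exposure records as derived QB observations in the linked dataset."""
    g = new_graph()
    ds_iri = dataset_iri(base, linked_id)
    g.add((ds_iri, RDF.type, QB.DataSet))
    quality = mint_iri(base, ["def", "coverage"])
    low = mint_iri(base, ["def", "lowCoverage"])
    for r in records:
        obs = mint_iri(
            base,
            [
                "linked-obs",
                r.event_id,
                r.dataset_id,
                r.variable,
                r.window_start.isoformat(),
                r.agg_function,
            ],
        )
        g.add((obs, RDF.type, QB.Observation))
        g.add((obs, QB.dataSet, ds_iri))
        g.add((obs, SDMX_DIM.refPeriod, Literal(r.window_start.isoformat(), datatype=XSD.date)))
        g.add((obs, mint_iri(base, ["def", "event"]), mint_iri(base, ["event", r.event_id])))
        if not math.isnan(r.value):
            g.add((obs, measure_iri(base, f"{r.variable}_{r.agg_function}"), decimal_literal(r.value)))
        g.add((obs, quality, decimal_literal(r.coverage)))
        if r.flagged:
            g.add((obs, low, Literal(True)))
        g.add((obs, PROV.wasDerivedFrom, dataset_iri(base, r.dataset_id)))
    return g


# -------------------------------------------------------------- reporting


_PAGE = """<!DOCTYPE html>
<html lang="en"><head><meta charset="utf-8">
<title>{title}</title>
<style>
body {{ font-family: system-ui, sans-serif; margin: 2rem auto; max-width: 70rem; color: #222; }}
h1, h2 {{ color: #124; }}
table {{ border-collapse: collapse; margin: 1rem 0; font-size: 0.9rem; }}
th, td {{ border: 1px solid #bbb; padding: 0.25rem 0.6rem; text-align: left; }}
th {{ background: #eef; }}
.summary dt {{ font-weight: 600; }}
</style></head><body>
<h1>{title}</h1>
<dl class="summary">{summary}</dl>
<h2>Per-event exposure windows</h2>
{windows}
<h2>Linked exposures</h2>
{exposures}
<h2>Coverage</h2>
{coverage}
<h2>Skipped event-dataset pairs</h2>
{skips}
</body></html>
"""


def _table(df: pd.DataFrame, max_rows: int = 500) -> str:
    if df.empty:
        return "<p>none</p>"
    shown = df.head(max_rows)
    head = "".join(f"<th>{html.escape(str(c))}</th>" for c in shown.columns)
    body = "".join(
        "<tr>" + "".join(f"<td>{html.escape(str(v))}</td>" for v in row) + "</tr>"
        for row in shown.itertuples(index=False)
    )
    note = (
        f"<p>(first {max_rows} of {len(df)} rows)</p>" if len(df) > max_rows else ""
    )
    return f"<table><tr>{head}</tr>{body}</table>{note}"


def render_report(
    records: list[ExposureRecord],
    result: LinkageResult,
    spec: LinkageSpec,
    md: MetadataBundle | None,
) -> str:
    """Self-contained (inline-styled, no external assets) HTML report."""
    df = records_frame(records)
    windows = pd.DataFrame(
        [
            {
                "event_id": le.event_id,
                "dataset_id": le.dataset_id,
                "window_start": le.window.start_date.isoformat(),
                "window_end_exclusive": le.window.end_date_exclusive.isoformat(),
                "n_sources": len(le.context.sources),
                "sources": ", ".join(le.context.source_ids[:8]),
            }
            for le in result.links
        ]
    )
    coverages = [r.coverage for r in records]
    cov = pd.DataFrame(
        [
            {
                "records": len(records),
                "flagged_low_coverage": sum(r.flagged for r in records),
                "mean_coverage": round(float(np.mean(coverages)), 4) if coverages else "",
                "min_coverage": round(float(np.min(coverages)), 4) if coverages else "",
            }
        ]
    )
    summary_items = {
        "Events linked": len({le.event_id for le in result.links}),
        "Event-dataset pairs linked": len(result.links),
        "Pairs skipped": len(result.skips),
        "Spatial method": spec.spatial_method,
        "Window": f"{spec.window_days} days, lag {spec.lag_days} days, event day excluded",
        "Aggregation": f"{spec.agg_level}: {', '.join(spec.agg_functions)}",
    }
    if md is not None:
        summary_items["Run"] = f"{md.title} (version {md.version})"
    summary = "".join(
        f"<dt>{html.escape(str(k))}</dt><dd>{html.escape(str(v))}</dd>"
        for k, v in summary_items.items()
    )
    return _PAGE.format(
        title="Environment-health linkage report",
        summary=summary,
        windows=_table(windows),
        exposures=_table(df),
        coverage=_table(cov),
        skips=_table(result.skip_log),
    )


def export_bundle(
    records: list[ExposureRecord],
    result: LinkageResult,
    graphs: list[Graph],
    run_md: MetadataBundle,
    out_dir: str | Path,
    spec: LinkageSpec,
    base: str = DEFAULT_BASE,
    linked_id: str = "linked",
) -> dict[str, Path]:
    """Write the export triad plus the skip log; deterministic for fixed inputs.

    Files: ``linked_data.csv`` (analysis table), ``linked_data.ttl``
    (derived QB observations + full metadata graph), ``report.html``,
    ``skip_log.csv``. Flagged records are dropped from the CSV only when
    ``spec.exclude_low_coverage`` is set; the graph always keeps them.
    """
    out_dir = Path(out_dir)
    if not records and result.skip_log.empty:
        raise EnvLinkError("nothing to export: no records and no skip log")
    out_dir.mkdir(parents=True, exist_ok=True)
    if not out_dir.is_dir():
        raise OSError(f"not a writable directory: {out_dir}")

    csv_records = [
        r for r in records if not (spec.exclude_low_coverage and r.flagged)
    ]
    frame = records_frame(csv_records)
    from .kg import build_metadata_graph

    graph = merge_graphs(
        uplift_records(records, base, linked_id),
        build_metadata_graph(run_md, base),
        *graphs,
    )

    paths = {
        "csv": out_dir / "linked_data.csv",
        "ttl": out_dir / "linked_data.ttl",
        "html": out_dir / "report.html",
        "skip_log": out_dir / "skip_log.csv",
    }
    frame.to_csv(paths["csv"], index=False, lineterminator="\n")
    paths["ttl"].write_text(canonical_turtle(graph), encoding="utf-8")
    paths["html"].write_text(
        render_report(records, result, spec, run_md), encoding="utf-8"
    )
    result.skip_log.to_csv(paths["skip_log"], index=False, lineterminator="\n")
    return paths
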