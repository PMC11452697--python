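"""End-to-end run driver: read -> uplift -> link -> aggregate -> export.

A run is fully described by one config mapping (usually loaded from a
YAML file) so it can be reproduced from a single artifact. The CLI is a
thin wrapper over :func:`run`; there is no CLI-only behaviour.

Provenance timestamps in the exported metadata graph are *logical*: they
are derived from the run seed and the data's temporal extent rather than
the wall clock, so identical runs export byte-identical Turtle. The wall
clock of the actual execution is written to ``run_summary.json`` instead.
"""
from __future__ import annotations

import datetime as dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as eio
from .aggregate import aggregate, export_bundle
from .errors import ConfigurationError, EnvLinkError
from .kg import uplift_dataset
from .linkage import (
    DEFAULT_BASE,
    LinkageResult,
    bind_query_template,
    build_query_template,
    link_predicate,
    temporal_window,
)
from .types import (
    Activity,
    Agent,
    EnvDatasetGrid,
    LinkageSpec,
    MetadataBundle,
)

log = logging.getLogger("envlink")

VALID_KEYS = {
    "datasets",
    "events",
    "areas",
    "areas_format",
    "linkage",
    "base_iri",
    "output_dir",
    "seed",
    "metadata",
    "rename",
    "backend",
}

LINKAGE_KEYS = {
    "spatial_method",
    "buffer_km",
    "lag_days",
    "window_days",
    "agg_functions",
    "agg_level",
    "min_coverage",
    "exclude_low_coverage",
}


@dataclass
class RunConfig:
    """Validated run configuration (see VALID_KEYS for the file schema)."""

    datasets: list[dict]
    events: str
    spec: LinkageSpec
    areas: str | None = None
    areas_format: str | None = None
    base_iri: str = DEFAULT_BASE
    output_dir: str = "out"
    seed: int = 0
    metadata: dict = field(default_factory=dict)
    rename: dict = field(default_factory=dict)
    backend: str = "direct"


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(raw) - VALID_KEYS
    if unknown:
        raise ConfigurationError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(VALID_KEYS)}"
        )
    for key in ("datasets", "events"):
        if key not in raw:
            raise ConfigurationError(f"config is missing required key {key!r}")
    linkage_raw = raw.get("linkage", {})
    bad = set(linkage_raw) - LINKAGE_KEYS
    if bad:
        raise ConfigurationError(
            f"unknown linkage keys {sorted(bad)}; valid keys: {sorted(LINKAGE_KEYS)}"
        )
    spec = LinkageSpec(**linkage_raw)
    cfg = RunConfig(
        datasets=raw["datasets"],
        events=raw["events"],
        spec=spec,
        areas=raw.get("areas"),
        areas_format=raw.get("areas_format"),
        base_iri=raw.get("base_iri", DEFAULT_BASE),
        output_dir=raw.get("output_dir", "out"),
        seed=int(raw.get("seed", 0)),
        metadata=raw.get("metadata", {}),
        rename=raw.get("rename", {}),
        backend=raw.get("backend", "direct"),
    )
    base_dir = Path(path).parent
    for entry in cfg.datasets:
        if "path" not in entry:
            raise ConfigurationError("every datasets entry needs a 'path'")
        entry["path"] = str((base_dir / entry["path"]).resolve()) if not Path(entry["path"]).is_absolute() else entry["path"]
        if not Path(entry["path"]).exists():
            raise ConfigurationError(f"dataset path does not exist: {entry['path']}")
    for attr in ("events", "areas"):
        val = getattr(cfg, attr)
        if val is not None:
            p = Path(val) if Path(val).is_absolute() else (base_dir / val)
            if not p.exists():
                raise ConfigurationError(f"config key {attr!r}: path does not exist: {p}")
            setattr(cfg, attr, str(p))
    return cfg


def _metadata_bundle(cfg: RunConfig, datasets, events) -> MetadataBundle:
    md = cfg.metadata
    all_dates = [d for ds in datasets for d in ds.date_range]
    start, end = (min(all_dates), max(all_dates)) if all_dates else (
        dt.date(1970, 1, 1), dt.date(1970, 1, 1))
    bbox = _spatial_extent(datasets)
    # logical activity time: reproducible across identical runs
    logical = dt.datetime.combine(end, dt.time()) + dt.timedelta(seconds=cfg.seed % 86400)
    agents = [Agent(a["name"], a.get("role", "researcher")) for a in md.get("agents", [])]
    if not agents:
        agents = [Agent("envlink", "software")]
    return MetadataBundle(
        title=md.get("title", "Linked event-environment exposures"),
        licence=md.get("licence"),
        version=md.get("version", "1.0"),
        temporal_extent=(start, end),
        spatial_extent=bbox,
        distribution_url=md.get("distribution_url", "file://linked_data.ttl"),
        agents=agents,
        activity=Activity(
            started=logical,
            ended=logical,
            used=[ds.dataset_id for ds in datasets],
            generated="linked",
        ),
    )


def _spatial_extent(datasets):
    lons, lats = [], []
    for ds in datasets:
        if isinstance(ds, EnvDatasetGrid):
            lons += [float(ds.lon_axis[0]), float(ds.lon_axis[-1] + ds.dlon)]
            lats += [float(ds.lat_axis[0]), float(ds.lat_axis[-1] + ds.dlat)]
        else:
            lons += [s.lon for s in ds.stations]
            lats += [s.lat for s in ds.stations]
    if not lons:
        return "unknown"
    return (min(lons), min(lats), max(lons), max(lats))


def _read_inputs(cfg: RunConfig):
    datasets = []
    for entry in cfg.datasets:
        datasets.append(
            eio.read_env_dataset(
                entry["path"],
                format=entry.get("format"),
                schema=entry.get("schema"),
                dataset_id=entry.get("dataset_id"),
            )
        )
    areas = eio.read_areas(cfg.areas, cfg.areas_format) if cfg.areas else []
    events = eio.read_events(cfg.events)
    return datasets, areas, events


def dry_run(cfg: RunConfig) -> str:
    """Validate config and inputs, return the bound query template."""
    datasets, areas, events = _read_inputs(cfg)
    template = build_query_template(cfg.spec)
    if events and datasets:
        from .kg import dataset_iri, mint_iri

        window = temporal_window(
            events[0].event_date, cfg.spec.lag_days, cfg.spec.window_days
        )
        return bind_query_template(
            template,
            mint_iri(cfg.base_iri, ["event", events[0].event_id]),
            dataset_iri(cfg.base_iri, datasets[0].dataset_id),
            window,
            link_predicate(cfg.base_iri),
        )
    return template


def run(
    config: RunConfig | str | Path,
    output_dir: str | Path | None = None,
) -> dict:
    """Execute the full pipeline; returns a run summary dict.

    Skipped events are data (reported in the skip log), not failures;
    validation errors raise. On a stage failure any partial outputs are
    removed.
    """
    t0 = time.time()
    cfg = config if isinstance(config, RunConfig) else load_config(config)
    out_dir = Path(output_dir or cfg.output_dir)
    from .linkage import link_events

    stage = "read"
    try:
        datasets, areas, events = _read_inputs(cfg)
        log.info("read: %d datasets, %d areas, %d events",
                 len(datasets), len(areas), len(events))

        stage = "uplift"
        graphs = None
        n_triples = 0
        if cfg.backend == "graph":
            graphs = {ds.dataset_id: uplift_dataset(ds, areas, cfg.base_iri) for ds in datasets}
            n_triples = sum(len(g) for g in graphs.values())
            log.info("uplift: %d triples over %d dataset graphs", n_triples, len(graphs))

        stage = "link"
        result = link_events(
            events, datasets, areas, cfg.spec,
            rename=cfg.rename or None, backend=cfg.backend,
            base=cfg.base_iri, graphs=graphs,
        )
        log.info("link: %d pairs linked, %d skipped", len(result.links), len(result.skips))

        stage = "aggregate"
        renames = cfg.rename or {}
        dataset_variables = {
            ds.dataset_id: sorted(
                renames.get(ds.dataset_id, {}).get(v.name, v.name)
                for v in ds.variables
            )
            for ds in datasets
        }
        records = aggregate(result.links, cfg.spec, dataset_variables)
        log.info("aggregate: %d exposure records", len(records))

        stage = "export"
        run_md = _metadata_bundle(cfg, datasets, events)
        paths = export_bundle(
            records, result, [], run_md, out_dir, cfg.spec, base=cfg.base_iri
        )
    except EnvLinkError as exc:
        _cleanup_partial(out_dir)
        raise EnvLinkError(f"stage {stage!r} failed: {exc}") from exc

    summary = {
        "seed": cfg.seed,
        "backend": cfg.backend,
        "n_datasets": len(datasets),
        "n_events": len(events),
        "n_linked_pairs": len(result.links),
        "n_skipped_pairs": len(result.skips),
        "n_records": len(records),
        "n_uplift_triples": n_triples,
        "outputs": {k: str(v) for k, v in paths.items()},
        "wall_seconds": round(time.time() - t0, 3),
    }
    (out_dir / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return summary


def _cleanup_partial(out_dir: Path) -> None:
    for name in ("linked_data.csv", "linked_data.ttl", "report.html",
                 "skip_log.csv", "run_summary.json"):
        p = Path(out_dir) / name
        if p.exists():
            p.unlink()
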