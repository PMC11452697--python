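"""Semantic uplift to a standards-based observation knowledge graph.

Environmental datasets become RDF Data Cube (QB) datasets: one
``qb:Observation`` node per (location, date, variable) with a non-missing
value, carrying exactly five triples — type, dataset membership, a time
dimension (``sdmx-dimension:refPeriod``, xsd:date), a location dimension
(``sdmx-dimension:refArea``, the station/cell/area IRI) and one measure
literal (xsd:decimal). Structural triples describe the data-structure
definition, component specifications, measure properties with units, and
source geometries as GeoSPARQL WKT literals (CRS84, lon/lat order).

Run metadata becomes a DCAT catalog record, a PROV-O activity with its
agents, and an ODRL policy for data-use terms.

The uplift is a direct programmatic mapping; the QB target shape is the
contract. Serialization is canonicalized (sorted triples, fixed prefix
table) so output is byte-reproducible.
"""
from __future__ import annotations

from urllib.parse import quote

import numpy as np
from rdflib import RDF, RDFS, XSD, Graph, Literal, Namespace, URIRef

from .errors import EnvLinkError, UpliftError
from .types import (
    AdminArea,
    EnvDataset,
    EnvDatasetGrid,
    EnvDatasetStations,
    MetadataBundle,
)

QB = Namespace("http://purl.org/linked-data/cube#")
SDMX_DIM = Namespace("http://purl.org/linked-data/sdmx/2009/dimension#")
SDMX_ATTR = Namespace("http://purl.org/linked-data/sdmx/2009/attribute#")
GEO = Namespace("http://www.opengis.net/ont/geosparql#")
PROV = Namespace("http://www.w3.org/ns/prov#")
DCAT = Namespace("http://www.w3.org/ns/dcat#")
DCT = Namespace("http://purl.org/dc/terms/")
ODRL = Namespace("http://www.w3.org/ns/odrl/2/")

#: Fixed prefix table used by the canonical Turtle writer.
NAMESPACES: dict[str, Namespace] = {
    "qb": QB,
    "sdmx-dimension": SDMX_DIM,
    "sdmx-attribute": SDMX_ATTR,
    "geo": GEO,
    "prov": PROV,
    "dcat": DCAT,
    "dcterms": DCT,
    "odrl": ODRL,
    "rdf": Namespace(str(RDF)),
    "rdfs": Namespace(str(RDFS)),
    "xsd": Namespace(str(XSD)),
}

CRS84 = "<http://www.opengis.net/def/crs/OGC/1.3/CRS84>"


def new_graph() -> Graph:
    g = Graph()
    for prefix, ns in NAMESPACES.items():
        g.bind(prefix, ns)
    return g


def mint_iri(base: str, parts: list[str]) -> URIRef:
    """Deterministically mint an IRI: base joined with percent-encoded parts.

    Same inputs always give the same IRI; spaces and reserved characters
    are percent-encoded so the result is an absolute, valid IRI.
    """
    if not base or "://" not in base:
        raise EnvLinkError(f"base IRI must be absolute, got {base!r}")
    if not parts:
        raise EnvLinkError("parts must be non-empty")
    if any(p == "" for p in parts):
        raise EnvLinkError("empty IRI part")
    encoded = [quote(str(p), safe="") for p in parts]
    return URIRef(base.rstrip("/") + "/" + "/".join(encoded))


def decimal_literal(value: float) -> Literal:
    """xsd:decimal literal at round-trip-safe precision.

    Positional (no-exponent) shortest representation that parses back to
    the identical float — xsd:decimal forbids exponent notation.
    """
    text = np.format_float_positional(float(value), unique=True, trim="0")
    return Literal(text, datatype=XSD.decimal)


def dataset_iri(base: str, dataset_id: str) -> URIRef:
    return mint_iri(base, ["dataset", dataset_id])


def source_iri(base: str, kind: str, source_id: str) -> URIRef:
    return mint_iri(base, [kind, source_id])


def measure_iri(base: str, variable: str) -> URIRef:
    return mint_iri(base, ["measure", variable])


def _wkt_point(lon: float, lat: float) -> Literal:
    return Literal(f"{CRS84} POINT ({lon!r} {lat!r})", datatype=GEO.wktLiteral)


def _add_source_geometry(
    g: Graph, base: str, src: URIRef, label: str, wkt: Literal
) -> None:
    geom = URIRef(str(src) + "/geometry")
    g.add((src, RDF.type, GEO.Feature))
    g.add((src, RDFS.label, Literal(label)))
    g.add((src, GEO.hasGeometry, geom))
    g.add((geom, RDF.type, GEO.Geometry))
    g.add((geom, GEO.asWKT, wkt))


def _add_structure(g: Graph, base: str, ds: EnvDataset) -> URIRef:
    ds_iri = dataset_iri(base, ds.dataset_id)
    dsd = URIRef(str(ds_iri) + "/structure")
    g.add((ds_iri, RDF.type, QB.DataSet))
    g.add((ds_iri, DCT.identifier, Literal(ds.dataset_id)))
    g.add((ds_iri, QB.structure, dsd))
    g.add((dsd, RDF.type, QB.DataStructureDefinition))
    for dim in (SDMX_DIM.refPeriod, SDMX_DIM.refArea):
        comp = URIRef(str(dsd) + "/component/" + str(dim).rsplit("#", 1)[-1])
        g.add((dsd, QB.component, comp))
        g.add((comp, RDF.type, QB.ComponentSpecification))
        g.add((comp, QB.dimension, dim))
        g.add((dim, RDF.type, QB.DimensionProperty))
    for var in ds.variables:
        m = measure_iri(base, var.name)
        comp = URIRef(str(dsd) + "/component/measure-" + quote(var.name, safe=""))
        g.add((dsd, QB.component, comp))
        g.add((comp, RDF.type, QB.ComponentSpecification))
        g.add((comp, QB.measure, m))
        g.add((m, RDF.type, QB.MeasureProperty))
        g.add((m, RDFS.label, Literal(var.name)))
        if var.unit:
            g.add((m, SDMX_ATTR.unitMeasure, Literal(var.unit)))
        if var.definition:
            g.add((m, RDFS.comment, Literal(var.definition)))
    return ds_iri


def _grid_cell_wkt(ds: EnvDatasetGrid, cell_id: str) -> Literal:
    lon, lat = ds.cell_origin(cell_id)
    dlon, dlat = ds.dlon, ds.dlat
    ring = (
        f"({lon!r} {lat!r}, {lon + dlon!r} {lat!r}, "
        f"{lon + dlon!r} {lat + dlat!r}, {lon!r} {lat + dlat!r}, {lon!r} {lat!r})"
    )
    return Literal(f"{CRS84} POLYGON ({ring})", datatype=GEO.wktLiteral)


def uplift_dataset(
    ds: EnvDataset, areas: list[AdminArea] | None, base: str
) -> Graph:
    """Uplift a validated dataset to its QB observation graph.

    Emits exactly 5 triples per non-missing observation plus the
    structural set (dataset node, DSD, components, measures, geometries).
    """
    g = new_graph()
    ds_iri = _add_structure(g, base, ds)
    obs_table = ds.obs_table()

    source_kind = "cell" if isinstance(ds, EnvDatasetGrid) else "station"
    for sid in sorted(obs_table["source_id"].unique()):
        src = source_iri(base, source_kind, sid)
        if isinstance(ds, EnvDatasetGrid):
            wkt = _grid_cell_wkt(ds, sid)
        else:
            st = ds.station(sid)
            wkt = _wkt_point(st.lon, st.lat)
        _add_source_geometry(g, base, src, sid, wkt)

    area_by_id = {a.area_id: a for a in areas or []}
    referenced_areas = set()
    for row in obs_table.itertuples(index=False):
        obs = mint_iri(
            base,
            ["obs", ds.dataset_id, row.source_id, row.date.isoformat(), row.variable],
        )
        src = source_iri(base, source_kind, row.source_id)
        g.add((obs, RDF.type, QB.Observation))
        g.add((obs, QB.dataSet, ds_iri))
        g.add((obs, SDMX_DIM.refPeriod, Literal(row.date.isoformat(), datatype=XSD.date)))
        g.add((obs, SDMX_DIM.refArea, src))
        g.add((obs, measure_iri(base, row.variable), decimal_literal(row.value)))
    for aid in sorted(referenced_areas):
        if aid not in area_by_id:
            raise UpliftError(f"missing geometry for referenced area {aid!r}")
    return g


def observation_tuples(g: Graph, base: str, dataset_id: str) -> list[tuple]:
    """Query back all (source_id, iso date, variable, value) tuples.

    The inverse of :func:`uplift_dataset`'s observation mapping; used for
    the exact round-trip contract.
    """
    q = """
        SELECT ?src ?date ?var ?value WHERE {
            ?obs a qb:Observation ;
                 qb:dataSet ?ds ;
                 sdmx-dimension:refArea ?srcNode ;
                 sdmx-dimension:refPeriod ?date ;
                 ?measure ?value .
            ?measure a qb:MeasureProperty ; rdfs:label ?var .
            ?srcNode rdfs:label ?src .
        }
    """
    ds_iri = dataset_iri(base, dataset_id)
    rows = []
    for src, date, var, value in g.query(
        q, initNs={"qb": QB, "sdmx-dimension": SDMX_DIM, "rdfs": RDFS},
        initBindings={"ds": ds_iri},
    ):
        rows.append((str(src), str(date), str(var), float(value)))
    return sorted(rows)


def count_observation_triples(g: Graph) -> int:
    """Number of triples attached to observation nodes (5 per observation)."""
    obs_nodes = set(g.subjects(RDF.type, QB.Observation))
    return sum(1 for s, p, o in g if s in obs_nodes)


def build_metadata_graph(md: MetadataBundle, base: str) -> Graph:
    """Build the DCAT + PROV-O + ODRL metadata graph for a run.

    The catalogued dataset is the activity's generated output; every used
    input gets a ``prov:used`` link from the activity.
    """
    g = new_graph()
    ds_iri = dataset_iri(base, md.activity.generated)
    g.add((ds_iri, RDF.type, DCAT.Dataset))
    g.add((ds_iri, DCT.title, Literal(md.title)))
    g.add((ds_iri, DCAT.version, Literal(md.version)))
    if md.licence:
        if md.licence.startswith("http"):
            g.add((ds_iri, DCT.license, URIRef(md.licence)))
        else:
            g.add((ds_iri, DCT.license, Literal(md.licence)))
    policy = URIRef(str(ds_iri) + "/policy")
    g.add((ds_iri, ODRL.hasPolicy, policy))
    g.add((policy, RDF.type, ODRL.Policy))
    g.add((policy, ODRL.target, ds_iri))
    if md.licence:
        perm = URIRef(str(policy) + "/permission")
        g.add((policy, ODRL.permission, perm))
        g.add((perm, ODRL.action, ODRL.use))
    else:
        # open rights statement: recorded, not fatal
        g.add(
            (policy, RDFS.comment,
             Literal("No licence supplied; rights are unspecified and remain open."))
        )
    start, end = md.temporal_extent
    period = URIRef(str(ds_iri) + "/temporal")
    g.add((ds_iri, DCT.temporal, period))
    g.add((period, RDF.type, DCT.PeriodOfTime))
    g.add((period, DCAT.startDate, Literal(start.isoformat(), datatype=XSD.date)))
    g.add((period, DCAT.endDate, Literal(end.isoformat(), datatype=XSD.date)))
    if isinstance(md.spatial_extent, str):
        g.add((ds_iri, DCT.spatial, Literal(md.spatial_extent)))
    else:
        lon0, lat0, lon1, lat1 = md.spatial_extent
        bbox = (
            f"{CRS84} POLYGON (({lon0!r} {lat0!r}, {lon1!r} {lat0!r}, "
            f"{lon1!r} {lat1!r}, {lon0!r} {lat1!r}, {lon0!r} {lat0!r}))"
        )
        geom = URIRef(str(ds_iri) + "/extent")
        g.add((ds_iri, DCT.spatial, geom))
        g.add((geom, RDF.type, GEO.Geometry))
        g.add((geom, GEO.asWKT, Literal(bbox, datatype=GEO.wktLiteral)))
    dist = URIRef(str(ds_iri) + "/distribution")
    g.add((ds_iri, DCAT.distribution, dist))
    g.add((dist, RDF.type, DCAT.Distribution))
    g.add((dist, DCAT.downloadURL, Literal(md.distribution_url, datatype=XSD.anyURI)))

    act = URIRef(str(ds_iri) + "/activity")
    g.add((act, RDF.type, PROV.Activity))
    g.add((act, PROV.startedAtTime,
           Literal(md.activity.started.isoformat(), datatype=XSD.dateTime)))
    g.add((act, PROV.endedAtTime,
           Literal(md.activity.ended.isoformat(), datatype=XSD.dateTime)))
    for used_id in md.activity.used:
        g.add((act, PROV.used, dataset_iri(base, used_id)))
    g.add((act, PROV.generated, ds_iri))
    g.add((ds_iri, PROV.wasGeneratedBy, act))

    role_class = {
        "researcher": PROV.Person,
        "software": PROV.SoftwareAgent,
        "entity": PROV.Organization,
    }
    for agent in md.agents:
        a_iri = mint_iri(base, ["agent", agent.name])
        g.add((a_iri, RDF.type, PROV.Agent))
        g.add((a_iri, RDF.type, role_class.get(agent.role, PROV.Agent)))
        g.add((a_iri, RDFS.label, Literal(agent.name)))
        g.add((a_iri, DCT.type, Literal(agent.role)))
        g.add((act, PROV.wasAssociatedWith, a_iri))
    return g


def _term_n3(term, ns_items: list[tuple[str, str]]) -> str:
    if isinstance(term, URIRef):
        s = str(term)
        for prefix, ns in ns_items:
            if s.startswith(ns):
                local = s[len(ns):]
                if local and all(c.isalnum() or c in "-_." for c in local):
                    return f"{prefix}:{local}"
        return f"<{s}>"
    return term.n3()


def canonical_turtle(*graphs: Graph) -> str:
    """Serialize one or more graphs as canonical Turtle.

    Triples of the union are sorted and written one per line with the
    fixed prefix table, so equal graphs always serialize byte-identically.
    """
    ns_items = sorted(
        ((p, str(ns)) for p, ns in NAMESPACES.items()),
        key=lambda kv: -len(kv[1]),
    )
    triples = set()
    for g in graphs:
        triples.update(g)
    lines = sorted(
        f"{_term_n3(s, ns_items)} {_term_n3(p, ns_items)} {_term_n3(o, ns_items)} ."
        for s, p, o in triples
    )
    header = [f"@prefix {p}: <{ns}> ." for p, ns in sorted(NAMESPACES.items(), key=lambda kv: kv[0])]
    return "\n".join(header) + "\n\n" + "\n".join(lines) + "\n"


def merge_graphs(*graphs: Graph) -> Graph:
    out = new_graph()
    for g in graphs:
        for t in g:
            out.add(t)
    return out
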