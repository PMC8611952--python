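"""Property-graph bundle and export.

The pharmacology network is a labelled property graph: molecules, compound
names, assay results, targets, species-agnostic protein entries, protein
classes, scaffolds, annotation terms and morphology descriptors as nodes,
with a fixed vocabulary of relationship types between them.  The bundle is
an in-memory, storage-agnostic representation; export writes either a
single GraphML document or a set of bulk-import CSV files (one node file
per label, one edge file per relationship type) that a graph database can
ingest.  No database server is involved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import networkx as nx
import pandas as pd

NODE_LABELS = (
    "Molecule",
    "CompoundName",
    "Result",
    "AssayParameter",
    "Target",
    "UniprotInter",
    "ProteinClass",
    "Scaffold",
    "GO",
    "KEGG",
    "DO",
    "CellDesc",
    "NuclDesc",
    "CytoDesc",
)

RELATION_TYPES = (
    "actifConf9",
    "memberOf",
    "actIn",
    "hasScaffold",
    "parentScaffold",
    "hasResult",
    "hasName",
    "hasMorph",
    "hasParameter",
    "onTarget",
    "isUI",
)


class GraphValidationError(ValueError):
    """The bundle violates a structural invariant (checked before writing)."""


def node_id(label: str, raw_id: str) -> str:
    """Namespace a raw identifier by its label.

    Prevents collisions between, say, a molecule and a scaffold that share
    a raw id in their respective source tables.
    """
    return f"{label}:{raw_id}"


@dataclass
class GraphBundle:
    """Nodes and edges of the pharmacology network.

    ``nodes``: (node_id, label, properties); ``edges``: (source_id,
    target_id, relation_type, properties).  Node ids are already
    namespaced by label (see :func:`node_id`).
    """

    nodes: list[tuple[str, str, dict[str, Any]]] = field(default_factory=list)
    edges: list[tuple[str, str, str, dict[str, Any]]] = field(default_factory=list)

    def add_node(self, label: str, raw_id: str, **properties: Any) -> str:
        nid = node_id(label, raw_id)
        self.nodes.append((nid, label, properties))
        return nid

    def add_edge(self, source: str, target: str, relation: str, **properties: Any) -> None:
        self.edges.append((source, target, relation, properties))

    def validate(self) -> None:
        seen: set[str] = set()
        for nid, label, _ in self.nodes:
            if label not in NODE_LABELS:
                raise GraphValidationError(f"unknown node label {label!r}")
            if nid in seen:
                raise GraphValidationError(f"duplicate node id {nid!r}")
            seen.add(nid)
        triples: set[tuple[str, str, str]] = set()
        for src, dst, rel, _ in self.edges:
            if rel not in RELATION_TYPES:
                raise GraphValidationError(f"unknown relation type {rel!r}")
            if src not in seen or dst not in seen:
                raise GraphValidationError(
                    f"edge ({src}, {dst}, {rel}) has a dangling endpoint"
                )
            triple = (src, dst, rel)
            if triple in triples:
                raise GraphValidationError(f"duplicate edge triple {triple}")
            triples.add(triple)

    def node_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, label, _ in self.nodes:
            counts[label] = counts.get(label, 0) + 1
        return counts

    def edge_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, _, rel, _ in self.edges:
            counts[rel] = counts.get(rel, 0) + 1
        return counts


def export_graph(bundle: GraphBundle, out_dir: str | Path, format: str = "graphml") -> list[Path]:
    """Serialise a validated bundle; returns the files written.

    ``graphml`` writes one well-formed XML document.  ``neo4j_csv`` writes
    one node file per label with an ``:ID``/``:LABEL`` header and one edge
    file per relationship type with ``:START_ID``/``:END_ID``/``:TYPE``
    headers, matching bulk-import conventions.
    """
    bundle.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if format == "graphml":
        return [_export_graphml(bundle, out_dir / "network.graphml")]
    if format == "neo4j_csv":
        return _export_neo4j_csv(bundle, out_dir)
    raise ValueError(f"unknown export format {format!r}")


def _export_graphml(bundle: GraphBundle, path: Path) -> Path:
    g = nx.MultiDiGraph()
    for nid, label, props in bundle.nodes:
        g.add_node(nid, label=label, **{k: _scalar(v) for k, v in props.items()})
    for src, dst, rel, props in bundle.edges:
        g.add_edge(src, dst, relation=rel, **{k: _scalar(v) for k, v in props.items()})
    nx.write_graphml(g, path)
    return path


def _scalar(value: Any) -> Any:
    if isinstance(value, (str, int, float, bool)):
        return value
    return json.dumps(value, sort_keys=True)


def import_graphml(path: str | Path) -> GraphBundle:
    """Inverse of the GraphML export (round-trips a valid bundle)."""
    g = nx.read_graphml(path, force_multigraph=True)
    bundle = GraphBundle()
    for nid, data in g.nodes(data=True):
        data = dict(data)
        label = data.pop("label")
        bundle.nodes.append((nid, label, data))
    for src, dst, data in g.edges(data=True):
        data = dict(data)
        rel = data.pop("relation")
        bundle.edges.append((src, dst, rel, data))
    return bundle


def _export_neo4j_csv(bundle: GraphBundle, out_dir: Path) -> list[Path]:
    written = []
    by_label: dict[str, list[dict]] = {}
    for nid, label, props in bundle.nodes:
        by_label.setdefault(label, []).append({":ID": nid, ":LABEL": label, **props})
    for label, rows in sorted(by_label.items()):
        path = out_dir / f"nodes_{label}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    by_rel: dict[str, list[dict]] = {}
    for src, dst, rel, props in bundle.edges:
        by_rel.setdefault(rel, []).append(
            {":START_ID": src, ":END_ID": dst, ":TYPE": rel, **props}
        )
    for rel, rows in sorted(by_rel.items()):
        path = out_dir / f"edges_{rel}.csv"
        pd.DataFrame(rows).to_csv(path, index=False)
        written.append(path)
    return written


def import_neo4j_csv(out_dir: str | Path) -> GraphBundle:
    """Inverse of the bulk-import CSV export."""
    out_dir = Path(out_dir)
    bundle = GraphBundle()
    for path in sorted(out_dir.glob("nodes_*.csv")):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in df.to_dict(orient="records"):
            nid = row.pop(":ID")
            label = row.pop(":LABEL")
            bundle.nodes.append((nid, label, {k: v for k, v in row.items() if v != ""}))
    for path in sorted(out_dir.glob("edges_*.csv")):
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        for row in df.to_dict(orient="records"):
            src = row.pop(":START_ID")
            dst = row.pop(":END_ID")
            rel = row.pop(":TYPE")
            bundle.edges.append((src, dst, rel, {k: v for k, v in row.items() if v != ""}))
    return bundle
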