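"""Typed association networks: build, filter, slice, and export.

Nodes are concepts (CUI, name, entity type); undirected edges carry the
association score as weight plus the adjusted p-value, co-mention count, and
originating type pair.  Edges enter the graph only if their adjusted p-value
passes the construction threshold, so lowering the threshold always yields a
nested subgraph.  Node and edge ordering is made deterministic (sorted by CUI)
before export so repeated exports are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .assoc import AssociationRecord
from .vocab import EntityType

__all__ = ["build_network", "ego_subgraph", "export_graph", "import_graph"]

_EDGE_COLUMNS = [
    "cui_x",
    "name_x",
    "type_x",
    "cui_y",
    "name_y",
    "type_y",
    "count",
    "weight",
    "p_adj",
    "type_pair",
]


def build_network(
    records: Iterable[AssociationRecord] | Sequence[Iterable[AssociationRecord]],
    p_adj_threshold: float = 0.05,
) -> nx.Graph:
    """Filter scored records by adjusted p-value and assemble one typed graph.

    *records* may be a flat iterable or several per-type-pair record lists.
    Nodes appear only when incident to a retained edge.
    """
    if not 0.0 < p_adj_threshold <= 1.0:
        raise ValueError(f"p_adj_threshold must be in (0, 1], got {p_adj_threshold}")
    flat: list[AssociationRecord] = []
    for item in records:
        if isinstance(item, AssociationRecord):
            flat.append(item)
        else:
            flat.extend(item)
    graph = nx.Graph()
    graph.graph["p_adj_threshold"] = p_adj_threshold
    for rec in sorted(flat, key=lambda r: (r.pair.cui_x, r.pair.cui_y)):
        if rec.p_adj > p_adj_threshold:
            continue
        pair = rec.pair
        graph.add_node(
            pair.cui_x,
            name=rec.name_x if rec.name_x is not None else pair.cui_x,
            entity_type=pair.type_x.value,
        )
        graph.add_node(
            pair.cui_y,
            name=rec.name_y if rec.name_y is not None else pair.cui_y,
            entity_type=pair.type_y.value,
        )
        graph.add_edge(
            pair.cui_x,
            pair.cui_y,
            weight=float(rec.score),
            p_adj=float(rec.p_adj),
            count=int(rec.count),
            type_pair=f"{pair.type_x.value}-{pair.type_y.value}",
        )
    return graph


def ego_subgraph(graph: nx.Graph, center: str, radius: int) -> nx.Graph:
    """Induced subgraph of all nodes within *radius* hops of *center*."""
    if center not in graph:
        raise KeyError(f"center node {center!r} not in graph")
    sub = nx.ego_graph(graph, center, radius=radius).copy()
    sub.graph.update(graph.graph)
    return sub


def _sorted_copy(graph: nx.Graph) -> nx.Graph:
    ordered = nx.Graph(**graph.graph)
    for node in sorted(graph.nodes):
        ordered.add_node(node, **graph.nodes[node])
    for u, v in sorted((tuple(sorted(e)) for e in graph.edges), key=lambda e: e):
        ordered.add_edge(u, v, **graph.edges[u, v])
    return ordered


def export_graph(graph: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the graph as GraphML or a TSV edge list (stable ordering)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_sorted_copy(graph), path, named_key_ids=True)
    elif format == "edgelist-tsv":
        rows = []
        for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
            attrs = graph.edges[u, v]
            rows.append(
                {
                    "cui_x": u,
                    "name_x": graph.nodes[u].get("name", u),
                    "type_x": graph.nodes[u].get("entity_type", ""),
                    "cui_y": v,
                    "name_y": graph.nodes[v].get("name", v),
                    "type_y": graph.nodes[v].get("entity_type", ""),
                    "count": attrs["count"],
                    "weight": attrs["weight"],
                    "p_adj": attrs["p_adj"],
                    "type_pair": attrs["type_pair"],
                }
            )
        frame = pd.DataFrame(rows, columns=_EDGE_COLUMNS)
        frame.to_csv(path, sep="\t", index=False, float_format="%.17g", lineterminator="\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edgelist-tsv'")


def import_graph(path: str | Path, format: str = "graphml") -> nx.Graph:
    """Read a graph written by :func:`export_graph`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist-tsv":
        frame = pd.read_csv(path, sep="\t", dtype={"cui_x": str, "cui_y": str})
        graph = nx.Graph()
        for row in frame.itertuples(index=False):
            graph.add_node(row.cui_x, name=row.name_x, entity_type=row.type_x)
            graph.add_node(row.cui_y, name=row.name_y, entity_type=row.type_y)
            graph.add_edge(
                row.cui_x,
                row.cui_y,
                weight=float(row.weight),
                p_adj=float(row.p_adj),
                count=int(row.count),
                type_pair=row.type_pair,
            )
        return graph
    raise ValueError(f"unknown format {format!r}; use 'graphml' or 'edgelist-tsv'")
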