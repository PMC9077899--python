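"""Condition subnetworks and global network attributes.

The co-expression network is undirected; each edge carries the set of
condition labels it is associated with.  Summary statistics follow the
usual conventions: average connectivity 2E/N (mean node degree) and mean
local clustering coefficient <C>, with nodes of degree < 2 contributing 0
(so an acyclic subnetwork has <C> = 0 exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .csgcn_core import CsgcnEdge

__all__ = [
    "Network",
    "NetworkSummary",
    "network_from_edges",
    "extract_condition_subnetwork",
    "unique_elements",
    "summarize",
    "average_connectivity",
    "percentage",
    "round_half_up",
    "export_network",
    "import_network",
]


@dataclass
class Network:
    """Undirected co-expression network with per-edge condition labels."""

    graph: nx.Graph

    def __post_init__(self) -> None:
        if any(u == v for u, v in self.graph.edges):
            raise ValueError("self-loops are not allowed")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, _, data in self.graph.edges(data=True):
            for c in data.get("conditions", ()):
                seen.setdefault(c, None)
        return list(seen)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_connectivity: float
    avg_clustering_coefficient: float
    unique_nodes: int | None = None
    unique_edges: int | None = None
    unique_node_pct: float | None = None
    unique_edge_pct: float | None = None
    unique_connectivity: float | None = None


def network_from_edges(edges: Sequence[CsgcnEdge]) -> Network:
    """Build the csGCN graph from retained edges; edges of the same gene
    pair (different clusters) merge, unioning their condition labels."""
    g = nx.Graph()
    for e in edges:
        conds = set(e.labeled_conditions)
        if not conds:
            continue
        if g.has_edge(e.gene_a, e.gene_b):
            g[e.gene_a][e.gene_b]["conditions"] |= conds
            if abs(e.similarity) > abs(g[e.gene_a][e.gene_b]["similarity"]):
                g[e.gene_a][e.gene_b]["similarity"] = e.similarity
        else:
            g.add_edge(
                e.gene_a, e.gene_b, conditions=conds, similarity=e.similarity
            )
    return Network(g)


def extract_condition_subnetwork(net: Network, condition: str) -> Network:
    """Subnetwork of edges labeled with ``condition``; nodes are the
    endpoints of those edges."""
    if condition not in net.conditions:
        raise KeyError(f"unknown condition: {condition!r}")
    sub = nx.Graph()
    for u, v, data in net.graph.edges(data=True):
        if condition in data.get("conditions", ()):
            sub.add_edge(u, v, **data)
    return Network(sub)


def unique_elements(
    sub: Network, others: Iterable[Network]
) -> tuple[set[str], set[frozenset]]:
    """Nodes and edges of ``sub`` appearing in no other subnetwork."""
    other_nodes: set[str] = set()
    other_edges: set[frozenset] = set()
    for o in others:
        other_nodes |= o.nodes
        other_edges |= o.edges
    return sub.nodes - other_nodes, sub.edges - other_edges


def average_connectivity(n_nodes: int, n_edges: int) -> float:
    """Mean node degree, 2E/N."""
    return 2.0 * n_edges / n_nodes if n_nodes else 0.0


def percentage(part: int, whole: int) -> float:
    return 100.0 * part / whole if whole else 0.0


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Display rounding, half away from zero (so 2.405 -> 2.41)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(
    net: Network, others: Iterable[Network] | None = None
) -> NetworkSummary:
    """Global attributes; pass the sibling condition subnetworks as
    ``others`` to also fill the unique-element fields."""
    n, e = net.n_nodes, net.n_edges
    if n == 0:
        import warnings

        warnings.warn("empty network: all-zero summary")
        return NetworkSummary(0, 0, 0.0, 0.0)
    avg_c = nx.average_clustering(net.graph)  # degree<2 nodes count as 0
    summary = NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_connectivity=average_connectivity(n, e),
        avg_clustering_coefficient=avg_c,
    )
    if others is not None:
        u_nodes, u_edges = unique_elements(net, others)
        summary.unique_nodes = len(u_nodes)
        summary.unique_edges = len(u_edges)
        summary.unique_node_pct = percentage(len(u_nodes), n)
        summary.unique_edge_pct = percentage(len(u_edges), e)
        summary.unique_connectivity = average_connectivity(
            len(u_nodes), len(u_edges)
        )
    return summary


def export_network(net: Network, path: str | Path, fmt: str = "tsv_edgelist") -> None:
    """Lossless edge-attribute export as TSV edge list or GraphML."""
    path = Path(path)
    if fmt == "tsv_edgelist":
        rows = []
        for u, v, data in sorted(net.graph.edges(data=True)):
            row = {"source": u, "target": v}
            for k, val in data.items():
                row[k] = ";".join(sorted(val)) if isinstance(val, (set, frozenset)) else val
            rows.append(row)
        cols = ["source", "target"]
        extra = sorted({k for r in rows for k in r} - set(cols))
        pd.DataFrame(rows, columns=cols + extra).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        for u, v, data in net.graph.edges(data=True):
            attrs = {
                k: (";".join(sorted(val)) if isinstance(val, (set, frozenset)) else val)
                for k, val in data.items()
            }
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format: {fmt!r}")


def import_network(path: str | Path, fmt: str = "tsv_edgelist") -> Network:
    path = Path(path)
    if fmt == "tsv_edgelist":
        g = nx.Graph()
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            attrs = {}
            for k, v in row.items():
                if k in ("source", "target") or (isinstance(v, float) and np.isnan(v)):
                    continue
                attrs[k] = set(str(v).split(";")) if k == "conditions" else v
            g.add_edge(row["source"], row["target"], **attrs)
        return Network(g)
    if fmt == "graphml":
        g_in = nx.read_graphml(path)
        g = nx.Graph()
        for u, v, data in g_in.edges(data=True):
            attrs = dict(data)
            if "conditions" in attrs:
                attrs["conditions"] = set(str(attrs["conditions"]).split(";"))
            g.add_edge(u, v, **attrs)
        return Network(g)
    raise ValueError(f"unknown import format: {fmt!r}")
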