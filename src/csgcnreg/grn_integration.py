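"""Tissue-specific GRN integration and triangle-motif extraction.

A gene regulatory network (directed TF -> target edges, e.g. a
PANDA-style tissue network) is intersected with a condition-specific
co-expression subnetwork: regulatory edges whose target is a subnetwork
node are selected, and every TF that regulates *both* endpoints of a
co-expression edge forms a triangle motif — the candidate "biomarker
system" of a regulator and its condition-specifically co-expressed
targets.  Triangles are counted per (TF, co-expression edge) incidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .differential import RegulatoryEdgeAssessment
from .network_summary import Network

__all__ = [
    "GrnNetwork",
    "TriangleMotif",
    "load_grn",
    "write_grn",
    "select_targeting_edges",
    "extract_triangles",
    "triangles_to_frame",
    "merge_for_export",
]


@dataclass
class GrnNetwork:
    """Directed TF -> target network; duplicates collapsed on load."""

    graph: nx.DiGraph

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self.graph.edges)

    @property
    def tfs(self) -> set[str]:
        return {u for u, _ in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def regulators_of(self, gene: str) -> set[str]:
        if gene not in self.graph:
            return set()
        return set(self.graph.predecessors(gene))


@dataclass(frozen=True)
class TriangleMotif:
    tf: str
    gene_a: str
    gene_b: str
    condition: str
    fully_significant: bool | None = None  # None when no assessments given


def load_grn(path: str | Path) -> GrnNetwork:
    """Read a GRN TSV with columns ``tf``, ``target`` and optional
    ``weight``; duplicate (tf, target) rows collapse with a warning."""
    df = pd.read_csv(path, sep="\t", dtype={"tf": str, "target": str})
    for col in ("tf", "target"):
        if col not in df.columns:
            raise ValueError(f"GRN file {path} lacks required column {col!r}")
    n_dups = int(df.duplicated(subset=["tf", "target"]).sum())
    if n_dups:
        warnings.warn(f"{n_dups} duplicate GRN edge row(s) collapsed")
        df = df.drop_duplicates(subset=["tf", "target"])
    g = nx.DiGraph()
    has_weight = "weight" in df.columns
    for row in df.itertuples():
        attrs = {"weight": float(row.weight)} if has_weight else {}
        if row.tf == row.target:
            warnings.warn(f"self-regulation kept and flagged: {row.tf}")
            attrs["self_loop"] = True
        g.add_edge(row.tf, row.target, **attrs)
    return GrnNetwork(g)


def write_grn(grn: GrnNetwork, path: str | Path) -> None:
    rows = []
    for u, v, data in sorted(grn.graph.edges(data=True)):
        row = {"tf": u, "target": v}
        if "weight" in data:
            row["weight"] = data["weight"]
        rows.append(row)
    cols = ["tf", "target"] + (
        ["weight"] if any("weight" in r for r in rows) else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def select_targeting_edges(grn: GrnNetwork, subnet: Network) -> GrnNetwork:
    """GRN edges whose target is a node of the co-expression subnetwork."""
    nodes = subnet.nodes
    g = nx.DiGraph()
    for u, v, data in grn.graph.edges(data=True):
        if v in nodes:
            g.add_edge(u, v, **data)
    return GrnNetwork(g)


def extract_triangles(
    grn: GrnNetwork,
    subnet: Network,
    condition: str = "",
    assessments: Mapping[tuple[str, str], RegulatoryEdgeAssessment] | None = None,
) -> list[TriangleMotif]:
    """Triangle motifs: a TF regulating both endpoints of a subnetwork edge.

    One motif per (TF, edge) incidence, ordered lexicographically by
    (tf, gene_a, gene_b) with gene_a < gene_b.  When ``assessments`` are
    supplied, ``fully_significant`` is True iff both regulatory edges are
    doubly significant (both genes DEGs and ratio shifted).
    """
    motifs: list[TriangleMotif] = []
    for edge in subnet.edges:
        a, b = sorted(edge)
        common_tfs = grn.regulators_of(a) & grn.regulators_of(b)
        for tf in common_tfs:
            fully: bool | None = None
            if assessments is not None:
                ra = assessments.get((tf, a))
                rb = assessments.get((tf, b))
                fully = bool(
                    ra is not None
                    and rb is not None
                    and ra.doubly_significant
                    and rb.doubly_significant
                )
            motifs.append(TriangleMotif(tf, a, b, condition, fully))
    motifs.sort(key=lambda m: (m.tf, m.gene_a, m.gene_b))
    return motifs


def triangles_to_frame(motifs: Sequence[TriangleMotif]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tf": m.tf,
                "gene_a": m.gene_a,
                "gene_b": m.gene_b,
                "condition": m.condition,
                "fully_significant": m.fully_significant,
            }
            for m in motifs
        ],
        columns=["tf", "gene_a", "gene_b", "condition", "fully_significant"],
    )


def merge_for_export(
    subnet: Network,
    grn_subset: GrnNetwork,
    motifs: Sequence[TriangleMotif],
    de_results: pd.DataFrame | None = None,
) -> nx.DiGraph:
    """One mixed graph for visualization export.

    Undirected co-expression edges carry ``edge_type='gcn'`` (stored once,
    endpoints sorted); directed regulatory edges carry ``edge_type='grn'``
    and ``in_triangle``.  Nodes carry ``is_tf`` and, when DE results are
    supplied, ``de_direction``.
    """
    g = nx.DiGraph()
    triangle_grn_edges = {
        (m.tf, t) for m in motifs for t in (m.gene_a, m.gene_b)
    }
    for u, v, data in subnet.graph.edges(data=True):
        a, b = sorted((u, v))
        attrs = {
            k: (";".join(sorted(val)) if isinstance(val, (set, frozenset)) else val)
            for k, val in data.items()
        }
        g.add_edge(a, b, edge_type="gcn", **attrs)
    for u, v, data in grn_subset.graph.edges(data=True):
        if g.has_edge(u, v) and g[u][v].get("edge_type") == "gcn":
            raise ValueError(f"id clash: ({u}, {v}) is both a GCN and GRN edge")
        g.add_edge(
            u, v, edge_type="grn", in_triangle=(u, v) in triangle_grn_edges, **data
        )
    tfs = grn_subset.tfs
    for node in g.nodes:
        g.nodes[node]["is_tf"] = node in tfs
        if de_results is not None:
            g.nodes[node]["de_direction"] = (
                str(de_results.loc[node, "direction"])
                if node in de_results.index
                else "none"
            )
    return g
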