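"""Synthetic multi-condition expression data with planted ground truth.

The generator emulates the structure the network pipeline is built to
detect: several sample conditions (e.g. normal vs tumor subtypes); gene
pairs that are correlated *only within one condition*, so that across all
samples their joint distribution is a mixture; TF -> target regulatory
edges whose coupling strength depends on condition; differentially
expressed genes with specified log2 fold changes; and structured
missingness.  Everything is seeded and byte-reproducible.

Expression is generated on a log2 latent scale and exponentiated, so the
output GEM is linear-scale (FPKM-like, log-normal margins) and exercises
the full normalization path.  Planted correlations hit an exact target
Spearman rho through a Gaussian copula (Pearson r = 2 sin(pi * rho_s / 6)).
Planted pairs additionally shift their mean within the active condition —
the condition-coupled expression shift that lets a mixture model isolate
the active samples, mirroring how tumor-specific co-expression co-occurs
with tumor-specific expression levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gem_io import (
    GEM,
    LINEAR,
    SampleAnnotation,
    load_annotation,
    load_gem,
    write_annotation,
    write_gem,
)

__all__ = [
    "PlantedEdge",
    "PlantedGrnEdge",
    "PlantedDeg",
    "SyntheticTruth",
    "TruthSpec",
    "generate_dataset",
    "inject_missingness",
    "write_fixture",
    "load_fixture",
]


@dataclass(frozen=True)
class PlantedEdge:
    gene_a: str
    gene_b: str
    condition: str
    rho_target: float


@dataclass(frozen=True)
class PlantedGrnEdge:
    tf: str
    target: str
    coupling: tuple[tuple[str, float], ...]  # (condition, slope) pairs

    def coupling_of(self, condition: str) -> float:
        return dict(self.coupling).get(condition, 0.0)


@dataclass(frozen=True)
class PlantedDeg:
    gene: str
    cond_a: str
    cond_b: str
    log2_fc: float  # shift applied to cond_b relative to cond_a


@dataclass
class SyntheticTruth:
    """Realized ground truth of one generated dataset."""

    planted_edges: list[PlantedEdge]
    planted_grn: list[PlantedGrnEdge]
    planted_degs: list[PlantedDeg]
    missingness: dict[tuple[str, str], float]  # (gene, condition) -> rate
    seed: int


@dataclass
class TruthSpec:
    """What to plant.  Defaults give a small benchmark with strongly
    recoverable structure: rho 0.85 condition-specific pairs, a 3-unit
    log2 shift in the active condition, TF->target couplings that exist
    only in their active condition, and 4-fold expression changes."""

    n_planted_edges: int = 20
    rho_target: float = 0.85
    mean_shift: float = 3.0
    n_grn_edges: int = 8
    grn_coupling: float = 0.8
    grn_noise_sd: float = 0.4
    n_degs: int = 10
    deg_log2fc: float = 2.0
    n_triangle_tfs: int = 4
    triangle_tf_log2fc: float = -1.5
    base_mean_range: tuple[float, float] = (4.0, 9.0)
    base_sd: float = 0.8
    missingness: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < abs(self.rho_target) < 1.0):
            raise ValueError("|rho_target| must lie in (0, 1)")


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation of a bivariate Gaussian whose rank correlation
    is ``rho_s`` (Gaussian copula identity)."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


def generate_dataset(
    n_genes: int,
    samples_per_condition: Mapping[str, int],
    truth_config: TruthSpec | None = None,
    seed: int = 0,
) -> tuple[GEM, SampleAnnotation, SyntheticTruth]:
    """Generate a linear-scale GEM plus annotation and ground truth.

    Genes are named ``G0000``..; planted pairs, TFs/targets and DEGs are
    drawn from disjoint blocks of that pool so each planted feature is
    attributable.  Planted edges cycle through the condition labels.
    """
    spec = truth_config or TruthSpec()
    conditions = list(samples_per_condition)
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    reserved = (
        2 * spec.n_planted_edges
        + 2 * spec.n_grn_edges
        + spec.n_degs
        + spec.n_triangle_tfs
    )
    if spec.n_triangle_tfs and not spec.n_planted_edges:
        raise ValueError("triangle TFs require planted edges to sit on")
    if n_genes < reserved:
        raise ValueError(
            f"n_genes={n_genes} too small for planted structure ({reserved} needed)"
        )
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    sample_ids: list[str] = []
    labels: list[str] = []
    for cond in conditions:
        n = samples_per_condition[cond]
        sample_ids.extend(f"{cond}_s{i:03d}" for i in range(n))
        labels.extend([cond] * n)
    annot = SampleAnnotation(pd.Series(labels, index=sample_ids, name="condition"))
    cond_idx = {c: np.flatnonzero(np.asarray(labels) == c) for c in conditions}

    lo, hi = spec.base_mean_range
    base_mean = rng.uniform(lo, hi, size=n_genes)
    sd = spec.base_sd
    # Planted-structure genes keep their shifted means inside the
    # background support, so quantile normalization (rank-based, shared
    # across genes) retains resolution where the planted signal lives.
    n_edge_genes = 2 * spec.n_planted_edges
    base_mean[:n_edge_genes] = rng.uniform(
        lo, max(hi - spec.mean_shift, lo + 0.5), size=n_edge_genes
    )
    deg_lo = min(lo + spec.deg_log2fc, (lo + hi) / 2)
    deg_hi = max(hi - spec.deg_log2fc, (lo + hi) / 2 + 0.5)
    deg_start = n_edge_genes + 2 * spec.n_grn_edges
    base_mean[deg_start : deg_start + spec.n_degs] = rng.uniform(
        deg_lo, deg_hi, size=spec.n_degs
    )
    tf_start = deg_start + spec.n_degs
    tf_shift = spec.triangle_tf_log2fc
    base_mean[tf_start : tf_start + spec.n_triangle_tfs] = rng.uniform(
        min(lo - min(tf_shift, 0.0), hi - 1.0),
        max(hi - max(tf_shift, 0.0), lo + 1.0),
        size=spec.n_triangle_tfs,
    )
    # background: independent per condition, common mean
    latent = rng.normal(base_mean[:, None], sd, size=(n_genes, len(sample_ids)))

    cursor = 0

    planted_edges: list[PlantedEdge] = []
    r_pearson = spearman_to_pearson(spec.rho_target)
    for k in range(spec.n_planted_edges):
        ia, ib = cursor, cursor + 1
        cursor += 2
        cond = conditions[k % len(conditions)]
        idx = cond_idx[cond]
        z = rng.multivariate_normal(
            [0.0, 0.0], [[1.0, r_pearson], [r_pearson, 1.0]], size=idx.size
        )
        latent[ia, idx] = base_mean[ia] + spec.mean_shift + sd * z[:, 0]
        latent[ib, idx] = base_mean[ib] + spec.mean_shift + sd * z[:, 1]
        planted_edges.append(
            PlantedEdge(genes[ia], genes[ib], cond, spec.rho_target)
        )

    planted_grn: list[PlantedGrnEdge] = []
    for k in range(spec.n_grn_edges):
        itf, itg = cursor, cursor + 1
        cursor += 2
        cond = conditions[k % len(conditions)]
        coupling = tuple(
            (c, spec.grn_coupling if c == cond else 0.0) for c in conditions
        )
        for c, slope in coupling:
            idx = cond_idx[c]
            noise = rng.normal(0.0, spec.grn_noise_sd, size=idx.size)
            latent[itg, idx] = (
                base_mean[itg]
                + slope * (latent[itf, idx] - base_mean[itf])
                + noise
            )
        planted_grn.append(PlantedGrnEdge(genes[itf], genes[itg], coupling))

    planted_degs: list[PlantedDeg] = []
    cond_a, cond_b = conditions[0], conditions[1]
    for k in range(spec.n_degs):
        ig = cursor
        cursor += 1
        fc = spec.deg_log2fc if k % 2 == 0 else -spec.deg_log2fc
        latent[ig, cond_idx[cond_b]] += fc
        planted_degs.append(PlantedDeg(genes[ig], cond_a, cond_b, fc))

    # Triangle TFs: each regulates both endpoints of one planted
    # co-expression edge (the biomarker-system motif) and shifts
    # expression in that edge's active condition, so the TF/TR ratio
    # moves between conditions.
    for k in range(spec.n_triangle_tfs):
        itf = cursor
        cursor += 1
        pe = planted_edges[k % len(planted_edges)]
        latent[itf, cond_idx[pe.condition]] += spec.triangle_tf_log2fc
        # presence-only regulatory edges: the TF shifts with the
        # condition but the targets keep their pair-copula generation
        coupling = tuple((c, 0.0) for c in conditions)
        planted_grn.append(PlantedGrnEdge(genes[itf], pe.gene_a, coupling))
        planted_grn.append(PlantedGrnEdge(genes[itf], pe.gene_b, coupling))

    values = pd.DataFrame(
        np.exp2(latent), index=pd.Index(genes, name="gene"), columns=sample_ids
    )
    gem = GEM(values, scale=LINEAR)
    truth = SyntheticTruth(
        planted_edges=planted_edges,
        planted_grn=planted_grn,
        planted_degs=planted_degs,
        missingness=dict(spec.missingness),
        seed=seed,
    )
    if truth.missingness:
        gem = inject_missingness(gem, annot, truth.missingness, seed=seed + 1)
    return gem, annot, truth


def inject_missingness(
    gem: GEM,
    annot: SampleAnnotation,
    rates: Mapping[tuple[str, str], float],
    seed: int = 0,
) -> GEM:
    """Mask cells by independent Bernoulli draws.

    ``rates`` maps ``(gene, condition)`` to a missing probability; ``"*"``
    is a wildcard for either field.
    """
    for key, rate in rates.items():
        if not (0.0 <= rate <= 1.0):
            raise ValueError(f"missingness rate for {key} outside [0, 1]: {rate}")
    rng = np.random.default_rng(seed)
    vals = gem.values.copy()
    gene_pos = {g: i for i, g in enumerate(gem.gene_ids)}
    for (gene, cond), rate in rates.items():
        rows = list(gene_pos.values()) if gene == "*" else [gene_pos[gene]]
        if cond == "*":
            cols = np.arange(gem.n_samples)
        else:
            cols = gem.sample_ids.get_indexer(annot.samples_of(cond))
        for r in rows:
            hit = rng.random(cols.size) < rate
            vals.iloc[r, cols[hit]] = np.nan
    return GEM(vals, scale=gem.scale)


# ---------------------------------------------------------------------------
# Fixture files: gem.tsv, annotation.tsv, grn.tsv, truth.tsv
# ---------------------------------------------------------------------------


def write_fixture(
    bundle: tuple[GEM, SampleAnnotation, SyntheticTruth], directory: str | Path
) -> dict[str, Path]:
    """Write the four fixture files and return their paths."""
    gem, annot, truth = bundle
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "gem": directory / "gem.tsv",
        "annotation": directory / "annotation.tsv",
        "grn": directory / "grn.tsv",
        "truth": directory / "truth.tsv",
    }
    write_gem(gem, paths["gem"])
    write_annotation(annot, paths["annotation"])

    grn_rows = [
        {"tf": e.tf, "target": e.target, "weight": 1.0} for e in truth.planted_grn
    ]
    pd.DataFrame(grn_rows, columns=["tf", "target", "weight"]).to_csv(
        paths["grn"], sep="\t", index=False
    )

    rows: list[dict] = []
    for e in truth.planted_edges:
        rows.append(
            {"kind": "edge", "a": e.gene_a, "b": e.gene_b,
             "condition": e.condition, "value": e.rho_target}
        )
    for g in truth.planted_grn:
        for cond, slope in g.coupling:
            rows.append(
                {"kind": "grn", "a": g.tf, "b": g.target,
                 "condition": cond, "value": slope}
            )
    for d in truth.planted_degs:
        rows.append(
            {"kind": "deg", "a": d.gene, "b": d.cond_a,
             "condition": d.cond_b, "value": d.log2_fc}
        )
    for (gene, cond), rate in truth.missingness.items():
        rows.append(
            {"kind": "missing", "a": gene, "b": "", "condition": cond, "value": rate}
        )
    rows.append({"kind": "seed", "a": "", "b": "", "condition": "", "value": truth.seed})
    pd.DataFrame(rows, columns=["kind", "a", "b", "condition", "value"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return paths


def load_fixture(directory: str | Path) -> tuple[GEM, SampleAnnotation, SyntheticTruth]:
    directory = Path(directory)
    gem = load_gem(directory / "gem.tsv")
    annot = load_annotation(directory / "annotation.tsv")
    manifest = pd.read_csv(
        directory / "truth.tsv", sep="\t", keep_default_na=False, dtype={"a": str, "b": str}
    )
    edges = [
        PlantedEdge(r.a, r.b, r.condition, float(r.value))
        for r in manifest[manifest.kind == "edge"].itertuples()
    ]
    grn_rows = manifest[manifest.kind == "grn"]
    grn: dict[tuple[str, str], list[tuple[str, float]]] = {}
    for r in grn_rows.itertuples():
        grn.setdefault((r.a, r.b), []).append((r.condition, float(r.value)))
    planted_grn = [
        PlantedGrnEdge(tf, tg, tuple(c)) for (tf, tg), c in grn.items()
    ]
    degs = [
        PlantedDeg(r.a, r.b, r.condition, float(r.value))
        for r in manifest[manifest.kind == "deg"].itertuples()
    ]
    missing = {
        (r.a, r.condition): float(r.value)
        for r in manifest[manifest.kind == "missing"].itertuples()
    }
    seed_rows = manifest[manifest.kind == "seed"]
    seed = int(float(seed_rows.value.iloc[0])) if len(seed_rows) else 0
    truth = SyntheticTruth(edges, planted_grn, degs, missing, seed)
    return gem, annot, truth
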