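"""End-to-end orchestration: simulate/load -> normalize -> csGCN ->
summaries -> DE + ratio tests -> triangles -> classification.

Stages communicate through documented TSV files in the output directory
so a run can be inspected and restarted; an effective-config manifest
records every threshold and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classification, csgcn_core, differential, gem_io, grn_integration
from . import network_summary as ns
from . import synthetic_data as synth

log = logging.getLogger("csgcnreg")

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Every stage threshold, at the pipeline's standard defaults."""

    # csGCN
    min_similarity: float = 0.5
    min_cluster: int = 30
    cond_alpha: float = 0.001
    min_power: float = 0.8
    power_alpha: float = 0.001
    r2_min: float = 0.30
    welch_alpha: float = 0.001
    miss_p_cut: float = 0.1
    # QC / DE / ratio
    ks_threshold: float = 0.15
    de_alpha: float = 0.001
    ratio_alpha: float = 0.001
    ratio_eps: float = 0.01
    # run control
    seed: int = 17
    gem_path: str | None = None
    annot_path: str | None = None
    grn_path: str | None = None
    simulate: bool = False
    sim_n_genes: int = 80
    sim_samples_per_condition: dict = field(
        default_factory=lambda: {"normal": 60, "tumor_a": 60, "tumor_b": 60}
    )
    genes: list[str] | None = None
    max_pairs: int | None = None
    de_conditions: tuple[str, str] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def run_all(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage and write all artifacts under ``out_dir``.

    Returns a dict of the in-memory results keyed by stage name.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    # --- input stage -------------------------------------------------
    if config.simulate:
        log.info("simulating dataset (seed=%d)", config.seed)
        gem, annot, truth = synth.generate_dataset(
            config.sim_n_genes,
            config.sim_samples_per_condition,
            synth.TruthSpec(),
            seed=config.seed,
        )
        synth.write_fixture((gem, annot, truth), out / "fixture")
        grn_path = out / "fixture" / "grn.tsv"
        results["truth"] = truth
    else:
        if not (config.gem_path and config.annot_path):
            raise ValueError("gem_path and annot_path required unless simulate=True")
        gem = gem_io.load_gem(config.gem_path)
        annot = gem_io.load_annotation(config.annot_path)
        grn_path = config.grn_path

    # --- normalization + QC ------------------------------------------
    if gem.scale == gem_io.LINEAR:
        norm = gem_io.log2_quantile_normalize(gem)
    else:
        norm = gem
    flagged, undefined = gem_io.ks_outlier_detect(norm, config.ks_threshold)
    gem_io.write_gem(norm, out / "gem_normalized.tsv")
    (out / "qc_flagged_samples.txt").write_text(
        "\n".join(flagged + [f"{s}\t(D undefined)" for s in undefined]) + "\n"
        if (flagged or undefined)
        else ""
    )
    results["normalized"] = norm
    results["qc_flagged"] = flagged

    # --- csGCN -------------------------------------------------------
    params = csgcn_core.CsgcnParams(
        min_similarity=config.min_similarity,
        min_cluster=config.min_cluster,
        cond_alpha=config.cond_alpha,
        min_power=config.min_power,
        power_alpha=config.power_alpha,
        r2_min=config.r2_min,
        welch_alpha=config.welch_alpha,
        miss_p_cut=config.miss_p_cut,
        seed=config.seed,
        genes=config.genes,
        max_pairs=config.max_pairs,
    )
    edges = csgcn_core.build_csgcn(norm, annot, params)
    csgcn_core.edges_to_frame(edges).to_csv(
        out / "csgcn_edges.tsv", sep="\t", index=False
    )
    net = ns.network_from_edges(edges)
    ns.export_network(net, out / "csgcn_network.tsv")
    results["edges"] = edges
    results["network"] = net

    # --- per-condition summaries -------------------------------------
    conditions = net.conditions
    subnets = {
        c: ns.extract_condition_subnetwork(net, c) for c in conditions
    }
    rows = []
    full = ns.summarize(net)
    rows.append({"condition": "full", **asdict(full)})
    for c, sub in subnets.items():
        others = [s for k, s in subnets.items() if k != c]
        rows.append({"condition": c, **asdict(ns.summarize(sub, others))})
    pd.DataFrame(rows).to_csv(out / "network_summary.tsv", sep="\t", index=False)
    results["summaries"] = rows
    results["subnetworks"] = subnets

    # --- DE + ratio + triangles --------------------------------------
    conds = config.de_conditions or tuple(annot.conditions[:2])
    cond_a, cond_b = conds
    de = differential.de_test(
        norm, annot, cond_a, cond_b, alpha=config.de_alpha
    )
    de.to_csv(out / f"de_{cond_a}_vs_{cond_b}.tsv", sep="\t")
    results["de"] = de

    if grn_path is not None:
        grn = grn_integration.load_grn(grn_path)
        triangle_frames = []
        assessment_rows = []
        for c, sub in subnets.items():
            targeting = grn_integration.select_targeting_edges(grn, sub)
            ratios = {
                (tf, tr): differential.tf_tr_ratio_test(
                    norm, tf, tr, annot, cond_a, cond_b,
                    alpha=config.ratio_alpha, eps=config.ratio_eps,
                )
                for tf, tr in sorted(targeting.edges)
                if tf in norm.gene_ids and tr in norm.gene_ids
            }
            assessments, counts = differential.assess_regulatory_edges(
                sorted(ratios), de, ratios
            )
            assessment_rows.append({"condition": c, **counts})
            amap = {(a.tf, a.tr): a for a in assessments}
            motifs = grn_integration.extract_triangles(
                targeting, sub, condition=c, assessments=amap
            )
            triangle_frames.append(grn_integration.triangles_to_frame(motifs))
            results.setdefault("motifs", {})[c] = motifs
        triangles = (
            pd.concat(triangle_frames, ignore_index=True)
            if triangle_frames
            else pd.DataFrame()
        )
        triangles.to_csv(out / "triangles.tsv", sep="\t", index=False)
        pd.DataFrame(assessment_rows).to_csv(
            out / "regulatory_edge_counts.tsv", sep="\t", index=False
        )
        results["triangles"] = triangles
        results["regulatory_counts"] = assessment_rows

    # --- classification ----------------------------------------------
    gene_pool: list[str] = sorted(
        {g for e in edges for g in (e.gene_a, e.gene_b)}
    )
    if len(gene_pool) >= 2:
        subgem, absent = classification.subset_gem(norm, gene_pool)
        report = classification.train_evaluate(
            subgem, annot, classification.ClassifierConfig(seed=config.seed)
        )
        report.confusion.to_csv(out / "classification_confusion.tsv", sep="\t")
        (out / "classification_report.json").write_text(
            json.dumps(
                {
                    "overall_accuracy": report.overall_accuracy,
                    "per_class_accuracy": report.per_class_accuracy.to_dict(),
                    "imputed_missing": report.imputed_missing,
                },
                indent=2,
            )
        )
        results["classification"] = report

    # --- manifest -----------------------------------------------------
    manifest = asdict(config)
    manifest["n_edges"] = len(edges)
    manifest["conditions"] = conditions
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
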