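"""Build a condition-specific co-expression network and summarize it.

Runs the full per-pair pipeline (GMM clustering, per-cluster Spearman,
power filter, condition z-tests, bias filters) over the planted gene
subset and prints the recovered network's global attributes per
condition, in the style of a network-attribute table.
"""

from csgcnreg import csgcn_core as cc
from csgcnreg import gem_io
from csgcnreg import network_summary as ns
from csgcnreg import synthetic_data as sd

gem, annot, truth = sd.generate_dataset(
    200, {"normal": 100, "tumor_a": 100, "tumor_b": 100}, seed=17
)
norm = gem_io.log2_quantile_normalize(gem)

# the all-pairs stage is quadratic; restrict to the planted block
genes = sorted({g for e in truth.planted_edges for g in (e.gene_a, e.gene_b)})
edges = cc.build_csgcn(norm, annot, cc.CsgcnParams(seed=17, genes=genes))
print(f"{len(edges)} retained edges over {len(genes)} genes")

net = ns.network_from_edges(edges)
subnets = {c: ns.extract_condition_subnetwork(net, c) for c in net.conditions}
full = ns.summarize(net)
print(f"full network: {full.n_nodes} nodes, {full.n_edges} edges, "
      f"connectivity {ns.round_half_up(full.avg_connectivity)}, "
      f"<C> {full.avg_clustering_coefficient:.3f}")
for cond, sub in subnets.items():
    others = [s for k, s in subnets.items() if k != cond]
    s = ns.summarize(sub, others)
    print(f"  {cond}: {s.n_nodes} nodes, {s.n_edges} edges, "
          f"unique-edge {ns.round_half_up(s.unique_edge_pct)}%")

planted = {tuple(sorted((e.gene_a, e.gene_b))): e.condition
           for e in truth.planted_edges}
hits = sum(1 for e in edges
           if planted.get(tuple(sorted((e.gene_a, e.gene_b)))) in e.labeled_conditions)
print(f"planted-edge recovery: {hits}/{len(planted)} with the correct "
      f"condition label")
# Each planted pair is correlated only inside its active condition, so a
# correct recovery means the mixture model isolated those samples and
# both proportion z-tests confirmed the enrichment at p < 0.001.
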