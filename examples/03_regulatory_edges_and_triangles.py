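"""Integrate a regulatory network: DE calls, TF/TR ratio tests,
edge categories and triangle biomarker motifs.

A TF that regulates both endpoints of a condition-specific co-expression
edge forms a triangle motif; when both regulatory edges are "doubly
significant" (TF and target are DEGs and the TF/TR expression ratio
shifts between conditions) the motif is a candidate biomarker system.
"""

import networkx as nx

from csgcnreg import csgcn_core as cc
from csgcnreg import differential as diff
from csgcnreg import gem_io
from csgcnreg import grn_integration as gi
from csgcnreg import network_summary as ns
from csgcnreg import synthetic_data as sd

gem, annot, truth = sd.generate_dataset(
    200, {"normal": 100, "tumor_a": 100, "tumor_b": 100}, seed=17
)
norm = gem_io.log2_quantile_normalize(gem)
genes = sorted({g for e in truth.planted_edges for g in (e.gene_a, e.gene_b)})
edges = cc.build_csgcn(norm, annot, cc.CsgcnParams(seed=17, genes=genes))
net = ns.network_from_edges(edges)

de = diff.de_test(norm, annot, "normal", "tumor_a")
print(f"differential expression normal vs tumor_a: "
      f"{int(de.is_deg.sum())} DEGs of {len(de)} genes "
      f"({de.attrs['method']})")

grn = gi.GrnNetwork(nx.DiGraph([(g.tf, g.target) for g in truth.planted_grn]))
for cond in net.conditions:
    sub = ns.extract_condition_subnetwork(net, cond)
    targeting = gi.select_targeting_edges(grn, sub)
    ratios = {
        (tf, tr): diff.tf_tr_ratio_test(norm, tf, tr, annot, "normal", "tumor_a")
        for tf, tr in sorted(targeting.edges)
    }
    assessments, counts = diff.assess_regulatory_edges(sorted(ratios), de, ratios)
    amap = {(a.tf, a.tr): a for a in assessments}
    motifs = gi.extract_triangles(targeting, sub, condition=cond, assessments=amap)
    print(f"{cond}: {counts['total']} regulatory edges targeting the "
          f"subnetwork, {counts['doubly_significant']} doubly significant; "
          f"{len(motifs)} triangle motif(s)")
    for m in motifs:
        print(f"  {m.tf} -> ({m.gene_a} -- {m.gene_b})"
              f"{'  [fully significant]' if m.fully_significant else ''}")
# A fully significant triangle means the TF and both of its targets
# changed expression between conditions AND both TF/target ratios
# shifted: the regulatory relationship itself is condition-dependent.
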