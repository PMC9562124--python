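"""Cluster NPCG expression into the two main expression programmes.

Genes are clustered on 1 - Spearman rank correlation with centroid
linkage; the two-cluster cut separates genes more expressed in one
group from genes more expressed in the other.
"""

from npcg import SimulationConfig, cluster_npcg, npc_combine, \
    simulate_dataset
from npcg.annotation import annotate_sites
from npcg.cluster import normalize_log, to_newick
from npcg.methylation import filter_coverage
from npcg.npc import build_gene_omics

cfg = SimulationConfig(seed=5, n_cpg=1500, n_genes=200, prop_deg=0.3)
ann, meth, counts, samples, truth = simulate_dataset(cfg)
filtered = filter_coverage(meth)
go = build_gene_omics(filtered, annotate_sites(filtered.sites, ann), counts)
npc = npc_combine(go, samples, B=1000, seed=5)
npcg = npc.index[npc["is_npcg"]].tolist()
print(f"{len(npcg)} NPCG")

expr = normalize_log(counts.loc[npcg])
expr = expr.sub(expr.median(axis=1), axis=0)
res = cluster_npcg(expr, k=2)
sizes = res.assignment.value_counts().sort_index()
print("cluster sizes:", sizes.to_dict())
print("dendrogram (truncated):", to_newick(res)[:100], "...")
# Each cluster gathers genes whose expression moves the same way
# between the groups; the dendrogram text can be loaded by any Newick
# reader for display.
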