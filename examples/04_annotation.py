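"""Annotate CpG sites by nearest TSS, gene structure and island context.

Promoters span +/-1000 bp of a TSS (both endpoints included), CpG-island
shores span 2000 bp on each side of an island, and every site is
assigned to its nearest TSS with no distance cutoff.
"""

from npcg import SimulationConfig, genes_of, simulate_dataset, test_dmc
from npcg.annotation import annotate_sites
from npcg.methylation import filter_coverage

cfg = SimulationConfig(seed=4, n_cpg=2000, n_genes=150)
ann, meth, counts, samples, truth = simulate_dataset(cfg)
filtered = filter_coverage(meth)

site_ann = annotate_sites(filtered.sites, ann)
print(site_ann["gene_structure"].value_counts().to_string())
print(site_ann["cpg_context"].value_counts().to_string())

dmc = test_dmc(filtered, samples)
genes = genes_of(dmc, site_ann, genic_only=True)
print(f"\ngenes with a genic DMC: {len(genes)}")
# Structure precedence is promoter > exon > intron > intergenic, and
# island > shore > open sea, so each site carries exactly one label of
# each kind.
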