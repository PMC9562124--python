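"""Generate a coupled methylome/transcriptome dataset.

Two groups of four samples (in-vivo MOET reference vs in-vitro IVP), a
toy one-chromosome annotation, beta-binomial CpG counts with a logit
shift at 10% of sites, NB gene counts with a log2 fold change at 10% of
genes, and a negative coupling between each gene's realised methylation
and its expression.
"""

from npcg import SimulationConfig, simulate_dataset
from npcg.methylation import global_methylation

cfg = SimulationConfig(seed=1, n_cpg=2000, n_genes=300)
ann, meth, counts, samples, truth = simulate_dataset(cfg)

print(f"{meth.n_sites} CpG sites x {len(meth.samples)} samples; "
      f"{counts.shape[0]} genes")
print(f"true DMC sites: {int(truth.cpg['is_dmc'].sum())}, "
      f"true DEG: {int(truth.genes['is_deg'].sum())}")
for s in meth.samples[:2]:
    print(f"global CpG methylation of {s}: "
          f"{global_methylation(meth, s):.1f}%")
# ~48% global methylation is what a uniform(-2, 2) baseline logit gives;
# the flagged sites push the IVP group's average slightly up.
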