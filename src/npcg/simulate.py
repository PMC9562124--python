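"""Coupled methylome/transcriptome simulator for a two-group design.

Emulates the statistical structure of a WGBS + RNA-seq study contrasting
two groups of four animals (in-vitro-produced, IVP, versus in-vivo
MOET): beta-binomial CpG counts with logit-scale group shifts at a
minority of sites, negative-binomial gene counts with log2 fold changes
at a minority of genes, and a negative log-scale coupling between a
gene's realised methylation proportion and its expected expression.

Everything is a pure function of (seed, config): the same configuration
produces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CpGMatrix, GenomeAnnotation, SampleTable

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "simulate_annotation",
    "simulate_methylome",
    "simulate_transcriptome",
    "simulate_dataset",
]

_CHROM = "chrSim"


@dataclass
class SimulationConfig:
    """Parameters of the coupled two-omics simulation.

    Defaults mirror the two-group, n = 4-per-group design with modest
    genome scale: ~10% of CpGs carry a logit shift of 2 (a 10% -> 47%
    proportion change at a central baseline), ~10% of genes a log2 fold
    change of 1, beta-binomial overdispersion rho = 0.05, NB dispersion
    0.1 and ~30x coverage — values a bulk WGBS/RNA-seq practitioner
    would call typical.  ``coupling_gamma`` < 0 reproduces the negative
    methylation-expression association.
    """

    seed: int = 0
    n_per_group: int = 4
    n_cpg: int = 2000
    n_genes: int = 400
    prop_dmc: float = 0.1
    prop_deg: float = 0.1
    meth_logit_shift: float = 2.0
    lfc: float = 1.0
    bb_rho: float = 0.05
    nb_dispersion: float = 0.1
    mean_coverage: float = 30.0
    mean_count: float = 100.0
    coupling_gamma: float = -1.0
    age_days: list[float] | None = None
    island_fraction: float = 0.5
    promoter_cpg_fraction: float = 0.6
    group_labels: tuple[str, str] = ("MOET", "IVP")  # (reference, other)

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("prop_dmc", "prop_deg", "island_fraction",
                     "promoter_cpg_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.bb_rho < 1.0:
            raise ValueError("bb_rho must lie in [0, 1)")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.mean_coverage <= 0 or self.mean_count <= 0:
            raise ValueError("mean_coverage and mean_count must be > 0")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_cpg < 1:
            raise ValueError("n_cpg must be >= 1")
        if self.age_days is not None and len(self.age_days) != 2 * self.n_per_group:
            raise ValueError("age_days must list one value per sample")

    def sample_table(self) -> SampleTable:
        ref, other = self.group_labels
        ids = [f"{ref}_{i + 1}" for i in range(self.n_per_group)]
        ids += [f"{other}_{i + 1}" for i in range(self.n_per_group)]
        groups = [ref] * self.n_per_group + [other] * self.n_per_group
        tab = pd.DataFrame({"sample_id": ids, "group": groups})
        if self.age_days is not None:
            tab["age_days"] = list(self.age_days)
        return SampleTable(tab, reference=ref)


@dataclass
class TruthTable:
    """Ground truth of the simulation, for parameter-recovery tests."""

    cpg: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: chrom, pos, strand, baseline_logit, is_dmc, shift
    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns: gene_id, is_deg, lfc, coupling_gamma


# gene tiling geometry (bp); bodies never overlap
_BODY_LEN = 4000
_GAP_LEN = 3000
_ISLAND_HALF = 300


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Tile ``n_genes`` non-overlapping genes on one synthetic chromosome.

    Each gene gets a TSS at its 5' end, one to three exons (introns in
    between), and — for a seeded random ``island_fraction`` of genes — a
    CpG island centred on the promoter.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_genes
    starts = _GAP_LEN + np.arange(n) * (_BODY_LEN + _GAP_LEN)  # 0-based
    ends = starts + _BODY_LEN
    strands = np.where(np.arange(n) % 2 == 0, "+", "-")
    gene_ids = [f"gene{i + 1:04d}" for i in range(n)]
    tss_pos = np.where(strands == "+", starts + 1, ends)  # 1-based point

    exon_rows = []
    n_exons = rng.integers(1, 4, size=n)
    for i in range(n):
        k = int(n_exons[i])
        # split the body into 2k-1 alternating exon/intron chunks
        cuts = np.linspace(starts[i], ends[i], 2 * k, dtype=int) if k > 1 else None
        if k == 1:
            exon_rows.append((gene_ids[i], _CHROM, int(starts[i]), int(ends[i])))
        else:
            for j in range(k):
                exon_rows.append((gene_ids[i], _CHROM,
                                  int(cuts[2 * j]), int(cuts[2 * j + 1])))
    exons = pd.DataFrame(exon_rows, columns=["gene_id", "chrom", "start", "end"])

    has_island = rng.random(n) < config.island_fraction
    isl = pd.DataFrame({
        "chrom": _CHROM,
        "start": np.maximum(tss_pos[has_island] - 1 - _ISLAND_HALF, 0),
        "end": tss_pos[has_island] - 1 + _ISLAND_HALF,
    })
    tss = pd.DataFrame({"gene_id": gene_ids, "chrom": _CHROM,
                        "pos": tss_pos.astype(int), "strand": strands})
    return GenomeAnnotation(tss=tss, exons=exons, cpg_islands=isl)


def _truncated_poisson(rng: np.random.Generator, mean: float, size) -> np.ndarray:
    """Poisson(mean) conditioned on >= 1, by redrawing zeros."""
    out = rng.poisson(mean, size=size)
    while np.any(out == 0):
        zeros = out == 0
        out[zeros] = rng.poisson(mean, size=int(zeros.sum()))
    return out


def _beta_binomial(rng, cov, mu, rho):
    if rho < 1e-12:
        return rng.binomial(cov, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    p = rng.beta(np.maximum(a, 1e-8), np.maximum(b, 1e-8))
    return rng.binomial(cov, p)


def simulate_methylome(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    truth_out: TruthTable,
) -> CpGMatrix:
    """Draw beta-binomial CpG counts with group shifts at flagged sites.

    Per site s and sample j: coverage ~ Poisson(mean_coverage) truncated
    at >= 1; methylated ~ BetaBinomial(cov, mu_sj, bb_rho) with
    logit(mu_sj) = baseline_s + group_j * shift_s, where shift_s equals
    ``meth_logit_shift`` at the flagged ``prop_dmc`` fraction of sites
    and 0 elsewhere.  Baseline logits are uniform on [-2, 2].
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    samples = config.sample_table()
    group = samples.group_indicator()  # (n,)
    n_samples = len(group)

    # CpG placement: a fraction inside promoters, the rest uniform
    n_prom = int(round(config.promoter_cpg_fraction * config.n_cpg))
    hw = annotation.promoter_halfwidth
    tss = annotation.tss["pos"].to_numpy()
    chrom_len = int(annotation.gene_bodies["end"].max() + _GAP_LEN)
    which_gene = rng.integers(0, len(tss), size=n_prom)
    prom_pos = tss[which_gene] + rng.integers(-hw, hw + 1, size=n_prom)
    open_pos = rng.integers(1, chrom_len + 1, size=config.n_cpg - n_prom)
    pos = np.unique(np.concatenate([prom_pos, open_pos]))
    pos = pos[pos >= 1]
    n_sites = len(pos)

    baseline = rng.uniform(-2.0, 2.0, size=n_sites)
    is_dmc = np.zeros(n_sites, dtype=bool)
    n_dmc = int(round(config.prop_dmc * n_sites))
    if n_dmc > 0:
        is_dmc[rng.choice(n_sites, size=n_dmc, replace=False)] = True
    shift = np.where(is_dmc, config.meth_logit_shift, 0.0)

    cov = _truncated_poisson(rng, config.mean_coverage, (n_sites, n_samples))
    logits = baseline[:, None] + np.outer(shift, group)
    mu = 1.0 / (1.0 + np.exp(-logits))
    meth = _beta_binomial(rng, cov, mu, config.bb_rho)

    strand = np.where(np.arange(n_sites) % 2 == 0, "+", "-")
    sites = pd.DataFrame({"chrom": _CHROM, "pos": pos, "strand": strand})
    truth_out.cpg = pd.DataFrame({
        "chrom": _CHROM, "pos": pos, "strand": strand,
        "baseline_logit": baseline, "is_dmc": is_dmc, "shift": shift,
    })
    return CpGMatrix(sites=sites, coverage=cov, methylated=meth,
                     samples=samples.sample_ids)


def simulate_transcriptome(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    methylome: CpGMatrix,
    truth_out: TruthTable,
) -> pd.DataFrame:
    """Draw NB gene counts coupled to realised gene-level methylation.

    count_gj ~ NB(mean, dispersion) with
    log mean = log(mean_count) + group_j * lfc_g * ln 2
               + coupling_gamma * m_gj,
    where m_gj is the mean methylation proportion over the CpGs whose
    nearest TSS is gene g in sample j (0 for genes with no such CpG).
    Coupling acts on the realised proportions, so the pathway model can
    recover ``coupling_gamma`` from observable data.
    """
    from .annotation import annotate_sites  # deferred: avoids import cycle

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    samples = config.sample_table()
    group = samples.group_indicator()
    gene_ids = annotation.tss["gene_id"].tolist()
    n_genes = len(gene_ids)

    site_ann = annotate_sites(methylome.sites, annotation)
    props = methylome.proportions()
    m = np.zeros((n_genes, len(group)))
    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    nearest = site_ann["nearest_gene"].to_numpy()
    for g, idx in gene_pos.items():
        sel = nearest == g
        if sel.any():
            m[idx] = np.nanmean(props[sel], axis=0)

    is_deg = np.zeros(n_genes, dtype=bool)
    n_deg = int(round(config.prop_deg * n_genes))
    if n_deg > 0:
        is_deg[rng.choice(n_genes, size=n_deg, replace=False)] = True
    lfc = np.where(is_deg, config.lfc, 0.0)

    log_mean = (np.log(config.mean_count)
                + np.outer(lfc * np.log(2.0), group)
                + config.coupling_gamma * m)
    mean = np.exp(log_mean)
    disp = config.nb_dispersion
    if disp < 1e-8:
        counts = rng.poisson(mean)
    else:
        r = 1.0 / disp
        counts = rng.negative_binomial(r, r / (r + mean))

    truth_out.genes = pd.DataFrame({
        "gene_id": gene_ids, "is_deg": is_deg, "lfc": lfc,
        "coupling_gamma": config.coupling_gamma,
    })
    return pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"),
                        columns=samples.sample_ids)


def simulate_dataset(config: SimulationConfig):
    """Run all three generators; returns (annotation, methylome, counts,
    sample table, truth)."""
    truth = TruthTable()
    ann = simulate_annotation(config)
    meth = simulate_methylome(config, ann, truth)
    counts = simulate_transcriptome(config, ann, meth, truth)
    return ann, meth, counts, config.sample_table(), truth
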