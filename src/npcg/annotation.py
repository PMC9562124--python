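"""CpG site annotation: nearest TSS, gene structure, CpG-island context.

Conventions (pinned so boundary behaviour is testable):

* CpG positions are 1-based; BED intervals 0-based half-open.  A 1-based
  position ``pos`` lies in a BED interval [start, end) iff
  ``start < pos <= end``.
* A promoter covers TSS +/- 1000 bp inclusive of both endpoints (in
  1-based coordinates, |pos - tss| <= 1000).
* Shores are 2000 bp flanks on each side of a CpG island, excluding the
  island itself.
* Nearest-TSS assignment uses absolute genomic distance with no cutoff;
  strand is ignored for distance.  Equidistant TSS are resolved toward
  the smaller coordinate, then the lexicographically smaller gene id.
* Precedence: promoter > exon > intron > intergenic, and
  island > shore > open sea.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .containers import GenomeAnnotation

__all__ = ["annotate_sites", "genes_of"]

logger = logging.getLogger(__name__)

GENE_STRUCTURES = ("promoter", "exon", "intron", "intergenic")
CPG_CONTEXTS = ("island", "shore", "open_sea")


def _interval_trees(frame: pd.DataFrame, payload: str | None = None):
    """Per-chromosome IntervalTree over 0-based half-open rows."""
    trees: dict[str, IntervalTree] = {}
    for chrom, grp in frame.groupby("chrom"):
        data = zip(grp["start"], grp["end"],
                   grp[payload] if payload else [None] * len(grp))
        trees[chrom] = IntervalTree.from_tuples(
            (int(s), int(e), v) for s, e, v in data if e > s)
    return trees


def _nearest_tss(chrom: str, pos: np.ndarray, tss: pd.DataFrame):
    """Vectorised nearest TSS on one chromosome with deterministic ties."""
    sub = tss[tss["chrom"] == chrom]
    if sub.empty:
        return (np.array([None] * len(pos), dtype=object),
                np.full(len(pos), np.nan))
    # tie-break: sort by (pos, gene_id) and prefer the earlier record
    sub = sub.sort_values(["pos", "gene_id"], kind="mergesort")
    tpos = sub["pos"].to_numpy()
    tgene = sub["gene_id"].to_numpy()
    idx = np.searchsorted(tpos, pos)
    left = np.clip(idx - 1, 0, len(tpos) - 1)
    right = np.clip(idx, 0, len(tpos) - 1)
    dl = np.abs(pos - tpos[left])
    dr = np.abs(pos - tpos[right])
    # ties at equal distance go to the left (smaller coordinate / earlier id)
    pick_left = dl <= dr
    chosen = np.where(pick_left, left, right)
    signed = pos - tpos[chosen]
    return tgene[chosen], signed


def annotate_sites(sites: pd.DataFrame, ann: GenomeAnnotation) -> pd.DataFrame:
    """Annotate CpG sites with nearest gene, structure, and CpG context.

    Parameters
    ----------
    sites:
        DataFrame with columns ``chrom`` and ``pos`` (1-based), e.g.
        ``CpGMatrix.sites``.
    ann:
        Genome annotation providing TSS, exons and CpG islands.

    Returns
    -------
    pandas.DataFrame
        One row per input site, same order, with columns
        ``nearest_gene``, ``tss_distance`` (signed bp, 0 at the TSS),
        ``gene_structure`` and ``cpg_context``.  Sites on chromosomes
        absent from the annotation are intergenic/open_sea with a
        logged warning.
    """
    sites = sites.reset_index(drop=True)
    # promoter [tss-1000, tss+1000] inclusive (1-based) as 0-based half-open
    prom = pd.DataFrame({
        "chrom": ann.tss["chrom"],
        "start": np.maximum(ann.tss["pos"] - 1 - ann.promoter_halfwidth, 0),
        "end": ann.tss["pos"] + ann.promoter_halfwidth,
    })
    prom_trees = _interval_trees(prom)
    exon_trees = _interval_trees(ann.exons, "gene_id")
    intron_trees = _interval_trees(ann.introns(), "gene_id")
    island_trees = _interval_trees(ann.cpg_islands)
    shores = _shore_intervals(ann)
    shore_trees = _interval_trees(shores)
    known = set(ann.tss["chrom"]) | set(exon_trees) | set(island_trees)

    out_gene = np.empty(len(sites), dtype=object)
    out_dist = np.full(len(sites), np.nan)
    out_struct = np.empty(len(sites), dtype=object)
    out_ctx = np.empty(len(sites), dtype=object)

    for chrom, grp in sites.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        rows = grp.index.to_numpy()
        if chrom not in known:
            logger.warning("chromosome %s absent from annotation; "
                           "sites marked intergenic/open_sea", chrom)
            out_gene[rows] = None
            out_struct[rows] = "intergenic"
            out_ctx[rows] = "open_sea"
            continue
        gene, signed = _nearest_tss(chrom, pos, ann.tss)
        out_gene[rows] = gene
        out_dist[rows] = signed
        ptree = prom_trees.get(chrom, IntervalTree())
        etree = exon_trees.get(chrom, IntervalTree())
        itree = intron_trees.get(chrom, IntervalTree())
        ktree = island_trees.get(chrom, IntervalTree())
        stree = shore_trees.get(chrom, IntervalTree())
        for r, p in zip(rows, pos):
            # 1-based point p overlaps BED interval iff it contains p-1
            if ptree.overlaps_point(int(p) - 1):
                out_struct[r] = "promoter"
            elif etree.overlaps_point(int(p) - 1):
                out_struct[r] = "exon"
            elif itree.overlaps_point(int(p) - 1):
                out_struct[r] = "intron"
            else:
                out_struct[r] = "intergenic"
            if ktree.overlaps_point(int(p) - 1):
                out_ctx[r] = "island"
            elif stree.overlaps_point(int(p) - 1):
                out_ctx[r] = "shore"
            else:
                out_ctx[r] = "open_sea"
    res = sites[["chrom", "pos"]].copy()
    res["nearest_gene"] = out_gene
    res["tss_distance"] = out_dist
    res["gene_structure"] = out_struct
    res["cpg_context"] = out_ctx
    return res


def _shore_intervals(ann: GenomeAnnotation) -> pd.DataFrame:
    """Island flanks of ``shore_width`` bp, island bases excluded."""
    w = ann.shore_width
    isl = ann.cpg_islands
    left = pd.DataFrame({"chrom": isl["chrom"],
                         "start": np.maximum(isl["start"] - w, 0),
                         "end": isl["start"]})
    right = pd.DataFrame({"chrom": isl["chrom"], "start": isl["end"],
                          "end": isl["end"] + w})
    shores = pd.concat([left, right], ignore_index=True)
    return shores[shores["end"] > shores["start"]]


def genes_of(
    dmc: pd.DataFrame,
    site_ann: pd.DataFrame,
    genic_only: bool = False,
    status_col: str = "status",
) -> set[str]:
    """Unique nearest-gene ids of significant sites.

    ``dmc`` is a DMC table carrying ``chrom``/``pos`` and a status
    column whose value ``"ns"`` marks non-significant sites; rows with
    any other status count.  With ``genic_only``, intergenic sites are
    excluded.
    """
    ann_idx = site_ann.set_index(["chrom", "pos"])
    sig = dmc[dmc[status_col] != "ns"] if status_col in dmc.columns else dmc
    genes: set[str] = set()
    for _, row in sig.iterrows():
        rec = ann_idx.loc[(row["chrom"], row["pos"])]
        if genic_only and rec["gene_structure"] == "intergenic":
            continue
        if rec["nearest_gene"] is not None:
            genes.add(rec["nearest_gene"])
    return genes
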