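"""Nearest-TSS assignment and structure/context classification."""

import numpy as np
import pandas as pd
import pytest

from npcg.annotation import annotate_sites, genes_of
from npcg.containers import GenomeAnnotation


@pytest.fixture
def toy_annotation():
    """Two genes on chr1: TSS at 5000 and 20000 (1-based), an island at
    [9999, 10600) (0-based half-open), exons covering parts of the
    bodies."""
    tss = pd.DataFrame({
        "gene_id": ["gA", "gB"], "chrom": "chr1",
        "pos": [5000, 20000], "strand": ["+", "+"]})
    exons = pd.DataFrame({
        "gene_id": ["gA", "gA", "gB"], "chrom": "chr1",
        "start": [4999, 8000, 19999], "end": [6500, 9000, 21000]})
    islands = pd.DataFrame({"chrom": ["chr1"], "start": [9999],
                            "end": [10600]})
    return GenomeAnnotation(tss=tss, exons=exons, cpg_islands=islands)


def brute_force_annotation(sites, ann):
    """Exhaustive interval-membership / nearest-neighbor oracle."""
    out = []
    introns = ann.introns()
    for _, row in sites.iterrows():
        pos, chrom = row["pos"], row["chrom"]
        tss = ann.tss[ann.tss["chrom"] == chrom]
        if tss.empty:
            out.append((None, np.nan, "intergenic", "open_sea"))
            continue
        dists = (pos - tss["pos"]).to_numpy()
        best = min(range(len(tss)),
                   key=lambda i: (abs(dists[i]), tss["pos"].iloc[i],
                                  tss["gene_id"].iloc[i]))
        gene, signed = tss["gene_id"].iloc[best], dists[best]

        def in_any(frame):
            sub = frame[frame["chrom"] == chrom]
            return any(s < pos <= e for s, e in zip(sub["start"], sub["end"]))

        in_prom = any(abs(pos - t) <= ann.promoter_halfwidth
                      for t in tss["pos"])
        if in_prom:
            struct = "promoter"
        elif in_any(ann.exons):
            struct = "exon"
        elif in_any(introns):
            struct = "intron"
        else:
            struct = "intergenic"
        isl = ann.cpg_islands
        shore_frames = pd.concat([
            pd.DataFrame({"chrom": isl["chrom"],
                          "start": isl["start"] - ann.shore_width,
                          "end": isl["start"]}),
            pd.DataFrame({"chrom": isl["chrom"], "start": isl["end"],
                          "end": isl["end"] + ann.shore_width})])
        if in_any(isl):
            ctx = "island"
        elif in_any(shore_frames):
            ctx = "shore"
        else:
            ctx = "open_sea"
        out.append((gene, signed, struct, ctx))
    return out


def test_site_at_tss(toy_annotation):
    sites = pd.DataFrame({"chrom": ["chr1"], "pos": [5000]})
    res = annotate_sites(sites, toy_annotation)
    assert res["tss_distance"][0] == 0
    assert res["gene_structure"][0] == "promoter"
    assert res["nearest_gene"][0] == "gA"


def test_promoter_boundary_inclusive_at_1000bp(toy_annotation):
    """tss+1000 is inside the promoter; tss+1001 is not."""
    sites = pd.DataFrame({"chrom": "chr1", "pos": [6000, 6001]})
    res = annotate_sites(sites, toy_annotation)
    assert res["gene_structure"][0] == "promoter"
    assert res["gene_structure"][1] == "exon"  # falls into gA's first exon


def test_ten_site_fixture_matches_bruteforce(toy_annotation):
    """Hand-built sites spanning every category vs the exhaustive oracle."""
    sites = pd.DataFrame({"chrom": "chr1", "pos": [
        5000,   # TSS itself -> promoter
        6000,   # promoter boundary
        6499,   # exon (inside gA exon 1, beyond +/-1000)
        7000,   # intron (between gA exons)
        8500,   # exon (gA exon 2)
        10100,  # island, intergenic
        10900,  # right shore of the island
        8500 - 500,  # island left shore? no: 8000 exon, shore starts 7999
        15000,  # open sea, intergenic, nearest gB
        21000 + 2000,  # downstream of gB body -> intergenic
    ]})
    res = annotate_sites(sites, toy_annotation)
    oracle = brute_force_annotation(sites, toy_annotation)
    for i, (gene, signed, struct, ctx) in enumerate(oracle):
        assert res["nearest_gene"][i] == gene
        assert res["tss_distance"][i] == signed
        assert res["gene_structure"][i] == struct, f"site {i}"
        assert res["cpg_context"][i] == ctx, f"site {i}"


def test_random_sites_match_bruteforce(toy_annotation, rng):
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.sort(rng.integers(1, 30000, 300))})
    res = annotate_sites(sites, toy_annotation)
    oracle = brute_force_annotation(sites, toy_annotation)
    for i, (gene, signed, struct, ctx) in enumerate(oracle):
        assert res["nearest_gene"][i] == gene
        assert res["gene_structure"][i] == struct
        assert res["cpg_context"][i] == ctx


def test_category_partition(toy_annotation, rng):
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.sort(rng.integers(1, 30000, 200))})
    res = annotate_sites(sites, toy_annotation)
    assert res["gene_structure"].isin(
        ["promoter", "exon", "intron", "intergenic"]).all()
    assert res["cpg_context"].isin(["island", "shore", "open_sea"]).all()
    assert res["gene_structure"].value_counts().sum() == len(sites)


def test_translation_invariance(toy_annotation, rng):
    """Shifting annotation and sites by a constant preserves categories."""
    shift = 7919
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.sort(rng.integers(1, 30000, 100))})
    res = annotate_sites(sites, toy_annotation)
    moved = GenomeAnnotation(
        tss=toy_annotation.tss.assign(pos=toy_annotation.tss["pos"] + shift),
        exons=toy_annotation.exons.assign(
            start=toy_annotation.exons["start"] + shift,
            end=toy_annotation.exons["end"] + shift),
        cpg_islands=toy_annotation.cpg_islands.assign(
            start=toy_annotation.cpg_islands["start"] + shift,
            end=toy_annotation.cpg_islands["end"] + shift))
    res2 = annotate_sites(sites.assign(pos=sites["pos"] + shift), moved)
    assert (res["gene_structure"] == res2["gene_structure"]).all()
    assert (res["cpg_context"] == res2["cpg_context"]).all()
    assert (res["nearest_gene"] == res2["nearest_gene"]).all()


def test_unknown_chromosome_warns(toy_annotation, caplog):
    sites = pd.DataFrame({"chrom": ["chrUn"], "pos": [100]})
    import logging
    with caplog.at_level(logging.WARNING):
        res = annotate_sites(sites, toy_annotation)
    assert res["gene_structure"][0] == "intergenic"
    assert res["cpg_context"][0] == "open_sea"
    assert "chrUn" in caplog.text


def test_equidistant_tie_goes_to_smaller_coordinate():
    tss = pd.DataFrame({"gene_id": ["gZ", "gA"], "chrom": "chr1",
                        "pos": [100, 300], "strand": "+"})
    exons = pd.DataFrame({"gene_id": ["gZ", "gA"], "chrom": "chr1",
                          "start": [99, 299], "end": [150, 350]})
    ann = GenomeAnnotation(tss=tss, exons=exons,
                           cpg_islands=pd.DataFrame(
                               columns=["chrom", "start", "end"]))
    res = annotate_sites(pd.DataFrame({"chrom": ["chr1"], "pos": [200]}), ann)
    assert res["nearest_gene"][0] == "gZ"


class TestGenesOf:
    def _fixture(self):
        site_ann = pd.DataFrame({
            "chrom": "chr1", "pos": [10, 20, 30, 40, 50],
            "nearest_gene": ["g1", "g1", "g2", "g3", "g3"],
            "tss_distance": [0, 5, 10, 2000, 0],
            "gene_structure": ["promoter", "exon", "promoter", "intergenic",
                               "promoter"],
            "cpg_context": ["open_sea"] * 5})
        dmc = pd.DataFrame({"chrom": "chr1", "pos": [10, 20, 30, 40, 50],
                            "status": ["hyper", "hyper", "hypo", "hyper",
                                       "ns"]})
        return dmc, site_ann

    def test_zero_dmc_empty_set(self):
        dmc, site_ann = self._fixture()
        dmc["status"] = "ns"
        assert genes_of(dmc, site_ann) == set()

    def test_deduplication(self):
        dmc, site_ann = self._fixture()
        assert genes_of(dmc, site_ann) == {"g1", "g2", "g3"}

    def test_genic_only_drops_intergenic_site(self):
        dmc, site_ann = self._fixture()
        # g3's only significant site (pos 40) is intergenic
        assert genes_of(dmc, site_ann, genic_only=True) == {"g1", "g2"}
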