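"""Per-gene summarisation, stage p-values, and the permutation engine."""

import itertools

import numpy as np
import pandas as pd
import pytest

from npcg.containers import CpGMatrix, SampleTable
from npcg.expression import test_deg as call_deg
from npcg.methylation import test_dmc as call_dmc
from npcg.npc import (build_gene_omics, enumerate_assignments,
                      npc_combine, stage_pvalues,
                      summarize_methylation_per_gene, _fisher_t)


def _site_ann(genes):
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, len(genes) + 1) * 10,
        "nearest_gene": genes,
        "tss_distance": 0, "gene_structure": "promoter",
        "cpg_context": "open_sea"})


def _cpg(cov, meth, samples):
    sites = pd.DataFrame({"chrom": "chr1",
                          "pos": np.arange(1, len(cov) + 1) * 10,
                          "strand": "+"})
    return CpGMatrix(sites=sites, coverage=np.asarray(cov),
                     methylated=np.asarray(meth), samples=samples)


class TestSummarize:
    def test_single_site_gene(self):
        m = _cpg([[10]], [[5]], ["s0"])
        out = summarize_methylation_per_gene(m, _site_ann(["g1"]))
        assert out.loc["g1", "s0"] == pytest.approx(0.5)

    def test_unweighted_average_of_proportions(self):
        # 0.2 (2/10) and 0.8 (80/100): unweighted mean 0.5, not pooled
        m = _cpg([[10], [100]], [[2], [80]], ["s0"])
        out = summarize_methylation_per_gene(m, _site_ann(["g1", "g1"]))
        assert out.loc["g1", "s0"] == pytest.approx(0.5)

    def test_three_genes_four_sites_hand_computed(self):
        cov = [[10, 20], [10, 20], [10, 20], [10, 20]]
        meth = [[1, 2], [3, 4], [5, 6], [7, 8]]
        genes = ["gA", "gA", "gB", "gC"]
        out = summarize_methylation_per_gene(
            _cpg(cov, meth, ["s0", "s1"]), _site_ann(genes))
        assert out.loc["gA", "s0"] == pytest.approx((0.1 + 0.3) / 2)
        assert out.loc["gA", "s1"] == pytest.approx((0.1 + 0.2) / 2)
        assert out.loc["gB", "s0"] == pytest.approx(0.5)
        assert out.loc["gC", "s1"] == pytest.approx(0.4)


@pytest.fixture(scope="module")
def omics_with_signal():
    """16 genes, 4 vs 4, methylation and expression signal in gene g01."""
    rng = np.random.default_rng(42)
    samples = [f"s{i}" for i in range(8)]
    st = SampleTable(pd.DataFrame({"sample_id": samples,
                                   "group": ["A"] * 4 + ["B"] * 4}), "A")
    genes = [f"g{i:02d}" for i in range(16)]
    site_genes = np.repeat(genes, 3)
    cov = rng.poisson(30, (len(site_genes), 8)) + 1
    p = np.full((len(site_genes), 8), 0.4)
    p[site_genes == "g01", 4:] = 0.85
    meth = rng.binomial(cov, p)
    cpg = _cpg(cov, meth, samples)
    mu = np.full((16, 8), 80.0)
    mu[1, 4:] = 300.0
    counts = pd.DataFrame(rng.negative_binomial(20, 20 / (20 + mu)),
                          index=genes, columns=samples)
    return cpg, _site_ann(list(site_genes)), counts, st


def test_build_gene_omics_matches_features(omics_with_signal):
    cpg, site_ann, counts, st = omics_with_signal
    go = build_gene_omics(cpg, site_ann, counts.iloc[:10])
    assert go.gene_ids == sorted(counts.index[:10])
    assert go.meth.shape == (10, 8)
    # pooled counts equal the sum over the gene's sites
    i = go.gene_ids.index("g03")
    sel = site_ann["nearest_gene"] == "g03"
    assert np.array_equal(go.meth[i], cpg.methylated[sel.to_numpy()].sum(0))


def test_stage_pvalues_consistent_with_single_omic_modules(omics_with_signal):
    cpg, site_ann, counts, st = omics_with_signal
    go = build_gene_omics(cpg, site_ann, counts)
    pm, pe = stage_pvalues(go, st)
    deg = call_deg(counts.loc[go.gene_ids], st)
    assert np.allclose(pe, deg["p_value"].to_numpy(), atol=1e-10)
    # methylation stage: same p as running the site-level DMC test on the
    # gene-pooled counts
    pooled = CpGMatrix(
        sites=pd.DataFrame({"chrom": "chr1",
                            "pos": np.arange(1, len(go.gene_ids) + 1),
                            "strand": "+"}),
        coverage=go.cov.astype(int), methylated=go.meth.astype(int),
        samples=go.samples)
    dmc = call_dmc(pooled, st)
    assert np.allclose(pm, dmc["p_value"].to_numpy(), atol=1e-10)


def test_stage_pvalues_signal_lands_in_right_stage(omics_with_signal):
    cpg, site_ann, counts, st = omics_with_signal
    go = build_gene_omics(cpg, site_ann, counts)
    pm, pe = stage_pvalues(go, st)
    i = go.gene_ids.index("g01")
    assert pm[i] < 0.01 and pe[i] < 0.01
    assert np.median(np.delete(pm, i)) > 0.1


def test_stage_pvalues_group_swap_invariant(omics_with_signal):
    cpg, site_ann, counts, st = omics_with_signal
    go = build_gene_omics(cpg, site_ann, counts)
    pm, pe = stage_pvalues(go, st)
    swapped = st.table["group"].map({"A": "B", "B": "A"}).to_numpy()
    pm2, pe2 = stage_pvalues(go, st, labels=swapped)
    assert np.allclose(pm, pm2, atol=1e-8)
    assert np.allclose(pe, pe2, atol=1e-8)


def test_constant_methylation_gives_p_one():
    samples = [f"s{i}" for i in range(8)]
    st = SampleTable(pd.DataFrame({"sample_id": samples,
                                   "group": ["A"] * 4 + ["B"] * 4}), "A")
    cpg = _cpg([np.full(8, 20)], [np.full(8, 10)], samples)
    counts = pd.DataFrame(np.full((1, 8), 50), index=["g1"], columns=samples)
    go = build_gene_omics(cpg, _site_ann(["g1"]), counts)
    pm, _ = stage_pvalues(go, st)
    assert pm[0] > 0.99


class TestFisherT:
    def test_zero_statistic_at_p_one(self):
        assert _fisher_t(np.array([1.0]), np.array([1.0]))[0] == 0.0

    def test_nonnegative_and_floors_zero(self):
        with pytest.warns(UserWarning, match="floored"):
            t = _fisher_t(np.array([0.0]), np.array([0.5]))
        assert np.isfinite(t[0]) and t[0] > 0


class TestPermutationEngine:
    def test_enumeration_counts_c_8_4(self):
        groups = np.array(["A"] * 4 + ["B"] * 4)
        assigns = enumerate_assignments(groups, "A")
        # oracle: explicit enumeration of C(8,4) index subsets
        oracle = set(itertools.combinations(range(8), 4))
        got = {tuple(np.flatnonzero(a == "A")) for a in assigns}
        assert len(assigns) == 70 and got == oracle
        assert np.array_equal(assigns[0], groups)  # observed first

    def test_p_one_when_both_stage_ps_one(self):
        samples = [f"s{i}" for i in range(8)]
        st = SampleTable(pd.DataFrame({"sample_id": samples,
                                       "group": ["A"] * 4 + ["B"] * 4}), "A")
        cpg = _cpg([np.full(8, 20)], [np.full(8, 10)], samples)
        counts = pd.DataFrame(np.full((1, 8), 50), index=["g1"],
                              columns=samples)
        go = build_gene_omics(cpg, _site_ann(["g1"]), counts)
        res = npc_combine(go, st, B=1000, seed=0)
        assert res["fisher_t"].iloc[0] == pytest.approx(0.0, abs=1e-8)
        assert res["p_combined"].iloc[0] == 1.0
        assert not res["is_npcg"].iloc[0]

    def test_exhaustive_p_granularity_and_signal(self, omics_with_signal):
        cpg, site_ann, counts, st = omics_with_signal
        go = build_gene_omics(cpg, site_ann, counts)
        res = npc_combine(go, st, B=1000, seed=0)
        assert np.all(res["p_combined"] >= 1 / 70 - 1e-12)
        # two-sided stage tests are label-swap invariant, so T values come
        # in complement pairs: the smallest attainable exhaustive p is 2/70
        assert res.loc["g01", "p_combined"] == pytest.approx(2 / 70)
        assert res.loc["g01", "is_npcg"]
        assert res.loc["g01", "direction"] == 1.0

    def test_sampled_mode_seed_reproducible(self, omics_with_signal):
        cpg, site_ann, counts, st = omics_with_signal
        go = build_gene_omics(cpg, site_ann, counts)
        a = npc_combine(go, st, B=20, seed=3)
        b = npc_combine(go, st, B=20, seed=3)
        pd.testing.assert_frame_equal(a, b)
        assert np.all(a["p_combined"] >= 1 / 21 - 1e-12)

    def test_minp_reduction_flag(self, omics_with_signal):
        cpg, site_ann, counts, st = omics_with_signal
        go = build_gene_omics(cpg, site_ann, counts)
        res = npc_combine(go, st, B=1000, seed=1, meth_reduction="minp")
        assert res.loc["g01", "p_combined"] < 0.05

    def test_invalid_args(self, omics_with_signal):
        cpg, site_ann, counts, st = omics_with_signal
        go = build_gene_omics(cpg, site_ann, counts)
        with pytest.raises(ValueError):
            npc_combine(go, st, B=0)
        with pytest.raises(ValueError):
            npc_combine(go, st, permute_mode="sideways")


def test_combined_p_attains_minimum_for_consistent_signal(omics_with_signal):
    """Consistent two-omic signal drives the combined p to the smallest
    value the 70-assignment permutation scheme can produce, i.e. the
    combination loses none of the evidence either partial test carries."""
    cpg, site_ann, counts, st = omics_with_signal
    go = build_gene_omics(cpg, site_ann, counts)
    res = npc_combine(go, st, B=1000, seed=0)
    assert res.loc["g01", "p_combined"] == res["p_combined"].min()
    assert res.loc["g01", "p_combined"] == pytest.approx(2 / 70)
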