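"""Ordination, Spearman/centroid clustering, overlaps, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from npcg.cluster import (cluster_npcg, enrich_hypergeometric, overlap_sets,
                          pca_samples, spearman_distance)


class TestPCA:
    def test_duplicated_samples_coincide(self, rng):
        base = rng.poisson(50, (40, 1))
        mat = pd.DataFrame(np.hstack([base, base, base + 0,
                                      rng.poisson(50, (40, 1))]),
                           columns=["a", "b", "c", "d"])
        coords, _ = pca_samples(mat, normalized=False)
        assert np.allclose(coords.loc["a"], coords.loc["b"], atol=1e-8)

    def test_variance_fractions_sorted_and_bounded(self, rng):
        mat = pd.DataFrame(rng.poisson(60, (100, 6)))
        coords, var = pca_samples(mat, normalized=True)
        assert np.all(np.diff(var) <= 1e-12)
        assert var.sum() <= 1 + 1e-9

    def test_pc1_separates_planted_groups(self, rng):
        mu = np.full((200, 6), 50.0)
        mu[:60, 3:] *= 3.0  # group structure in samples 3-5
        mat = pd.DataFrame(rng.poisson(mu))
        coords, var = pca_samples(mat, normalized=True)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:3].max() < pc1[3:].min()) or (pc1[:3].min()
                                                   > pc1[3:].max())

    def test_constant_matrix_rejected(self):
        mat = pd.DataFrame(np.full((10, 4), 7))
        with pytest.raises(ValueError, match="constant"):
            pca_samples(mat, normalized=False)


class TestSpearmanDistance:
    def test_range_symmetry_and_monotone_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 10)))
        # add a monotone transform of row 0 and a constant row
        expr.loc[20] = np.exp(expr.loc[0] * 2)
        expr.loc[21] = 5.0
        d = spearman_distance(expr)
        assert np.allclose(d, d.T)
        assert np.all((d >= 0) & (d <= 2))
        assert np.allclose(np.diag(d), 0)
        assert d[0, 20] == pytest.approx(0.0, abs=1e-12)  # rank invariance
        assert d[21, 0] == pytest.approx(1.0)  # constant row -> corr 0

    def test_matches_scipy_spearmanr(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 12)))
        d = spearman_distance(expr)
        for i, j in itertools.combinations(range(8), 2):
            rho = stats.spearmanr(expr.iloc[i], expr.iloc[j]).statistic
            assert d[i, j] == pytest.approx(1 - rho, abs=1e-12)


def centroid_linkage_oracle(d2):
    """Direct centroid-distance formula on the original squared
    distances (independent of the Lance-Williams recurrence):

    ||c_A - c_B||^2 = mean_{a in A, b in B} d2(a,b)
                      - mean_{a,a' in A} d2(a,a')/2
                      - mean_{b,b' in B} d2(b,b')/2
    """
    n = d2.shape[0]
    clusters = {i: [i] for i in range(n)}
    rep = {i: i for i in range(n)}
    heights = []

    def cdist2(A, B):
        cross = np.mean([d2[a, b] for a in A for b in B])
        within_a = (np.mean([d2[a, b] for a in A for b in A]) / 2
                    if len(A) > 1 else 0.0)
        within_b = (np.mean([d2[a, b] for a in B for b in B]) / 2
                    if len(B) > 1 else 0.0)
        return cross - within_a - within_b

    next_id = n
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for x, y in itertools.combinations(keys, 2):
            d = cdist2(clusters[x], clusters[y])
            key = (d, min(rep[x], rep[y]), max(rep[x], rep[y]))
            if best is None or key < best[0]:
                best = (key, x, y)
        (_, x, y) = best[1:], best[1], best[2]
        heights.append(np.sqrt(max(best[0][0], 0.0)))
        clusters[next_id] = clusters.pop(x) + clusters.pop(y)
        rep[next_id] = min(rep[x], rep[y])
        next_id += 1
    return np.array(heights)


class TestCentroidLinkage:
    def test_merge_heights_match_direct_centroid_oracle(self, rng):
        """30-gene random fixture: recurrence vs direct centroid formula."""
        expr = pd.DataFrame(rng.normal(size=(30, 8)))
        res = cluster_npcg(expr, k=2)
        d = spearman_distance(expr)
        oracle = centroid_linkage_oracle(d**2)
        assert np.allclose(res.merges[:, 2], oracle, atol=1e-8)

    def test_two_anticorrelated_blocks_recovered(self, rng):
        t = np.linspace(0, 1, 10)
        up = np.outer(np.ones(15), t) + rng.normal(0, 0.01, (15, 10))
        down = np.outer(np.ones(15), -t) + rng.normal(0, 0.01, (15, 10))
        expr = pd.DataFrame(np.vstack([up, down]),
                            index=[f"u{i}" for i in range(15)]
                            + [f"d{i}" for i in range(15)])
        res = cluster_npcg(expr, k=2)
        labels = res.assignment
        assert labels[[f"u{i}" for i in range(15)]].nunique() == 1
        assert labels[[f"d{i}" for i in range(15)]].nunique() == 1
        assert (labels["u0"] != labels["d0"])

    def test_leaf_order_is_permutation(self, rng):
        expr = pd.DataFrame(rng.normal(size=(12, 6)))
        res = cluster_npcg(expr, k=2)
        assert sorted(res.leaf_order) == list(range(12))

    def test_clusters_partition_genes(self, rng):
        expr = pd.DataFrame(rng.normal(size=(15, 6)),
                            index=[f"g{i}" for i in range(15)])
        res = cluster_npcg(expr, k=3)
        assert set(res.assignment.index) == set(expr.index)
        assert res.assignment.nunique() == 3

    def test_deterministic_for_fixed_input(self, rng):
        expr = pd.DataFrame(rng.normal(size=(20, 6)))
        a = cluster_npcg(expr, k=2)
        b = cluster_npcg(expr, k=2)
        assert np.array_equal(a.merges, b.merges)
        assert a.leaf_order == b.leaf_order

    def test_input_validation(self, rng):
        expr = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(ValueError):
            cluster_npcg(expr, k=4)
        with pytest.raises(ValueError):
            cluster_npcg(expr.iloc[:, :1], k=2)


class TestOverlaps:
    def test_disjoint(self):
        out = overlap_sets(a={1, 2}, b={3, 4})
        assert out[("a", "b")] == 0
        assert out[("a",)] == 2 and out[("b",)] == 2

    def test_identical(self):
        out = overlap_sets(a={1, 2}, b={1, 2})
        assert out[("a", "b")] == 2
        assert out[("a",)] == 0 and out[("b",)] == 0

    def test_random_matches_set_algebra(self, rng):
        a = set(rng.integers(0, 50, 30).tolist())
        b = set(rng.integers(0, 50, 30).tolist())
        c = set(rng.integers(0, 50, 30).tolist())
        out = overlap_sets(A=a, B=b, C=c)
        assert out[("A", "B", "C")] == len(a & b & c)
        assert out[("A",)] == len(a - b - c)
        assert out[("A", "B")] == len((a & b) - c)
        assert sum(out.values()) == len(a | b | c)


class TestEnrichment:
    def test_full_set_is_most_enriched(self):
        universe = {f"g{i}" for i in range(100)}
        sets = {"hit": {f"g{i}" for i in range(10)},
                "other": {f"g{i}" for i in range(50, 70)}}
        res = enrich_hypergeometric({f"g{i}" for i in range(10)}, sets,
                                    universe)
        assert res.loc["hit", "p_value"] == res["p_value"].min()
        assert res.loc["hit", "overlap"] == 10

    def test_no_overlap_p_one(self):
        universe = {f"g{i}" for i in range(40)}
        res = enrich_hypergeometric(
            {f"g{i}" for i in range(10)},
            {"s": {f"g{i}" for i in range(20, 30)}}, universe)
        assert res.loc["s", "p_value"] == pytest.approx(1.0)

    def test_matches_bruteforce_tail_sum(self):
        """20-gene toy vs exact combinatorial enumeration."""
        from math import comb
        universe = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(8)}
        gene_set = {f"g{i}" for i in range(5, 12)}  # |set|=7, overlap=3
        res = enrich_hypergeometric(query, {"s": gene_set}, universe)
        M, n, N, k = 20, 7, 8, 3
        tail = sum(comb(n, x) * comb(M - n, N - x) / comb(M, N)
                   for x in range(k, min(n, N) + 1))
        assert res.loc["s", "p_value"] == pytest.approx(tail, rel=1e-12)
        assert res.loc["s", "overlap"] == 3

    def test_validation(self):
        with pytest.raises(ValueError, match="universe"):
            enrich_hypergeometric({"a"}, {}, set())
        with pytest.raises(ValueError, match="subset"):
            enrich_hypergeometric({"zz"}, {}, {"a"})
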