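"""Sample ordination, NPCG clustering, set overlaps and enrichment.

NPCG expression profiles are clustered agglomeratively with centroid
linkage on the Spearman rank-correlation distance (d = 1 - rho), the
similarity/linkage pair used for the study's heat maps.  The centroid
recurrence is applied directly in the distance-embedded space (Lance-
Williams update on squared distances); inversions — merge heights that
dip below an earlier merge — can occur with centroid linkage and are
permitted, so the two-cluster cut is defined by the merge sequence (the
state just before the last k-1 merges) rather than by a height
threshold.  Distance ties are broken by lexicographic gene-pair order,
making the dendrogram deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import size_factors
from .multitest import bh_adjust

__all__ = [
    "pca_samples",
    "spearman_distance",
    "ClusterResult",
    "cluster_npcg",
    "overlap_sets",
    "enrich_hypergeometric",
    "normalize_log",
    "to_newick",
    "export_heatmap_text",
    "plot_heatmap",
]


def normalize_log(counts: pd.DataFrame) -> pd.DataFrame:
    """log1p of size-factor-normalised counts."""
    sf = size_factors(counts)
    return np.log1p(counts / sf)


def pca_samples(matrix: pd.DataFrame, normalized: bool = True):
    """Principal components of the samples (columns) of an omics matrix.

    ``matrix`` is features x samples; with ``normalized`` the counts are
    size-factor-scaled and log1p-transformed first (skip for methylation
    proportions).  Returns (coordinates DataFrame samples x PCs,
    variance-explained fractions).
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    X = normalize_log(matrix) if normalized else matrix
    A = X.to_numpy(dtype=float).T  # samples x features
    A = A - A.mean(axis=0, keepdims=True)
    if np.allclose(A, 0):
        raise ValueError("constant matrix: PCA undefined")
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    coords = U * s
    var = s**2 / (s**2).sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (pd.DataFrame(coords, index=matrix.columns, columns=cols),
            var)


def spearman_distance(expr: pd.DataFrame) -> np.ndarray:
    """Pairwise 1 - Spearman correlation between rows (genes).

    Ties receive average ranks; a zero-variance profile is defined to
    have correlation 0 with everything (distance 1) instead of NaN.
    """
    ranks = np.apply_along_axis(stats.rankdata, 1, expr.to_numpy(dtype=float))
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((centered**2).sum(axis=1))
    safe = norm > 0
    denom = np.where(safe, norm, 1.0)
    unit = centered / denom[:, None]
    corr = unit @ unit.T
    corr[~safe, :] = 0.0
    corr[:, ~safe] = 0.0
    np.fill_diagonal(corr, 1.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class ClusterResult:
    """Agglomerative clustering output.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height,
    size); original genes are clusters 0..n-1, the i-th merge creates
    cluster n+i (scipy linkage convention).
    """

    genes: list[str]
    merges: np.ndarray  # (n-1, 4)
    leaf_order: list[int]
    assignment: pd.Series  # gene -> cluster label (0..k-1)

    def cluster_genes(self, label: int) -> list[str]:
        return self.assignment.index[self.assignment == label].tolist()


def _centroid_linkage(d2: np.ndarray) -> np.ndarray:
    """Centroid linkage from a squared-distance matrix (Lance-Williams).

    Ties in merge distance resolve toward the lexicographically smallest
    (smallest-leaf-index) cluster pair.
    """
    n = d2.shape[0]
    d2 = d2.astype(float).copy()
    sizes = {i: 1 for i in range(n)}
    rep = {i: i for i in range(n)}  # smallest original leaf in cluster
    # grow the matrix to hold merged clusters
    full = np.full((2 * n - 1, 2 * n - 1), np.inf)
    full[:n, :n] = d2
    merges = np.zeros((n - 1, 4))
    alive = list(range(n))
    for m in range(n - 1):
        idx = np.array(alive)
        sub = full[np.ix_(idx, idx)]
        iu, ju = np.triu_indices(len(idx), k=1)
        vals = sub[iu, ju]
        dmin = vals.min()
        cand = np.flatnonzero(vals <= dmin + 1e-15)
        best = min(
            cand,
            key=lambda c: (min(rep[idx[iu[c]]], rep[idx[ju[c]]]),
                           max(rep[idx[iu[c]]], rep[idx[ju[c]]])),
        )
        a, b = int(idx[iu[best]]), int(idx[ju[best]])
        na, nb = sizes[a], sizes[b]
        dab2 = full[a, b]
        new = n + m
        for c in alive:
            if c in (a, b):
                continue
            full[new, c] = full[c, new] = (
                (na * full[a, c] + nb * full[b, c]) / (na + nb)
                - na * nb * dab2 / (na + nb) ** 2
            )
        sizes[new] = na + nb
        rep[new] = min(rep[a], rep[b])
        lo, hi = (a, b) if rep[a] <= rep[b] else (b, a)
        merges[m] = (lo, hi, np.sqrt(max(dab2, 0.0)), na + nb)
        alive = [c for c in alive if c not in (a, b)] + [new]
    return merges


def _leaf_order(merges: np.ndarray, n: int) -> list[int]:
    children = {n + i: (int(merges[i, 0]), int(merges[i, 1]))
                for i in range(len(merges))}

    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = children[node]
        return walk(a) + walk(b)

    return walk(n + len(merges) - 1) if len(merges) else list(range(n))


def _cut_k(merges: np.ndarray, n: int, k: int) -> np.ndarray:
    """Cluster labels from the state before the last k-1 merges."""
    parent = list(range(2 * n - 1))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    stop = max(n - k, 0)
    for i in range(stop):
        a, b = int(merges[i, 0]), int(merges[i, 1])
        parent[find(a)] = parent[find(b)] = n + i
    roots = {}
    labels = np.zeros(n, dtype=int)
    for g in range(n):
        r = find(g)
        roots.setdefault(r, len(roots))
        labels[g] = roots[r]
    return labels


def cluster_npcg(expr: pd.DataFrame, k: int = 2) -> ClusterResult:
    """Hierarchical clustering of gene expression profiles.

    ``expr`` is genes x samples, typically log1p-normalised,
    median-centred NPCG expression.  Distance is 1 - Spearman rho,
    linkage centroid, and the ``k``-cluster assignment (default 2, the
    "two main clusters") is read off the merge sequence.
    """
    if expr.shape[0] < k:
        raise ValueError(f"need at least k={k} genes")
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    genes = expr.index.tolist()
    d = spearman_distance(expr)
    merges = _centroid_linkage(d**2)
    n = len(genes)
    labels = _cut_k(merges, n, k)
    return ClusterResult(
        genes=genes,
        merges=merges,
        leaf_order=_leaf_order(merges, n),
        assignment=pd.Series(labels, index=genes, name="cluster"),
    )


def overlap_sets(**named_sets: set) -> dict[tuple[str, ...], int]:
    """Sizes of every intersection region of the given named sets.

    Returns a dict keyed by the tuple of set names a region belongs to
    (exclusively), e.g. for sets A, B the keys are ("A",), ("B",) and
    ("A", "B") with mutually exclusive counts — the numbers a Venn
    diagram displays.
    """
    names = list(named_sets)
    elements = set().union(*named_sets.values()) if named_sets else set()
    out: dict[tuple[str, ...], int] = {}
    for el in elements:
        member = tuple(nm for nm in names if el in named_sets[nm])
        out[member] = out.get(member, 0) + 1
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            out.setdefault(combo, 0)
    return out


def enrich_hypergeometric(
    genes: set,
    gene_sets: dict[str, set],
    universe: set,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``genes``.

    For each named set: fold enrichment (observed/expected overlap) and
    the upper-tail hypergeometric p, BH-adjusted across sets.
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("query genes must be a subset of the universe")
    M = len(universe)
    N = len(genes)
    rows = []
    for name, gs in gene_sets.items():
        gs_u = gs & universe
        n = len(gs_u)
        k = len(genes & gs_u)
        expected = N * n / M
        fold = k / expected if expected > 0 else np.nan
        p = stats.hypergeom.sf(k - 1, M, n, N) if n > 0 else 1.0
        rows.append((name, n, k, fold, p))
    df = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap",
                                     "fold_enrichment", "p_value"])
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df.set_index("gene_set")


def to_newick(result: ClusterResult) -> str:
    """Newick serialisation of the dendrogram (branch lengths = merge
    heights; negative increments from inversions are clamped at 0)."""
    n = len(result.genes)
    height = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return result.genes[i]
        a, b, h, _ = result.merges[i - n]
        sa, sb = node(int(a)), node(int(b))  # sets children's heights
        la = max(h - height[int(a)], 0.0)
        lb = max(h - height[int(b)], 0.0)
        height[i] = h
        return f"({sa}:{la:.6g},{sb}:{lb:.6g})"

    root = n + len(result.merges) - 1 if len(result.merges) else 0
    return node(root) + ";"


def export_heatmap_text(expr: pd.DataFrame, result: ClusterResult) -> str:
    """Byte-stable text form of the heat map: genes in dendrogram leaf
    order with their cluster label and expression values."""
    lines = ["gene_id\tcluster\t" + "\t".join(map(str, expr.columns))]
    for idx in result.leaf_order:
        g = result.genes[idx]
        vals = "\t".join(f"{v:.6g}" for v in expr.loc[g])
        lines.append(f"{g}\t{result.assignment[g]}\t{vals}")
    return "\n".join(lines) + "\n"


def plot_heatmap(expr: pd.DataFrame, result: ClusterResult, path) -> None:
    """Clustered expression heat map (genes in leaf order) to PNG/SVG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = expr.iloc[result.leaf_order]
    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * expr.shape[1]), max(4, 0.12 * len(expr))))
    im = ax.pcolormesh(ordered.to_numpy(), cmap="RdBu_r")
    ax.set_xticks(np.arange(expr.shape[1]) + 0.5,
                  labels=ordered.columns, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_ylabel(f"{len(expr)} genes (dendrogram order)")
    fig.colorbar(im, ax=ax, label="centred log expression")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
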