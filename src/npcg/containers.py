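"""In-memory containers for the coupled methylome/transcriptome analysis.

Conventions
-----------
* CpG positions are 1-based (Bismark coverage dialect).
* Interval annotations (exons, CpG islands) are 0-based half-open (BED).
  Conversion happens at the I/O boundary; see :mod:`npcg.annotation`.
* Gene count matrices are plain ``pandas.DataFrame`` objects, genes as
  rows, samples as columns, validated by :func:`validate_counts`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CpGMatrix", "SampleTable", "GenomeAnnotation", "validate_counts"]


@dataclass
class CpGMatrix:
    """Per-site, per-sample methylated/total read counts.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom`` (str), ``pos`` (1-based int) and
        ``strand`` (+/-), unique and sorted by (chrom, pos).
    coverage, methylated:
        Integer arrays of shape (n_sites, n_samples).
    samples:
        Sample identifiers, one per column.
    """

    sites: pd.DataFrame
    coverage: np.ndarray
    methylated: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.sites = self.sites.reset_index(drop=True)
        self.coverage = np.asarray(self.coverage)
        self.methylated = np.asarray(self.methylated)
        n_sites = len(self.sites)
        if self.coverage.shape != (n_sites, len(self.samples)):
            raise ValueError("coverage shape does not match sites x samples")
        if self.methylated.shape != self.coverage.shape:
            raise ValueError("methylated and coverage shapes differ")
        if np.any(self.methylated < 0) or np.any(self.methylated > self.coverage):
            raise ValueError("methylated counts must satisfy 0 <= m <= coverage")
        key = self.sites[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            raise ValueError("duplicate (chrom, pos, strand) site keys")
        order = self.sites.sort_values(["chrom", "pos"], kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(n_sites)):
            self.sites = self.sites.loc[order].reset_index(drop=True)
            self.coverage = self.coverage[order.to_numpy()]
            self.methylated = self.methylated[order.to_numpy()]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_sites(self, mask: np.ndarray) -> "CpGMatrix":
        mask = np.asarray(mask)
        return CpGMatrix(
            sites=self.sites.loc[mask].reset_index(drop=True),
            coverage=self.coverage[mask],
            methylated=self.methylated[mask],
            samples=list(self.samples),
        )

    def proportions(self) -> np.ndarray:
        """Methylation proportions m/cov; NaN where coverage is zero."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0,
                            self.methylated / np.maximum(self.coverage, 1), np.nan)


@dataclass
class SampleTable:
    """Sample sheet for a two-group design.

    ``group`` must take exactly two values; ``reference`` names the
    baseline level (e.g. the in-vivo MOET group), so positive group
    effects mean "higher in the non-reference group".
    """

    table: pd.DataFrame  # columns: sample_id, group, optionally age_days
    reference: str

    def __post_init__(self) -> None:
        req = {"sample_id", "group"}
        if not req.issubset(self.table.columns):
            raise ValueError("sample table needs columns sample_id, group")
        levels = sorted(self.table["group"].unique())
        if len(levels) != 2:
            raise ValueError(f"group must have exactly 2 levels, got {levels}")
        if self.reference not in levels:
            raise ValueError(f"reference {self.reference!r} not among {levels}")
        counts = self.table["group"].value_counts()
        if counts.min() < 2:
            raise ValueError("need >= 2 samples per group")
        self.table = self.table.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    @property
    def other(self) -> str:
        levels = set(self.table["group"].unique())
        return (levels - {self.reference}).pop()

    def group_indicator(self, labels: np.ndarray | None = None) -> np.ndarray:
        """0/1 vector: 1 for the non-reference group.

        ``labels`` optionally overrides the observed groups (used by the
        permutation engine); it must be a permutation of them.
        """
        obs = self.table["group"].to_numpy()
        if labels is None:
            labels = obs
        labels = np.asarray(labels)
        if sorted(labels) != sorted(obs):
            raise ValueError("labels must be a permutation of the observed groups")
        return (labels != self.reference).astype(float)

    def design_matrix(
        self,
        labels: np.ndarray | None = None,
        covariates: list[str] | None = None,
    ) -> np.ndarray:
        """Intercept + group indicator (+ centred numeric covariates)."""
        cols = [np.ones(len(self.table)), self.group_indicator(labels)]
        for cov in covariates or []:
            vals = self.table[cov].to_numpy(dtype=float)
            cols.append(vals - vals.mean())
        return np.column_stack(cols)

    def ordered_like(self, sample_ids: list[str]) -> "SampleTable":
        tab = (self.table.set_index("sample_id").loc[sample_ids]
               .reset_index())
        return SampleTable(tab, self.reference)


@dataclass
class GenomeAnnotation:
    """TSS points, exon intervals and CpG islands, with derived features.

    ``tss.pos`` is 1-based; interval frames (``exons``, ``cpg_islands``,
    ``gene_bodies``) are 0-based half-open.  Promoters are +/-
    ``promoter_halfwidth`` bp around each TSS (both endpoints included);
    shores are ``shore_width`` bp flanks on each side of an island,
    excluding the island itself.
    """

    tss: pd.DataFrame  # gene_id, chrom, pos (1-based), strand
    exons: pd.DataFrame  # gene_id, chrom, start, end
    cpg_islands: pd.DataFrame  # chrom, start, end
    gene_bodies: pd.DataFrame | None = None  # gene_id, chrom, start, end
    promoter_halfwidth: int = 1000
    shore_width: int = 2000

    def __post_init__(self) -> None:
        if (self.exons["end"] <= self.exons["start"]).any():
            raise ValueError("degenerate exon interval (end <= start)")
        if self.promoter_halfwidth <= 0 or self.shore_width <= 0:
            raise ValueError("promoter/shore widths must be positive")
        if self.gene_bodies is None:
            gb = (self.exons.groupby("gene_id")
                  .agg(chrom=("chrom", "first"), start=("start", "min"),
                       end=("end", "max")).reset_index())
            self.gene_bodies = gb

    def introns(self) -> pd.DataFrame:
        """Gene bodies minus exons (0-based half-open intervals)."""
        rows = []
        exons = self.exons.sort_values(["gene_id", "start"])
        for gene_id, grp in exons.groupby("gene_id"):
            body = self.gene_bodies.set_index("gene_id").loc[gene_id]
            cursor = int(body["start"])
            for _, ex in grp.iterrows():
                if ex["start"] > cursor:
                    rows.append((gene_id, ex["chrom"], cursor, int(ex["start"])))
                cursor = max(cursor, int(ex["end"]))
            if cursor < int(body["end"]):
                rows.append((gene_id, body["chrom"], cursor, int(body["end"])))
        return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Validate a genes x samples integer count matrix."""
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise ValueError("negative counts")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be integers; round averaged counts upstream")
    return counts.astype(np.int64)
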