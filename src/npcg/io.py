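"""Readers and writers for the plain-text formats of the pipeline.

* Bismark coverage dialect (one file per sample): chrom, start, end
  (1-based inclusive, start == end for a CpG), methylation percentage,
  count methylated, count unmethylated.
* Gene counts: TSV, first column gene id, header row of sample ids.
* Sample sheet: TSV with sample_id, group, optional age_days.
* Annotation: BED6 (0-based half-open).  TSS records are 1-bp intervals
  whose name field is the gene id; exon records carry the gene id too.
* Pathway gene sets: GMT (name, description, members...) or two-column
  TSV (set name, gene id).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CpGMatrix, GenomeAnnotation, SampleTable

__all__ = [
    "write_bismark_coverage", "read_bismark_coverage",
    "write_counts", "read_counts",
    "write_sample_sheet", "read_sample_sheet",
    "write_annotation_beds", "read_annotation_beds",
    "read_gene_sets", "write_table",
]


def write_bismark_coverage(data: CpGMatrix, outdir: str | Path) -> list[Path]:
    """Write one ``<sample>.cov`` file per sample; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, sample in enumerate(data.samples):
        cov = data.coverage[:, j]
        meth = data.methylated[:, j]
        keep = cov > 0
        with np.errstate(invalid="ignore"):
            pct = np.where(keep, 100.0 * meth / np.maximum(cov, 1), 0.0)
        df = pd.DataFrame({
            "chrom": data.sites["chrom"][keep],
            "start": data.sites["pos"][keep],
            "end": data.sites["pos"][keep],
            "pct": np.round(pct[keep], 6),
            "meth": meth[keep],
            "unmeth": (cov - meth)[keep],
        })
        path = outdir / f"{sample}.cov"
        df.to_csv(path, sep="\t", header=False, index=False)
        paths.append(path)
    return paths


def read_bismark_coverage(
    paths: dict[str, str | Path],
    strand_default: str = "+",
) -> CpGMatrix:
    """Merge per-sample coverage files into a CpGMatrix.

    ``paths`` maps sample id to file.  Sites absent from a sample get
    coverage 0 there (the coverage filter removes them downstream).
    The dialect carries no strand; ``strand_default`` is recorded.
    """
    frames = {}
    for sample, path in paths.items():
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "pct",
                                "meth", "unmeth"])
        df["pos"] = df["start"]
        frames[sample] = df.set_index(["chrom", "pos"])
    all_sites = sorted(set().union(*[f.index for f in frames.values()]))
    idx = pd.MultiIndex.from_tuples(all_sites, names=["chrom", "pos"])
    samples = list(paths)
    cov = np.zeros((len(idx), len(samples)), dtype=np.int64)
    meth = np.zeros_like(cov)
    for j, sample in enumerate(samples):
        sub = frames[sample].reindex(idx)
        m = sub["meth"].fillna(0).to_numpy(dtype=np.int64)
        u = sub["unmeth"].fillna(0).to_numpy(dtype=np.int64)
        meth[:, j] = m
        cov[:, j] = m + u
    sites = pd.DataFrame({"chrom": [c for c, _ in all_sites],
                          "pos": [p for _, p in all_sites],
                          "strand": strand_default})
    return CpGMatrix(sites=sites, coverage=cov, methylated=meth,
                     samples=samples)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sample_sheet(samples: SampleTable, path: str | Path) -> None:
    df = samples.table.copy()
    df["reference"] = (df["group"] == samples.reference)
    df.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path, reference: str | None = None
                      ) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    if reference is None:
        if "reference" in df.columns:
            reference = df.loc[df["reference"], "group"].iloc[0]
        else:
            reference = sorted(df["group"].unique())[0]
    return SampleTable(df.drop(columns=["reference"], errors="ignore"),
                       reference=reference)


def _write_bed6(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def write_annotation_beds(ann: GenomeAnnotation, outdir: str | Path) -> dict:
    """Write tss.bed, exons.bed and cpg_islands.bed (BED6)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tss = pd.DataFrame({
        "chrom": ann.tss["chrom"], "start": ann.tss["pos"] - 1,
        "end": ann.tss["pos"], "name": ann.tss["gene_id"],
        "score": 0, "strand": ann.tss["strand"],
    })
    exons = pd.DataFrame({
        "chrom": ann.exons["chrom"], "start": ann.exons["start"],
        "end": ann.exons["end"], "name": ann.exons["gene_id"],
        "score": 0, "strand": ".",
    })
    isl = pd.DataFrame({
        "chrom": ann.cpg_islands["chrom"], "start": ann.cpg_islands["start"],
        "end": ann.cpg_islands["end"],
        "name": [f"island{i + 1}" for i in range(len(ann.cpg_islands))],
        "score": 0, "strand": ".",
    })
    paths = {"tss": outdir / "tss.bed", "exons": outdir / "exons.bed",
             "cpg_islands": outdir / "cpg_islands.bed"}
    _write_bed6(tss, paths["tss"])
    _write_bed6(exons, paths["exons"])
    _write_bed6(isl, paths["cpg_islands"])
    return paths


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_annotation_beds(
    tss_path: str | Path,
    exons_path: str | Path,
    islands_path: str | Path,
    promoter_halfwidth: int = 1000,
    shore_width: int = 2000,
) -> GenomeAnnotation:
    tss_bed = pd.read_csv(tss_path, sep="\t", header=None, names=_BED_COLS)
    exons_bed = pd.read_csv(exons_path, sep="\t", header=None, names=_BED_COLS)
    isl_bed = pd.read_csv(islands_path, sep="\t", header=None, names=_BED_COLS)
    tss = pd.DataFrame({"gene_id": tss_bed["name"], "chrom": tss_bed["chrom"],
                        "pos": tss_bed["end"], "strand": tss_bed["strand"]})
    exons = exons_bed.rename(columns={"name": "gene_id"})[
        ["gene_id", "chrom", "start", "end"]]
    islands = isl_bed[["chrom", "start", "end"]]
    return GenomeAnnotation(tss=tss, exons=exons, cpg_islands=islands,
                            promoter_halfwidth=promoter_halfwidth,
                            shore_width=shore_width)


def read_gene_sets(path: str | Path) -> dict[str, set]:
    """Read GMT or two-column TSV gene sets."""
    path = Path(path)
    sets: dict[str, set] = {}
    if path.suffix.lower() == ".gmt":
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            sets[parts[0]] = set(parts[2:])
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["gene_set", "gene_id"])
        for name, grp in df.groupby("gene_set"):
            sets[str(name)] = set(grp["gene_id"])
    return sets


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    """Stable TSV writer used by every stage output."""
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
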