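"""Library-level evaluation metrics.

Two families: per-feature PCR-duplicate fractions from a duplicate-marked
alignment file, and cross-library reproducibility of a feature x library
count matrix — per-feature coefficients of variation (CV = SD/mean) whose
sum gives a single "total CV" per matrix, and counts of features whose
abundance differs between two libraries by at least a fold threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree


@dataclass(frozen=True)
class DuplicateFractionRecord:
    group_id: str
    reads_total: int
    reads_duplicate: int

    @property
    def fraction(self) -> float:
        return self.reads_duplicate / self.reads_total


def read_features(path: str) -> pd.DataFrame:
    """Load feature intervals from BED6 or GFF3 into 0-based half-open form.

    Returns columns (chrom, start, end, name, strand).  GFF3 coordinates
    (1-based closed) are shifted; the feature name is the ``ID`` attribute
    when present, else ``type:chrom:start-end``.
    """
    if path.endswith((".gff", ".gff3", ".gtf")):
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "source", "type", "start", "end", "score", "strand", "frame", "attributes"],
            dtype={"chrom": str},
        )
        def gff_name(row):
            for part in str(row["attributes"]).replace("; ", ";").split(";"):
                if part.startswith("ID="):
                    return part[3:]
                if part.startswith("gene_id "):
                    return part.split()[1].strip('"')
            return f"{row.type}:{row.chrom}:{row.start}-{row.end}"
        return pd.DataFrame(
            {
                "chrom": df.chrom,
                "start": df.start - 1,
                "end": df.end,
                "name": df.apply(gff_name, axis=1),
                "strand": df.strand,
            }
        )
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        usecols=range(6), dtype={"chrom": str, "name": str},
    )
    return df[["chrom", "start", "end", "name", "strand"]]


def duplicate_fraction_by_group(
    alignment_path: str, features: pd.DataFrame | str
) -> tuple[list[DuplicateFractionRecord], float]:
    """Fraction of duplicate-flagged reads per feature, plus the median.

    Every primary alignment is assigned to all features it overlaps (a
    read spanning two features counts in both); features with zero
    assigned reads are omitted.  Returns (records, median fraction).
    """
    if isinstance(features, str):
        features = read_features(features)
    trees: dict[str, IntervalTree] = {}
    for row in features.itertuples():
        if row.end <= row.start:
            continue
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.name)

    total: dict[str, int] = {}
    dup: dict[str, int] = {}
    with pysam.AlignmentFile(alignment_path, check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            tree = trees.get(fh.get_reference_name(aln.reference_id))
            if tree is None:
                continue
            for iv in tree.overlap(aln.reference_start, aln.reference_end):
                total[iv.data] = total.get(iv.data, 0) + 1
                if aln.is_duplicate:
                    dup[iv.data] = dup.get(iv.data, 0) + 1

    records = [
        DuplicateFractionRecord(name, n, dup.get(name, 0))
        for name, n in sorted(total.items())
    ]
    median = float(np.median([r.fraction for r in records])) if records else float("nan")
    return records, median


def cv_profile(matrix: pd.DataFrame, ddof: int = 1) -> tuple[pd.Series, float]:
    """Per-feature CV across libraries and the total (summed) CV.

    CV = SD/mean per feature over the library columns, with the sample
    (n-1) SD by default (``ddof=0`` gives the population SD).  Features
    with zero mean are excluded.  Returns (per-feature CV, total CV).
    """
    if matrix.shape[1] < 2:
        raise ValueError("CV requires at least two libraries")
    values = matrix.astype(float)
    mean = values.mean(axis=1)
    keep = mean > 0
    cv = values.loc[keep].std(axis=1, ddof=ddof) / mean[keep]
    return cv, float(cv.sum())


def irreproducibility_count(
    matrix: pd.DataFrame,
    lib_a: str,
    lib_b: str,
    fold: float = 1.25,
    count_single_zeros: bool = True,
) -> int:
    """Number of features differing >= ``fold`` between two libraries.

    A feature counts when max(a,b)/min(a,b) >= fold (the default 1.25
    corresponds to a >=25% abundance difference).  Features detected in
    exactly one library are counted as differing (configurable); features
    absent from both are excluded.
    """
    if fold <= 1:
        raise ValueError("fold threshold must exceed 1")
    a = matrix[lib_a].astype(float).to_numpy()
    b = matrix[lib_b].astype(float).to_numpy()
    both_zero = (a == 0) & (b == 0)
    one_zero = ((a == 0) ^ (b == 0)) & ~both_zero
    pos = (a > 0) & (b > 0)
    ratio = np.maximum(a[pos], b[pos]) / np.minimum(a[pos], b[pos])
    n = int((ratio >= fold).sum())
    if count_single_zeros:
        n += int(one_zero.sum())
    return n
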