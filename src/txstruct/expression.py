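"""Gene-level read counting, RPKM quantification and external correlation.

RPKM (reads per kilobase of gene per million unambiguously mapped library reads) is

    rpkm(g) = counts(g) * 1e9 / (length(g) * total_unambiguous_reads)

with the *library* total (all unambiguously mapped reads, not only gene-assigned ones)
in the denominator.  Reads are assigned to the gene with the largest overlap provided
the overlap reaches ``min_overlap_fraction`` of the read length; exact overlap ties are
discarded, so each read is counted at most once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .annotation_io import AlignmentRecord, GenomeAnnotation


@dataclass
class GeneCounts:
    """Reads assigned per gene in one sample plus the library total."""

    sample_id: str
    counts: dict[str, int]
    total_unambiguous_reads: int

    def assigned_total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class ExpressionMatrix:
    """RPKM and detectability, genes (rows) by samples (columns)."""

    rpkm: pd.DataFrame
    detectable: pd.DataFrame
    counts: Optional[pd.DataFrame] = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rpkm.columns)


def count_reads_per_gene(
    records: Iterable[AlignmentRecord],
    annotation: GenomeAnnotation,
    min_overlap_fraction: float = 0.5,
    sample_id: str = "sample",
) -> GeneCounts:
    """Assign each (already filtered) read to its maximal-overlap gene.

    A read is assigned when its best overlap is at least ``min_overlap_fraction`` of the
    read length and strictly beats every other gene; ties are discarded.  The returned
    total counts *all* reads seen, assigned or not.
    """
    if not (0 < min_overlap_fraction <= 1):
        raise ValueError("min_overlap_fraction must be in (0, 1]")
    tree = IntervalTree()
    for g in annotation.genes:
        tree.addi(g.start, g.end, g.locus_tag)
    counts: dict[str, int] = {g.locus_tag: 0 for g in annotation.genes}
    total = 0
    for rec in records:
        total += 1
        lo, hi = rec.position, rec.position + rec.length
        best_tag = None
        best_ov = 0
        tie = False
        for iv in tree.overlap(lo, hi):
            ov = min(hi, iv.end) - max(lo, iv.begin)
            if ov > best_ov:
                best_tag, best_ov, tie = iv.data, ov, False
            elif ov == best_ov and best_ov > 0:
                tie = True
        if best_tag is not None and not tie and best_ov >= min_overlap_fraction * rec.length:
            counts[best_tag] += 1
    return GeneCounts(sample_id=sample_id, counts=counts, total_unambiguous_reads=total)


def rpkm(counts: GeneCounts, annotation: GenomeAnnotation) -> pd.Series:
    """One RPKM column; exact in integer arithmetic before the final division."""
    if counts.total_unambiguous_reads <= 0:
        raise ValueError("total_unambiguous_reads must be positive")
    tags = [g.locus_tag for g in annotation.genes]
    lengths = np.array([g.length for g in annotation.genes], dtype=np.int64)
    if np.any(lengths <= 0):
        raise ValueError("zero-length gene in annotation")
    c = np.array([counts.counts.get(t, 0) for t in tags], dtype=np.int64)
    values = c * 1e9 / (lengths * float(counts.total_unambiguous_reads))
    return pd.Series(values, index=tags, name=counts.sample_id)


def flag_detectable(counts: GeneCounts, min_reads: int = 1) -> dict[str, bool]:
    """Detection flag per gene: at least ``min_reads`` assigned reads."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    return {tag: c >= min_reads for tag, c in counts.counts.items()}


def build_expression_matrix(
    counts_list: Iterable[GeneCounts],
    annotation: GenomeAnnotation,
    min_reads: int = 1,
) -> ExpressionMatrix:
    """Assemble the per-gene x per-sample RPKM / detectable / raw-count tables."""
    counts_list = list(counts_list)
    if not counts_list:
        raise ValueError("need at least one sample")
    rpkm_cols = {c.sample_id: rpkm(c, annotation) for c in counts_list}
    tags = [g.locus_tag for g in annotation.genes]
    count_cols = {
        c.sample_id: pd.Series([c.counts.get(t, 0) for t in tags], index=tags)
        for c in counts_list
    }
    rpkm_df = pd.DataFrame(rpkm_cols)
    counts_df = pd.DataFrame(count_cols)
    detectable = counts_df >= min_reads
    return ExpressionMatrix(rpkm=rpkm_df, detectable=detectable, counts=counts_df)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    pairs: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def correlate_external(
    matrix: ExpressionMatrix,
    sample_id: str,
    external: Mapping[str, float],
    transform: str = "log2",
) -> CorrelationResult:
    """Pearson correlation of one RPKM column against an external measurement.

    Genes missing on either side, and (under ``log2``) genes with a non-positive value
    on either side, are excluded and reported.  Requires at least 3 usable pairs.
    """
    if transform not in ("log2", "identity"):
        raise ValueError("transform must be 'log2' or 'identity'")
    col = matrix.rpkm[sample_id]
    shared = [t for t in col.index if t in external]
    excluded = [t for t in col.index if t not in external]
    x = col.loc[shared].to_numpy(dtype=float)
    y = np.array([external[t] for t in shared], dtype=float)
    if transform == "log2":
        ok = (x > 0) & (y > 0)
        excluded += [t for t, keep in zip(shared, ok) if not keep]
        shared = [t for t, keep in zip(shared, ok) if keep]
        x, y = np.log2(x[ok]), np.log2(y[ok])
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared positive pairs; need >= 3")
    r, p = stats.pearsonr(x, y)
    pairs = pd.DataFrame({"rnaseq": x, "external": y}, index=shared)
    return CorrelationResult(r=float(r), p_value=float(p), pairs=pairs, excluded=excluded)
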