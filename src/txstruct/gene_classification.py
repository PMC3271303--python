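"""Expression-based gene classes: silent genes, housekeeping genes, pseudogenes, COG enrichment.

* A **silent gene** is a protein-coding gene with zero unambiguously assigned reads in
  every sample.
* A **housekeeping gene (HKG)** is detectable in all samples, expressed above a minimum
  mean RPKM, and has a coefficient of variation (sample sd / mean) of RPKM strictly
  below ``cv_max`` (default 30%).
* **Pseudogene transcription** is summarized as transcribed (RPKM above a floor in at
  least one sample), completely silent, or neither, plus the pooled share of library
  reads falling on pseudogenes.
* **COG enrichment** of a gene subset against the annotation background uses one-sided
  Fisher's exact tests per COG letter with optional Benjamini-Hochberg correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .annotation_io import GenomeAnnotation
from .expression import ExpressionMatrix, GeneCounts

#: relative tolerance when deciding whether a table's probability "ties" the observed
#: one in the two-sided Fisher sum (guards against floating-point order effects)
_FISHER_TIE_RTOL = 1e-7

NO_COG = "-"  # pseudo-class for genes without a COG assignment


@dataclass
class GeneClassification:
    locus_tag: str
    silent: bool
    housekeeping: bool
    cv: float  # nan when the mean RPKM is 0
    mean_rpkm: float
    n_samples_detectable: int


@dataclass
class COGEnrichmentResult:
    cog_class: str
    in_set: int
    in_background: int
    set_size: int
    background_size: int
    p_value: float
    adjusted_p: float


def find_silent_genes(
    counts_per_sample: Sequence[GeneCounts], annotation: GenomeAnnotation
) -> list[str]:
    """Protein-coding genes with zero assigned reads in every sample.

    Pseudogenes are excluded here and reported separately by
    :func:`pseudogene_report`.
    """
    if not counts_per_sample:
        raise ValueError("need at least one sample")
    silent: list[str] = []
    for gene in annotation.genes_of_kind("CDS"):
        if all(c.counts.get(gene.locus_tag, 0) == 0 for c in counts_per_sample):
            silent.append(gene.locus_tag)
    return silent


def coefficient_of_variation(values: Iterable[float]) -> float:
    """Sample (n-1) standard deviation divided by the mean; nan when the mean is 0."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    mean = arr.mean()
    if mean == 0:
        return float("nan")
    return float(arr.std(ddof=1) / mean)


def classify_genes(
    matrix: ExpressionMatrix,
    cv_max: float = 0.30,
    min_rpkm: float = 10.0,
    annotation: Optional[GenomeAnnotation] = None,
) -> list[GeneClassification]:
    """Per-gene silent/housekeeping classification from the expression matrix.

    When the annotation is supplied, only protein-coding (CDS) genes are classified;
    housekeeping and silent labels are defined for protein-coding genes, pseudogenes
    being reported separately.
    """
    if cv_max <= 0:
        raise ValueError("cv_max must be positive")
    n_samples = len(matrix.sample_ids)
    tags = list(matrix.rpkm.index)
    if annotation is not None:
        cds = {g.locus_tag for g in annotation.genes_of_kind("CDS")}
        tags = [t for t in tags if t in cds]
    out: list[GeneClassification] = []
    for tag in tags:
        row = matrix.rpkm.loc[tag].to_numpy(dtype=float)
        n_det = int(matrix.detectable.loc[tag].sum())
        mean = float(row.mean())
        cv = float(row.std(ddof=1) / mean) if mean > 0 else float("nan")
        silent = n_det == 0
        hkg = (
            n_det == n_samples
            and mean >= min_rpkm
            and not math.isnan(cv)
            and cv < cv_max
        )
        out.append(
            GeneClassification(
                locus_tag=tag,
                silent=silent,
                housekeeping=hkg,
                cv=cv,
                mean_rpkm=mean,
                n_samples_detectable=n_det,
            )
        )
    return out


def find_housekeeping(
    matrix: ExpressionMatrix,
    cv_max: float = 0.30,
    min_rpkm: float = 10.0,
    annotation: Optional[GenomeAnnotation] = None,
) -> list[GeneClassification]:
    """The housekeeping subset, sorted by CV ascending (most stable first)."""
    hkgs = [
        c
        for c in classify_genes(matrix, cv_max=cv_max, min_rpkm=min_rpkm, annotation=annotation)
        if c.housekeeping
    ]
    hkgs.sort(key=lambda c: c.cv)
    return hkgs


# ---------------------------------------------------------------------------
# Fisher's exact test (2x2) by direct hypergeometric enumeration
# ---------------------------------------------------------------------------


def fisher_exact_2x2(a: int, b: int, c: int, d: int, alternative: str = "two_sided") -> float:
    """Exact p-value for the 2x2 table [[a, b], [c, d]] with fixed margins.

    ``two_sided`` sums the probabilities of all tables (same margins) whose point
    probability does not exceed the observed table's; ``greater``/``less`` are the upper
    and lower hypergeometric tails in ``a``.  Degenerate margins give p = 1.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    N = a + b + c + d
    K = a + b  # row-1 margin
    n = a + c  # column-1 margin
    if N == 0:
        raise ValueError("at least one margin must be positive")
    amin = max(0, K + n - N)
    amax = min(K, n)
    support = np.arange(amin, amax + 1)
    pmf = hypergeom.pmf(support, N, K, n)
    p_obs = float(pmf[a - amin])
    if alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    elif alternative == "two_sided":
        p = float(pmf[pmf <= p_obs * (1 + _FISHER_TIE_RTOL)].sum())
    else:
        raise ValueError("alternative must be two_sided, greater or less")
    return min(p, 1.0)


def cog_enrichment(
    subset: Sequence[str],
    annotation: GenomeAnnotation,
    correction: str = "benjamini_hochberg",
    background_kinds: tuple[str, ...] = ("CDS", "pseudogene"),
) -> list[COGEnrichmentResult]:
    """One-sided (greater) Fisher enrichment of each COG letter in ``subset``.

    The background is every annotated gene of ``background_kinds``; genes lacking a COG
    assignment are gathered into the pseudo-class ``-``; a gene carrying several COG
    letters counts once per letter.  Benjamini-Hochberg adjustment across the tested
    classes is applied when requested.
    """
    if not subset:
        raise ValueError("empty subset")
    if correction not in ("benjamini_hochberg", "none"):
        raise ValueError("correction must be 'benjamini_hochberg' or 'none'")
    background = annotation.genes_of_kind(*background_kinds)
    bg_tags = {g.locus_tag for g in background}
    subset_set = set(subset) & bg_tags

    def classes_of(gene) -> list[str]:
        return list(gene.cog_class) if gene.cog_class else [NO_COG]

    all_classes = sorted({c for g in background for c in classes_of(g)})
    class_bg = {c: 0 for c in all_classes}
    class_in = {c: 0 for c in all_classes}
    for g in background:
        for c in classes_of(g):
            class_bg[c] += 1
            if g.locus_tag in subset_set:
                class_in[c] += 1

    set_size = len(subset_set)
    bg_size = len(bg_tags)
    results: list[COGEnrichmentResult] = []
    pvals: list[float] = []
    for cls in all_classes:
        a = class_in[cls]
        b = set_size - a
        c = class_bg[cls] - a
        d = (bg_size - set_size) - c
        p = fisher_exact_2x2(a, b, c, d, alternative="greater")
        pvals.append(p)
        results.append(
            COGEnrichmentResult(
                cog_class=cls,
                in_set=a,
                in_background=class_bg[cls],
                set_size=set_size,
                background_size=bg_size,
                p_value=p,
                adjusted_p=p,
            )
        )
    if correction == "benjamini_hochberg" and results:
        adj = multipletests(pvals, method="fdr_bh")[1]
        for res, q in zip(results, adj):
            res.adjusted_p = float(q)
    results.sort(key=lambda r: r.p_value)
    return results


def pseudogene_report(
    counts_per_sample: Sequence[GeneCounts],
    matrix: ExpressionMatrix,
    annotation: GenomeAnnotation,
    min_rpkm_active: float = 10.0,
) -> tuple[pd.DataFrame, dict]:
    """Transcription status of every annotated pseudogene plus a pooled summary.

    ``transcribed`` means RPKM >= ``min_rpkm_active`` in at least one sample; ``silent``
    means zero assigned reads in every sample; ``share_of_reads`` is the pseudogene's
    pooled read count over the pooled library total.
    """
    pseudo = annotation.genes_of_kind("pseudogene")
    total_reads = sum(c.total_unambiguous_reads for c in counts_per_sample)
    rows = []
    for g in pseudo:
        pooled = sum(c.counts.get(g.locus_tag, 0) for c in counts_per_sample)
        rpkm_row = matrix.rpkm.loc[g.locus_tag]
        transcribed = bool((rpkm_row >= min_rpkm_active).any())
        silent = pooled == 0
        rows.append(
            {
                "pseudogene": g.locus_tag,
                "transcribed": transcribed,
                "silent": silent,
                "share_of_reads": pooled / total_reads if total_reads else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=["pseudogene", "transcribed", "silent", "share_of_reads"])
    summary = {
        "n_pseudogenes": len(pseudo),
        "n_transcribed": int(table["transcribed"].sum()) if len(table) else 0,
        "n_silent": int(table["silent"].sum()) if len(table) else 0,
        "total_read_share": float(table["share_of_reads"].sum()) if len(table) else 0.0,
    }
    return table, summary
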