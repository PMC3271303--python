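"""Transcript structure from coverage: segments, TSSs, 5'-UTRs, operons, novel regions.

The pipeline replaces by-eye inspection of coverage plots with explicit rules:

* **Hysteresis segmentation** — a transcribed segment opens where depth reaches
  ``t_on``, extends while depth stays at or above ``t_off``, tolerates sub-``t_off``
  gaps up to ``max_gap`` bases, and is dropped if shorter than ``min_segment_length``.
* **TSS calling** — the 5' boundary (strand aware) of the segment overlapping a gene's
  annotated translation start, refined upstream through contiguous coverage of at least
  ``tss_min_depth`` (transcription begins where coverage begins, not where it first
  clears the segmentation threshold).  The region between the TSS and the annotated
  translation start is the 5'-UTR.
* **Consensus 5'-UTRs** — per-gene median TSS across samples; high confidence requires
  support in ``min_support`` samples within a ``concordance_window`` (default 50 nt).
* **Operons** — consecutive same-strand genes are linked when, in at least one sample,
  every intergenic base is covered at
  ``max(link_abs_min, link_depth_fraction * min(gene mean depths))``; transitive closure
  of the links yields the operon map, and the downstream/upstream mean-depth ratio per
  junction records within-operon attenuation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .annotation_io import GeneRecord, GenomeAnnotation
from .coverage import CoverageTrack, SampleCoverageSet

# default segmentation / structure parameters (all overridable per call)
T_ON = 5
T_OFF = 2
MAX_GAP = 25
MIN_SEGMENT_LENGTH = 50
MAX_UPSTREAM = 300
CONCORDANCE_WINDOW = 50
LINK_DEPTH_FRACTION = 0.25
LINK_ABS_MIN = 2
MAX_INTERGENIC = 500
MIN_NOVEL_LENGTH = 150
MIN_NOVEL_DEPTH = 5
MIN_NOVEL_RATIO = 5.0
MIN_START_OFFSET = 30
MIN_SUPPORT_SAMPLES = 2

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TranscribedSegment:
    sample_id: str
    start: int
    end: int
    mean_depth: float


@dataclass
class TSSCall:
    locus_tag: str
    sample_id: str
    position: int
    utr_length: int


@dataclass
class UTRRecord:
    locus_tag: str
    consensus_tss: int
    utr_length: int
    n_samples_supporting: int
    high_confidence: bool
    tss_spread: int


@dataclass
class Operon:
    operon_id: str
    members: list[str]
    strand: str
    start: int
    end: int
    leader_tss: Optional[int] = None
    attenuation_ratios: list[float] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class NovelRegion:
    start: int
    end: int
    mean_depth: float
    depth_ratio_vs_background: float
    samples_supporting: list[str] = field(default_factory=list)
    candidate_orfs: list[tuple[int, int, str, int]] = field(default_factory=list)


@dataclass
class StartAnomalyFlag:
    locus_tag: str
    onset_position: int
    offset_into_gene: int
    samples_supporting: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def call_segments(
    track: CoverageTrack | np.ndarray,
    t_on: int = T_ON,
    t_off: int = T_OFF,
    max_gap: int = MAX_GAP,
    min_segment_length: int = MIN_SEGMENT_LENGTH,
    sample_id: Optional[str] = None,
) -> list[TranscribedSegment]:
    """Hysteresis segmentation of a depth array into transcribed segments.

    Equivalent to a per-base automaton: closed until depth >= t_on, then open while
    depth >= t_off, bridging sub-t_off stretches of at most ``max_gap`` bases.  The
    returned segments are disjoint and sorted.
    """
    if not (t_on >= t_off >= 1):
        raise ValueError("need t_on >= t_off >= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if isinstance(track, CoverageTrack):
        depth = track.depth
        sample_id = sample_id or track.sample_id
    else:
        depth = np.asarray(track)
        sample_id = sample_id or "sample"

    above = depth >= t_off
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    run_starts, run_ends = edges[0::2], edges[1::2]

    segments: list[TranscribedSegment] = []
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] <= max_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    for s, e in merged:
        window = depth[s:e]
        seeds = np.flatnonzero(window >= t_on)
        if seeds.size == 0:
            continue
        start = s + int(seeds[0])
        if e - start < min_segment_length:
            continue
        segments.append(
            TranscribedSegment(
                sample_id=sample_id,
                start=start,
                end=e,
                mean_depth=float(depth[start:e].mean()),
            )
        )
    return segments


def segments_per_sample(coverage_set: SampleCoverageSet, **params) -> dict[str, list[TranscribedSegment]]:
    return {sid: call_segments(coverage_set[sid], **params) for sid in coverage_set.sample_ids}


# ---------------------------------------------------------------------------
# TSS and 5'-UTR calling
# ---------------------------------------------------------------------------


def _refine_onset(depth: np.ndarray, boundary: int, strand: str, limit: int, min_depth: int = 1) -> int:
    """Walk the 5' boundary upstream through contiguous coverage >= min_depth.

    ``boundary`` and the return value use segment-edge convention: for a plus-strand
    unit it is the first covered position, for a minus-strand unit the half-open right
    edge.  ``limit`` bounds how far the walk may go.
    """
    if strand == "+":
        p = boundary
        while p > 0 and boundary - (p - 1) <= limit and depth[p - 1] >= min_depth:
            p -= 1
        return p
    p = boundary
    n = len(depth)
    while p < n and (p + 1) - boundary <= limit and depth[p] >= min_depth:
        p += 1
    return p


def call_tss(
    segments: Sequence[TranscribedSegment],
    gene: GeneRecord,
    max_upstream: int = MAX_UPSTREAM,
    depth: Optional[np.ndarray] = None,
    upstream_gene: Optional[GeneRecord] = None,
    sample_id: Optional[str] = None,
    tss_min_depth: int = 1,
) -> Optional[TSSCall]:
    """TSS for one gene in one sample, or None when no independent TSS exists.

    The TSS is the strand-aware 5' boundary of the segment overlapping the gene's
    annotated translation start, refined upstream through contiguous coverage when the
    depth array is supplied.  The call is rejected when the boundary falls inside the
    next upstream same-strand gene (operon-internal genes share the leader TSS) or lies
    more than ``max_upstream`` nt away.
    """
    anchor = gene.start if gene.strand == "+" else gene.end - 1
    seg = next((s for s in segments if s.start <= anchor < s.end), None)
    if seg is None:
        return None
    boundary = seg.start if gene.strand == "+" else seg.end
    if depth is not None:
        boundary = _refine_onset(depth, boundary, gene.strand, max_upstream, tss_min_depth)
    if gene.strand == "+":
        utr = gene.start - boundary
        if upstream_gene is not None and boundary < upstream_gene.end:
            return None
    else:
        utr = boundary - gene.end
        if upstream_gene is not None and boundary > upstream_gene.start:
            return None
    if utr < 0 or utr > max_upstream:
        return None
    return TSSCall(
        locus_tag=gene.locus_tag,
        sample_id=sample_id or seg.sample_id,
        position=boundary,
        utr_length=utr,
    )


def call_tss_all_samples(
    coverage_set: SampleCoverageSet,
    annotation: GenomeAnnotation,
    max_upstream: int = MAX_UPSTREAM,
    segment_params: Optional[dict] = None,
    tss_min_depth: int = 1,
) -> dict[str, list[TSSCall]]:
    """Per-gene TSS calls pooled over all samples (convenience driver)."""
    seg_by_sample = segments_per_sample(coverage_set, **(segment_params or {}))
    upstream = {g.locus_tag: annotation.upstream_same_strand_gene(g) for g in annotation.genes}
    calls: dict[str, list[TSSCall]] = {}
    for sid, segs in seg_by_sample.items():
        depth = coverage_set[sid].depth
        for gene in annotation.genes:
            call = call_tss(
                segs,
                gene,
                max_upstream=max_upstream,
                depth=depth,
                upstream_gene=upstream[gene.locus_tag],
                sample_id=sid,
                tss_min_depth=tss_min_depth,
            )
            if call is not None:
                calls.setdefault(gene.locus_tag, []).append(call)
    return calls


def consensus_utrs(
    calls: Mapping[str, Sequence[TSSCall]],
    annotation: GenomeAnnotation,
    concordance_window: int = CONCORDANCE_WINDOW,
    min_support: Optional[int] = None,
    n_samples: Optional[int] = None,
) -> list[UTRRecord]:
    """Aggregate per-sample TSS calls into consensus 5'-UTR records.

    The consensus TSS is the median of the supporting positions, rounded toward the
    gene's annotated start on half-integer ties; the spread is max-min.  High confidence
    requires support in at least ``min_support`` samples (default: all samples) within a
    window of ``concordance_window`` nt.
    """
    if concordance_window < 0:
        raise ValueError("concordance_window must be >= 0")
    by_tag = annotation.by_tag
    records: list[UTRRecord] = []
    for tag, tag_calls in calls.items():
        if not tag_calls:
            continue
        gene = by_tag[tag]
        positions = np.array(sorted(c.position for c in tag_calls))
        med = float(np.median(positions))
        # round toward the gene start: up for plus-strand genes, down for minus
        consensus = int(math.ceil(med)) if gene.strand == "+" else int(math.floor(med))
        spread = int(positions.max() - positions.min())
        utr = gene.start - consensus if gene.strand == "+" else consensus - gene.end
        support_floor = min_support if min_support is not None else (n_samples or len(tag_calls))
        records.append(
            UTRRecord(
                locus_tag=tag,
                consensus_tss=consensus,
                utr_length=int(utr),
                n_samples_supporting=len(tag_calls),
                high_confidence=(len(tag_calls) >= support_floor and spread <= concordance_window),
                tss_spread=spread,
            )
        )
    records.sort(key=lambda r: by_tag[r.locus_tag].start)
    return records


# ---------------------------------------------------------------------------
# operon assembly
# ---------------------------------------------------------------------------


def assemble_operons(
    annotation: GenomeAnnotation,
    coverage_set: SampleCoverageSet,
    link_depth_fraction: float = LINK_DEPTH_FRACTION,
    link_abs_min: int = LINK_ABS_MIN,
    max_intergenic: int = MAX_INTERGENIC,
    utrs: Optional[Sequence[UTRRecord]] = None,
) -> list[Operon]:
    """Link consecutive same-strand genes whose intergenic gap is continuously covered.

    A junction links when, in at least one sample, every intergenic base reaches
    ``max(link_abs_min, link_depth_fraction * min(mean depth of the two genes))`` and
    both genes show some expression.  Attenuation per junction is the downstream /
    upstream mean-depth ratio in the best-linking sample; genes not linked to any
    neighbour become monocistronic operons.
    """
    if not (0 < link_depth_fraction <= 1):
        raise ValueError("link_depth_fraction must be in (0, 1]")
    genes = annotation.genes
    n = len(genes)
    sample_ids = coverage_set.sample_ids
    means = {
        sid: np.array(
            [coverage_set[sid].depth[g.start : g.end].mean() if g.length else 0.0 for g in genes]
        )
        for sid in sample_ids
    }

    linked = np.zeros(max(n - 1, 0), dtype=bool)
    atten = np.full(max(n - 1, 0), np.nan)
    for i in range(n - 1):
        g1, g2 = genes[i], genes[i + 1]
        if g1.strand != g2.strand:
            continue
        gap_lo, gap_hi = g1.end, g2.start
        if gap_hi - gap_lo > max_intergenic:
            continue
        best_score = -np.inf
        best_sid = None
        for sid in sample_ids:
            m1, m2 = means[sid][i], means[sid][i + 1]
            if min(m1, m2) <= 0:
                continue
            thr = max(link_abs_min, link_depth_fraction * min(m1, m2))
            gap = coverage_set[sid].depth[gap_lo:gap_hi]
            gap_min = float(gap.min()) if gap.size else float(min(m1, m2))
            score = gap_min / thr
            if score >= 1.0 and score > best_score:
                best_score, best_sid = score, sid
        if best_sid is not None:
            linked[i] = True
            m1, m2 = means[best_sid][i], means[best_sid][i + 1]
            up, down = (m1, m2) if g1.strand == "+" else (m2, m1)
            atten[i] = down / up if up > 0 else np.nan

    utr_by_tag = {u.locus_tag: u for u in (utrs or [])}
    operons: list[Operon] = []
    i = 0
    idx = 1
    while i < n:
        j = i
        while j < n - 1 and linked[j]:
            j += 1
        block = genes[i : j + 1]
        strand = block[0].strand
        members = [g.locus_tag for g in block]
        ratios = [float(atten[k]) for k in range(i, j)]
        if strand == "-":
            members = members[::-1]
            ratios = ratios[::-1]
        leader = members[0]
        leader_tss = utr_by_tag[leader].consensus_tss if leader in utr_by_tag else None
        operons.append(
            Operon(
                operon_id=f"OP{idx:04d}",
                members=members,
                strand=strand,
                start=block[0].start,
                end=block[-1].end,
                leader_tss=leader_tss,
                attenuation_ratios=ratios,
            )
        )
        idx += 1
        i = j + 1
    return operons


def operon_junctions(operons: Iterable[Operon]) -> set[tuple[str, str]]:
    """The set of linked adjacent gene pairs (in transcription order)."""
    pairs: set[tuple[str, str]] = set()
    for op in operons:
        for a, b in zip(op.members, op.members[1:]):
            pairs.add((a, b))
    return pairs


# ---------------------------------------------------------------------------
# novel transcribed regions
# ---------------------------------------------------------------------------


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[0::2].tolist(), edges[1::2].tolist()))


def detect_novel_regions(
    coverage_set: SampleCoverageSet,
    annotation: GenomeAnnotation,
    min_novel_length: int = MIN_NOVEL_LENGTH,
    min_depth: int = MIN_NOVEL_DEPTH,
    min_ratio_vs_background: float = MIN_NOVEL_RATIO,
    genome_sequence: Optional[str] = None,
    min_orf_aa: int = 30,
) -> list[NovelRegion]:
    """Maximal unannotated intervals with sustained transcription in >= 1 sample.

    A candidate run must stay at ``min_depth`` throughout and its mean depth must exceed
    ``min_ratio_vs_background`` times the sample's median intergenic depth (a zero
    background accepts any run; bacterial intergenic medians are typically 0-2).
    Overlapping per-sample runs are merged; ORFs of ``min_orf_aa`` aa or more are
    attached when the genome sequence is available.
    """
    if min_novel_length <= 0 or min_depth <= 0 or min_ratio_vs_background <= 0:
        raise ValueError("thresholds must be positive")
    gene_mask = annotation.gene_mask()
    candidates: list[tuple[int, int, str, float, float]] = []
    for sid in coverage_set.sample_ids:
        depth = coverage_set[sid].depth
        background = float(np.median(depth[~gene_mask])) if (~gene_mask).any() else 0.0
        ok = (depth >= min_depth) & ~gene_mask
        for s, e in _runs_of(ok):
            if e - s < min_novel_length:
                continue
            mean = float(depth[s:e].mean())
            if background > 0 and mean < min_ratio_vs_background * background:
                continue
            ratio = mean / background if background > 0 else float("inf")
            candidates.append((s, e, sid, mean, ratio))

    candidates.sort()
    regions: list[NovelRegion] = []
    for s, e, sid, mean, ratio in candidates:
        if regions and s < regions[-1].end:
            reg = regions[-1]
            reg.end = max(reg.end, e)
            if sid not in reg.samples_supporting:
                reg.samples_supporting.append(sid)
            if mean > reg.mean_depth:
                reg.mean_depth = mean
                reg.depth_ratio_vs_background = ratio
        else:
            regions.append(
                NovelRegion(
                    start=s,
                    end=e,
                    mean_depth=mean,
                    depth_ratio_vs_background=ratio,
                    samples_supporting=[sid],
                )
            )
    if genome_sequence is not None:
        for reg in regions:
            reg.candidate_orfs = find_orfs(
                genome_sequence[reg.start : reg.end], strand_both=True, min_length_aa=min_orf_aa
            )
    return regions


# ---------------------------------------------------------------------------
# mis-annotated translation starts
# ---------------------------------------------------------------------------


def flag_start_anomalies(
    coverage_set: SampleCoverageSet,
    annotation: GenomeAnnotation,
    min_start_offset: int = MIN_START_OFFSET,
    min_support_samples: int = MIN_SUPPORT_SAMPLES,
    segment_params: Optional[dict] = None,
    min_body_coverage: float = 0.8,
) -> list[StartAnomalyFlag]:
    """Genes whose transcription onset lies well inside the annotated coding interval.

    A gene is flagged when, in at least ``min_support_samples`` samples, the segment
    covering it begins >= ``min_start_offset`` nt inside the annotated start
    (strand-aware, onset refined through contiguous coverage) while at least
    ``min_body_coverage`` of the remaining gene body is transcribed.
    """
    if min_start_offset < 1:
        raise ValueError("min_start_offset must be >= 1")
    seg_by_sample = segments_per_sample(coverage_set, **(segment_params or {}))
    flags: list[StartAnomalyFlag] = []
    for gene in annotation.genes:
        offsets: list[int] = []
        onsets: list[int] = []
        supporting: list[str] = []
        for sid, segs in seg_by_sample.items():
            overlapping = [
                s for s in segs if s.start < gene.end and s.end > gene.start
            ]
            if not overlapping:
                continue
            seg = max(overlapping, key=lambda s: min(s.end, gene.end) - max(s.start, gene.start))
            depth = coverage_set[sid].depth
            boundary = seg.start if gene.strand == "+" else seg.end
            boundary = _refine_onset(depth, boundary, gene.strand, gene.length)
            offset = boundary - gene.start if gene.strand == "+" else gene.end - boundary
            if offset < min_start_offset:
                continue
            covered = min(seg.end, gene.end) - max(seg.start, gene.start)
            if covered < min_body_coverage * (gene.length - offset):
                continue
            offsets.append(int(offset))
            onsets.append(int(boundary))
            supporting.append(sid)
        if len(supporting) >= min_support_samples:
            order = np.argsort(offsets)
            mid = order[len(order) // 2]
            flags.append(
                StartAnomalyFlag(
                    locus_tag=gene.locus_tag,
                    onset_position=onsets[mid],
                    offset_into_gene=offsets[mid],
                    samples_supporting=supporting,
                )
            )
    return flags


# ---------------------------------------------------------------------------
# ORF finding (lightweight annotation of novel regions)
# ---------------------------------------------------------------------------


def _orfs_one_strand(seq: str, min_length_aa: int) -> list[tuple[int, int, int]]:
    """(start, end, length_aa) for ATG..stop ORFs on the given sequence, all 3 frames."""
    n = len(seq)
    out: list[tuple[int, int, int]] = []
    for frame in range(3):
        stops: list[int] = []
        starts: list[int] = []
        for p in range(frame, n - 2, 3):
            codon = seq[p : p + 3]
            if codon == "ATG":
                starts.append(p)
            elif codon in STOP_CODONS:
                stops.append(p)
        stops_arr = np.array(stops, dtype=int)
        for s in starts:
            nxt = np.searchsorted(stops_arr, s)
            if nxt == len(stops_arr):
                continue
            stop = int(stops_arr[nxt])
            length_aa = (stop - s) // 3
            if length_aa >= min_length_aa:
                out.append((s, stop + 3, length_aa))
    return out


def find_orfs(
    sequence: str, strand_both: bool = True, min_length_aa: int = 1
) -> list[tuple[int, int, str, int]]:
    """All ATG-initiated, stop-terminated ORFs of >= ``min_length_aa`` codons.

    ``length_aa`` counts codons from ATG up to (excluding) the stop; coordinates are
    0-based half-open in region space and include the stop codon.
    """
    sequence = sequence.upper()
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence contains non-ACGT characters")
    result = [(s, e, "+", aa) for s, e, aa in _orfs_one_strand(sequence, min_length_aa)]
    if strand_both:
        rc = sequence.translate(_COMPLEMENT)[::-1]
        n = len(sequence)
        for s, e, aa in _orfs_one_strand(rc, min_length_aa):
            result.append((n - e, n - s, "-", aa))
    result.sort()
    return result
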