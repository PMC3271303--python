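"""Segmentation, TSS/5'-UTR calling, operon assembly, novel regions, ORFs."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import txstruct as tx
from txstruct.transcript_structure import _refine_onset

from conftest import make_annotation


# ---------------------------------------------------------------------------
# hysteresis segmentation
# ---------------------------------------------------------------------------


def automaton_segments(depth, t_on, t_off, max_gap, min_len):
    """Independent per-base state-machine oracle for the hysteresis rule."""
    segments = []
    open_start = None
    gap_run = 0
    last_good = None
    for i, d in enumerate(depth):
        if open_start is None:
            if d >= t_on:
                open_start, last_good, gap_run = i, i, 0
        else:
            if d >= t_off:
                last_good, gap_run = i, 0
            else:
                gap_run += 1
                if gap_run > max_gap:
                    if last_good + 1 - open_start >= min_len:
                        segments.append((open_start, last_good + 1))
                    open_start = None
                    if d >= t_on:  # may immediately reopen
                        open_start, last_good, gap_run = i, i, 0
    if open_start is not None and last_good + 1 - open_start >= min_len:
        segments.append((open_start, last_good + 1))
    return segments


def test_basic_segment_call():
    depth = np.array([0, 0, 9, 9, 9, 0, 0])
    segs = tx.call_segments(depth, t_on=5, t_off=2, max_gap=0, min_segment_length=3)
    assert [(s.start, s.end) for s in segs] == [(2, 5)]
    assert segs[0].mean_depth == 9.0


def test_gap_tolerance_merges_blocks():
    depth = np.concatenate([np.full(10, 9), np.zeros(4), np.full(10, 9)]).astype(int)
    segs = tx.call_segments(depth, t_on=5, t_off=2, max_gap=5, min_segment_length=3)
    assert [(s.start, s.end) for s in segs] == [(0, 24)]
    segs = tx.call_segments(depth, t_on=5, t_off=2, max_gap=3, min_segment_length=3)
    assert [(s.start, s.end) for s in segs] == [(0, 10), (14, 24)]


@pytest.mark.parametrize("seed", range(20))
def test_segments_match_independent_automaton(seed):
    """Random tracks against a per-base state-machine written independently."""
    rng = np.random.default_rng(seed)
    depth = rng.choice([0, 0, 1, 2, 3, 6, 9, 20], size=600, p=[0.3, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
    for params in [(5, 2, 0, 1), (5, 2, 3, 5), (9, 1, 10, 20), (3, 3, 1, 2)]:
        t_on, t_off, max_gap, min_len = params
        got = [
            (s.start, s.end)
            for s in tx.call_segments(depth, t_on, t_off, max_gap, min_len)
        ]
        assert got == automaton_segments(depth, t_on, t_off, max_gap, min_len), params


@settings(max_examples=200, derandomize=True, deadline=None)
@given(
    depth=st.lists(st.sampled_from([0, 1, 2, 4, 7, 15]), min_size=1, max_size=120),
    max_gap=st.integers(0, 6),
    min_len=st.integers(1, 10),
)
def test_segments_match_automaton_property(depth, max_gap, min_len):
    arr = np.array(depth)
    got = [(s.start, s.end) for s in tx.call_segments(arr, 4, 2, max_gap, min_len)]
    assert got == automaton_segments(arr, 4, 2, max_gap, min_len)


def test_segmentation_idempotence():
    rng = np.random.default_rng(42)
    depth = rng.choice([0, 0, 0, 4, 9], size=400)
    segs = tx.call_segments(depth, t_on=3, t_off=2, max_gap=2, min_segment_length=5)
    indicator = np.zeros_like(depth)
    for s in segs:
        indicator[s.start : s.end] = 1
    again = tx.call_segments(indicator, t_on=1, t_off=1, max_gap=0, min_segment_length=1)
    assert [(s.start, s.end) for s in segs] == [(s.start, s.end) for s in again]


# ---------------------------------------------------------------------------
# TSS calling
# ---------------------------------------------------------------------------


def _seg(start, end, sid="s1", depth=10.0):
    return tx.TranscribedSegment(sample_id=sid, start=start, end=end, mean_depth=depth)


def test_plus_strand_tss_and_utr():
    gene = tx.GeneRecord("g", 150, 400, "+")
    call = tx.call_tss([_seg(100, 400)], gene, max_upstream=300)
    assert call.position == 100
    assert call.utr_length == 50


def test_minus_strand_tss_mirrors_plus():
    gene = tx.GeneRecord("g", 150, 400, "-")
    call = tx.call_tss([_seg(100, 450)], gene, max_upstream=300)
    assert call.position == 450
    assert call.utr_length == 50


def test_operon_internal_gene_has_no_independent_tss():
    upstream = tx.GeneRecord("up", 50, 140, "+")
    gene = tx.GeneRecord("g", 150, 400, "+")
    call = tx.call_tss([_seg(100, 400)], gene, max_upstream=300, upstream_gene=upstream)
    assert call is None  # segment boundary at 100 sits inside the upstream gene


def test_tss_refinement_walks_to_coverage_onset():
    depth = np.zeros(500, dtype=int)
    depth[97:400] = [1, 1, 3] + [10] * 300
    gene = tx.GeneRecord("g", 150, 400, "+")
    call = tx.call_tss([_seg(100, 400)], gene, max_upstream=300, depth=depth)
    assert call.position == 97
    assert call.utr_length == 53


def test_consensus_median_rounds_toward_gene():
    ann = make_annotation(
        [("gP", 150, 400, "+", "CDS", None), ("gM", 600, 900, "-", "CDS", None)],
        genome_length=2000,
    )
    calls_p = [tx.TSSCall("gP", f"s{i}", p, 150 - p) for i, p in enumerate((100, 100, 102, 101))]
    (rec,) = tx.consensus_utrs({"gP": calls_p}, ann, min_support=2)
    assert rec.consensus_tss == 101  # median 100.5 rounded toward the plus-strand gene
    assert rec.tss_spread == 2
    assert rec.high_confidence
    assert rec.utr_length == 150 - 101

    calls_m = [tx.TSSCall("gM", f"s{i}", p, p - 900) for i, p in enumerate((950, 951, 953, 952))]
    (rec_m,) = tx.consensus_utrs({"gM": calls_m}, ann, min_support=2)
    assert rec_m.consensus_tss == 951  # median 951.5 rounded toward the minus-strand gene


def test_wide_spread_is_not_high_confidence():
    ann = make_annotation([("g", 450, 900, "+", "CDS", None)], genome_length=2000)
    calls = [tx.TSSCall("g", "s1", 100, 350), tx.TSSCall("g", "s2", 400, 50)]
    (rec,) = tx.consensus_utrs({"g": calls}, ann, concordance_window=50, min_support=2)
    assert rec.tss_spread == 300
    assert not rec.high_confidence


def test_single_sample_support_below_floor():
    ann = make_annotation([("g", 450, 900, "+", "CDS", None)], genome_length=2000)
    calls = [tx.TSSCall("g", "s1", 400, 50)]
    (rec,) = tx.consensus_utrs({"g": calls}, ann, min_support=2)
    assert not rec.high_confidence


def test_high_confidence_utrs_satisfy_invariants(noisy_fixture, noisy_coverage):
    ann = noisy_fixture.annotation
    calls = tx.call_tss_all_samples(noisy_coverage, ann)
    utrs = tx.consensus_utrs(calls, ann, n_samples=6)
    assert utrs, "fixture must yield UTR calls"
    for u in utrs:
        gene = ann.by_tag[u.locus_tag]
        expected = gene.start - u.consensus_tss if gene.strand == "+" else u.consensus_tss - gene.end
        assert u.utr_length == expected
        if u.high_confidence:
            assert u.tss_spread <= 50


# ---------------------------------------------------------------------------
# operon assembly
# ---------------------------------------------------------------------------


def _coverage_set_from_depth(depth_by_sample):
    tracks = {
        sid: tx.CoverageTrack(sid, np.asarray(d, dtype=np.int64), bases_mapped=int(np.sum(d)))
        for sid, d in depth_by_sample.items()
    }
    return tx.SampleCoverageSet(tracks=tracks)


def test_four_gene_operon_called_in_gene_order():
    genes = [
        ("ald", 100, 400, "+", "CDS", None),
        ("ctfA", 430, 700, "+", "CDS", None),
        ("ctfB", 720, 1000, "+", "CDS", None),
        ("adc", 1040, 1300, "+", "CDS", None),
    ]
    ann = make_annotation(genes, genome_length=2000)
    depth = np.zeros(2000, dtype=int)
    depth[80:1330] = 30
    cs = _coverage_set_from_depth({"s1": depth})
    (op,) = tx.assemble_operons(ann, cs)
    assert op.members == ["ald", "ctfA", "ctfB", "adc"]
    assert op.strand == "+"
    assert (op.start, op.end) == (100, 1300)


def test_attenuated_junction_still_links_and_records_ratio():
    """A regulator linked over a 71-nt gap; a weak downstream junction keeps ~0.2 ratio."""
    genes = [
        ("reg", 100, 400, "+", "CDS", None),
        ("gap", 471, 900, "+", "CDS", None),  # 71-nt intergenic gap
        ("pgk", 950, 1400, "+", "CDS", None),
    ]
    ann = make_annotation(genes, genome_length=2000)
    depth = np.zeros(2000, dtype=int)
    depth[90:950] = 50  # reg + gap fully covered
    depth[950:1420] = 10  # attenuated tail at ratio 0.2
    cs = _coverage_set_from_depth({"s1": depth})
    (op,) = tx.assemble_operons(ann, cs, link_depth_fraction=0.25, link_abs_min=2)
    assert op.members == ["reg", "gap", "pgk"]
    assert op.attenuation_ratios[1] == pytest.approx(0.2, rel=1e-6)


def test_opposite_strands_never_link():
    genes = [("gA", 100, 400, "+", "CDS", None), ("gB", 420, 800, "-", "CDS", None)]
    ann = make_annotation(genes, genome_length=1000)
    depth = np.full(1000, 40, dtype=int)
    cs = _coverage_set_from_depth({"s1": depth})
    ops = tx.assemble_operons(ann, cs)
    assert sorted(len(op.members) for op in ops) == [1, 1]


def test_minus_strand_operon_members_in_transcription_order():
    genes = [("gA", 100, 400, "-", "CDS", None), ("gB", 430, 800, "-", "CDS", None)]
    ann = make_annotation(genes, genome_length=1000)
    depth = np.zeros(1000, dtype=int)
    depth[90:820] = 30
    cs = _coverage_set_from_depth({"s1": depth})
    (op,) = tx.assemble_operons(ann, cs)
    assert op.members == ["gB", "gA"]  # transcription right-to-left


def test_no_gene_in_two_operons_and_members_consecutive(clean_fixture, clean_coverage):
    ops = tx.assemble_operons(clean_fixture.annotation, clean_coverage)
    seen: set[str] = set()
    order = {g.locus_tag: i for i, g in enumerate(clean_fixture.annotation.genes)}
    for op in ops:
        assert not (set(op.members) & seen)
        seen.update(op.members)
        idx = sorted(order[m] for m in op.members)
        assert idx == list(range(idx[0], idx[-1] + 1))
    assert seen == set(order)


# ---------------------------------------------------------------------------
# novel regions and start anomalies
# ---------------------------------------------------------------------------


def test_novel_region_thresholds():
    ann = make_annotation([("g", 100, 400, "+", "CDS", None)], genome_length=3000)
    depth = np.full(3000, 2, dtype=int)
    depth[1000:1300] = 50  # 300-nt unannotated block
    cs = _coverage_set_from_depth({"s1": depth})
    regions = tx.detect_novel_regions(cs, ann, min_novel_length=150, min_depth=5, min_ratio_vs_background=5)
    assert [(r.start, r.end) for r in regions] == [(1000, 1300)]
    assert regions[0].depth_ratio_vs_background == pytest.approx(25.0)

    depth2 = np.full(3000, 2, dtype=int)
    depth2[1000:1100] = 50  # same block, 100 nt: below the length floor
    cs2 = _coverage_set_from_depth({"s1": depth2})
    assert tx.detect_novel_regions(cs2, ann, 150, 5, 5) == []


def test_novel_regions_never_intersect_genes(clean_fixture, clean_coverage):
    regions = tx.detect_novel_regions(clean_coverage, clean_fixture.annotation)
    for r in regions:
        for g in clean_fixture.annotation.genes:
            assert r.end <= g.start or r.start >= g.end


def test_start_anomaly_rule_application():
    ann = make_annotation([("g", 1000, 1600, "+", "CDS", None)], genome_length=3000)
    depth_hit = np.zeros(3000, dtype=int)
    depth_hit[1060:1650] = 30  # onset 60 nt into the CDS
    depth_clean = np.zeros(3000, dtype=int)
    depth_clean[960:1650] = 30  # onset upstream of the start
    cs = _coverage_set_from_depth({"s1": depth_hit, "s2": depth_hit, "s3": depth_hit, "s4": depth_clean})
    flags = tx.flag_start_anomalies(cs, ann, min_start_offset=30, min_support_samples=2)
    assert len(flags) == 1
    assert flags[0].locus_tag == "g"
    assert flags[0].offset_into_gene == 60
    assert set(flags[0].samples_supporting) == {"s1", "s2", "s3"}

    cs_clean = _coverage_set_from_depth({"s1": depth_clean, "s2": depth_clean})
    assert tx.flag_start_anomalies(cs_clean, ann) == []


def test_onset_exactly_at_start_not_flagged():
    ann = make_annotation([("g", 1000, 1600, "+", "CDS", None)], genome_length=3000)
    depth = np.zeros(3000, dtype=int)
    depth[1000:1650] = 30
    cs = _coverage_set_from_depth({"s1": depth, "s2": depth})
    assert tx.flag_start_anomalies(cs, ann) == []


def test_refine_onset_respects_limit():
    depth = np.ones(200, dtype=int)
    assert _refine_onset(depth, 100, "+", limit=10) == 90
    assert _refine_onset(depth, 100, "-", limit=10) == 110


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------


def brute_orfs(seq, min_aa):
    """Exhaustive 6-frame oracle: every ATG walked codon-by-codon to its first stop."""
    comp = str.maketrans("ACGT", "TGCA")
    out = []
    for strand, s in (("+", seq), ("-", seq.translate(comp)[::-1])):
        n = len(s)
        for p in range(n - 2):
            if s[p : p + 3] != "ATG":
                continue
            q = p + 3
            while q + 3 <= n and s[q : q + 3] not in ("TAA", "TAG", "TGA"):
                q += 3
            if q + 3 > n:
                continue
            aa = (q - p) // 3
            if aa < min_aa:
                continue
            if strand == "+":
                out.append((p, q + 3, "+", aa))
            else:
                out.append((n - (q + 3), n - p, "-", aa))
    return sorted(out)


def test_minimal_orf_hand_decoded():
    assert tx.find_orfs("ATGAAATAA", strand_both=False) == [(0, 9, "+", 2)]


def test_no_atg_means_no_orfs():
    assert tx.find_orfs("CCCGGGCCCGGG") == []


def test_non_acgt_rejected():
    with pytest.raises(ValueError):
        tx.find_orfs("ATGNNNTAA")


def test_orfs_match_six_frame_oracle():
    rng = np.random.default_rng(13)
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    assert tx.find_orfs(seq, strand_both=True, min_length_aa=10) == brute_orfs(seq, 10)
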