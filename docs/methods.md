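# Methods

## Scope and data model

`txstruct` reconstructs the physical structure of a bacterial transcriptome from
single-end, fixed-length RNA-Seq alignments over a multi-sample growth course. The
pipeline consumes alignments (SAM), a genome (FASTA) and a feature annotation
(GFF3/GenBank) and produces coverage tracks, an RPKM expression matrix, TSS/5'-UTR
calls, an operon map, novel transcribed regions, start-codon anomaly flags, expression
classes and a refined annotation. All coordinates are 0-based half-open internally;
GFF3/GenBank conventions are converted only at the file boundary. Reads are treated as
gapless reference blocks: with short single-end prokaryotic reads there are no splice
gaps, and clipping is ignored.

The library is unstranded by default. 2009-era mRNA-Seq chemistry did not preserve
strand, so sense and antisense signal are pooled; a stranded mode exists for modern
data. In unstranded mode operon strand comes from the annotation and antisense
transcription is invisible — the pipeline does not claim it.

## Filtering and coverage

A read is *ambiguous* when its MAPQ is below the cutoff (default 30, matching the
quality filter typically applied to short-read bacterial mappings) or it carries an
explicit multi-hit tag (NH>1, X0>1, XT:A:R). Only unambiguous reads contribute. Depth is
an exact per-base alignment-membership count (difference-array accumulation); the sum of
the depth array equals the summed aligned lengths, exactly. "Percent of genome
represented" counts bases at depth ≥ 1 (`depth_min` is exposed; 1 is the least arbitrary
floor for "represented"), and the union statistic counts bases reaching the floor in at
least one sample.

## RPKM

`rpkm(g) = counts(g) · 1e9 / (length(g) · N)` where `N` is the per-library total of
unambiguously mapped reads (not only gene-assigned reads). Read→gene assignment is
maximal-overlap with a floor of 50 % of the read length and ties discarded — a single
assignment rule with no double counting; both knobs are parameters. The detection floor
for "detectable expression" is 1 assigned read (weakest defensible criterion, exposed).
RPKM is scale-invariant under uniform count scaling to 1e-9 relative, and
`Σ rpkm·len·N/1e9` returns the assigned-read total exactly.

## Segmentation, TSS and 5'-UTRs

Transcribed segments come from two-threshold hysteresis segmentation: a segment opens
where depth ≥ `t_on` (default 5), extends while depth ≥ `t_off` (2), bridges
sub-threshold gaps up to `max_gap` (25 nt), and is discarded below `min_segment_length`
(50 nt). The defaults replace what is otherwise manual inspection of coverage plots;
all four are parameters.

The TSS of a gene is the strand-aware 5' boundary of the segment overlapping its
annotated translation start, **refined upstream through contiguous coverage of depth
≥ 1** (bounded by `max_upstream`, default 300 nt). The refinement matters: at 30-fold
coverage with 75-nt reads, depth ramps up linearly over the first read length, so the
`t_off` crossing sits several bases downstream of the true onset; transcription starts
where coverage starts, which is where a human reading the coverage plot would put the
TSS. A call is rejected when the boundary falls inside the next upstream same-strand
gene (operon-internal genes share the leader's TSS) or exceeds `max_upstream`.

The per-gene consensus TSS across samples is the median, rounded toward the gene start
on half-integer ties (robust to one outlier sample); the spread is max−min. A 5'-UTR is
*high-confidence* when supported in all samples (parameter `min_support`) within a 50-nt
concordance window. `utr_length` is by construction the strand-aware distance between
consensus TSS and annotated start.

## Operon assembly

Adjacent same-strand genes with intergenic gap ≤ `max_intergenic` (500 nt — comfortably
above the longest junction gaps validated experimentally for this kind of data, ~440 nt)
are linked when **in at least one sample** every intergenic base reaches
`max(link_abs_min, link_depth_fraction · min(mean depth of the two genes))` with
defaults (2, 0.25). One qualifying sample suffices because operons expressed in a single
growth phase (e.g. sporulation clusters) must still be called; the fractional floor
tolerates attenuated junctions. Both genes must show some expression (an empty gap
between two silent genes is not evidence). Transitive closure of links yields the map;
unlinked genes become monocistronic operons; members are reported in transcription
order; the per-junction downstream/upstream mean-depth ratio (best-linking sample)
records attenuation. The map is static — one operon call per run, not
condition-dependent splitting.

## Novel regions and start anomalies

Novel transcribed regions are maximal unannotated intervals ≥ `min_novel_length`
(150 nt) covered at depth ≥ `min_depth` (5) throughout in at least one sample, with mean
depth ≥ `min_ratio_vs_background` (5×) times that sample's median intergenic depth (the
median is typically 0–2 in bacteria; a zero background accepts the run). These
thresholds are explicit stand-ins for a qualitative "significant transcriptional
activity" judgement. Candidate ORFs (all ATG-initiated, stop-terminated frames ≥ 30 aa,
both strands) annotate each region; downstream gene prediction, terminator and
riboswitch searches are out of scope — the pipeline exports the sequences such tools
would consume.

A start anomaly is flagged when, in ≥ `min_support_samples` (2) samples, the segment
covering a gene begins ≥ `min_start_offset` (30 nt) inside the annotated CDS
(strand-aware, onset refined as for TSSs) while ≥ 80 % of the remaining gene body is
covered. The offset/support defaults separate genuine mis-annotation from ragged 5'
coverage; under Poisson noise occasional ragged-onset flags can still appear, which is
why support in multiple samples is required.

## Expression classes and enrichment

Silent genes: protein-coding genes with zero assigned reads in every sample (pseudogenes
are reported separately). Housekeeping genes: protein-coding, detectable in all samples,
mean RPKM ≥ `min_rpkm` (10 — the CV of near-zero RPKM is noise-dominated, so a floor is
imposed), and CV < 30 % (strict), using the sample (n−1) standard deviation; results are
sorted by CV ascending. Pseudogenes are *transcribed* when RPKM ≥ `min_rpkm_active` in
at least one sample and *silent* when they collect zero reads; the pooled share of
library reads on pseudogenes is reported. `min_rpkm_active` is scale-dependent: its
default (10) suits multi-million-read libraries, while the ~45k-read synthetic fixtures
inflate RPKM roughly 250-fold, so fixture analyses use a matched floor of 1000. The
2×2 Fisher test is an exact hypergeometric enumeration over the table support
(two-sided = sum of tables no more probable than the observed one, with a 1e-7 relative
tie guard; degenerate margins give p = 1). COG enrichment tests each category one-sided
(greater) against the annotation background, gathers unassigned genes into a pseudo
class, counts multi-class genes once per class, and applies Benjamini–Hochberg
correction across categories; raw and adjusted p-values are both reported.

## Synthetic data generator

The generator emulates the assumed study: a ~120-kb chromosome carrying 120 CDS in
operon blocks (size distribution {1: 0.4, 2: 0.2, 3: 0.2, 4: 0.1, 8: 0.1}), both
strands, gene lengths 300–900 nt, intra-operon gaps 5–50 nt, inter-unit gaps 100–300 nt,
per-operon 5'-UTRs of 20 + Exp(30) nt capped at 140, and 30-nt 3' trailers (3'-UTRs are
not otherwise characterized, so a fixed small trailer keeps boundaries testable). It
plants 12 silent genes, ~18 housekeeping genes, 10 pseudogenes (3 strongly transcribed,
5 at 1 % abundance, 2 silent), 5 unannotated transcripts (250–400 nt, left out of the
GFF3), and 4 genes whose annotated start sits 50 nt upstream of the true onset.
Junctions attenuate with probability 0.3 at a ratio drawn from U(0.2, 0.7).

Expression over six samples (2–26.5 h): per-transcript base abundance LogNormal(0, 0.5);
early and late phase programs swing 4-fold ((4,4,1,1,1,1) vs (1,1,4,4,4,4)), assigned in
alternation so library totals stay balanced (RPKM is compositional — a strongly
imbalanced design would leak phase variance into housekeeping CVs); housekeeping
transcripts are flat with LogNormal jitter σ = 0.04 (realized CV ≈ 5 %, below the 10 %
truth target), other transcripts carry σ = 0.2 jitter. Reads are 75-nt gapless blocks at
MAPQ 60; starts are Poisson-sampled uniformly within each attenuation segment at a rate
of abundance × 30-fold coverage, constrained to lie inside the transcript. With
`poisson_noise=False` the same expected counts are placed at exact even spacing anchored
at both transcript edges, giving noise-free coverage whose onsets coincide exactly with
the true boundaries — the fixture used for exact-recovery tests. An optional decoy
fraction adds uniformly placed MAPQ-0 reads genome-wide to exercise the ambiguity
filter (without modeling repeat families). Reads carry no sequencing errors: the
pipeline consumes alignments, and MAPQ models ambiguity. Everything is deterministic per
seed, with one child generator per stage.

What the generator does **not** emulate — realistic base composition and codon
structure, rRNA contamination, repeat-driven multi-mapping, fragment-length variation,
3'-UTR structure, and condition-dependent operon splitting — bounds what passing tests
show: they certify the inference rules under the stated statistical model, not
performance on any particular real library.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 120-gene / 120-kb fixture (about 45k–75k
reads per sample), 20 replicate simulations for the noisy operon-recovery study, a full
enumeration of 2×2 tables with margins ≤ 30 against an independent log-factorial oracle,
and 500–1000 null draws for enrichment calibration — sizes chosen so the whole analysis
reproduces in minutes on one CPU while every recovery statistic still has enough support
to be meaningful. Floating-point ties in the two-sided Fisher sum are guarded with a
1e-7 relative tolerance on the point probabilities (the same convention as the oracle);
RPKM comparisons use 1e-9 relative tolerance; consensus-TSS ties round toward the gene.
Degenerate inputs are defined explicitly: empty coverage sets and empty enrichment
subsets are errors, zero-mean CV is NaN (gene excluded from HKG consideration),
degenerate Fisher margins give p = 1, and an annotation with zero features is valid.

## Known limitations

3' transcript ends are reported as segment ends without claiming terminator positions;
operon calls are unsigned evidence of co-transcription in at least one condition, not a
promoter map; TSS calls inherit the coverage-onset definition and so sit at the first
reproducibly covered base, which under very low coverage is downstream of the true
start; housekeeping-gene stability beyond the observed CV (e.g. across media or stress
conditions) is not claimed; and differential expression between samples is out of
scope.
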