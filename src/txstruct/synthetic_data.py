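"""Synthetic genome, annotation, truth set and per-sample alignments.

The generator emulates the statistical structure the analysis assumes for a bacterial
growth-course RNA-Seq experiment: a multi-gene-operon genome with per-operon 5'-UTRs and
short 3' trailers, six samples whose expression programs shift between an early
(acidogenic-like) and a late (solventogenic-like) phase, constant-expression
housekeeping transcripts, fully silent genes, transcribed/low/silent pseudogenes,
unannotated (novel) transcripts, deliberately mis-annotated translation starts, and
within-operon attenuation at a fraction of junctions.  Reads are gapless fixed-length
blocks with Poisson-sampled start positions (or exact deterministic placement with
``poisson_noise=False``), plus an optional fraction of ambiguous decoy reads placed
uniformly genome-wide at MAPQ 0.

Everything is deterministic for a fixed ``seed``; each of the three stages draws from
its own child generator so stages can be re-run independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .annotation_io import AlignmentRecord, GeneRecord, GenomeAnnotation
from .coverage import CoverageTrack, SampleCoverageSet, compute_coverage, filter_alignments

COG_LETTERS = "JKLDVTMNUOCGEFHP"

#: truth programs
EARLY, LATE, HKG, SILENT = "early", "late", "hkg", "silent"
PSEUDO_HIGH, PSEUDO_LOW, PSEUDO_SILENT = "pseudo_high", "pseudo_low", "pseudo_silent"
NOVEL, MISANNOTATED = "novel", "misannotated"

_FLAT_PROGRAMS = (HKG, PSEUDO_HIGH, PSEUDO_LOW, NOVEL, MISANNOTATED)


@dataclass
class SimulationConfig:
    """All knobs of the simulated study; defaults give a ~100 kb, 120-gene fixture."""

    genome_length: int = 120_000
    n_genes: int = 120
    operon_size_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.4, 2: 0.2, 3: 0.2, 4: 0.1, 8: 0.1}
    )
    # gene lengths in codons (CDS length = 3 * aa)
    gene_min_aa: int = 100
    gene_max_aa: int = 300
    # 5'-UTR length: utr_min + Exponential(utr_scale), capped at utr_max
    utr_min: int = 20
    utr_scale: float = 30.0
    utr_max: int = 140
    trailer_length: int = 30
    # intergenic gaps (nt): within operons and between transcription units
    gap_intra_min: int = 5
    gap_intra_max: int = 50
    gap_between_min: int = 100
    gap_between_max: int = 300
    # samples
    n_samples: int = 6
    sample_times: tuple[float, ...] = (2.0, 4.5, 10.0, 14.0, 17.0, 26.5)
    read_length: int = 75
    target_depth: float = 30.0
    # planted classes
    fraction_silent: float = 0.10
    fraction_hkg: float = 0.15
    n_pseudogenes: int = 10
    pseudo_n_transcribed: int = 3
    pseudo_n_silent: int = 2
    pseudo_low_multiplier: float = 0.01
    n_novel_unannotated_transcripts: int = 5
    novel_min_length: int = 250
    novel_max_length: int = 400
    n_misannotated_starts: int = 4
    misannotation_offset: int = 50
    # attenuation at operon junctions
    attenuation_probability: float = 0.3
    attenuation_ratio_range: tuple[float, float] = (0.2, 0.7)
    # expression program
    expression_sigma: float = 0.5  # lognormal sigma of per-transcript base abundance
    hkg_sigma: float = 0.3
    hkg_jitter_sigma: float = 0.04  # keeps realized HKG abundance CV < 10%
    phase_jitter_sigma: float = 0.2
    phase_high: float = 4.0  # fold-change of the active vs inactive phase
    # read noise
    poisson_noise: bool = True
    decoy_fraction: float = 0.0
    mapq_real: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        total = sum(self.operon_size_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("operon_size_distribution probabilities must sum to 1")
        if self.n_samples != len(self.sample_times):
            raise ValueError("sample_times must have n_samples entries")
        if not (0 <= self.decoy_fraction < 1):
            raise ValueError("decoy_fraction must be in [0, 1)")

    @property
    def sample_ids(self) -> list[str]:
        return [f"s{i + 1}" for i in range(self.n_samples)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sample_times"] = list(d["sample_times"])
        d["attenuation_ratio_range"] = list(d["attenuation_ratio_range"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "sample_times" in d:
            d["sample_times"] = tuple(d["sample_times"])
        if "attenuation_ratio_range" in d:
            d["attenuation_ratio_range"] = tuple(d["attenuation_ratio_range"])
        if "operon_size_distribution" in d:
            d["operon_size_distribution"] = {
                int(k): float(v) for k, v in d["operon_size_distribution"].items()
            }
        return cls(**d)


@dataclass
class TruthTranscript:
    """One true transcription unit: interval, members, TSS, program, attenuation."""

    transcript_id: str
    members: list[str]  # locus tags in transcription order; empty for novel regions
    strand: str
    start: int  # transcript interval, 0-based half-open (includes UTR and trailer)
    end: int
    utr_length: int
    program: str
    attenuation: list[float] = field(default_factory=list)  # per junction, 1.0 = none
    gene_intervals: list[tuple[int, int]] = field(default_factory=list)  # transcription order
    misannotation_offset: int = 0

    @property
    def tss(self) -> int:
        """5' edge: the first transcribed base (plus) or half-open right edge (minus)."""
        return self.start if self.strand == "+" else self.end

    @property
    def length(self) -> int:
        return self.end - self.start

    def segments(self) -> list[tuple[int, int, float]]:
        """(ref_lo, ref_hi, multiplier) pieces induced by junction attenuation."""
        if len(self.members) <= 1 or all(r == 1.0 for r in self.attenuation):
            return [(self.start, self.end, 1.0)]
        cuts: list[int] = []
        for (_, _), nxt in zip(self.gene_intervals, self.gene_intervals[1:]):
            cuts.append(nxt[0] if self.strand == "+" else nxt[1])
        mults = np.cumprod([1.0] + list(self.attenuation))
        pieces: list[tuple[int, int, float]] = []
        if self.strand == "+":
            bounds = [self.start] + cuts + [self.end]
            for k in range(len(bounds) - 1):
                pieces.append((bounds[k], bounds[k + 1], float(mults[k])))
        else:
            bounds = [self.end] + cuts + [self.start]
            for k in range(len(bounds) - 1):
                pieces.append((bounds[k + 1], bounds[k], float(mults[k])))
        return pieces


@dataclass
class TruthSet:
    """Ground truth for parameter-recovery tests."""

    transcripts: list[TruthTranscript]

    def by_program(self, *programs: str) -> list[TruthTranscript]:
        return [t for t in self.transcripts if t.program in programs]

    @property
    def silent_genes(self) -> set[str]:
        return {m for t in self.by_program(SILENT) for m in t.members}

    @property
    def hkg_genes(self) -> set[str]:
        return {m for t in self.by_program(HKG) for m in t.members}

    @property
    def pseudogene_classes(self) -> dict[str, str]:
        out = {}
        for t in self.by_program(PSEUDO_HIGH, PSEUDO_LOW, PSEUDO_SILENT):
            for m in t.members:
                out[m] = t.program
        return out

    @property
    def novel_intervals(self) -> list[tuple[int, int]]:
        return [(t.start, t.end) for t in self.by_program(NOVEL)]

    @property
    def misannotated_offsets(self) -> dict[str, int]:
        return {t.members[0]: t.misannotation_offset for t in self.by_program(MISANNOTATED)}

    def operon_junction_pairs(self) -> set[tuple[str, str]]:
        """True co-transcribed adjacent gene pairs (transcription order), CDS operons."""
        pairs: set[tuple[str, str]] = set()
        for t in self.transcripts:
            if t.program in (NOVEL,):
                continue
            for a, b in zip(t.members, t.members[1:]):
                pairs.add((a, b))
        return pairs

    def expressed_leaders(self) -> list[TruthTranscript]:
        """Annotated operons with a genuine upstream TSS (the TSS-recovery target set)."""
        return [t for t in self.by_program(EARLY, LATE, HKG) if t.utr_length > 0]


@dataclass
class Fixture:
    """A fully simulated experiment: inputs plus the truth that produced them."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    truth: TruthSet
    abundances: pd.DataFrame
    reads: dict[str, list[AlignmentRecord]]

    def coverage_set(self, min_mapq: int = 30, mode: str = "unstranded") -> SampleCoverageSet:
        tracks = {
            sid: compute_coverage(
                filter_alignments(recs, min_mapq=min_mapq),
                self.annotation.genome_length,
                mode=mode,
                sample_id=sid,
            )
            for sid, recs in self.reads.items()
        }
        times = dict(zip(self.config.sample_ids, self.config.sample_times))
        return SampleCoverageSet(tracks=tracks, sample_times=times)


# ---------------------------------------------------------------------------
# stage 1: genome + annotation + truth layout
# ---------------------------------------------------------------------------


def _plan_operon_sizes(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    sizes = sorted(config.operon_size_distribution)
    probs = np.array([config.operon_size_distribution[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    plan: list[int] = []
    remaining = config.n_genes
    while remaining > 0:
        k = int(rng.choice(sizes, p=probs))
        k = min(k, remaining)
        plan.append(k)
        remaining -= k
    # guarantee enough monocistronic units for the planted silent / mis-annotated genes
    needed_mono = round(config.fraction_silent * config.n_genes) + config.n_misannotated_starts
    while sum(1 for s in plan if s == 1) < needed_mono:
        multi = max(range(len(plan)), key=lambda i: plan[i])
        if plan[multi] == 1:
            break
        k = plan.pop(multi)
        plan.extend([1] * k)
    return plan


def generate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, TruthSet]:
    """Lay out the synthetic chromosome; returns the annotation and the truth set.

    Genes are placed in operon blocks on both strands with 5'-UTRs and 3' trailers;
    designated units are silent, housekeeping, pseudogenes, novel (left out of the
    annotation) or mis-annotated (annotated start upstream of the true onset).
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    if config.n_genes == 0:
        seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
        ann = GenomeAnnotation("synthchr", config.genome_length, [], sequence=seq)
        return ann, TruthSet(transcripts=[])

    plan = _plan_operon_sizes(config, rng)
    mono_idx = [i for i, s in enumerate(plan) if s == 1]
    rng.shuffle(mono_idx)
    n_silent = round(config.fraction_silent * config.n_genes)
    silent_ops = set(mono_idx[:n_silent])
    mis_ops = set(mono_idx[n_silent : n_silent + config.n_misannotated_starts])

    hkg_target = round(config.fraction_hkg * config.n_genes)
    other_idx = [i for i in range(len(plan)) if i not in silent_ops and i not in mis_ops]
    rng.shuffle(other_idx)
    hkg_ops: set[int] = set()
    got = 0
    for i in other_idx:
        if got >= hkg_target:
            break
        hkg_ops.add(i)
        got += plan[i]

    # phase programs alternate over the remaining operons to keep library totals balanced
    phase_ops = [i for i in other_idx if i not in hkg_ops]
    phase_of = {i: (EARLY if k % 2 == 0 else LATE) for k, i in enumerate(phase_ops)}

    pseudo_programs = (
        [PSEUDO_HIGH] * config.pseudo_n_transcribed
        + [PSEUDO_SILENT] * config.pseudo_n_silent
        + [PSEUDO_LOW]
        * (config.n_pseudogenes - config.pseudo_n_transcribed - config.pseudo_n_silent)
    )

    # unit descriptors: ("operon", plan_index) | ("pseudo", program) | ("novel", None)
    units: list[tuple[str, object]] = [("operon", i) for i in range(len(plan))]
    units += [("pseudo", p) for p in pseudo_programs]
    units += [("novel", None)] * config.n_novel_unannotated_transcripts
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    genes: list[GeneRecord] = []
    transcripts: list[TruthTranscript] = []
    cursor = 200
    cds_counter = 0
    psg_counter = 0
    tx_counter = 0

    def draw_utr() -> int:
        return int(min(config.utr_min + rng.exponential(config.utr_scale), config.utr_max))

    for kind, payload in units:
        gap = int(rng.integers(config.gap_between_min, config.gap_between_max + 1))
        cursor += gap
        strand = "+" if rng.random() < 0.5 else "-"
        tx_counter += 1
        tid = f"T{tx_counter:04d}"

        if kind == "novel":
            length = int(rng.integers(config.novel_min_length, config.novel_max_length + 1))
            transcripts.append(
                TruthTranscript(
                    transcript_id=tid,
                    members=[],
                    strand=strand,
                    start=cursor,
                    end=cursor + length,
                    utr_length=0,
                    program=NOVEL,
                )
            )
            cursor += length
            continue

        if kind == "pseudo":
            program = str(payload)
            n_members, feature_kind = 1, "pseudogene"
            utr = draw_utr()
            offset = 0
        else:
            i = int(payload)
            n_members, feature_kind = plan[i], "CDS"
            if i in silent_ops:
                program = SILENT
            elif i in mis_ops:
                program = MISANNOTATED
            elif i in hkg_ops:
                program = HKG
            else:
                program = phase_of[i]
            offset = config.misannotation_offset if program == MISANNOTATED else 0
            utr = 0 if program == MISANNOTATED else draw_utr()

        # local layout in transcription orientation
        local: list[tuple[int, int]] = []
        pos = utr
        for m in range(n_members):
            length = 3 * int(rng.integers(config.gene_min_aa, config.gene_max_aa + 1))
            local.append((pos, pos + length))
            pos += length
            if m < n_members - 1:
                pos += int(rng.integers(config.gap_intra_min, config.gap_intra_max + 1))
        unit_len = pos + config.trailer_length

        member_tags: list[str] = []
        gene_intervals: list[tuple[int, int]] = []
        for s_loc, e_loc in local:
            if strand == "+":
                g_start, g_end = cursor + s_loc, cursor + e_loc
            else:
                g_start, g_end = cursor + unit_len - e_loc, cursor + unit_len - s_loc
            if feature_kind == "CDS":
                cds_counter += 1
                tag = f"CDS{cds_counter:04d}"
            else:
                psg_counter += 1
                tag = f"PSG{psg_counter:02d}"
            # mis-annotated starts: annotate the start upstream of the true onset
            a_start, a_end = g_start, g_end
            cog = (
                "".join(rng.choice(list(COG_LETTERS))) if rng.random() < 0.8 else None
            )
            genes.append(
                GeneRecord(
                    locus_tag=tag,
                    start=a_start,
                    end=a_end,
                    strand=strand,
                    kind=feature_kind,
                    cog_class=cog,
                    product=f"synthetic protein {tag}",
                )
            )
            member_tags.append(tag)
            gene_intervals.append((g_start, g_end))

        # the true transcript: for mis-annotated genes it starts `offset` nt inside
        tx_start, tx_end = cursor, cursor + unit_len
        if offset:
            if strand == "+":
                tx_start = gene_intervals[0][0] + offset
            else:
                tx_end = gene_intervals[0][1] - offset

        attenuation = []
        for _ in range(n_members - 1):
            if rng.random() < config.attenuation_probability:
                attenuation.append(float(rng.uniform(*config.attenuation_ratio_range)))
            else:
                attenuation.append(1.0)

        transcripts.append(
            TruthTranscript(
                transcript_id=tid,
                members=member_tags,
                strand=strand,
                start=tx_start,
                end=tx_end,
                utr_length=utr,
                program=program,
                attenuation=attenuation,
                gene_intervals=gene_intervals,
                misannotation_offset=offset,
            )
        )
        cursor += unit_len

    cursor += 200
    if cursor > config.genome_length:
        raise ValueError(
            f"cannot pack {config.n_genes} genes plus extras into {config.genome_length} nt "
            f"(need ~{cursor}); increase genome_length"
        )
    seq = "".join(rng.choice(list("ACGT"), size=config.genome_length))
    annotation = GenomeAnnotation(
        sequence_id="synthchr",
        genome_length=config.genome_length,
        genes=genes,
        sequence=seq,
    )
    return annotation, TruthSet(transcripts=transcripts)


# ---------------------------------------------------------------------------
# stage 2: per-transcript per-sample abundance
# ---------------------------------------------------------------------------


def simulate_abundances(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Relative depth multipliers, transcripts (rows) x samples (columns).

    HKG transcripts are constant up to a small lognormal jitter (realized CV < 10%);
    silent transcripts are exactly 0; phase transcripts follow early/late profiles with
    a ``phase_high``-fold swing; pseudogene classes scale a flat profile.
    """
    rng = np.random.default_rng([config.seed, 2])
    n_half = config.n_samples // 2
    profile = {
        EARLY: np.array([config.phase_high] * n_half + [1.0] * (config.n_samples - n_half)),
        LATE: np.array([1.0] * n_half + [config.phase_high] * (config.n_samples - n_half)),
    }
    flat = np.ones(config.n_samples)
    rows = {}
    # pseudogene / novel / mis-annotated transcripts ride the phase programs too
    # (alternating, like ordinary genes); only HKGs are constant.
    phase_cycle = 0
    for t in truth.transcripts:
        if t.program in (SILENT, PSEUDO_SILENT):
            rows[t.transcript_id] = np.zeros(config.n_samples)
            continue
        if t.program == HKG:
            base = float(np.exp(rng.normal(0.0, config.hkg_sigma)))
            jitter = np.exp(rng.normal(0.0, config.hkg_jitter_sigma, config.n_samples))
            rows[t.transcript_id] = base * flat * jitter
            continue
        base = float(np.exp(rng.normal(0.0, config.expression_sigma)))
        if t.program == PSEUDO_LOW:
            base *= config.pseudo_low_multiplier
        if t.program in (EARLY, LATE):
            prof = profile[t.program]
        else:
            prof = profile[EARLY if phase_cycle % 2 == 0 else LATE]
            phase_cycle += 1
        jitter = np.exp(rng.normal(0.0, config.phase_jitter_sigma, config.n_samples))
        rows[t.transcript_id] = base * prof * jitter
    return pd.DataFrame.from_dict(rows, orient="index", columns=config.sample_ids)


# ---------------------------------------------------------------------------
# stage 3: reads
# ---------------------------------------------------------------------------


def simulate_reads(
    truth: TruthSet,
    abundances: pd.DataFrame,
    config: SimulationConfig,
) -> dict[str, list[AlignmentRecord]]:
    """Simulate per-sample alignments (already 'mapped'; write with annotation_io.write_sam).

    Read starts are Poisson-sampled uniformly within each attenuation segment of each
    transcript at a rate of ``abundance x target_depth`` fold-coverage (or placed
    deterministically at even spacing when ``poisson_noise`` is off).  Reads never cross
    transcript boundaries.  Decoy ambiguous reads (MAPQ 0) are added uniformly
    genome-wide at ``decoy_fraction`` of the library.
    """
    rng = np.random.default_rng([config.seed, 3])
    rl = config.read_length
    genome_length = config.genome_length
    out: dict[str, list[AlignmentRecord]] = {}
    for s_idx, sid in enumerate(config.sample_ids):
        records: list[AlignmentRecord] = []
        for t in truth.transcripts:
            abundance = float(abundances.at[t.transcript_id, sid])
            if abundance <= 0 or t.length < rl:
                continue
            for seg_lo, seg_hi, mult in t.segments():
                lo = max(seg_lo, t.start)
                hi = min(seg_hi, t.end - rl + 1)
                span = hi - lo
                if span <= 0:
                    continue
                rate = abundance * mult * config.target_depth * span / rl
                if config.poisson_noise:
                    n = int(rng.poisson(rate))
                    starts = rng.integers(lo, hi, size=n) if n else np.array([], dtype=int)
                else:
                    # exact placement anchored at both segment edges so noise-free
                    # coverage onsets coincide with the true transcript boundaries
                    n = int(round(rate))
                    starts = np.round(np.linspace(lo, hi - 1, num=n)).astype(int)
                for k, st in enumerate(starts):
                    records.append(
                        AlignmentRecord(
                            read_id=f"{t.transcript_id}_{sid}_{seg_lo}_{k}",
                            position=int(st),
                            length=rl,
                            strand=t.strand,
                            mapping_quality=config.mapq_real,
                            ambiguous=False,
                        )
                    )
        if config.decoy_fraction > 0:
            n_decoy = int(round(len(records) * config.decoy_fraction / (1 - config.decoy_fraction)))
            positions = rng.integers(0, genome_length - rl + 1, size=n_decoy)
            for k, st in enumerate(positions):
                records.append(
                    AlignmentRecord(
                        read_id=f"decoy_{sid}_{k}",
                        position=int(st),
                        length=rl,
                        strand="+" if rng.random() < 0.5 else "-",
                        mapping_quality=0,
                        ambiguous=True,
                    )
                )
        records.sort(key=lambda r: r.position)
        out[sid] = records
    return out


def generate_fixture(config: Optional[SimulationConfig] = None, **overrides) -> Fixture:
    """Run all three stages; ``overrides`` update the default configuration."""
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        d = asdict(config)
        d.update(overrides)
        config = SimulationConfig(**d)
    annotation, truth = generate_genome(config)
    abundances = simulate_abundances(truth, config)
    reads = simulate_reads(truth, abundances, config)
    return Fixture(config=config, annotation=annotation, truth=truth, abundances=abundances, reads=reads)


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------


def junction_precision_recall(predicted_operons, truth: TruthSet) -> tuple[float, float]:
    """Precision/recall of predicted operon junctions against true co-transcribed pairs."""
    from .transcript_structure import operon_junctions

    predicted = operon_junctions(predicted_operons)
    true_pairs = truth.operon_junction_pairs()
    if not predicted:
        return (1.0 if not true_pairs else 0.0), (1.0 if not true_pairs else 0.0)
    tp = len(predicted & true_pairs)
    precision = tp / len(predicted)
    recall = tp / len(true_pairs) if true_pairs else 1.0
    return precision, recall
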