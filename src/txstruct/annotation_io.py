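"""Genome annotation and alignment I/O, and the shared data model.

All internal coordinates are 0-based half-open intervals on a single circular-or-linear
bacterial chromosome; conversion to/from the 1-based inclusive conventions of GFF3 and
GenBank happens only at the file boundary.  Strands are the literal characters ``+`` and
``-``.

Readers: GFF3 (via :mod:`gffutils`), GenBank and FASTA (via Biopython), SAM (via
:mod:`pysam`).  Writers: GFF3 and GenBank (refined annotation with operon / novel-region
/ start-anomaly features), bedGraph coverage tracks, SAM.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import numpy as np
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

GENE_KINDS = ("CDS", "pseudogene", "rRNA", "tRNA", "other")

#: default MAPQ below which an alignment is considered ambiguous (multi-mapping),
#: mirroring the MAQ pileup quality cutoff the source alignments were filtered at.
DEFAULT_MAPQ_CUTOFF = 30


class AnnotationError(ValueError):
    """Malformed or inconsistent annotation input."""


class AlignmentError(ValueError):
    """Malformed or inconsistent alignment input."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------


@dataclass
class GeneRecord:
    """One annotated feature (CDS, pseudogene, rRNA, tRNA or other).

    ``cog_class`` is a string of one-letter COG category codes (a gene may carry
    several); ``None`` means the gene is not assigned to any COG.
    """

    locus_tag: str
    start: int
    end: int
    strand: str
    kind: str = "CDS"
    cog_class: Optional[str] = None
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"{self.locus_tag}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.locus_tag}: strand must be '+' or '-'")
        if self.kind not in GENE_KINDS:
            raise AnnotationError(f"{self.locus_tag}: unknown feature kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def five_prime(self) -> int:
        """Annotated translation-start position (strand aware).

        For a plus-strand gene this is ``start``; for a minus-strand gene it is the
        half-open right edge ``end``, so a 5'-UTR of length u spans ``[end, end+u)``.
        """
        return self.start if self.strand == "+" else self.end


@dataclass
class GenomeAnnotation:
    """A genome with its ordered feature set.

    ``genes`` is kept sorted by start coordinate; ``sequence`` is optional (needed only
    for ORF finding and for writing GenBank/FASTA with real bases).
    """

    sequence_id: str
    genome_length: int
    genes: list[GeneRecord] = field(default_factory=list)
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise AnnotationError("genome_length must be positive")
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        seen: set[str] = set()
        for g in self.genes:
            if g.end > self.genome_length:
                raise AnnotationError(
                    f"{g.locus_tag}: interval [{g.start}, {g.end}) exceeds genome length "
                    f"{self.genome_length}"
                )
            if g.locus_tag in seen:
                raise AnnotationError(f"duplicate locus_tag {g.locus_tag!r}")
            seen.add(g.locus_tag)
        if self.sequence is not None and len(self.sequence) != self.genome_length:
            raise AnnotationError("sequence length disagrees with genome_length")

    @property
    def by_tag(self) -> dict[str, GeneRecord]:
        return {g.locus_tag: g for g in self.genes}

    def genes_of_kind(self, *kinds: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.kind in kinds]

    def gene_mask(self) -> np.ndarray:
        """Boolean array marking every annotated-gene base."""
        mask = np.zeros(self.genome_length, dtype=bool)
        for g in self.genes:
            mask[g.start : g.end] = True
        return mask

    def upstream_same_strand_gene(self, gene: GeneRecord) -> Optional[GeneRecord]:
        """The nearest same-strand gene on the 5' side of ``gene`` (or None)."""
        best: Optional[GeneRecord] = None
        for g in self.genes:
            if g.locus_tag == gene.locus_tag or g.strand != gene.strand:
                continue
            if gene.strand == "+" and g.end <= gene.start:
                if best is None or g.end > best.end:
                    best = g
            elif gene.strand == "-" and g.start >= gene.end:
                if best is None or g.start < best.start:
                    best = g
        return best


@dataclass
class AlignmentRecord:
    """One mapped read, reduced to a gapless reference block."""

    read_id: str
    position: int
    length: int
    strand: str
    mapping_quality: int
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_genome_fasta(path: str | Path) -> tuple[str, str]:
    """Read a single-sequence genome FASTA; returns (sequence_id, sequence)."""
    record = SeqIO.read(str(path), "fasta")
    return record.id, str(record.seq).upper()


def write_genome_fasta(sequence_id: str, sequence: str, path: str | Path) -> None:
    record = SeqRecord(Seq(sequence), id=sequence_id, description="")
    SeqIO.write([record], str(path), "fasta")


# ---------------------------------------------------------------------------
# annotation reading
# ---------------------------------------------------------------------------

_TYPED_FEATURES = {"CDS", "pseudogene", "rRNA", "tRNA"}


def _is_pseudo_qualifier(values: Iterable[str]) -> bool:
    return any(v.lower() in ("", "true", "yes", "1", "pseudo") for v in values)


def read_annotation(path: str | Path, format: str = "gff3") -> GenomeAnnotation:
    """Read a GFF3 or GenBank annotation into the internal model.

    Coordinates are converted from the native 1-based inclusive convention to 0-based
    half-open.  Pseudogenes are recognized either as ``pseudogene`` feature types or as
    CDS/gene features carrying a ``pseudo`` qualifier, covering both RefSeq dialects.
    """
    if format == "gff3":
        return _read_gff3(Path(path))
    if format == "genbank":
        return _read_genbank(Path(path))
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: Path) -> GenomeAnnotation:
    import gffutils

    lines = path.read_text().splitlines()
    if not any(line.strip() and not line.startswith("#") for line in lines):
        # featureless file: gffutils refuses it, but an empty annotation is valid
        for line in lines:
            if line.startswith("##sequence-region"):
                parts = line.split()
                return GenomeAnnotation(sequence_id=parts[1], genome_length=int(parts[3]))
        raise AnnotationError(f"{path}: no sequence-region directive and no features")

    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - message shape depends on gffutils
        raise AnnotationError(f"failed to parse GFF3 {path}: {exc}") from exc

    sequence_id = None
    genome_length = None
    for directive in db.directives:
        if directive.startswith("sequence-region"):
            parts = directive.split()
            sequence_id = parts[1]
            genome_length = int(parts[3])

    genes: list[GeneRecord] = []
    max_end = 0
    for feat in db.all_features(order_by="start"):
        if sequence_id is None:
            sequence_id = feat.seqid
        if feat.featuretype not in _TYPED_FEATURES:
            continue
        kind = feat.featuretype
        if kind == "CDS" and _is_pseudo_qualifier(feat.attributes.get("pseudo", [])):
            kind = "pseudogene"
        tag = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [None])[0]
        if tag is None:
            raise AnnotationError(
                f"GFF3 feature at {feat.seqid}:{feat.start}-{feat.end} lacks "
                "locus_tag/ID"
            )
        if feat.strand not in ("+", "-"):
            raise AnnotationError(f"{tag}: missing strand in GFF3")
        cog = (feat.attributes.get("cog_class") or [None])[0]
        product = (feat.attributes.get("product") or [None])[0]
        genes.append(
            GeneRecord(
                locus_tag=tag,
                start=feat.start - 1,  # GFF3 is 1-based inclusive
                end=feat.end,
                strand=feat.strand,
                kind=kind,
                cog_class=cog,
                product=product,
            )
        )
        max_end = max(max_end, feat.end)

    if sequence_id is None:
        raise AnnotationError(f"{path}: no sequence-region directive and no features")
    if genome_length is None:
        genome_length = max_end
    return GenomeAnnotation(sequence_id=sequence_id, genome_length=genome_length, genes=genes)


def _read_genbank(path: Path) -> GenomeAnnotation:
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:
        raise AnnotationError(f"failed to parse GenBank {path}: {exc}") from exc

    genes: list[GeneRecord] = []
    for feat in record.features:
        if feat.type not in _TYPED_FEATURES:
            continue
        quals = feat.qualifiers
        kind = feat.type
        if kind == "CDS" and ("pseudo" in quals or "pseudogene" in quals):
            kind = "pseudogene"
        tag = (quals.get("locus_tag") or quals.get("gene") or [None])[0]
        if tag is None:
            raise AnnotationError(f"GenBank {feat.type} feature at {feat.location} lacks locus_tag")
        strand = "+" if feat.location.strand in (1, None) else "-"
        genes.append(
            GeneRecord(
                locus_tag=tag,
                start=int(feat.location.start),  # Biopython locations are 0-based half-open
                end=int(feat.location.end),
                strand=strand,
                kind=kind,
                cog_class=(quals.get("cog_class") or [None])[0],
                product=(quals.get("product") or [None])[0],
            )
        )

    sequence = str(record.seq) if len(record.seq) else None
    if sequence is not None and set(sequence) <= {"N"}:
        sequence = None  # placeholder sequence, carry length only
    return GenomeAnnotation(
        sequence_id=record.id or record.name,
        genome_length=len(record.seq),
        genes=genes,
        sequence=sequence,
    )


# ---------------------------------------------------------------------------
# annotation writing (plain annotation and the refined file)
# ---------------------------------------------------------------------------


def _gff3_escape(text: str) -> str:
    return text.replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _gene_gff3_line(seqid: str, g: GeneRecord, extra_notes: Sequence[str] = ()) -> str:
    attrs = [f"ID={_gff3_escape(g.locus_tag)}", f"locus_tag={_gff3_escape(g.locus_tag)}"]
    if g.product:
        attrs.append(f"product={_gff3_escape(g.product)}")
    if g.cog_class:
        attrs.append(f"cog_class={_gff3_escape(g.cog_class)}")
    for note in extra_notes:
        attrs.append(f"note={_gff3_escape(note)}")
    return "\t".join(
        [
            seqid,
            "txstruct",
            g.kind,
            str(g.start + 1),
            str(g.end),
            ".",
            g.strand,
            ".",
            ";".join(attrs),
        ]
    )


def write_annotation(annotation: GenomeAnnotation, path: str | Path, format: str = "gff3") -> None:
    """Write the bare annotation (no structural extras)."""
    write_refined_annotation(annotation, [], [], [], path, format=format)


def write_refined_annotation(
    annotation: GenomeAnnotation,
    operons: Sequence,
    anomalies: Sequence,
    novel: Sequence,
    path: str | Path,
    format: str = "gff3",
) -> None:
    """Write the refined annotation: genes plus operons, start anomalies and novel regions.

    Operons become grouped features spanning their members (GFF3 ``operon`` type /
    GenBank ``misc_feature`` with an ``operon`` qualifier); novel transcribed regions
    become ``misc_feature`` entries with a note; start anomalies become notes on the
    affected gene.  Reading the written file back reproduces every gene interval exactly.
    """
    by_tag = annotation.by_tag
    for op in operons:
        for tag in op.members:
            if tag not in by_tag:
                raise AnnotationError(f"operon {op.operon_id}: member {tag!r} not in annotation")
    anomaly_notes: dict[str, list[str]] = {}
    for flag in anomalies:
        if flag.locus_tag not in by_tag:
            raise AnnotationError(f"start anomaly references unknown gene {flag.locus_tag!r}")
        anomaly_notes.setdefault(flag.locus_tag, []).append(
            "possible mis-annotated start codon: transcription onset "
            f"{flag.offset_into_gene} nt inside the annotated CDS "
            f"({len(flag.samples_supporting)} samples)"
        )

    if format == "gff3":
        _write_gff3(annotation, operons, anomaly_notes, novel, Path(path))
    elif format == "genbank":
        _write_genbank(annotation, operons, anomaly_notes, novel, Path(path))
    else:
        raise ValueError(f"unknown annotation format {format!r}")


def _write_gff3(annotation, operons, anomaly_notes, novel, path: Path) -> None:
    lines = [
        "##gff-version 3",
        f"##sequence-region {annotation.sequence_id} 1 {annotation.genome_length}",
    ]
    for g in annotation.genes:
        lines.append(_gene_gff3_line(annotation.sequence_id, g, anomaly_notes.get(g.locus_tag, ())))
    for op in operons:
        attrs = (
            f"ID={_gff3_escape(op.operon_id)};members={_gff3_escape(','.join(op.members))}"
        )
        lines.append(
            "\t".join(
                [
                    annotation.sequence_id,
                    "txstruct",
                    "operon",
                    str(op.start + 1),
                    str(op.end),
                    ".",
                    op.strand,
                    ".",
                    attrs,
                ]
            )
        )
    for i, region in enumerate(novel, start=1):
        note = _gff3_escape(
            f"novel transcribed region (mean depth {region.mean_depth:.1f}, "
            f"{len(region.samples_supporting)} samples)"
        )
        lines.append(
            "\t".join(
                [
                    annotation.sequence_id,
                    "txstruct",
                    "transcribed_region",
                    str(region.start + 1),
                    str(region.end),
                    ".",
                    ".",
                    ".",
                    f"ID=novel{i:03d};note={note}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _write_genbank(annotation, operons, anomaly_notes, novel, path: Path) -> None:
    seq = annotation.sequence or "N" * annotation.genome_length
    record = SeqRecord(
        Seq(seq),
        id=annotation.sequence_id,
        name=annotation.sequence_id[:16].replace("|", "_"),
        description="refined annotation produced by txstruct",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for g in annotation.genes:
        loc = FeatureLocation(g.start, g.end, strand=1 if g.strand == "+" else -1)
        quals: dict[str, list[str]] = {"locus_tag": [g.locus_tag]}
        if g.product:
            quals["product"] = [g.product]
        if g.cog_class:
            quals["cog_class"] = [g.cog_class]
        if g.locus_tag in anomaly_notes:
            quals["note"] = list(anomaly_notes[g.locus_tag])
        ftype = g.kind
        if g.kind == "pseudogene":
            # minimal, parser-safe key: CDS with a /pseudo qualifier
            ftype = "CDS"
            quals["pseudo"] = [""]
        elif g.kind == "other":
            ftype = "misc_feature"
        record.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    for op in operons:
        loc = FeatureLocation(op.start, op.end, strand=1 if op.strand == "+" else -1)
        record.features.append(
            SeqFeature(
                loc,
                type="misc_feature",
                qualifiers={"operon": [op.operon_id], "note": ["members: " + ",".join(op.members)]},
            )
        )
    for i, region in enumerate(novel, start=1):
        loc = FeatureLocation(region.start, region.end)
        record.features.append(
            SeqFeature(
                loc,
                type="misc_feature",
                qualifiers={
                    "note": [
                        f"novel transcribed region novel{i:03d} "
                        f"(mean depth {region.mean_depth:.1f})"
                    ]
                },
            )
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def read_alignments(
    path: str | Path,
    mapq_cutoff: int = DEFAULT_MAPQ_CUTOFF,
    expected_sequence_id: Optional[str] = None,
    expected_genome_length: Optional[int] = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped reads from a SAM file as :class:`AlignmentRecord`.

    Unmapped records are skipped.  A record is flagged ``ambiguous`` when its MAPQ is
    below ``mapq_cutoff`` or when an explicit multi-hit tag (NH>1, X0>1, XT:A:R) is
    present.  Raises :class:`AlignmentError` on reference mismatch or truncation,
    reporting the number of records read so far.
    """
    n_emitted = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        ref_names = list(sam.references)
        ref_lengths = list(sam.lengths)
        if expected_sequence_id is not None and ref_names and ref_names[0] != expected_sequence_id:
            raise AlignmentError(
                f"SAM reference {ref_names[0]!r} does not match annotation "
                f"{expected_sequence_id!r}"
            )
        if (
            expected_genome_length is not None
            and ref_lengths
            and ref_lengths[0] != expected_genome_length
        ):
            raise AlignmentError(
                f"SAM reference length {ref_lengths[0]} does not match genome length "
                f"{expected_genome_length}"
            )
        try:
            for aln in sam:
                if aln.is_unmapped:
                    continue
                length = aln.reference_length
                if length is None or length <= 0:
                    length = aln.query_length
                ambiguous = aln.mapping_quality < mapq_cutoff
                if not ambiguous:
                    try:
                        if aln.has_tag("NH") and aln.get_tag("NH") > 1:
                            ambiguous = True
                        elif aln.has_tag("X0") and aln.get_tag("X0") > 1:
                            ambiguous = True
                        elif aln.has_tag("XT") and aln.get_tag("XT") == "R":
                            ambiguous = True
                    except (KeyError, ValueError):
                        pass
                yield AlignmentRecord(
                    read_id=aln.query_name or f"read{n_emitted}",
                    position=int(aln.reference_start),
                    length=int(length),
                    strand="-" if aln.is_reverse else "+",
                    mapping_quality=int(aln.mapping_quality),
                    ambiguous=ambiguous,
                )
                n_emitted += 1
        except (OSError, ValueError) as exc:
            raise AlignmentError(
                f"truncated or malformed SAM {path} after {n_emitted} records: {exc}"
            ) from exc


def write_sam(
    records: Iterable[AlignmentRecord],
    path: str | Path,
    sequence_id: str,
    genome_length: int,
    genome_sequence: Optional[str] = None,
) -> int:
    """Write alignment records as coordinate-sorted plain-text SAM; returns count."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sequence_id, "LN": int(genome_length)}],
    }
    records = sorted(records, key=lambda r: r.position)
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rec.read_id
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_id = 0
            a.reference_start = rec.position
            a.mapping_quality = rec.mapping_quality
            a.cigartuples = [(0, rec.length)]
            if genome_sequence is not None:
                a.query_sequence = genome_sequence[rec.position : rec.position + rec.length]
            out.write(a)
            n += 1
    return n


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------


def write_coverage_bedgraph(track, path: str | Path) -> None:
    """Write a coverage track as run-length-encoded bedGraph (0-based half-open)."""
    depth = np.asarray(track.total_depth() if hasattr(track, "total_depth") else track)
    change = np.flatnonzero(np.diff(depth)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(depth)]))
    name = getattr(track, "sample_id", "coverage")
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        seqid = getattr(track, "sequence_id", None) or "genome"
        for s, e in zip(starts, ends):
            fh.write(f"{seqid}\t{s}\t{e}\t{int(depth[s])}\n")


def read_coverage_bedgraph(path: str | Path, genome_length: Optional[int] = None) -> np.ndarray:
    """Re-parse a bedGraph written by :func:`write_coverage_bedgraph` into a depth array."""
    runs: list[tuple[int, int, int]] = []
    max_end = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "#", "browser")) or not line.strip():
                continue
            _, s, e, v = line.rstrip("\n").split("\t")
            runs.append((int(s), int(e), int(v)))
            max_end = max(max_end, int(e))
    depth = np.zeros(genome_length or max_end, dtype=np.int64)
    for s, e, v in runs:
        depth[s:e] = v
    return depth
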