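"""Per-base coverage tracks and genome-representation statistics.

The central data object of the pipeline: each base carries the number of unambiguously
mapped reads covering it.  Reads are gapless fixed-length blocks, so depth is computed
with a difference-array accumulation that is exact (no smoothing, no normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import numpy as np

from .annotation_io import AlignmentRecord


@dataclass
class CoverageTrack:
    """Per-base read depth for one sample.

    In unstranded mode ``depth`` holds one array of length ``genome_length``; in
    stranded mode ``depth_fwd``/``depth_rev`` are populated and ``depth`` is their sum.
    """

    sample_id: str
    depth: np.ndarray
    reads_used: int = 0
    bases_mapped: int = 0
    depth_fwd: Optional[np.ndarray] = None
    depth_rev: Optional[np.ndarray] = None
    sequence_id: Optional[str] = None

    @property
    def genome_length(self) -> int:
        return len(self.depth)

    def total_depth(self) -> np.ndarray:
        return self.depth

    def validate(self) -> None:
        assert int(self.depth.sum()) == self.bases_mapped, "depth mass must equal mapped bases"
        if self.depth_fwd is not None and self.depth_rev is not None:
            assert np.array_equal(self.depth_fwd + self.depth_rev, self.depth)


@dataclass
class SampleCoverageSet:
    """Coverage tracks for all samples of one experiment, keyed by sample id."""

    tracks: dict[str, CoverageTrack] = field(default_factory=dict)
    sample_times: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {t.genome_length for t in self.tracks.values()}
        if len(lengths) > 1:
            raise ValueError("all coverage tracks must share the genome length")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.tracks)

    @property
    def genome_length(self) -> int:
        return next(iter(self.tracks.values())).genome_length

    def __iter__(self) -> Iterator[CoverageTrack]:
        return iter(self.tracks.values())

    def __getitem__(self, sample_id: str) -> CoverageTrack:
        return self.tracks[sample_id]


def filter_alignments(
    records: Iterable[AlignmentRecord], min_mapq: int = 30
) -> Iterator[AlignmentRecord]:
    """Keep only unambiguous records with MAPQ >= ``min_mapq``; order preserved."""
    if min_mapq < 0:
        raise ValueError("min_mapq must be >= 0")
    for rec in records:
        if not rec.ambiguous and rec.mapping_quality >= min_mapq:
            yield rec


def compute_coverage(
    records: Iterable[AlignmentRecord],
    genome_length: int,
    mode: str = "unstranded",
    sample_id: str = "sample",
) -> CoverageTrack:
    """Accumulate per-base depth: ``depth[i]`` counts alignments whose interval contains i.

    ``records`` are assumed to be already filtered.  An alignment extending past the
    genome end is a hard error naming the read.
    """
    if mode not in ("unstranded", "stranded"):
        raise ValueError("mode must be 'unstranded' or 'stranded'")
    diff_fwd = np.zeros(genome_length + 1, dtype=np.int64)
    diff_rev = np.zeros(genome_length + 1, dtype=np.int64) if mode == "stranded" else None
    reads_used = 0
    bases = 0
    for rec in records:
        if rec.position < 0 or rec.position + rec.length > genome_length:
            raise ValueError(
                f"alignment {rec.read_id!r} [{rec.position}, {rec.position + rec.length}) "
                f"exceeds genome bounds (length {genome_length})"
            )
        target = diff_rev if (mode == "stranded" and rec.strand == "-") else diff_fwd
        target[rec.position] += 1
        target[rec.position + rec.length] -= 1
        reads_used += 1
        bases += rec.length

    depth_fwd = np.cumsum(diff_fwd)[:-1]
    if mode == "stranded":
        depth_rev = np.cumsum(diff_rev)[:-1]
        return CoverageTrack(
            sample_id=sample_id,
            depth=depth_fwd + depth_rev,
            depth_fwd=depth_fwd,
            depth_rev=depth_rev,
            reads_used=reads_used,
            bases_mapped=bases,
        )
    return CoverageTrack(sample_id=sample_id, depth=depth_fwd, reads_used=reads_used, bases_mapped=bases)


def genome_fraction_transcribed(
    track_or_set: Union[CoverageTrack, SampleCoverageSet], depth_min: int = 1
) -> float:
    """Fraction of genome positions covered at >= ``depth_min``.

    For a :class:`SampleCoverageSet` a position counts when it reaches ``depth_min`` in
    at least one sample (the "transcribed in at least one sample" union statistic);
    for a single track it is the plain per-track fraction.
    """
    if depth_min < 1:
        raise ValueError("depth_min must be >= 1")
    if isinstance(track_or_set, CoverageTrack):
        return float(np.count_nonzero(track_or_set.depth >= depth_min)) / track_or_set.genome_length
    if not track_or_set.tracks:
        raise ValueError("empty coverage set")
    covered = np.zeros(track_or_set.genome_length, dtype=bool)
    for track in track_or_set:
        covered |= track.depth >= depth_min
    return float(np.count_nonzero(covered)) / track_or_set.genome_length
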