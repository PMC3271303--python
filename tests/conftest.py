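"""Shared fixtures: one noise-free and one Poisson-noise synthetic experiment.

Session-scoped because the full pipeline (layout, abundances, ~70k reads x 6 samples,
coverage) is rebuilt deterministically from seed 1 and reused by many tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import txstruct as tx


@pytest.fixture(scope="session")
def clean_fixture() -> tx.Fixture:
    """Deterministic (noise-free) default fixture: exact read placement, no decoys."""
    return tx.generate_fixture(seed=1, poisson_noise=False)


@pytest.fixture(scope="session")
def clean_coverage(clean_fixture) -> tx.SampleCoverageSet:
    return clean_fixture.coverage_set()


@pytest.fixture(scope="session")
def clean_counts(clean_fixture):
    return [
        tx.count_reads_per_gene(
            tx.filter_alignments(records), clean_fixture.annotation, sample_id=sid
        )
        for sid, records in clean_fixture.reads.items()
    ]


@pytest.fixture(scope="session")
def clean_matrix(clean_fixture, clean_counts) -> tx.ExpressionMatrix:
    return tx.build_expression_matrix(clean_counts, clean_fixture.annotation)


@pytest.fixture(scope="session")
def noisy_fixture() -> tx.Fixture:
    """Default fixture with Poisson read-start noise (no decoys)."""
    return tx.generate_fixture(seed=1, poisson_noise=True)


@pytest.fixture(scope="session")
def noisy_coverage(noisy_fixture) -> tx.SampleCoverageSet:
    return noisy_fixture.coverage_set()


def make_annotation(genes, genome_length=10_000, sequence=None) -> tx.GenomeAnnotation:
    """Small-annotation builder for hand-constructed cases."""
    records = [
        tx.GeneRecord(locus_tag=tag, start=s, end=e, strand=strand, kind=kind, cog_class=cog)
        for (tag, s, e, strand, kind, cog) in genes
    ]
    return tx.GenomeAnnotation(
        sequence_id="chr", genome_length=genome_length, genes=records, sequence=sequence
    )


def make_reads(spec, length=75, mapq=60):
    """[(position, strand), ...] -> AlignmentRecords."""
    return [
        tx.AlignmentRecord(
            read_id=f"r{i}", position=p, length=length, strand=strand, mapping_quality=mapq
        )
        for i, (p, strand) in enumerate(spec)
    ]


def brute_force_depth(records, genome_length: int) -> np.ndarray:
    """Independent per-base interval-membership count."""
    depth = np.zeros(genome_length, dtype=np.int64)
    for rec in records:
        for p in range(rec.position, rec.position + rec.length):
            depth[p] += 1
    return depth
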