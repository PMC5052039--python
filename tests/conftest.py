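"""Shared fixtures: tiny hand-built annotations and seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from circkit.genome_annotation import GeneModel, GenomeSequence
from circkit.junction_io import LibraryInfo


@pytest.fixture
def gene4() -> GeneModel:
    """4-exon plus-strand gene: exons at [100,200) [300,400) [500,600) [700,800)."""
    return GeneModel(
        "GENE1", "GENE1.iso1", "chr1", "+",
        (100, 300, 500, 700), (200, 400, 600, 800),
    )


@pytest.fixture
def gene4_minus() -> GeneModel:
    return GeneModel(
        "GENE2", "GENE2.iso1", "chr1", "-",
        (100, 300, 500, 700), (200, 400, 600, 800),
    )


@pytest.fixture
def random_genome() -> GenomeSequence:
    rng = np.random.default_rng(7)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = b"".join(bases[rng.integers(0, 4, size=2000)]).decode()
    return GenomeSequence({"chr1": seq})


@pytest.fixture
def library() -> LibraryInfo:
    return LibraryInfo("LIB1", "pA_minus", 1_000_000, "CL1")


@pytest.fixture
def pa_plus_library() -> LibraryInfo:
    return LibraryInfo("LIBP", "pA_plus", 1_000_000, "CL1")


def random_models(rng: np.random.Generator, n_genes: int, chrom: str = "chr1"):
    """Random non-overlapping multi-exon genes for oracle tests."""
    models = []
    pos = 0
    for gi in range(n_genes):
        pos += int(rng.integers(50, 200))
        n_ex = int(rng.integers(2, 7))
        strand = "+" if rng.random() < 0.5 else "-"
        starts, ends = [], []
        for k in range(n_ex):
            if k > 0:
                pos += int(rng.integers(40, 150))
            starts.append(pos)
            pos += int(rng.integers(30, 120))
            ends.append(pos)
        models.append(
            GeneModel(
                f"G{gi}", f"G{gi}.t1", chrom, strand, tuple(starts), tuple(ends)
            )
        )
    return models
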