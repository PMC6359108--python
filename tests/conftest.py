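"""Shared fixtures: a small hand-built genome and QTL set.

The toy genome has 12 genes on two chromosomes with three family labels;
everything about it (order, overlaps, counts) is enumerable by hand, so
tests against it freeze hand-derived expectations.
"""

import pytest

from lectinqtl import GeneRecord, Genome, QTLRecord


@pytest.fixture
def toy_genome() -> Genome:
    genes = [
        # chr1: 8 genes; GNA at g1,g2,g4; Jacalin at g6,g7; others unlabeled
        GeneRecord("g1", "chr1", 100, 200, "+", "GNA"),
        GeneRecord("g2", "chr1", 300, 450, "-", "GNA"),
        GeneRecord("g3", "chr1", 500, 600, "+", None),
        GeneRecord("g4", "chr1", 700, 900, "+", "GNA"),
        GeneRecord("g5", "chr1", 1000, 1100, "-", None),
        GeneRecord("g6", "chr1", 1200, 1400, "+", "Jacalin"),
        GeneRecord("g7", "chr1", 1500, 1600, "-", "Jacalin"),
        GeneRecord("g8", "chr1", 1700, 1900, "+", None),
        # chr2: 4 genes; one LysM
        GeneRecord("g9", "chr2", 50, 150, "+", "LysM"),
        GeneRecord("g10", "chr2", 200, 380, "-", None),
        GeneRecord("g11", "chr2", 400, 520, "+", None),
        GeneRecord("g12", "chr2", 600, 800, "+", None),
    ]
    return Genome(chromosomes=[("chr1", 2000), ("chr2", 1000)], genes=genes)


@pytest.fixture
def toy_qtls() -> list[QTLRecord]:
    return [
        # traitA: two overlapping QTLs on chr1 plus one on chr2
        QTLRecord("q1", "resistance_tolerance", "traitA", "chr1", 0, 600),
        QTLRecord("q2", "resistance_tolerance", "traitA", "chr1", 400, 1000),
        QTLRecord("q3", "resistance_tolerance", "traitA", "chr2", 0, 300),
        # traitB: one QTL covering the Jacalin pair, one gene-empty QTL
        QTLRecord("q4", "physiological", "traitB", "chr1", 1150, 1650),
        QTLRecord("q5", "physiological", "traitB", "chr2", 850, 990),
    ]
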