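"""Sweep-line interval intersection between genes and QTL regions.

The assignment of genes to trait regions is the input to every downstream
count (n, x, co-occurrence, coverage), so the engine is deliberately small
and fully specified: a gene overlaps a region iff the half-open intervals
share at least one base, i.e. ``max(starts) < min(ends)``; intervals that
merely abut do not overlap. The sweep is linear over the two sorted lists
and is tested for exact agreement with a naive all-pairs check.

Inputs must arrive sorted by (chrom, start); an unsorted list is a contract
violation and raises rather than being silently re-sorted, because callers
rely on gene rank order elsewhere (tandem detection) and a hidden re-sort
would mask bugs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .genome_model import GeneRecord, Genome
from .qtl_processing import MergedTraitRegions

__all__ = [
    "OverlapAssignment",
    "sweep_overlaps",
    "intersect",
    "lectin_count",
    "trait_cooccurrence",
    "write_assignment_tsv",
]


@dataclass
class OverlapAssignment:
    """Gene <-> trait-region assignment.

    ``pairs`` lists every ``(gene_id, trait, region_index)`` with a genuine
    >=1 bp overlap; ``by_gene`` and ``by_trait`` are the two transposed
    index views of the same relation.
    """

    pairs: list[tuple[str, str, int]]
    by_gene: dict[str, set[str]] = field(default_factory=dict)
    by_trait: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.by_gene and not self.by_trait:
            for gene_id, trait, _ in self.pairs:
                self.by_gene.setdefault(gene_id, set()).add(trait)
                self.by_trait.setdefault(trait, set()).add(gene_id)

    def traits(self) -> list[str]:
        return sorted(self.by_trait)


def _group_by_chrom(
    keyed: Sequence[tuple[str, int, int]], what: str
) -> dict[str, list[tuple[int, int, int]]]:
    """Split (chrom, start, end) rows into per-chromosome (index, start, end)
    lists, checking starts are non-decreasing within each chromosome and that
    each chromosome's rows form one contiguous block (any total chromosome
    order is acceptable as long as rows are not interleaved)."""
    groups: dict[str, list[tuple[int, int, int]]] = {}
    last_chrom: str | None = None
    for i, (chrom, start, end) in enumerate(keyed):
        if chrom != last_chrom:
            if chrom in groups:
                raise ValueError(f"{what} not sorted: chromosome {chrom!r} interleaved")
            groups[chrom] = []
            last_chrom = chrom
        elif groups[chrom] and start < groups[chrom][-1][1]:
            raise ValueError(
                f"{what} not sorted by start within {chrom!r} "
                f"(position {groups[chrom][-1][1]} then {start})"
            )
        groups[chrom].append((i, start, end))
    return groups


def sweep_overlaps(
    genes: Sequence[GeneRecord],
    intervals: Sequence[tuple[str, int, int]],
) -> list[tuple[int, int]]:
    """All (gene index, interval index) pairs with >=1 bp half-open overlap.

    Both lists must be sorted by (chrom, start); ``intervals`` may overlap
    each other (raw QTLs do). Linear sweep per chromosome: genes are
    consumed in start order while a candidate window of intervals is
    maintained — an interval leaves the window permanently once its end is
    at or before the current gene's start, which is safe because later
    genes start no earlier.
    """
    gene_groups = _group_by_chrom([(g.chrom, g.start, g.end) for g in genes], "genes")
    interval_groups = _group_by_chrom(intervals, "intervals")

    out: list[tuple[int, int]] = []
    for chrom, chrom_genes in gene_groups.items():
        chrom_ivals = interval_groups.get(chrom)
        if not chrom_ivals:
            continue
        j = 0
        active: list[tuple[int, int, int]] = []
        for gi, gstart, gend in chrom_genes:
            # admit intervals starting before the gene ends
            while j < len(chrom_ivals) and chrom_ivals[j][1] < gend:
                active.append(chrom_ivals[j])
                j += 1
            # retire intervals that cannot overlap this or any later gene
            active = [iv for iv in active if iv[2] > gstart]
            for ii, istart, iend in active:
                if max(gstart, istart) < min(gend, iend):
                    out.append((gi, ii))
    return sorted(out)


def intersect(
    genes: Sequence[GeneRecord],
    regions: MergedTraitRegions | Iterable[MergedTraitRegions],
) -> OverlapAssignment:
    """Assign genes to the regions of one or several traits.

    ``genes`` must be sorted by (chrom, start) — a :class:`Genome`'s gene
    list already is. Region indices in the result are per trait.
    """
    if isinstance(regions, MergedTraitRegions):
        regions = [regions]
    pairs: list[tuple[str, str, int]] = []
    for merged in regions:
        order = sorted(range(len(merged.regions)), key=lambda i: merged.regions[i][:2])
        sorted_regions = [merged.regions[i] for i in order]
        for gi, ri in sweep_overlaps(genes, sorted_regions):
            pairs.append((genes[gi].gene_id, merged.trait, order[ri]))
    return OverlapAssignment(pairs=pairs)


def lectin_count(
    assignment: OverlapAssignment,
    genome: Genome,
    trait: str,
    family: str | None = None,
) -> int:
    """Unique family-labelled genes overlapping a trait's regions.

    ``family=None`` counts genes of any family (the "all lectins" filter);
    a specific label restricts to that family. This is the statistic's x.
    """
    if trait not in assignment.by_trait:
        raise KeyError(f"trait {trait!r} absent from assignment")
    fam_of = {g.gene_id: g.family for g in genome.genes}
    count = 0
    for gene_id in assignment.by_trait[trait]:
        fam = fam_of.get(gene_id)
        if fam is not None and (family is None or fam == family):
            count += 1
    return count


def trait_cooccurrence(
    assignment: OverlapAssignment, genome: Genome, trait_a: str, trait_b: str
) -> int:
    """Family-labelled genes assigned to both traits' regions."""
    for t in (trait_a, trait_b):
        if t not in assignment.by_trait:
            raise KeyError(f"trait {t!r} absent from assignment")
    fam_of = {g.gene_id: g.family for g in genome.genes}
    shared = assignment.by_trait[trait_a] & assignment.by_trait[trait_b]
    return sum(1 for gid in shared if fam_of.get(gid) is not None)


def write_assignment_tsv(
    assignment: OverlapAssignment,
    genome: Genome,
    regions: Iterable[MergedTraitRegions],
    path,
) -> None:
    """Audit dump: one row per (gene, trait, region) assignment."""
    region_lookup = {m.trait: m.regions for m in regions}
    fam_of = {g.gene_id: g.family for g in genome.genes}
    with open(path, "w") as fh:
        fh.write("gene_id\tfamily\ttrait\tregion\n")
        for gene_id, trait, ri in sorted(assignment.pairs):
            chrom, start, end = region_lookup[trait][ri]
            fh.write(
                f"{gene_id}\t{fam_of.get(gene_id) or ''}\t{trait}\t"
                f"{chrom}:{start}-{end}\n"
            )
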