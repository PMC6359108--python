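"""Non-redundant QTL region sets per trait.

Published QTL tables are heavily redundant: the same genomic region is often
reported many times for one trait. Before testing whether a gene family is
overrepresented in the regions associated with a trait, all overlapping QTLs
for that trait are coalesced into a disjoint interval union, and regions
containing no annotated gene at all are excluded (they contribute no
information to a gene-count statistic).

Merging is always per trait name, never across traits: a gene family may
legitimately co-occur in QTLs of several traits and those signals must stay
separate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .genome_model import Genome, QTLRecord

__all__ = ["MergedTraitRegions", "merge_trait_qtls", "drop_geneless_regions", "write_regions_bed"]


@dataclass
class MergedTraitRegions:
    """Disjoint, sorted interval union of one trait's QTLs.

    ``regions`` holds ``(chrom, start, end)`` half-open tuples, pairwise
    disjoint within a chromosome and sorted by (chrom, start);
    ``source_qtl_ids[i]`` lists the QTL IDs merged into ``regions[i]``.
    ``n_genes`` is the number of unique gene IDs overlapping any region; it
    is -1 until :func:`drop_geneless_regions` has run.
    """

    trait: str
    category: str
    regions: list[tuple[str, int, int]]
    source_qtl_ids: list[list[str]]
    n_genes: int = -1
    skip: bool = field(default=False)

    @property
    def total_bp(self) -> int:
        return sum(end - start for _, start, end in self.regions)

    def __len__(self) -> int:
        return len(self.regions)


def merge_trait_qtls(qtls: Sequence[QTLRecord]) -> MergedTraitRegions:
    """Coalesce one trait's QTLs into a non-redundant region set.

    Overlapping or bookended intervals on the same chromosome (half-open
    ``a.end == b.start`` means no base lies between them) merge into one
    region. The covered base-pair total equals the interval union exactly.

    Raises ``ValueError`` on empty input (a trait without QTLs is not
    analyzable) or on mixed trait labels.
    """
    if not qtls:
        raise ValueError("cannot merge an empty QTL list: trait has no QTLs")
    traits = {q.trait for q in qtls}
    if len(traits) > 1:
        raise ValueError(f"merge_trait_qtls got several traits: {sorted(traits)}")
    categories = {q.category for q in qtls}
    if len(categories) > 1:
        raise ValueError(
            f"trait {qtls[0].trait!r} spans categories {sorted(categories)}"
        )

    ordered = sorted(qtls, key=lambda q: (q.chrom, q.start, q.end, q.qtl_id))
    regions: list[tuple[str, int, int]] = []
    sources: list[list[str]] = []
    for q in ordered:
        if regions and regions[-1][0] == q.chrom and q.start <= regions[-1][2]:
            chrom, start, end = regions[-1]
            regions[-1] = (chrom, start, max(end, q.end))
            sources[-1].append(q.qtl_id)
        else:
            regions.append((q.chrom, q.start, q.end))
            sources.append([q.qtl_id])
    return MergedTraitRegions(
        trait=qtls[0].trait,
        category=qtls[0].category,
        regions=regions,
        source_qtl_ids=sources,
    )


def drop_geneless_regions(merged: MergedTraitRegions, genome: Genome) -> MergedTraitRegions:
    """Remove regions overlapping zero genes; recount unique genes.

    A QTL region containing no annotated gene cannot carry a gene-count
    signal and is excluded from the statistic. ``n_genes`` on the result is
    the number of *unique* gene IDs overlapping any surviving region (a gene
    spanning two regions counts once). A trait left with zero regions is
    flagged ``skip`` so the enrichment screen passes it over.
    """
    from .interval_overlap import intersect  # local import: circular at module load

    assignment = intersect(genome.genes, [merged])
    genes_per_region: dict[int, set[str]] = {}
    for gene_id, _trait, region_idx in assignment.pairs:
        genes_per_region.setdefault(region_idx, set()).add(gene_id)

    keep = [i for i in range(len(merged.regions)) if genes_per_region.get(i)]
    unique_genes: set[str] = set()
    for i in keep:
        unique_genes |= genes_per_region[i]
    return MergedTraitRegions(
        trait=merged.trait,
        category=merged.category,
        regions=[merged.regions[i] for i in keep],
        source_qtl_ids=[merged.source_qtl_ids[i] for i in keep],
        n_genes=len(unique_genes),
        skip=not keep,
    )


def write_regions_bed(merged_list: Sequence[MergedTraitRegions], path) -> None:
    """Dump merged region sets as BED with trait and source-QTL columns."""
    with open(path, "w") as fh:
        for merged in merged_list:
            for (chrom, start, end), ids in zip(merged.regions, merged.source_qtl_ids):
                fh.write(
                    f"{chrom}\t{start}\t{end}\t{merged.trait}\t{merged.category}\t"
                    f"{','.join(ids)}\n"
                )
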