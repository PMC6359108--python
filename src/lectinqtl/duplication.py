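"""Tandem duplication blocks and segmental duplication summaries.

Two genes of the same family form a tandem link when they sit on the same
chromosome with at most ``max_intervening`` (default 10) other annotated
genes strictly between them in chromosomal rank order; a tandem block is a
maximal chain of such links (connected component). "Intervening" counts all
annotated genes, whatever their family — the definition is positional, not
family-relative.

Segmental duplications are consumed from a precomputed pair table (PGDD
style) carrying Ks, the synonymous substitution rate: pairs with Ks above
the cutoff (default 1.0; the boundary value itself survives) are discarded
as too ancient, and the remainder are restricted to pairs touching at least
one family gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome_model import DuplicatePair, Genome

__all__ = [
    "DuplicationBlock",
    "FamilyExpansionSummary",
    "find_tandem_blocks",
    "find_all_tandem_blocks",
    "filter_segmental_pairs",
    "summarize_family_expansion",
    "write_blocks_tsv",
]


@dataclass(frozen=True)
class DuplicationBlock:
    """A maximal tandem array (or a segmental pair) of same-family genes."""

    block_id: str
    family: str
    chrom: str
    member_gene_ids: tuple[str, ...]
    kind: str = "tandem"

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError(f"block {self.block_id!r}: needs >=2 members")
        if self.kind not in ("tandem", "segmental"):
            raise ValueError(f"block {self.block_id!r}: bad kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.member_gene_ids)


@dataclass(frozen=True)
class FamilyExpansionSummary:
    """How much of a family's size is explained by duplication events."""

    family: str
    n_genes: int
    n_tandem_blocks: int
    n_genes_in_tandem: int
    pct_tandem: float
    n_genes_in_segmental: int
    pct_segmental: float


def find_tandem_blocks(
    genome: Genome, family: str, max_intervening: int = 10
) -> list[DuplicationBlock]:
    """Tandem blocks of one family.

    Genes are ranked per chromosome by the genome's sort order; two family
    genes are linked iff the number of other genes strictly between their
    ranks is <= ``max_intervening``. Because rank gaps only grow along the
    chromosome, the connected components are exactly the maximal chains of
    consecutive family genes with small gaps. Singleton family genes form
    no block.
    """
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")
    genome.family_members(family)  # raises KeyError on unknown family
    blocks: list[DuplicationBlock] = []
    counter = 0
    for chrom, chrom_genes in genome.genes_by_chrom().items():
        member_ranks = [i for i, g in enumerate(chrom_genes) if g.family == family]
        chain: list[int] = []
        for rank in member_ranks + [None]:  # sentinel flushes the last chain
            if chain and (rank is None or rank - chain[-1] - 1 > max_intervening):
                if len(chain) >= 2:
                    counter += 1
                    blocks.append(
                        DuplicationBlock(
                            block_id=f"{family}_tandem_{counter:03d}",
                            family=family,
                            chrom=chrom,
                            member_gene_ids=tuple(chrom_genes[i].gene_id for i in chain),
                        )
                    )
                chain = []
            if rank is not None:
                chain.append(rank)
    return blocks


def find_all_tandem_blocks(genome: Genome, max_intervening: int = 10) -> list[DuplicationBlock]:
    """Tandem blocks across every family present in the genome."""
    blocks = []
    for family in genome.families:
        blocks.extend(find_tandem_blocks(genome, family, max_intervening))
    return blocks


def filter_segmental_pairs(
    pairs: Sequence[DuplicatePair],
    genome: Genome | None = None,
    ks_max: float = 1.0,
) -> list[DuplicatePair]:
    """Ks-filter a duplicate-pair table and restrict it to family genes.

    Pairs with ``ks > ks_max`` are discarded (Ks equal to the cutoff is
    kept: only strictly higher values are "too old"). When a genome is
    given, the survivors are further restricted to pairs in which at least
    one member carries a family label.
    """
    for p in pairs:
        if p.ks < 0:
            raise ValueError(f"pair ({p.gene_a}, {p.gene_b}): negative Ks {p.ks}")
    kept = [p for p in pairs if p.ks <= ks_max]
    if genome is not None:
        family_genes = {g.gene_id for g in genome.genes if g.family is not None}
        kept = [p for p in kept if p.gene_a in family_genes or p.gene_b in family_genes]
    return kept


def summarize_family_expansion(
    genome: Genome,
    tandem_blocks: Sequence[DuplicationBlock],
    segmental_pairs: Sequence[DuplicatePair],
    family: str,
) -> FamilyExpansionSummary:
    """Fraction of a family's genes involved in tandem / segmental events."""
    members = {g.gene_id for g in genome.family_members(family)}
    fam_blocks = [b for b in tandem_blocks if b.family == family]
    in_tandem = {gid for b in fam_blocks for gid in b.member_gene_ids}
    stray = in_tandem - members
    if stray:
        raise ValueError(f"tandem members outside family {family!r}: {sorted(stray)[:3]}")
    in_segmental = set()
    for p in segmental_pairs:
        in_segmental.update(gid for gid in (p.gene_a, p.gene_b) if gid in members)
    n = len(members)
    return FamilyExpansionSummary(
        family=family,
        n_genes=n,
        n_tandem_blocks=len(fam_blocks),
        n_genes_in_tandem=len(in_tandem),
        pct_tandem=100.0 * len(in_tandem) / n,
        n_genes_in_segmental=len(in_segmental),
        pct_segmental=100.0 * len(in_segmental) / n,
    )


def write_blocks_tsv(blocks: Sequence[DuplicationBlock], path) -> None:
    """Write blocks to a path or an open text stream."""
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        fh.write("block_id\tkind\tfamily\tchrom\tn_members\tmember_gene_ids\n")
        for b in blocks:
            fh.write(
                f"{b.block_id}\t{b.kind}\t{b.family}\t{b.chrom}\t{len(b)}\t"
                f"{','.join(b.member_gene_ids)}\n"
            )
    finally:
        if fh is not path:
            fh.close()
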