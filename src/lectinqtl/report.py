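"""Descriptive report tables: chromosome density, QTL coverage, co-occurrence.

Two denominators coexist deliberately. The enrichment screen works on
*merged* trait regions (redundant QTLs would otherwise inflate counts), but
the coverage tables here count *original database QTLs* — "4 of 5 QTLs for
this trait contain a lectin" is a statement about database entries, which
merging would destroy. ``trait_coverage`` therefore intersects each raw QTL
interval independently; a ``use_merged`` switch is available for the other
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .genome_model import Genome, QTLRecord
from .interval_overlap import OverlapAssignment, sweep_overlaps
from .qtl_processing import merge_trait_qtls

__all__ = [
    "ChromosomeDensityRow",
    "TraitCoverageRow",
    "chromosome_density",
    "density_table",
    "trait_coverage",
    "coverage_table",
    "cooccurrence_matrix",
    "plot_ideogram",
]


@dataclass(frozen=True)
class ChromosomeDensityRow:
    """One chromosome's share of family genes vs its share of genome length."""

    chrom: str
    n_lectins: int
    pct_lectins: float  # share of all family genes, percent
    chrom_len: int
    pct_genome: float  # share of summed chromosome lengths, percent


@dataclass(frozen=True)
class TraitCoverageRow:
    """Per trait: how many of its database QTLs contain >=1 family gene."""

    trait: str
    category: str
    n_qtls_total: int
    n_qtls_with_lectin: int
    pct_with_lectin: float


def chromosome_density(genome: Genome) -> list[ChromosomeDensityRow]:
    """Family-gene density per chromosome, full precision.

    Raises on a genome without any family-labelled gene (shares would be
    undefined). Percentages are exact here; rounding (1 decimal for gene
    shares, 2 for genome shares) is applied only in :func:`density_table`.
    """
    lectins = genome.family_members(None)
    if not lectins:
        raise ValueError("no family-labelled genes in genome: density undefined")
    total_len = sum(length for _, length in genome.chromosomes)
    per_chrom = {name: 0 for name, _ in genome.chromosomes}
    for g in lectins:
        per_chrom[g.chrom] += 1
    return [
        ChromosomeDensityRow(
            chrom=name,
            n_lectins=per_chrom[name],
            pct_lectins=100.0 * per_chrom[name] / len(lectins),
            chrom_len=length,
            pct_genome=100.0 * length / total_len,
        )
        for name, length in genome.chromosomes
    ]


def density_table(genome: Genome) -> pd.DataFrame:
    """Density rows as a DataFrame with report-layer rounding applied."""
    rows = chromosome_density(genome)
    df = pd.DataFrame([vars(r) for r in rows])
    df["pct_lectins"] = df["pct_lectins"].round(1)
    df["pct_genome"] = df["pct_genome"].round(2)
    return df


def trait_coverage(
    qtls: Sequence[QTLRecord], genome: Genome, use_merged: bool = False
) -> list[TraitCoverageRow]:
    """Per-trait fraction of QTLs containing at least one family gene.

    By default each *original* QTL interval is tested independently (a QTL
    "contains" the family iff >=1 family gene overlaps it by >=1 bp); with
    ``use_merged`` the denominators are post-merge regions instead. Rows
    come back sorted by (category, trait).
    """
    fam_genes = [g for g in genome.genes if g.family is not None]
    by_trait: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_trait.setdefault(q.trait, []).append(q)
    rows = []
    for trait, trait_qtls in by_trait.items():
        if use_merged:
            merged = merge_trait_qtls(trait_qtls)
            intervals = sorted(merged.regions)
        else:
            intervals = sorted((q.chrom, q.start, q.end) for q in trait_qtls)
        hit_intervals = {ii for _, ii in sweep_overlaps(fam_genes, intervals)}
        total = len(intervals)
        with_lectin = len(hit_intervals)
        rows.append(
            TraitCoverageRow(
                trait=trait,
                category=trait_qtls[0].category,
                n_qtls_total=total,
                n_qtls_with_lectin=with_lectin,
                pct_with_lectin=100.0 * with_lectin / total,
            )
        )
    return sorted(rows, key=lambda r: (r.category, r.trait))


def coverage_table(
    qtls: Sequence[QTLRecord], genome: Genome, use_merged: bool = False
) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in trait_coverage(qtls, genome, use_merged)])


def cooccurrence_matrix(
    assignment: OverlapAssignment, genome: Genome, traits: Sequence[str] | None = None
) -> pd.DataFrame:
    """Symmetric trait x trait matrix of shared family genes.

    Diagonal entries are each trait's family-gene count; off-diagonal
    entries count unique family genes simultaneously assigned to both
    traits' regions.
    """
    if traits is None:
        traits = assignment.traits()
    for t in traits:
        if t not in assignment.by_trait:
            raise KeyError(f"trait {t!r} absent from assignment")
    fam_genes = {g.gene_id for g in genome.genes if g.family is not None}
    sets = {t: assignment.by_trait[t] & fam_genes for t in traits}
    data = [[len(sets[a] & sets[b]) for b in traits] for a in traits]
    return pd.DataFrame(data, index=list(traits), columns=list(traits))


def combined_share(
    rows: Sequence[ChromosomeDensityRow], chroms: Sequence[str]
) -> tuple[int, float]:
    """Summed shares for a chromosome subset, at the report's printed
    precision: per-chromosome family-gene shares (1 decimal) are summed and
    rounded to an integer percentage; genome-size shares (2 decimals) are
    summed and kept at 2 decimals. This is the "k chromosomes hold X% of
    the family while representing Y% of the genome" headline."""
    sel = [r for r in rows if r.chrom in set(chroms)]
    if len(sel) != len(set(chroms)):
        missing = set(chroms) - {r.chrom for r in sel}
        raise KeyError(f"chromosomes absent from density rows: {sorted(missing)}")
    pct_fam = round(sum(round(r.pct_lectins, 1) for r in sel))
    pct_genome = round(sum(round(r.pct_genome, 2) for r in sel), 2)
    return pct_fam, pct_genome


def plot_ideogram(genome: Genome, qtls: Sequence[QTLRecord] | None = None, ax=None):
    """Plain per-chromosome ideogram: family genes as ticks, QTLs as bars.

    A tabular-era replacement for drawn chromosome figures; returns the
    matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 0.5 * len(genome.chromosomes) + 1))
    ypos = {name: i for i, (name, _) in enumerate(genome.chromosomes)}
    for name, length in genome.chromosomes:
        y = ypos[name]
        ax.hlines(y, 0, length, color="lightgray", linewidth=6, zorder=1)
    for g in genome.family_members(None):
        ax.vlines(g.start, ypos[g.chrom] - 0.2, ypos[g.chrom] + 0.2, color="crimson",
                  linewidth=0.8, zorder=3)
    if qtls:
        for q in qtls:
            ax.hlines(ypos[q.chrom] + 0.3, q.start, q.end, color="steelblue",
                      linewidth=2, alpha=0.5, zorder=2)
    ax.set_yticks(list(ypos.values()), list(ypos.keys()))
    ax.set_xlabel("position (bp)")
    ax.invert_yaxis()
    return ax
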