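"""Domain types and I/O for gene annotations, QTL tables and auxiliary tables.

This module is the single source of coordinate-convention truth for the
package: every interval held in memory is **0-based, half-open** ``[start,
end)``, the BED convention. Conversion from 1-based inclusive formats (GFF3,
QTL tables) happens only at the I/O boundary, on the way in and on the way
out.

Supported dialects
------------------
* GFF3 — genes as ``type=gene`` features carrying an ``ID`` attribute;
  1-based inclusive coordinates.
* BED4 — ``chrom  start  end  gene_id``; already 0-based half-open.
* gene TSV — headered columns ``gene_id, chrom, start, end, strand, family``;
  0-based half-open (the BED convention, since this is our own dialect).
* QTL TSV — headered columns ``qtl_id, category, trait, chrom, start, end``;
  1-based inclusive (database convention), converted on read.
* duplicate-pair TSV — ``gene_a, gene_b, ks``.
* ID-map TSV — two headered columns, source ID then target ID.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "GeneRecord",
    "QTLRecord",
    "Genome",
    "DuplicatePair",
    "IdMapReport",
    "normalize_category",
    "read_genes",
    "write_genes",
    "read_family_table",
    "assign_families",
    "read_qtls",
    "write_qtls",
    "read_duplicate_pairs",
    "read_id_map",
    "apply_id_map",
]

#: The four trait categories used by the Q-TARO database.
CATEGORIES = ("morphological", "physiological", "resistance_tolerance", "other")

_STRANDS = ("+", "-", "unknown")


class FormatError(ValueError):
    """A malformed input line; the message names the offending line."""


class IntegrityError(ValueError):
    """A structural violation (duplicate IDs, conflicting mappings, ...)."""


@dataclass(frozen=True, order=True)
class GeneRecord:
    """One annotated gene: location plus an optional family label.

    ``start``/``end`` are 0-based half-open base-pair coordinates. ``family``
    is the lectin-family label (e.g. ``"GNA"``) or ``None`` for genes outside
    the annotated families; a gene carries at most one family label.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"
    family: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class QTLRecord:
    """One published QTL interval with its Q-TARO trait category and name."""

    qtl_id: str
    category: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"QTL {self.qtl_id!r}: category {self.category!r} not in {CATEGORIES}"
            )
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"QTL {self.qtl_id!r}: require 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class DuplicatePair:
    """A candidate duplicated gene pair with its synonymous substitution rate."""

    gene_a: str
    gene_b: str
    ks: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if self.ks < 0:
            raise ValueError(f"pair ({self.gene_a}, {self.gene_b}): Ks {self.ks} < 0")


def _natural_key(name: str) -> tuple:
    """Sort key treating digit runs numerically, so chr2 < chr10."""
    return tuple(int(t) if t.isdigit() else t for t in re.split(r"(\d+)", name))


@dataclass
class Genome:
    """An ordered chromosome set with its sorted gene annotation.

    Genes are kept sorted by (chromosome order, start, end, gene_id);
    chromosome order follows ``chromosomes``. Two genes may share coordinates,
    in which case gene_id breaks the tie — this keeps intervening-gene counts
    downstream deterministic.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[GeneRecord]
    provenance: str = ""
    _chrom_rank: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._chrom_rank = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        if len(self._chrom_rank) != len(self.chromosomes):
            raise IntegrityError("duplicate chromosome name")
        lengths = dict(self.chromosomes)
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise IntegrityError(f"duplicate gene_id {g.gene_id!r}")
            seen.add(g.gene_id)
            if g.chrom not in lengths:
                raise IntegrityError(f"gene {g.gene_id!r}: unknown chromosome {g.chrom!r}")
            if g.end > lengths[g.chrom]:
                raise IntegrityError(
                    f"gene {g.gene_id!r} ends at {g.end} beyond "
                    f"{g.chrom} length {lengths[g.chrom]}"
                )
        self.genes = sorted(self.genes, key=self._gene_key)

    def _gene_key(self, g: GeneRecord) -> tuple:
        return (self._chrom_rank[g.chrom], g.start, g.end, g.gene_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def families(self) -> list[str]:
        """Family vocabulary present in the annotation, sorted."""
        return sorted({g.family for g in self.genes if g.family is not None})

    def family_members(self, family: str | None = None) -> list[GeneRecord]:
        """Genes of one family, or all family-labelled genes when None."""
        if family is None:
            return [g for g in self.genes if g.family is not None]
        members = [g for g in self.genes if g.family == family]
        if not members:
            raise KeyError(f"family {family!r} absent from genome")
        return members

    def genes_by_chrom(self) -> dict[str, list[GeneRecord]]:
        out: dict[str, list[GeneRecord]] = {name: [] for name, _ in self.chromosomes}
        for g in self.genes:
            out[g.chrom].append(g)
        return out

    def with_genes(self, genes: Iterable[GeneRecord], provenance: str | None = None) -> "Genome":
        return Genome(
            chromosomes=list(self.chromosomes),
            genes=list(genes),
            provenance=self.provenance if provenance is None else provenance,
        )


# ---------------------------------------------------------------------------
# gene annotation I/O


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".gff", ".gff3"}:
        return "gff3"
    if suffix == ".bed":
        return "bed"
    if suffix in {".tsv", ".txt"}:
        return "tsv"
    raise ValueError(f"cannot sniff annotation format from {path.name!r}")


def _genome_from_records(
    records: list[GeneRecord],
    seq_lengths: Mapping[str, int],
    provenance: str,
) -> Genome:
    lengths = dict(seq_lengths)
    for g in records:
        if g.chrom not in lengths or g.end > lengths[g.chrom]:
            lengths[g.chrom] = max(lengths.get(g.chrom, 0), g.end)
    chromosomes = sorted(lengths.items(), key=lambda kv: _natural_key(kv[0]))
    return Genome(chromosomes=chromosomes, genes=records, provenance=provenance)


def _read_gff3(path: Path) -> Genome:
    import gffutils

    seq_lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            m = re.match(r"##sequence-region\s+(\S+)\s+(\d+)\s+(\d+)", line)
            if m:
                seq_lengths[m.group(1)] = int(m.group(3))
            elif not line.startswith("#"):
                break
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    records = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise FormatError(f"{path.name}: gene feature at {feat.seqid}:{feat.start} lacks ID")
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        # GFF3 is 1-based inclusive: [start, end] -> [start-1, end)
        records.append(
            GeneRecord(ids[0], feat.seqid, feat.start - 1, feat.end, strand=strand)
        )
    return _genome_from_records(records, seq_lengths, provenance=f"gff3:{path.name}")


def _read_bed(path: Path) -> Genome:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path.name}:{lineno}: expected >=4 BED columns")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            except ValueError as exc:
                raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "unknown"
            records.append(GeneRecord(name, chrom, start, end, strand=strand))
    return _genome_from_records(records, {}, provenance=f"bed:{path.name}")


_GENE_TSV_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "family"]


def _read_gene_tsv(path: Path) -> Genome:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _GENE_TSV_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing columns {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        try:
            records.append(
                GeneRecord(
                    gene_id=row.gene_id,
                    chrom=row.chrom,
                    start=int(row.start),
                    end=int(row.end),
                    strand=getattr(row, "strand", "unknown") or "unknown",
                    family=getattr(row, "family", "") or None,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path.name}:{lineno}: {exc}") from exc
    return _genome_from_records(records, {}, provenance=f"tsv:{path.name}")


def read_genes(path: str | Path, format: str | None = None) -> Genome:
    """Read a gene annotation into a :class:`Genome`.

    GFF3 coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED and the package's gene TSV pass
    through. Records come back sorted by (chromosome, start, end, gene_id).
    Chromosome lengths come from ``##sequence-region`` pragmas where present,
    otherwise from the rightmost gene end per chromosome.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _sniff_format(path)
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed":
        return _read_bed(path)
    if fmt == "tsv":
        return _read_gene_tsv(path)
    raise ValueError(f"unknown annotation format {fmt!r}")


def write_genes(genome: Genome, path: str | Path, format: str | None = None) -> None:
    """Serialize a genome; the inverse of :func:`read_genes` per format.

    GFF3 output restores 1-based inclusive coordinates and writes
    ``##sequence-region`` pragmas so chromosome lengths round-trip.
    """
    path = Path(path)
    fmt = format or _sniff_format(path)
    buf = io.StringIO()
    if fmt == "gff3":
        buf.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            buf.write(f"##sequence-region {name} 1 {length}\n")
        for g in genome.genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            buf.write(
                f"{g.chrom}\tlectinqtl\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
    elif fmt == "bed":
        for g in genome.genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            buf.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{strand}\n")
    elif fmt == "tsv":
        buf.write("\t".join(_GENE_TSV_COLUMNS) + "\n")
        for g in genome.genes:
            buf.write(
                f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                f"{g.family or ''}\n"
            )
    else:
        raise ValueError(f"unknown annotation format {fmt!r}")
    path.write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# family membership


def read_family_table(path: str | Path) -> dict[str, str]:
    """Read a two-column headered TSV mapping gene_id -> family label.

    A gene may appear at most once: the families are treated as disjoint, so
    a gene listed under two families is an input error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: need two columns (gene_id, family)")
    gene_col, fam_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for gene_id, fam in zip(df[gene_col], df[fam_col]):
        if gene_id in mapping and mapping[gene_id] != fam:
            raise IntegrityError(
                f"gene {gene_id!r} assigned to two families "
                f"({mapping[gene_id]!r}, {fam!r}); families are disjoint"
            )
        mapping[gene_id] = fam
    return mapping


def assign_families(genome: Genome, families: Mapping[str, str]) -> Genome:
    """Return a genome whose genes carry the given family labels.

    Labels for gene IDs absent from the genome are ignored; existing labels
    on the genome are replaced wholesale.
    """
    genes = [
        replace(g, family=families.get(g.gene_id)) for g in genome.genes
    ]
    return genome.with_genes(genes)


# ---------------------------------------------------------------------------
# QTL table I/O

_CATEGORY_ALIASES = {
    "morphological": "morphological",
    "morphologicaltrait": "morphological",
    "morphologicaltraits": "morphological",
    "physiological": "physiological",
    "physiologicaltrait": "physiological",
    "physiologicaltraits": "physiological",
    "resistancetolerance": "resistance_tolerance",
    "resistanceortolerance": "resistance_tolerance",
    "resistance": "resistance_tolerance",
    "tolerance": "resistance_tolerance",
    "other": "other",
    "others": "other",
}


def normalize_category(token: str) -> str:
    """Map a Q-TARO-style category token onto the four canonical groups."""
    key = re.sub(r"[^a-z]", "", token.lower())
    try:
        return _CATEGORY_ALIASES[key]
    except KeyError:
        raise ValueError(
            f"unknown QTL category {token!r}; expected one of {CATEGORIES}"
        ) from None


_QTL_COLUMNS = ["qtl_id", "category", "trait", "chrom", "start", "end"]


def read_qtls(
    path: str | Path, trait_vocabulary: Mapping[str, str] | None = None
) -> list[QTLRecord]:
    """Read a Q-TARO-like QTL TSV (1-based inclusive coordinates).

    ``trait_vocabulary``, when given, renames trait labels (e.g. to collapse
    synonyms); unknown category tokens raise naming the offending value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _QTL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {missing}")
    records = []
    for lineno, row in enumerate(df.itertuples(index=False), 2):
        trait = row.trait
        if trait_vocabulary is not None:
            trait = trait_vocabulary.get(trait, trait)
        try:
            records.append(
                QTLRecord(
                    qtl_id=row.qtl_id,
                    category=normalize_category(row.category),
                    trait=trait,
                    chrom=row.chrom,
                    start=int(row.start) - 1,  # 1-based inclusive -> half-open
                    end=int(row.end),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{Path(path).name}:{lineno}: {exc}") from exc
    return records


def write_qtls(qtls: Sequence[QTLRecord], path: str | Path) -> None:
    """Write QTLs back to the 1-based inclusive TSV dialect."""
    with open(path, "w") as fh:
        fh.write("\t".join(_QTL_COLUMNS) + "\n")
        for q in qtls:
            fh.write(
                f"{q.qtl_id}\t{q.category}\t{q.trait}\t{q.chrom}\t{q.start + 1}\t{q.end}\n"
            )


# ---------------------------------------------------------------------------
# duplicate pairs and ID maps


def read_duplicate_pairs(path: str | Path) -> list[DuplicatePair]:
    """Read a PGDD-like pair table: headered TSV (gene_a, gene_b, ks)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "ks": float})
    missing = [c for c in ("gene_a", "gene_b", "ks") if c not in df.columns]
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {missing}")
    return [
        DuplicatePair(row.gene_a, row.gene_b, float(row.ks))
        for row in df.itertuples(index=False)
    ]


def read_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column headered TSV mapping source gene IDs to target IDs."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: need two columns (source, target)")
    src_col, dst_col = df.columns[:2]
    mapping: dict[str, str] = {}
    for src, dst in zip(df[src_col], df[dst_col]):
        if src in mapping and mapping[src] != dst:
            raise IntegrityError(f"source ID {src!r} mapped to two targets")
        mapping[src] = dst
    return mapping


@dataclass(frozen=True)
class IdMapReport:
    """Bookkeeping from :func:`apply_id_map`."""

    mapped: int
    unmapped: int
    dropped: int = 0


def apply_id_map(genome: Genome, mapping: Mapping[str, str]) -> tuple[Genome, IdMapReport]:
    """Rename gene IDs through a MSU<->RAP-DB-style two-column mapping.

    Unmapped genes keep their original IDs and are counted in the report.
    Two source IDs mapping onto one target would silently merge distinct
    genes, so that is rejected up front.
    """
    targets_used: dict[str, str] = {}
    for src, dst in mapping.items():
        if dst in targets_used and targets_used[dst] != src:
            raise IntegrityError(
                f"target ID {dst!r} receives both {targets_used[dst]!r} and {src!r}"
            )
        targets_used[dst] = src
    mapped = unmapped = 0
    genes = []
    for g in genome.genes:
        if g.gene_id in mapping:
            genes.append(replace(g, gene_id=mapping[g.gene_id]))
            mapped += 1
        else:
            genes.append(g)
            unmapped += 1
    return genome.with_genes(genes), IdMapReport(mapped=mapped, unmapped=unmapped)
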