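"""Seeded synthetic genomes, QTL tables and duplicate-pair tables.

The generator emulates the statistical structure the enrichment analysis
assumes, with full ground truth:

* genes are non-overlapping intervals per chromosome (log-normal lengths,
  exponential inter-gene gaps), so gene *rank order* — what tandem
  detection consumes — is well defined;
* family (lectin) labels are assigned to genes by weighted sampling without
  replacement: genes never move, only labels do, so the gene content n of
  any region is fixed and the family count x is the only random quantity.
  With all placement weights at 1 the labels are a uniform random subset
  and x in any fixed region is exactly hypergeometric — the null of the
  Wald test. A weight lambda > 1 on a trait makes its regions attract
  labels (planted enrichment);
* tandem arrays are planted as runs of same-family genes with intra-array
  rank gaps <= a threshold and guard zones keeping other labels of that
  family away, so the planted partition is recoverable exactly;
* duplicate pairs carry Ks values spanning the retention cutoff.

One integer seed drives everything through ``numpy.random.SeedSequence``
spawning (one child stream per concern, in a fixed order), so emitted files
are byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_model import (
    DuplicatePair,
    GeneRecord,
    Genome,
    QTLRecord,
    write_genes,
    write_qtls,
)
from .qtl_processing import drop_geneless_regions, merge_trait_qtls

__all__ = [
    "TraitSpec",
    "TandemArraySpec",
    "SimConfig",
    "GroundTruth",
    "SimResult",
    "generate",
    "paper_replica_config",
    "RICE_CHROM_LENGTHS_BP",
]

#: Assembled chromosome lengths of the O. sativa japonica reference
#: (IRGSP-1.0), in bp; sum ~ 373.2 Mb.
RICE_CHROM_LENGTHS_BP = [
    43_270_923, 35_937_250, 36_413_819, 35_502_694, 29_958_434, 31_248_787,
    29_697_621, 28_443_022, 23_012_720, 23_207_287, 29_021_106, 27_531_856,
]


@dataclass(frozen=True)
class TraitSpec:
    """One simulated trait: how many QTLs it gets and how long they are."""

    name: str
    category: str
    n_qtls: int
    qtl_length_mean: float = 2_000_000.0  # bp; log-normal mean
    qtl_length_sigma: float = 0.5  # sigma of log length


@dataclass(frozen=True)
class TandemArraySpec:
    """Planted tandem arrays for one family.

    ``intra_gap_max`` bounds the number of unlabeled genes between
    consecutive array members; ``inter_gap_min`` is the guard distance (in
    gene ranks) separating arrays from each other and from any other label
    of the same family, and must exceed ``intra_gap_max`` for planted
    arrays to be recoverable as distinct blocks.
    """

    family: str
    n_arrays: int
    size_min: int = 2
    size_max: int = 5
    intra_gap_max: int = 10
    inter_gap_min: int = 30

    def __post_init__(self) -> None:
        if self.size_min < 2 or self.size_max < self.size_min:
            raise ValueError("array sizes must satisfy 2 <= size_min <= size_max")
        if self.inter_gap_min <= self.intra_gap_max:
            raise ValueError("inter_gap_min must exceed intra_gap_max")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one synthetic dataset."""

    seed: int
    chrom_lengths: Sequence[int]
    n_genes: int
    family_spec: Mapping[str, int]
    traits: Sequence[TraitSpec] = ()
    enrichment: Mapping[str, float] = field(default_factory=dict)
    tandem_specs: Sequence[TandemArraySpec] = ()
    n_pairs: int = 0
    ks_low: float = 0.0
    ks_high: float = 2.0
    gene_length_mean: float = 2_500.0
    gene_length_sigma: float = 0.7

    def __post_init__(self) -> None:
        if sum(self.family_spec.values()) > self.n_genes:
            raise ValueError("family counts exceed gene count")
        for trait, lam in self.enrichment.items():
            if lam < 0:
                raise ValueError(f"enrichment weight for {trait!r} must be >= 0")
        known = {t.name for t in self.traits}
        unknown = set(self.enrichment) - known
        if unknown:
            raise ValueError(f"enrichment for unspecified traits: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """What the generator knows it planted, recomputed into pipeline terms.

    ``trait_n_genes``/``trait_lectin_counts`` are the n and x of the
    enrichment statistic per trait (unique genes / family genes in the
    trait's merged, gene-bearing regions); ``qtl_contains_lectin`` flags
    each original QTL; ``planted_blocks`` maps family -> planted member-ID
    tuples; ``retained_pair_indices`` indexes pairs surviving the Ks filter
    while touching a family gene.
    """

    trait_n_genes: dict[str, int]
    trait_lectin_counts: dict[str, int]
    qtl_contains_lectin: dict[str, bool]
    planted_blocks: dict[str, list[list[str]]]
    retained_pair_indices: list[int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "trait_n_genes": self.trait_n_genes,
                "trait_lectin_counts": self.trait_lectin_counts,
                "qtl_contains_lectin": self.qtl_contains_lectin,
                "planted_blocks": self.planted_blocks,
                "retained_pair_indices": self.retained_pair_indices,
            },
            indent=1,
            sort_keys=True,
        )


# ---------------------------------------------------------------------------
# placement helpers


def _split_counts(total: int, weights: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of ``total`` across weights."""
    ideal = total * weights / weights.sum()
    counts = np.floor(ideal).astype(int)
    rem = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _place_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneRecord]:
    lengths = np.asarray(config.chrom_lengths, dtype=float)
    per_chrom = _split_counts(config.n_genes, lengths)
    genes: list[GeneRecord] = []
    for ci, (chrom_len, m) in enumerate(zip(config.chrom_lengths, per_chrom)):
        chrom = f"chr{ci + 1:02d}"
        if m == 0:
            continue
        glen = np.maximum(
            50,
            rng.lognormal(np.log(config.gene_length_mean), config.gene_length_sigma, m),
        ).astype(int)
        available = chrom_len - int(glen.sum())
        if available < m + 1:
            raise ValueError(
                f"{chrom}: cannot fit {m} genes of total length {glen.sum()} "
                f"into {chrom_len} bp"
            )
        raw_gaps = rng.exponential(1.0, m + 1)
        gaps = np.floor(raw_gaps / raw_gaps.sum() * available).astype(int)
        starts = np.cumsum(gaps[:-1] + np.concatenate([[0], glen[:-1]]))
        strands = rng.choice(["+", "-"], size=m)
        for i in range(m):
            genes.append(
                GeneRecord(
                    gene_id=f"g{chrom}_{i + 1:05d}",
                    chrom=chrom,
                    start=int(starts[i]),
                    end=int(starts[i] + glen[i]),
                    strand=str(strands[i]),
                )
            )
    return genes


def _place_qtls(
    config: SimConfig, chroms: list[tuple[str, int]], rng: np.random.Generator
) -> list[QTLRecord]:
    qtls: list[QTLRecord] = []
    names = [c for c, _ in chroms]
    lens = np.asarray([l for _, l in chroms], dtype=float)
    probs = lens / lens.sum()
    for spec in config.traits:
        slug = "".join(ch if ch.isalnum() else "_" for ch in spec.name)
        for k in range(spec.n_qtls):
            ci = int(rng.choice(len(names), p=probs))
            chrom_len = int(lens[ci])
            length = int(
                np.clip(
                    rng.lognormal(np.log(spec.qtl_length_mean), spec.qtl_length_sigma),
                    50_000,
                    chrom_len // 2,
                )
            )
            start = int(rng.integers(0, chrom_len - length))
            qtls.append(
                QTLRecord(
                    qtl_id=f"q_{slug}_{k + 1:03d}",
                    category=spec.category,
                    trait=spec.name,
                    chrom=names[ci],
                    start=start,
                    end=start + length,
                )
            )
    return qtls


def _region_gene_indices(
    genes: Sequence[GeneRecord], regions: Sequence[tuple[str, int, int]]
) -> np.ndarray:
    """Indices of genes overlapping any region (vectorized brute force).

    Deliberately independent of the sweep engine: the generator's
    bookkeeping must not inherit that engine's bugs.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    starts = np.asarray([g.start for g in genes])
    ends = np.asarray([g.end for g in genes])
    hit = np.zeros(len(genes), dtype=bool)
    for chrom, rstart, rend in regions:
        idx = np.asarray(by_chrom.get(chrom, []), dtype=int)
        if idx.size:
            sub = (np.maximum(starts[idx], rstart) < np.minimum(ends[idx], rend))
            hit[idx[sub]] = True
    return np.flatnonzero(hit)


def _plant_tandem_arrays(
    config: SimConfig,
    genes: list[GeneRecord],
    rng: np.random.Generator,
) -> tuple[dict[int, str], dict[str, list[list[str]]], dict[str, set[int]]]:
    """Choose array member genes; return (gene index -> family) assignments,
    planted block membership per family, and per-family guard-zone indices
    where random labels of that family must not land."""
    by_chrom: dict[str, list[int]] = {}
    for i, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(i)
    chrom_names = sorted(by_chrom)

    planted: dict[int, str] = {}
    blocks: dict[str, list[list[str]]] = {}
    guards: dict[str, set[int]] = {}
    occupied_ranks: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_names}

    for spec in config.tandem_specs:
        blocks.setdefault(spec.family, [])
        guards.setdefault(spec.family, set())
        for _ in range(spec.n_arrays):
            size = int(rng.integers(spec.size_min, spec.size_max + 1))
            gaps = rng.integers(0, spec.intra_gap_max + 1, size - 1)
            span = int(size + gaps.sum())
            placed = False
            for _attempt in range(200):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                ranks_on_chrom = by_chrom[chrom]
                margin = spec.inter_gap_min + 1
                if len(ranks_on_chrom) <= span + 2 * margin:
                    continue
                r0 = int(rng.integers(margin, len(ranks_on_chrom) - span - margin))
                lo, hi = r0 - margin, r0 + span + margin
                if any(not (hi < a or lo > b) for a, b in occupied_ranks[chrom]):
                    continue
                member_ranks = [r0]
                for gap in gaps:
                    member_ranks.append(member_ranks[-1] + int(gap) + 1)
                member_idx = [ranks_on_chrom[r] for r in member_ranks]
                for gi in member_idx:
                    planted[gi] = spec.family
                blocks[spec.family].append([genes[gi].gene_id for gi in member_idx])
                guards[spec.family].update(
                    ranks_on_chrom[r] for r in range(max(0, lo), min(len(ranks_on_chrom), hi + 1))
                )
                occupied_ranks[chrom].append((lo, hi))
                placed = True
                break
            if not placed:
                raise ValueError(
                    f"cannot place a {size}-gene array for family {spec.family!r}; "
                    "chromosomes too crowded for the requested guard distances"
                )
    return planted, blocks, guards


def draw_family_labels(
    config: SimConfig,
    genes: Sequence[GeneRecord],
    weights: np.ndarray,
    rng: np.random.Generator,
    planted: Mapping[int, str] | None = None,
    guards: Mapping[str, set[int]] | None = None,
) -> dict[int, str]:
    """Assign family labels to gene indices by weighted sampling.

    Planted assignments are honored first; each family's remaining quota is
    drawn without replacement from the still-unlabeled genes, proportional
    to ``weights`` (all-ones = uniform = exchangeable labels). Guard zones
    exclude a family's random labels from the neighborhoods of its planted
    arrays.
    """
    planted = dict(planted or {})
    guards = guards or {}
    labels: dict[int, str] = dict(planted)
    taken = np.zeros(len(genes), dtype=bool)
    for gi in planted:
        taken[gi] = True
    uniform = bool(np.all(weights == weights[0]))
    for family in sorted(config.family_spec):
        quota = config.family_spec[family] - sum(
            1 for f in planted.values() if f == family
        )
        if quota < 0:
            raise ValueError(f"family {family!r}: planted arrays exceed family size")
        if quota == 0:
            continue
        mask = ~taken
        for gi in guards.get(family, ()):  # keep random labels off planted arrays
            mask[gi] = False
        pool = np.flatnonzero(mask)
        if pool.size < quota:
            raise ValueError(f"family {family!r}: not enough unlabeled genes")
        if uniform:
            chosen = rng.choice(pool, size=quota, replace=False)
        else:
            w = weights[pool].astype(float)
            chosen = rng.choice(pool, size=quota, replace=False, p=w / w.sum())
        for gi in chosen:
            labels[int(gi)] = family
            taken[gi] = True
    return labels


@dataclass
class SimResult:
    """A generated dataset plus its ground truth and emission helpers."""

    config: SimConfig
    genome: Genome
    qtls: list[QTLRecord]
    pairs: list[DuplicatePair]
    ground_truth: GroundTruth
    label_weights: np.ndarray = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit genes.gff3, families.tsv, qtls.tsv, pairs.tsv, truth.json."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.gff3",
            "families": outdir / "families.tsv",
            "qtls": outdir / "qtls.tsv",
            "pairs": outdir / "pairs.tsv",
            "truth": outdir / "truth.json",
        }
        write_genes(self.genome, paths["genes"], format="gff3")
        with open(paths["families"], "w") as fh:
            fh.write("gene_id\tfamily\n")
            for g in self.genome.genes:
                if g.family is not None:
                    fh.write(f"{g.gene_id}\t{g.family}\n")
        write_qtls(self.qtls, paths["qtls"])
        with open(paths["pairs"], "w") as fh:
            fh.write("gene_a\tgene_b\tks\n")
            for p in self.pairs:
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.ks:.6f}\n")
        paths["truth"].write_text(self.ground_truth.to_json())
        return paths

    def redraw_labels(self, rng: np.random.Generator) -> np.ndarray:
        """Draw a fresh label assignment (same weights); returns the labeled
        gene indices. Genes stay put — this is the fast path for studying
        the null/alternative distribution of per-region family counts."""
        labels = draw_family_labels(
            self.config, self.genome.genes, self.label_weights, rng
        )
        return np.asarray(sorted(labels), dtype=int)


def generate(config: SimConfig) -> SimResult:
    """Generate a dataset; fully reproducible from ``config.seed``."""
    streams = np.random.SeedSequence(config.seed).spawn(5)
    rng_genes, rng_qtls, rng_tandem, rng_labels, rng_ks = (
        np.random.default_rng(s) for s in streams
    )

    bare_genes = _place_genes(config, rng_genes)
    chroms = [
        (f"chr{i + 1:02d}", int(l)) for i, l in enumerate(config.chrom_lengths)
    ]
    qtls = _place_qtls(config, chroms, rng_qtls)

    # per-gene placement weights from trait enrichment factors
    weights = np.ones(len(bare_genes))
    by_trait: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_trait.setdefault(q.trait, []).append(q)
    for trait, lam in config.enrichment.items():
        if lam == 1.0:
            continue
        merged = merge_trait_qtls(by_trait[trait])
        idx = _region_gene_indices(bare_genes, merged.regions)
        weights[idx] = np.maximum(weights[idx], lam)

    planted, planted_blocks, guards = _plant_tandem_arrays(config, bare_genes, rng_tandem)
    labels = draw_family_labels(
        config, bare_genes, weights, rng_labels, planted=planted, guards=guards
    )
    genes = [
        replace(g, family=labels.get(i)) for i, g in enumerate(bare_genes)
    ]
    genome = Genome(
        chromosomes=chroms, genes=genes, provenance=f"lectinqtl-sim(seed={config.seed})"
    )

    # duplicate pairs: half anchored on family genes, Ks spanning the cutoff
    fam_ids = [g.gene_id for g in genome.genes if g.family is not None]
    other_ids = [g.gene_id for g in genome.genes if g.family is None]
    pairs: list[DuplicatePair] = []
    for k in range(config.n_pairs):
        ks = float(rng_ks.uniform(config.ks_low, config.ks_high))
        if k % 2 == 0 and fam_ids:
            a = fam_ids[int(rng_ks.integers(len(fam_ids)))]
        else:
            a = other_ids[int(rng_ks.integers(len(other_ids)))]
        b = a
        while b == a:
            b = other_ids[int(rng_ks.integers(len(other_ids)))]
        pairs.append(DuplicatePair(a, b, round(ks, 6)))

    truth = _ground_truth(genome, qtls, pairs, planted_blocks)
    return SimResult(
        config=config,
        genome=genome,
        qtls=qtls,
        pairs=pairs,
        ground_truth=truth,
        label_weights=weights,
    )


def _ground_truth(
    genome: Genome,
    qtls: list[QTLRecord],
    pairs: list[DuplicatePair],
    planted_blocks: dict[str, list[list[str]]],
) -> GroundTruth:
    genes = genome.genes
    fam_idx = {i for i, g in enumerate(genes) if g.family is not None}
    by_trait: dict[str, list[QTLRecord]] = {}
    for q in qtls:
        by_trait.setdefault(q.trait, []).append(q)

    trait_n: dict[str, int] = {}
    trait_x: dict[str, int] = {}
    for trait, trait_qtls in sorted(by_trait.items()):
        merged = drop_geneless_regions(merge_trait_qtls(trait_qtls), genome)
        idx = _region_gene_indices(genes, merged.regions)
        trait_n[trait] = int(idx.size)
        trait_x[trait] = int(sum(1 for i in idx if i in fam_idx))

    qtl_flags: dict[str, bool] = {}
    for q in qtls:
        idx = _region_gene_indices(genes, [(q.chrom, q.start, q.end)])
        qtl_flags[q.qtl_id] = any(i in fam_idx for i in idx)

    fam_ids = {genes[i].gene_id for i in fam_idx}
    retained = [
        k
        for k, p in enumerate(pairs)
        if p.ks <= 1.0 and (p.gene_a in fam_ids or p.gene_b in fam_ids)
    ]
    return GroundTruth(
        trait_n_genes=trait_n,
        trait_lectin_counts=trait_x,
        qtl_contains_lectin=qtl_flags,
        planted_blocks=planted_blocks,
        retained_pair_indices=retained,
    )


# ---------------------------------------------------------------------------
# the replica configuration

_REPLICA_FAMILIES = {
    "GNA": 135,
    "Legume": 44,
    "Jacalin": 30,
    "Nictaba": 25,
    "LysM": 20,
    "ClassV_chitinase": 15,
    "Hevein": 12,
    "CRA": 6,
    "EUL": 4,
}  # nine families, 291 genes total

_REPLICA_TRAITS: list[tuple[str, str, int]] = [
    # resistance / tolerance (10)
    ("drought tolerance", "resistance_tolerance", 22),
    ("salinity tolerance", "resistance_tolerance", 14),
    ("cold tolerance", "resistance_tolerance", 18),
    ("submergency tolerance", "resistance_tolerance", 6),
    ("soil stress tolerance", "resistance_tolerance", 12),
    ("lodging resistance", "resistance_tolerance", 5),
    ("blast resistance", "resistance_tolerance", 30),
    ("sheath blight resistance", "resistance_tolerance", 10),
    ("insect resistance", "resistance_tolerance", 16),
    ("bacterial blight resistance", "resistance_tolerance", 12),
    # morphological (6)
    ("culm leaf", "morphological", 24),
    ("dwarf", "morphological", 10),
    ("panicle flower", "morphological", 20),
    ("seeds", "morphological", 26),
    ("root", "morphological", 14),
    ("shoot seedling", "morphological", 12),
    # physiological (6)
    ("eating quality", "physiological", 12),
    ("sterility", "physiological", 16),
    ("lethality", "physiological", 6),
    ("germination dormancy", "physiological", 8),
    ("source activity", "physiological", 10),
    ("flowering", "physiological", 18),
    # other (3)
    ("biochemical content", "other", 8),
    ("plant pigmentation", "other", 5),
    ("other miscellaneous", "other", 4),
]


def paper_replica_config(
    seed: int = 0,
    enrichment: Mapping[str, float] | None = None,
    tandem_specs: Sequence[TandemArraySpec] = (),
    n_pairs: int = 0,
) -> SimConfig:
    """The genome-scale study configuration: 27,912 genes on 12 rice-length
    chromosomes, 291 family genes in nine families, and 25 traits across
    the four Q-TARO categories with Q-TARO-like QTL loads (~2 Mb QTLs,
    4–30 per trait). With no ``enrichment`` the labels are uniform — the
    exact null of the test."""
    return SimConfig(
        seed=seed,
        chrom_lengths=list(RICE_CHROM_LENGTHS_BP),
        n_genes=27_912,
        family_spec=dict(_REPLICA_FAMILIES),
        traits=[
            TraitSpec(name=n, category=c, n_qtls=k) for n, c, k in _REPLICA_TRAITS
        ],
        enrichment=dict(enrichment or {}),
        tandem_specs=tuple(tandem_specs),
        n_pairs=n_pairs,
    )
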