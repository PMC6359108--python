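"""Tandem block detection, Ks filtering and family expansion summaries."""

import numpy as np
import pytest

from lectinqtl import (
    DuplicatePair,
    GeneRecord,
    Genome,
    filter_segmental_pairs,
    find_all_tandem_blocks,
    find_tandem_blocks,
    summarize_family_expansion,
)


def _genome_from_families(family_by_rank, chrom="chr1"):
    """Build one chromosome of consecutive genes from rank -> family map."""
    n = max(family_by_rank) + 1 if family_by_rank else 0
    genes = [
        GeneRecord(f"g{i:03d}", chrom, i * 100, i * 100 + 50,
                   family=family_by_rank.get(i))
        for i in range(n)
    ]
    return Genome([(chrom, n * 100 + 100)], genes)


def _brute_force_blocks(genome, family, max_intervening):
    """All-pairs link + union-find oracle for tandem block membership."""
    parent = {}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        parent[find(a)] = find(b)

    for chrom, chrom_genes in genome.genes_by_chrom().items():
        members = [(i, g) for i, g in enumerate(chrom_genes) if g.family == family]
        for ai in range(len(members)):
            for bi in range(ai + 1, len(members)):
                (ra, ga), (rb, gb) = members[ai], members[bi]
                if abs(rb - ra) - 1 <= max_intervening:
                    union(ga.gene_id, gb.gene_id)
    groups = {}
    for gid in parent:
        groups.setdefault(find(gid), set()).add(gid)
    return {frozenset(v) for v in groups.values() if len(v) >= 2}


class TestTandemBlocks:
    def test_ten_intervening_genes_link(self):
        genome = _genome_from_families({0: "GNA", 11: "GNA"})  # ranks 1..10 between
        blocks = find_tandem_blocks(genome, "GNA", max_intervening=10)
        assert len(blocks) == 1 and len(blocks[0]) == 2

    def test_eleven_intervening_genes_do_not_link(self):
        genome = _genome_from_families({0: "GNA", 12: "GNA"})
        assert find_tandem_blocks(genome, "GNA", max_intervening=10) == []

    def test_transitive_chaining_builds_one_block(self):
        # 0-5-10-15: each consecutive gap is 4 <= 10, ends are 14 apart
        genome = _genome_from_families({0: "GNA", 5: "GNA", 10: "GNA", 15: "GNA"})
        (block,) = find_tandem_blocks(genome, "GNA")
        assert len(block) == 4

    def test_intervening_counts_all_genes_not_just_family(self):
        # other-family genes between members still count as intervening
        fam = {0: "GNA", 12: "GNA"}
        fam.update({i: "Jacalin" for i in range(1, 12)})
        genome = _genome_from_families(fam)
        assert find_tandem_blocks(genome, "GNA", max_intervening=10) == []

    def test_unknown_family_raises(self, toy_genome):
        with pytest.raises(KeyError):
            find_tandem_blocks(toy_genome, "NoSuchFamily")

    def test_matches_brute_force_oracle_on_random_genomes(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(30, 300))
            fams = {}
            for i in range(n):
                u = rng.random()
                if u < 0.12:
                    fams[i] = "GNA"
                elif u < 0.18:
                    fams[i] = "LysM"
            if "GNA" not in fams.values():
                fams[0] = "GNA"
            genome = _genome_from_families(fams)
            maxi = int(rng.integers(0, 15))
            blocks = find_tandem_blocks(genome, "GNA", max_intervening=maxi)
            got = {frozenset(b.member_gene_ids) for b in blocks}
            assert got == _brute_force_blocks(genome, "GNA", maxi)

    def test_blocks_partition_member_genes(self):
        genome = _genome_from_families(
            {i: "GNA" for i in [0, 2, 4, 40, 42, 80, 95]}
        )
        blocks = find_tandem_blocks(genome, "GNA")
        seen = []
        for b in blocks:
            seen.extend(b.member_gene_ids)
        assert len(seen) == len(set(seen))

    def test_raising_threshold_is_monotone(self):
        genome = _genome_from_families({i: "GNA" for i in [0, 4, 12, 30]})
        small = find_tandem_blocks(genome, "GNA", max_intervening=2)
        large = find_tandem_blocks(genome, "GNA", max_intervening=20)
        members = lambda bs: {g for b in bs for g in b.member_gene_ids}
        assert members(small) <= members(large)


class TestKsFilter:
    def test_boundary_ks_kept_and_above_discarded(self):
        pairs = [DuplicatePair("a", "b", 1.0), DuplicatePair("c", "d", 1.01)]
        kept = filter_segmental_pairs(pairs)
        assert kept == [DuplicatePair("a", "b", 1.0)]

    def test_pair_constructor_rejects_negative_ks(self):
        with pytest.raises(ValueError, match="< 0"):
            DuplicatePair("a", "b", -0.1)

    def test_family_restriction_with_fixture_counts(self, toy_genome):
        rng = np.random.default_rng(3)
        pairs = []
        # 20 pairs: 10 touch a family gene (g1..), Ks alternating around 1.0
        fam = ["g1", "g2", "g4", "g6", "g7"]
        for k in range(20):
            a = fam[k % 5] if k < 10 else f"g{(k % 4) + 20}"
            pairs.append(DuplicatePair(a, f"x{k}", ks=float(rng.uniform(0, 2))))
        kept = filter_segmental_pairs(pairs, toy_genome, ks_max=1.0)
        expect = [p for p in pairs if p.ks <= 1.0 and p.gene_a in fam]
        assert kept == expect


class TestFamilySummary:
    def test_twenty_gene_family_with_four_in_blocks(self):
        # two pairs = 4 genes of a 20-member family in tandem blocks -> 20%
        fams = {i * 30: "LysM" for i in range(16)}  # 16 isolated members
        fams.update({600: "LysM", 601: "LysM", 700: "LysM", 703: "LysM"})
        genome = _genome_from_families(fams)
        blocks = find_tandem_blocks(genome, "LysM")
        summary = summarize_family_expansion(genome, blocks, [], "LysM")
        assert summary.n_genes == 20
        assert summary.n_tandem_blocks == 2
        assert summary.n_genes_in_tandem == 4
        assert summary.pct_tandem == pytest.approx(20.0)

    def test_family_without_blocks_reports_zero(self, toy_genome):
        summary = summarize_family_expansion(toy_genome, [], [], "LysM")
        assert summary.n_tandem_blocks == 0
        assert summary.pct_tandem == 0.0

    def test_segmental_percentage_counts_family_side_only(self, toy_genome):
        pairs = [DuplicatePair("g1", "g3", 0.4), DuplicatePair("g2", "g99", 0.2)]
        kept = filter_segmental_pairs(pairs, toy_genome)
        summary = summarize_family_expansion(toy_genome, [], kept, "GNA")
        # GNA members in kept pairs: g1 and g2 out of 3 family genes
        assert summary.n_genes_in_segmental == 2
        assert summary.pct_segmental == pytest.approx(100 * 2 / 3)

    def test_all_families_scan(self, toy_genome):
        blocks = find_all_tandem_blocks(toy_genome, max_intervening=1)
        # toy genome: g1,g2 GNA adjacent-ish (1 intervening? ranks 0,1 -> 0)
        assert any(b.family == "GNA" for b in blocks)
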