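"""Readers, writers and coordinate-convention handling."""

import pytest

from lectinqtl import (
    GeneRecord,
    Genome,
    apply_id_map,
    assign_families,
    read_genes,
    read_qtls,
    write_genes,
    write_qtls,
)
from lectinqtl.genome_model import (
    FormatError,
    IntegrityError,
    normalize_category,
    read_family_table,
)

GFF3_FIXTURE = """##gff-version 3
##sequence-region chr1 1 5000
##sequence-region chr2 1 3000
chr1\tsrc\tgene\t100\t250\t.\t+\t.\tID=geneA
chr1\tsrc\tgene\t300\t400\t.\t-\t.\tID=geneB
chr1\tsrc\tgene\t300\t500\t.\t+\t.\tID=geneC
chr1\tsrc\tgene\t900\t1200\t.\t+\t.\tID=geneD
chr1\tsrc\tgene\t1500\t1600\t.\t-\t.\tID=geneE
chr1\tsrc\tgene\t2000\t2100\t.\t+\t.\tID=geneF
chr1\tsrc\tgene\t2500\t2600\t.\t+\t.\tID=geneG
chr2\tsrc\tgene\t50\t120\t.\t+\t.\tID=geneH
chr2\tsrc\tgene\t200\t340\t.\t-\t.\tID=geneI
chr2\tsrc\tgene\t400\t450\t.\t+\t.\tID=geneJ
chr2\tsrc\tgene\t500\t700\t.\t+\t.\tID=geneK
chr2\tsrc\tgene\t800\t900\t.\t+\t.\tID=geneL
"""


@pytest.fixture
def gff3_path(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(GFF3_FIXTURE)
    return p


class TestReadGenes:
    def test_gff3_converts_to_zero_based_half_open(self, gff3_path):
        genome = read_genes(gff3_path)
        gene_a = next(g for g in genome.genes if g.gene_id == "geneA")
        assert (gene_a.start, gene_a.end) == (99, 250)
        assert gene_a.length == 151  # 1-based inclusive span 100..250

    def test_bed_coordinates_pass_through(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t99\t250\tgene1\t0\t+\n")
        genome = read_genes(p)
        assert (genome.genes[0].start, genome.genes[0].end) == (99, 250)

    def test_twelve_gene_fixture_sorted_order(self, gff3_path):
        # expected order derived by hand: chrom, then start, end, gene_id
        genome = read_genes(gff3_path)
        assert genome.n_genes == 12
        assert [g.gene_id for g in genome.genes] == [
            "geneA", "geneB", "geneC", "geneD", "geneE", "geneF", "geneG",
            "geneH", "geneI", "geneJ", "geneK", "geneL",
        ]
        assert genome.chromosomes == [("chr1", 5000), ("chr2", 3000)]

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t0\t10\tg\nchr1\t20\t30\tg\n")
        with pytest.raises(IntegrityError, match="duplicate gene_id"):
            read_genes(p)

    def test_malformed_bed_line_names_line_number(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t0\t10\tg1\nchr1\tnotanumber\t30\tg2\n")
        with pytest.raises(FormatError, match=":2"):
            read_genes(p)

    @pytest.mark.parametrize("fmt,suffix", [("gff3", "gff3"), ("bed", "bed"), ("tsv", "tsv")])
    def test_round_trip_identity(self, gff3_path, tmp_path, fmt, suffix):
        genome = read_genes(gff3_path)
        genome = assign_families(genome, {"geneA": "GNA", "geneI": "LysM"})
        out = tmp_path / f"again.{suffix}"
        write_genes(genome, out, format=fmt)
        back = read_genes(out, format=fmt)
        assert [(g.gene_id, g.chrom, g.start, g.end, g.strand) for g in back.genes] == [
            (g.gene_id, g.chrom, g.start, g.end, g.strand) for g in genome.genes
        ]
        if fmt == "tsv":  # only the TSV dialect carries family labels
            assert [g.family for g in back.genes] == [g.family for g in genome.genes]
        # repeated reads serialize byte-identically (total, deterministic sort)
        out2 = tmp_path / f"thrice.{suffix}"
        write_genes(back, out2, format=fmt)
        assert out2.read_text() == out.read_text()

    def test_gff3_round_trip_restores_one_based(self, gff3_path, tmp_path):
        out = tmp_path / "rt.gff3"
        write_genes(read_genes(gff3_path), out, format="gff3")
        line = next(l for l in out.read_text().splitlines() if "ID=geneA" in l)
        fields = line.split("\t")
        assert (fields[3], fields[4]) == ("100", "250")


class TestQTLTable:
    def test_category_normalization_and_coordinates(self, tmp_path):
        p = tmp_path / "qtls.tsv"
        p.write_text(
            "qtl_id\tcategory\ttrait\tchrom\tstart\tend\n"
            "q1\tResistance or Tolerance\tblast resistance\tchr1\t1\t1000\n"
        )
        (q,) = read_qtls(p)
        assert q.category == "resistance_tolerance"
        assert (q.start, q.end) == (0, 1000)

    def test_empty_table_gives_empty_list(self, tmp_path):
        p = tmp_path / "qtls.tsv"
        p.write_text("qtl_id\tcategory\ttrait\tchrom\tstart\tend\n")
        assert read_qtls(p) == []

    def test_category_histogram_on_mixed_fixture(self, tmp_path):
        p = tmp_path / "qtls.tsv"
        p.write_text(
            "qtl_id\tcategory\ttrait\tchrom\tstart\tend\n"
            "q1\tMorphological trait\tdwarf\tchr1\t1\t100\n"
            "q2\tPhysiological trait\tsterility\tchr1\t1\t100\n"
            "q3\tResistance or Tolerance\tblast resistance\tchr2\t5\t50\n"
            "q4\tResistance or Tolerance\tcold tolerance\tchr2\t5\t50\n"
            "q5\tOthers\tmisc\tchr3\t10\t20\n"
        )
        records = read_qtls(p)
        assert len(records) == 5
        hist = {}
        for q in records:
            hist[q.category] = hist.get(q.category, 0) + 1
        assert hist == {
            "morphological": 1, "physiological": 1,
            "resistance_tolerance": 2, "other": 1,
        }

    def test_unknown_category_token_is_named(self):
        with pytest.raises(ValueError, match="flavour"):
            normalize_category("flavour")

    def test_write_read_round_trip(self, tmp_path, toy_qtls):
        p = tmp_path / "qtls.tsv"
        write_qtls(toy_qtls, p)
        assert read_qtls(p) == toy_qtls


class TestFamiliesAndIdMap:
    def test_multi_family_gene_rejected(self, tmp_path):
        p = tmp_path / "fam.tsv"
        p.write_text("gene_id\tfamily\ng1\tGNA\ng1\tJacalin\n")
        with pytest.raises(IntegrityError, match="two families"):
            read_family_table(p)

    def test_identity_map_changes_nothing(self, toy_genome):
        mapped, report = apply_id_map(
            toy_genome, {g.gene_id: g.gene_id for g in toy_genome.genes}
        )
        assert [g.gene_id for g in mapped.genes] == [g.gene_id for g in toy_genome.genes]
        assert (report.mapped, report.unmapped) == (12, 0)

    def test_partial_map_reports_counts(self, toy_genome):
        mapping = {"g1": "Os01g001", "g2": "Os01g002", "g9": "Os02g001"}
        mapped, report = apply_id_map(toy_genome, mapping)
        assert (report.mapped, report.unmapped) == (3, 9)
        ids = {g.gene_id for g in mapped.genes}
        assert {"Os01g001", "Os01g002", "Os02g001"} <= ids
        assert not {"g1", "g2", "g9"} & ids
        # family labels ride along with the rename
        assert next(g for g in mapped.genes if g.gene_id == "Os01g001").family == "GNA"

    def test_colliding_targets_rejected(self, toy_genome):
        with pytest.raises(IntegrityError, match="target"):
            apply_id_map(toy_genome, {"g1": "X", "g2": "X"})


class TestGenomeInvariants:
    def test_gene_beyond_chromosome_end_rejected(self):
        with pytest.raises(IntegrityError, match="beyond"):
            Genome([("chr1", 100)], [GeneRecord("g", "chr1", 50, 150)])

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="start < end"):
            GeneRecord("g", "chr1", 10, 10)

    def test_equal_coordinates_ordered_by_gene_id(self):
        genome = Genome(
            [("chr1", 100)],
            [GeneRecord("zz", "chr1", 10, 20), GeneRecord("aa", "chr1", 10, 20)],
        )
        assert [g.gene_id for g in genome.genes] == ["aa", "zz"]
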