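import textwrap
import warnings

import numpy as np
import pytest

from aletrace.variant_io import (
    EventMatrix,
    GeneIndex,
    MutationEvent,
    MutationTableError,
    StrainRecord,
    assign_genes,
    build_event_matrix,
    classify_mtype,
    read_gene_annotation,
    read_matrix,
    read_mutation_table,
    write_matrix,
)


def write_tsv(tmp_path, text, name="muts.tsv"):
    p = tmp_path / name
    p.write_text(textwrap.dedent(text))
    return p


@pytest.mark.parametrize(
    "ref,alt,expected",
    [
        ("A", "T", "SNV"),
        ("AT", "A", "deletion"),
        ("A", "AT", "insertion"),
        ("ACG", "AC", "deletion"),
    ],
)
def test_mtype_follows_allele_lengths(ref, alt, expected):
    assert classify_mtype(ref, alt) == expected


def test_multibase_substitution_rejected():
    with pytest.raises(MutationTableError):
        classify_mtype("AT", "GC")


def test_event_invariants():
    with pytest.raises(MutationTableError):
        MutationEvent(chrom="chrI", pos=0, ref="A", alt="T")
    ev = MutationEvent(chrom="chrI", pos=5, ref="AT", alt="A")
    assert ev.mtype == "deletion"
    assert ev.event_id == "chrI:5:AT>A"


class TestReadMutationTable:
    def test_three_line_tsv_read_back(self, tmp_path):
        p = write_tsv(
            tmp_path,
            """\
            strain\tchrom\tpos\tref\talt
            strainA\tchrI\t100\tA\tT
            strainA\tchrI\t200\tG\tC
            strainB\tchrI\t100\tA\tT
            """,
        )
        events, strains = read_mutation_table(p)
        assert len(events) == 2
        by_name = {s.strain_id: s for s in strains}
        assert len(by_name["strainA"].events) == 2
        assert by_name["strainB"].events == {"chrI:100:A>T"}

    def test_header_only_table(self, tmp_path):
        p = write_tsv(tmp_path, "strain\tchrom\tpos\tref\talt\n")
        events, strains = read_mutation_table(p)
        assert events == [] and strains == []

    def test_duplicate_pair_collapsed_with_warning(self, tmp_path):
        p = write_tsv(
            tmp_path,
            """\
            strain\tchrom\tpos\tref\talt
            s1\tchrI\t100\tA\tT
            s1\tchrI\t100\tA\tT
            """,
        )
        with pytest.warns(UserWarning, match="duplicate"):
            events, strains = read_mutation_table(p)
        assert len(events) == 1 and len(strains[0].events) == 1

    def test_bad_position_reports_line(self, tmp_path):
        p = write_tsv(
            tmp_path,
            """\
            strain\tchrom\tpos\tref\talt
            s1\tchrI\t0\tA\tT
            """,
        )
        with pytest.raises(MutationTableError, match=":2"):
            read_mutation_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = write_tsv(tmp_path, "strain\tchrom\tpos\tref\n")
        with pytest.raises(MutationTableError, match="alt"):
            read_mutation_table(p)

    def test_vcf_dialect_presence_from_genotypes(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=chrI,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsA\tsB\n"
            "chrI\t100\t.\tA\tT\t.\t.\t.\tGT\t1/1\t0/0\n"
            "chrI\t200\t.\tG\tGA\t.\t.\t.\tGT\t0/1\t./.\n"
        )
        events, strains = read_mutation_table(vcf, dialect="vcf")
        by_name = {s.strain_id: s for s in strains}
        assert {e.event_id for e in events} == {"chrI:100:A>T", "chrI:200:G>GA"}
        assert by_name["sA"].events == {"chrI:100:A>T", "chrI:200:G>GA"}
        assert by_name["sB"].events == set()


class TestGeneAnnotation:
    GFF = """\
    ##gff-version 3
    ##sequence-region chrI 1 6000000
    ##sequence-region chrII 1 6000000
    chrI\tx\tgene\t1000\t2000\t.\t+\t.\tID=GENE1;Name=GENE1
    chrII\tx\tgene\t500\t900\t.\t-\t.\tID=GENE2;Name=GENE2
    """

    def test_boundaries_inclusive(self, tmp_path):
        p = write_tsv(tmp_path, self.GFF, name="g.gff3")
        idx = read_gene_annotation(p)
        assert idx.lookup("chrI", 1000) == "GENE1"
        assert idx.lookup("chrI", 2000) == "GENE1"
        assert idx.lookup("chrI", 999) is None
        assert idx.lookup("chrI", 2001) is None

    def test_lookup_routes_by_chromosome(self, tmp_path):
        p = write_tsv(tmp_path, self.GFF, name="g.gff3")
        idx = read_gene_annotation(p)
        assert idx.lookup("chrII", 600) == "GENE2"
        assert idx.lookup("chrI", 600) is None

    def test_genome_length_from_sequence_regions(self, tmp_path):
        p = write_tsv(tmp_path, self.GFF, name="g.gff3")
        idx = read_gene_annotation(p)
        assert idx.genome_length == 12_000_000

    def test_overlapping_genes_rejected(self):
        with pytest.raises(ValueError, match="G1.*G2|overlap"):
            GeneIndex(
                {"chrI": [(100, 300, "G1"), (200, 400, "G2")]},
                genome_length=1000,
            )

    def test_missing_genome_length_instructs_override(self, tmp_path):
        p = write_tsv(
            tmp_path,
            "##gff-version 3\nchrI\tx\tgene\t10\t20\t.\t+\t.\tID=G\n",
            name="nolen.gff3",
        )
        with pytest.raises(ValueError, match="genome_length"):
            read_gene_annotation(p)


class TestAssignGenes:
    idx = GeneIndex(
        {"chrI": [(1000, 5999, "CDC25")], "chrII": [(10, 20, "OTHER")]},
        genome_length=12_000_000,
        chrom_lengths={"chrI": 6_000_000, "chrII": 6_000_000},
    )

    def test_inclusive_start_and_intergenic(self):
        evs = [
            MutationEvent(chrom="chrI", pos=1000, ref="A", alt="T"),
            MutationEvent(chrom="chrI", pos=999, ref="G", alt="C"),
        ]
        out = assign_genes(evs, self.idx)
        assert out[0].gene_id == "CDC25"
        assert out[1].gene_id is None

    def test_events_in_shared_interval(self):
        evs = [
            MutationEvent(chrom="chrI", pos=p, ref="A", alt="T")
            for p in (1000, 2500, 4000, 5999)
        ]
        out = assign_genes(evs, self.idx)
        assert {e.gene_id for e in out} == {"CDC25"}

    def test_unknown_chromosome_warns(self):
        evs = [MutationEvent(chrom="chrX", pos=5, ref="A", alt="T")]
        with pytest.warns(UserWarning, match="chrX"):
            out = assign_genes(evs, self.idx)
        assert out[0].gene_id is None

    def test_idempotent_and_order_independent(self):
        evs = [
            MutationEvent(chrom="chrI", pos=p, ref="A", alt="T")
            for p in (999, 1000, 3000)
        ]
        once = assign_genes(evs, self.idx)
        twice = assign_genes(once, self.idx)
        assert once == twice
        rev = assign_genes(evs[::-1], self.idx)
        assert sorted(rev, key=lambda e: e.pos) == sorted(once, key=lambda e: e.pos)


class TestBuildMatrix:
    def test_single_event(self):
        ev = MutationEvent(chrom="chrI", pos=10, ref="A", alt="T")
        strains = [
            StrainRecord("P", "parental", frozenset()),
            StrainRecord("s1", "", frozenset([ev.event_id])),
        ]
        m = build_event_matrix([ev], strains, parental="P")
        assert m.df.loc["s1"].tolist() == [1]
        assert m.df.loc["P"].tolist() == [0]

    def test_column_sums_shared_and_private(self):
        e = [MutationEvent(chrom="chrI", pos=p, ref="A", alt="T") for p in (1, 2, 3)]
        strains = [
            StrainRecord("P", "parental", frozenset()),
            StrainRecord("x", "", frozenset([e[0].event_id, e[1].event_id])),
            StrainRecord("y", "", frozenset([e[0].event_id, e[2].event_id])),
        ]
        m = build_event_matrix(e, strains, parental="P")
        assert sorted(m.df.sum(axis=0).tolist()) == [1, 1, 2]

    def test_parental_with_event_rejected(self):
        ev = MutationEvent(chrom="chrI", pos=10, ref="A", alt="T")
        strains = [StrainRecord("P", "parental", frozenset([ev.event_id]))]
        with pytest.raises(ValueError, match="[Pp]arental"):
            build_event_matrix([ev], strains, parental="P")

    def test_duplicate_strain_rejected(self):
        ev = MutationEvent(chrom="chrI", pos=10, ref="A", alt="T")
        strains = [
            StrainRecord("s1", "", frozenset([ev.event_id])),
            StrainRecord("s1", "", frozenset()),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            build_event_matrix([ev], strains, parental="P")

    def test_all_zero_columns_dropped(self):
        evs = [
            MutationEvent(chrom="chrI", pos=1, ref="A", alt="T"),
            MutationEvent(chrom="chrI", pos=2, ref="G", alt="C"),
        ]
        strains = [
            StrainRecord("P", "parental", frozenset()),
            StrainRecord("s1", "", frozenset([evs[0].event_id])),
        ]
        with pytest.warns(UserWarning, match="all-zero"):
            m = build_event_matrix(evs, strains, parental="P")
        assert m.n_events == 1

    def test_columns_deduplicated_by_site(self):
        a = MutationEvent(chrom="chrI", pos=1, ref="A", alt="T")
        b = MutationEvent(chrom="chrI", pos=1, ref="A", alt="T", gene_id="G")
        strains = [
            StrainRecord("P", "parental", frozenset()),
            StrainRecord("s1", "", frozenset([a.event_id])),
        ]
        m = build_event_matrix([a, b], strains, parental="P")
        assert m.n_events == 1

    def test_study_shape(self, study_matrix):
        m, _ = study_matrix
        assert len(m.taxa) == 19
        assert m.n_events == 49


def test_matrix_round_trip(tmp_path, study_matrix):
    m, _ = study_matrix
    path = tmp_path / "matrix.tsv"
    write_matrix(m, path)
    back = read_matrix(path)
    assert back.parental == m.parental
    assert (back.df == m.df).all().all()
    assert list(back.df.index) == list(m.df.index)
    assert list(back.df.columns) == list(m.df.columns)
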