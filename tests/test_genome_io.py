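"""Data model and format round-trips: BEDPE, VCF BND, CN TSV, genes."""

import pytest

from chromobal import (
    Breakend,
    CNSegment,
    GenomeError,
    SampleData,
    classify_sv_type,
    make_sv,
    read_bedpe_svs,
    read_cn_segments,
    read_genes,
    read_vcf_bnd,
    write_bedpe,
)


class TestClassify:
    @pytest.mark.parametrize(
        "b1,b2,expected",
        [
            (("chrY", 100, "+"), ("chrY", 500, "-"), "DEL"),
            (("chrY", 100, "-"), ("chrY", 500, "+"), "DUP"),
            (("chrY", 100, "+"), ("chrY", 500, "+"), "h2hINV"),
            (("chrY", 100, "-"), ("chrY", 500, "-"), "t2tINV"),
            (("chr1", 100, "+"), ("chr5", 200, "-"), "TRA"),
        ],
    )
    def test_orientation_table(self, b1, b2, expected):
        assert classify_sv_type(Breakend(*b1), Breakend(*b2)) == expected

    def test_argument_order_invariance(self):
        for sides in [("+", "-"), ("-", "+"), ("+", "+"), ("-", "-")]:
            a, b = Breakend("chrY", 100, sides[0]), Breakend("chrY", 500, sides[1])
            assert classify_sv_type(a, b) == classify_sv_type(b, a)

    def test_degenerate_junction_rejected(self):
        b = Breakend("chrY", 100, "+")
        with pytest.raises(GenomeError, match="degenerate"):
            classify_sv_type(b, Breakend("chrY", 100, "+"))

    def test_make_sv_canonical_order(self):
        sv = make_sv("s", Breakend("chrY", 500, "-"), Breakend("chrY", 100, "+"))
        assert (sv.bnd1.pos, sv.bnd2.pos) == (100, 500)
        assert sv.sv_class == "DEL"


class TestBedpe:
    def test_read_examples(self, tmp_path, toy_genome):
        p = tmp_path / "svs.bedpe"
        p.write_text(
            "chrY\t100\t101\tchrY\t500\t501\tsv1\t.\t+\t-\n"
            "chr1\t100\t101\tchr5\t200\t201\tsv2\t.\t+\t-\n"
            "chrY\t500\t501\tchrY\t100\t101\tsv3\t.\t-\t+\n"
        )
        svs = read_bedpe_svs(p, toy_genome)
        assert [sv.sv_class for sv in svs] == ["DEL", "TRA", "DEL"]
        first, swapped = svs[0], svs[2]
        assert (swapped.bnd1, swapped.bnd2) == (first.bnd1, first.bnd2)

    def test_unknown_chromosome_names_line(self, tmp_path, toy_genome):
        p = tmp_path / "bad.bedpe"
        p.write_text("chrZ\t1\t2\tchrY\t5\t6\tsv1\t.\t+\t-\n")
        with pytest.raises(GenomeError, match=":1"):
            read_bedpe_svs(p, toy_genome)

    def test_start_after_end_rejected(self, tmp_path, toy_genome):
        p = tmp_path / "bad.bedpe"
        p.write_text("chrY\t10\t5\tchrY\t50\t51\tsv1\t.\t+\t-\n")
        with pytest.raises(GenomeError, match="start > end"):
            read_bedpe_svs(p, toy_genome)

    def test_missing_strands_rejected(self, tmp_path, toy_genome):
        p = tmp_path / "bad.bedpe"
        p.write_text("chrY\t1\t2\tchrY\t5\t6\tsv1\t.\n")
        with pytest.raises(GenomeError, match="10 columns"):
            read_bedpe_svs(p, toy_genome)

    def test_duplicate_ids_rekeyed(self, tmp_path, toy_genome):
        p = tmp_path / "dup.bedpe"
        p.write_text(
            "chrY\t100\t101\tchrY\t500\t501\tsv\t.\t+\t-\n"
            "chrY\t700\t701\tchrY\t900\t901\tsv\t.\t+\t-\n"
        )
        svs = read_bedpe_svs(p, toy_genome)
        assert len({sv.id for sv in svs}) == 2

    def test_round_trip_bit_identical(self, tmp_path, toy_genome):
        p = tmp_path / "svs.bedpe"
        p.write_text(
            "chrY\t500\t501\tchrY\t100\t101\tsv1\t.\t-\t+\n"
            "chr1\t9\t10\tchr5\t7\t8\tsv2\t.\t-\t-\n"
        )
        svs = read_bedpe_svs(p, toy_genome)
        q = tmp_path / "out.bedpe"
        write_bedpe(svs, q)
        assert read_bedpe_svs(q, toy_genome) == svs
        write_bedpe(read_bedpe_svs(q, toy_genome), tmp_path / "out2.bedpe")
        assert q.read_text() == (tmp_path / "out2.bedpe").read_text()


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##INFO=<ID=MATEID,Number=1,Type=String,Description="Mate id">\n'
    '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n'
    "##contig=<ID=chrY,length=57227415>\n"
    "##contig=<ID=chr1,length=100000000>\n"
    "##contig=<ID=chr5,length=100000000>\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
)


class TestVcfBnd:
    def test_deletion_junction_pairing(self, tmp_path, toy_genome):
        # 1-based 101/501 with bracket ALTs encoding a DEL-type junction
        p = tmp_path / "svs.vcf"
        p.write_text(
            VCF_HEADER
            + "chrY\t101\tsv1_1\tN\tN[chrY:501[\t.\t.\tSVTYPE=BND;MATEID=sv1_2\n"
            + "chrY\t501\tsv1_2\tN\t]chrY:101]N\t.\t.\tSVTYPE=BND;MATEID=sv1_1\n"
        )
        svs = read_vcf_bnd(p, toy_genome)
        assert len(svs) == 1
        sv = svs[0]
        assert sv.sv_class == "DEL"
        assert (sv.bnd1.pos, sv.bnd2.pos) == (100, 500)  # 0-based internally

    def test_matches_bedpe_encoding(self, tmp_path, toy_genome):
        bedpe = tmp_path / "svs.bedpe"
        bedpe.write_text(
            "chrY\t100\t101\tchrY\t500\t501\tsv1\t.\t+\t-\n"
            "chrY\t200\t201\tchrY\t900\t901\tsv2\t.\t+\t+\n"
            "chrY\t300\t301\tchrY\t800\t801\tsv3\t.\t-\t-\n"
        )
        vcf = tmp_path / "svs.vcf"
        vcf.write_text(
            VCF_HEADER
            + "chrY\t101\tsv1_1\tN\tN[chrY:501[\t.\t.\tMATEID=sv1_2\n"
            + "chrY\t501\tsv1_2\tN\t]chrY:101]N\t.\t.\tMATEID=sv1_1\n"
            + "chrY\t201\tsv2_1\tN\tN]chrY:901]\t.\t.\tMATEID=sv2_2\n"
            + "chrY\t901\tsv2_2\tN\tN]chrY:201]\t.\t.\tMATEID=sv2_1\n"
            + "chrY\t301\tsv3_1\tN\t[chrY:801[N\t.\t.\tMATEID=sv3_2\n"
            + "chrY\t801\tsv3_2\tN\t[chrY:301[N\t.\t.\tMATEID=sv3_1\n"
        )
        assert read_vcf_bnd(vcf, toy_genome) == read_bedpe_svs(bedpe, toy_genome)

    def test_orphan_mate_is_error(self, tmp_path, toy_genome):
        p = tmp_path / "orphan.vcf"
        p.write_text(
            VCF_HEADER
            + "chrY\t101\tsv1_1\tN\tN[chrY:501[\t.\t.\tMATEID=sv1_2\n"
        )
        with pytest.raises(GenomeError, match="sv1_1"):
            read_vcf_bnd(p, toy_genome)

    def test_empty_body_and_non_bnd_skipped(self, tmp_path, toy_genome):
        p = tmp_path / "empty.vcf"
        p.write_text(VCF_HEADER)
        assert read_vcf_bnd(p, toy_genome) == []
        q = tmp_path / "snv.vcf"
        q.write_text(VCF_HEADER + "chrY\t101\trs1\tA\tG\t.\t.\t.\n")
        assert read_vcf_bnd(q, toy_genome) == []


class TestCnSegments:
    def test_read_and_sort(self, tmp_path, toy_genome):
        p = tmp_path / "cn.tsv"
        p.write_text(
            "chrom\tstart\tend\ttotal_cn\tminor_cn\n"
            "chrY\t1000000\t2000000\t2\t0\n"
            "chrY\t0\t1000000\t1\t0\n"
        )
        segs = read_cn_segments(p, toy_genome)
        assert [(s.start, s.total_cn) for s in segs] == [(0, 1), (1000000, 2)]

    def test_overlap_rejected(self, tmp_path, toy_genome):
        p = tmp_path / "cn.tsv"
        p.write_text(
            "chrom\tstart\tend\ttotal_cn\n"
            "chrY\t0\t1000\t1\nchrY\t500\t2000\t2\n"
        )
        with pytest.raises(GenomeError, match="overlap"):
            read_cn_segments(p, toy_genome)

    def test_negative_cn_rejected(self, tmp_path, toy_genome):
        p = tmp_path / "cn.tsv"
        p.write_text("chrom\tstart\tend\ttotal_cn\nchrY\t0\t1000\t-1\n")
        with pytest.raises(GenomeError, match="negative"):
            read_cn_segments(p, toy_genome)

    def test_minor_cn_bound(self):
        with pytest.raises(GenomeError, match="minor"):
            CNSegment("chrY", 0, 10, 1, 2)


class TestGenes:
    def test_bed6_and_driver_marking(self, tmp_path, toy_genome):
        bed = tmp_path / "genes.bed"
        bed.write_text(
            "chr1\t1000\t5000\tTMPRSS2\t0\t-\n"
            "chr5\t9000\t12000\tPTEN\t0\t+\n"
            "chrZ\t1\t10\tGHOST\t0\t+\n"
        )
        drv = tmp_path / "drivers.txt"
        drv.write_text("PTEN\n")
        genes = read_genes(bed, toy_genome, drivers=drv)
        assert [g.name for g in genes] == ["TMPRSS2", "PTEN"]  # GHOST dropped
        assert genes[0].strand == "-" and not genes[0].is_driver
        assert genes[1].is_driver

    def test_gff3_equivalent_to_bed6(self, tmp_path, toy_genome):
        bed = tmp_path / "genes.bed"
        bed.write_text("chr1\t999\t5000\tTMPRSS2\t0\t-\n")
        gff = tmp_path / "genes.gff3"
        gff.write_text(
            "##gff-version 3\n"
            "chr1\tensembl\tgene\t1000\t5000\t.\t-\t.\tID=gene:1;Name=TMPRSS2\n"
            "chr1\tensembl\texon\t1000\t2000\t.\t-\t.\tID=exon:1\n"
        )
        assert read_genes(gff, toy_genome) == read_genes(bed, toy_genome)

    def test_short_bed_rejected(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t1\t10\tX\n")
        with pytest.raises(GenomeError, match="6 columns"):
            read_genes(bed)


def test_sample_data_validates_chromosomes(toy_genome):
    sv = make_sv("s", Breakend("chr9", 1, "+"), Breakend("chr9", 5, "-"))
    with pytest.raises(GenomeError, match="chr9"):
        SampleData("s1", [sv], [], toy_genome)
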