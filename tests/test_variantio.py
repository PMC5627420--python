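"""Data model and file-format round trips (VCF dialect, TSVs, BED, catalog)."""

import numpy as np
import pandas as pd
import pytest

from lynchtrio import (
    Arm,
    GermlineSite,
    SignatureCatalog,
    VariantCall,
    default_catalog,
    read_annotation,
    read_arm_bed,
    read_caller_vcf,
    read_signature_catalog,
    write_vcf,
)
from lynchtrio.errors import DataIntegrityError, ParseError
from lynchtrio.variantio import (
    CONTEXT_LABELS,
    read_fasta,
    read_gene_lists,
    read_sites_tsv,
    sites_to_table,
    site_maf,
    table_to_sites,
    write_annotation,
    write_arm_bed,
    write_fasta,
    write_signature_catalog,
    write_sites_tsv,
)


class TestVariantCall:
    def test_invariants_enforced(self):
        with pytest.raises(DataIntegrityError):
            VariantCall(chrom="1", pos=0, ref="A", alt="C", sample="s")
        with pytest.raises(DataIntegrityError):
            VariantCall(chrom="1", pos=5, ref="A", alt="A", sample="s")
        with pytest.raises(DataIntegrityError):
            VariantCall(chrom="1", pos=5, ref="A", alt="C", sample="s", depth=10, alt_depth=11)

    def test_vaf_recomputed_from_depths(self):
        v = VariantCall(chrom="chr1", pos=101, ref="C", alt="T", sample="s", depth=40, alt_depth=10)
        assert v.vaf == 0.25
        assert v.chrom == "1"  # chr prefix normalized away
        assert VariantCall(chrom="1", pos=1, ref="C", alt="T", sample="s").vaf is None

    def test_identity_key_is_caller_independent(self):
        a = VariantCall(chrom="1", pos=5, ref="A", alt="C", sample="s", callers={"c1"})
        b = VariantCall(chrom="chr1", pos=5, ref="A", alt="C", sample="s", callers={"c2"})
        assert a.key == b.key


class TestVcf:
    def test_basic_record_maps_to_call(self, tmp_path):
        path = tmp_path / "c1.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tC\tT\t.\tPASS\t.\n"
        )
        calls = read_caller_vcf(path, "c1", "tumor")
        assert len(calls) == 1
        v = calls[0]
        assert (v.chrom, v.pos, v.ref, v.alt) == ("1", 101, "C", "T")
        assert v.callers == {"c1"}
        assert v.depth is None  # retained with depths absent

    def test_multiallelic_record_split_per_alt(self, tmp_path):
        path = tmp_path / "c1.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AD,Number=A,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t101\t.\tC\tT,G\t.\tPASS\tAD=7,3\n"
        )
        calls = read_caller_vcf(path, "c1", "tumor")
        assert [(v.pos, v.alt, v.alt_depth) for v in calls] == [(101, "T", 7), (101, "G", 3)]

    def test_round_trip_is_lossless(self, tmp_path, small_trio):
        calls = small_trio.callsets["rpc"]["caller1"]
        path = tmp_path / "rt.vcf"
        write_vcf(path, calls, contig_lengths={c: len(s) for c, s in small_trio.reference.items()})
        back = read_caller_vcf(path, "caller1", "rpc")
        orig = {(v.key, v.depth, v.alt_depth) for v in calls}
        rt = {(v.key, v.depth, v.alt_depth) for v in back}
        assert rt == orig

    def test_malformed_record_names_position(self, tmp_path):
        path = tmp_path / "bad.vcf"
        path.write_text("not a vcf at all\n")
        with pytest.raises(ParseError):
            read_caller_vcf(path, "c1", "t")


class TestAnnotation:
    def _write(self, tmp_path, rows):
        path = tmp_path / "ann.tsv"
        header = "chrom\tpos\tref\talt\tgene\tconsequence\tpop_freq\n"
        path.write_text(header + "".join(rows))
        return path

    def test_three_row_fixture(self, tmp_path):
        path = self._write(
            tmp_path,
            [
                "chr1\t101\tC\tT\tTP53\tnonsense\t0.0001\n",
                "1\t202\tA\tG\tAPC\tmissense\t\n",
                "2\t303\tG\tT\tMSH2\tweird_term\t0.5\n",
            ],
        )
        ann = read_annotation(path)
        assert len(ann) == 3
        assert ann[("1", 101, "C", "T")] == ("TP53", "nonsense", 0.0001)
        assert ann[("1", 202, "A", "G")][2] is None  # missing pop_freq cell
        assert ann[("2", 303, "G", "T")][1] == "noncoding"  # unknown term mapped

    def test_conflicting_duplicates_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            ["1\t101\tC\tT\tTP53\tnonsense\t0.1\n", "1\t101\tC\tT\tTP53\tmissense\t0.1\n"],
        )
        with pytest.raises(ParseError):
            read_annotation(path)

    def test_write_read_round_trip(self, tmp_path, small_trio):
        path = tmp_path / "ann.tsv"
        write_annotation(path, small_trio.annotation)
        assert read_annotation(path) == small_trio.annotation


class TestSignatureCatalog:
    def test_round_trip_and_normalization(self, tmp_path, catalog):
        path = tmp_path / "cat.tsv"
        write_signature_catalog(catalog, path)
        back = read_signature_catalog(path)
        assert back.names == catalog.names
        for name in catalog.names:
            np.testing.assert_allclose(back[name], catalog[name], atol=1e-9)
            assert abs(back[name].sum() - 1.0) < 1e-9

    def test_wrong_row_count_rejected(self, tmp_path, catalog):
        path = tmp_path / "cat.tsv"
        write_signature_catalog(catalog, path)
        lines = path.read_text().splitlines()
        (tmp_path / "short.tsv").write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ParseError):
            read_signature_catalog(tmp_path / "short.tsv")

    def test_zero_and_negative_columns_rejected(self):
        with pytest.raises(ParseError):
            SignatureCatalog(signatures={"z": np.zeros(96)})
        bad = np.full(96, 1.0 / 95)
        bad[0] = -1.0 / 95
        with pytest.raises(ParseError):
            SignatureCatalog(signatures={"n": bad})

    def test_labels_cover_six_classes(self, catalog):
        assert len(CONTEXT_LABELS) == 96
        assert len({lab[2:5] for lab in CONTEXT_LABELS}) == 6


class TestArms:
    def test_bed_round_trip_and_boundary_membership(self, tmp_path):
        arms = [Arm("1", "p", 0, 100), Arm("1", "q", 100, 250)]
        path = tmp_path / "arms.bed"
        write_arm_bed(arms, path)
        back = read_arm_bed(path)
        assert [(a.name, a.start, a.end) for a in back] == [("1p", 0, 100), ("1q", 100, 250)]
        p = back[0]
        # 1-based position p maps via start <= p-1 < end
        assert p.contains(1) and p.contains(100)
        assert not p.contains(101)

    def test_overlapping_arms_rejected(self, tmp_path):
        path = tmp_path / "arms.bed"
        path.write_text("chr1\t0\t100\t1p\nchr1\t90\t200\t1q\n")
        with pytest.raises(DataIntegrityError):
            read_arm_bed(path)


class TestGermlineSites:
    def test_maf_bounded_and_symmetric(self):
        site = GermlineSite(
            chrom="1", pos=10, ref="A", alt="C", is_dbsnp=True,
            genotype={"n": "het"}, depth={"n": 40}, alt_depth={"n": 30},
        )
        assert site.maf("n") == pytest.approx(0.25)
        assert 0.0 <= site.maf("n") <= 0.5

    def test_table_conversion_round_trip(self, small_trio):
        head = small_trio.sites.head(20)
        sites = table_to_sites(head)
        back = sites_to_table(sites, ["blood", "rpc", "sic"])
        pd.testing.assert_frame_equal(back, head.reset_index(drop=True), check_dtype=False)

    def test_sites_tsv_round_trip(self, tmp_path, small_trio):
        path = tmp_path / "sites.tsv"
        write_sites_tsv(small_trio.sites, path)
        back = read_sites_tsv(path)
        np.testing.assert_array_equal(
            site_maf(back, "rpc"), site_maf(small_trio.sites, "rpc")
        )


class TestFastaAndGeneLists:
    def test_fasta_round_trip(self, tmp_path, small_trio):
        path = tmp_path / "ref.fa"
        write_fasta(small_trio.reference, path)
        back = read_fasta(path)
        assert back == small_trio.reference

    def test_gene_lists_reader(self, tmp_path):
        path = tmp_path / "lists.tsv"
        path.write_text("list_name\tgene\nSMG\tAPC\nSMG\tTP53\npathway_wnt\tAPC\n")
        lists = read_gene_lists(path)
        assert lists == {"SMG": {"APC", "TP53"}, "pathway_wnt": {"APC"}}
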