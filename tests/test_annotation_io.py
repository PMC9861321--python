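"""Annotation and count-matrix IO: parsing, coordinate dialects, superfamily
classification, validation."""

import logging

import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from erv_pairscan.annotation_io import (
    SUPERFAMILIES,
    AnnotationError,
    CountMatrix,
    CountsError,
    GenomeAnnotation,
    GenomicInterval,
    classify_superfamily,
    gtf_to_internal,
    internal_to_gtf,
    normalize_chrom,
    read_counts,
    read_design,
    read_gene_annotation,
    read_herv_annotation,
    write_bed,
)
from conftest import make_gene, make_herv


class TestCoordinateConversion:
    def test_gtf_line_converts_to_zero_based_half_open(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text('chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "G1";\n')
        (rec,) = read_gene_annotation(gtf, "gtf")
        assert (rec.gene_id, rec.interval.chrom) == ("G1", "chr1")
        assert (rec.interval.start, rec.interval.end, rec.interval.strand) == \
            (1000, 2000, "+")

    def test_bed_line_is_taken_verbatim(self, tmp_path):
        bed = tmp_path / "g.bed"
        bed.write_text("chr2\t500\t900\tG2\t0\t-\n")
        (rec,) = read_gene_annotation(bed, "bed")
        assert (rec.interval.start, rec.interval.end, rec.interval.strand) == \
            (500, 900, "-")

    @given(st.integers(1, 10**9), st.integers(0, 10**6))
    def test_gtf_conversion_roundtrips(self, start, span):
        end = start + span
        assert internal_to_gtf(*gtf_to_internal(start, end)) == (start, end)
        s0, e0 = gtf_to_internal(start, end)
        assert gtf_to_internal(*internal_to_gtf(s0, e0)) == (s0, e0)

    @pytest.mark.parametrize("raw,expected", [
        ("1", "chr1"), ("chr1", "chr1"), ("MT", "chrM"), ("chrM", "chrM"),
    ])
    def test_chrom_normalization(self, raw, expected):
        assert normalize_chrom(raw) == expected


class TestGeneAnnotation:
    def test_gene_span_is_union_of_gene_feature_lines(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1101\t1200\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\texon\t2500\t2600\t.\t+\t.\tgene_id "G1";\n'
        )
        (rec,) = read_gene_annotation(gtf, "gtf")
        # the "gene" line wins over exon hull
        assert (rec.interval.start, rec.interval.end) == (1000, 2000)

    def test_gene_span_falls_back_to_line_hull(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\texon\t1101\t1200\t.\t-\t.\tgene_id "G1";\n'
            'chr1\tsrc\texon\t1500\t1800\t.\t-\t.\tgene_id "G1";\n'
        )
        (rec,) = read_gene_annotation(gtf, "gtf")
        assert (rec.interval.start, rec.interval.end) == (1100, 1800)

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        gtf = tmp_path / "empty.gtf"
        gtf.write_text("")
        with caplog.at_level(logging.WARNING):
            assert read_gene_annotation(gtf, "gtf") == []
        assert "empty" in caplog.text

    def test_malformed_line_names_line_number(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tsrc\tgene\t1\t100\t.\t+\t.\tgene_id "A";\n'
                       "chr1\tonly-three-cols\tgene\n")
        with pytest.raises(AnnotationError, match="line 2"):
            read_gene_annotation(gtf, "gtf")

    def test_conflicting_strand_for_one_gene_id_raises(self, tmp_path):
        gtf = tmp_path / "bad.gtf"
        gtf.write_text('chr1\tsrc\texon\t1\t100\t.\t+\t.\tgene_id "G";\n'
                       'chr1\tsrc\texon\t200\t300\t.\t-\t.\tgene_id "G";\n')
        with pytest.raises(AnnotationError, match="conflicting"):
            read_gene_annotation(gtf, "gtf")


class TestHervAnnotation:
    def test_rmsk_row_maps_family_and_coordinates(self, tmp_path):
        out = tmp_path / "rm.out"
        out.write_text(
            "  SW  perc perc perc  query     position in query\n"
            "score  div. del. ins.  sequence  begin  end\n"
            "\n"
            " 463  11.8  0.0  0.0  chr1  3001  3500  (100)  +  THE1B  "
            "LTR/ERVL-MaLR  1  500  (0)  1\n"
            " 300  10.0  0.0  0.0  chr1  9001  9400  (100)  C  HERVH  "
            "LTR/ERV1  1  400  (0)  2\n"
        )
        loci = read_herv_annotation(out, "rmsk_out")
        assert [l.superfamily for l in loci] == ["ERVL-MaLR", "ERV1"]
        assert (loci[0].interval.start, loci[0].interval.end) == (3000, 3500)
        assert loci[1].interval.strand == "-"

    def test_non_ltr_element_warns_and_is_unclassified(self, tmp_path, caplog):
        out = tmp_path / "rm.out"
        out.write_text(" 100  1.0  0.0  0.0  chr1  1001  1200  (0)  +  L1MC  "
                       "LINE/L1  1  200  (0)  1\n")
        with caplog.at_level(logging.WARNING):
            (locus,) = read_herv_annotation(out, "rmsk_out")
        assert locus.superfamily == "unclassified"
        assert "non-LTR" in caplog.text

    def test_bed_name_field_encodes_locus_and_family(self, tmp_path):
        bed = tmp_path / "h.bed"
        bed.write_text("chr1\t100\t600\tH1|LTR/ERVK\t0\t+\n")
        (locus,) = read_herv_annotation(bed, "bed")
        assert (locus.locus_id, locus.family_name, locus.superfamily) == \
            ("H1", "LTR/ERVK", "ERVK")

    def test_missing_family_kept_unclassified_with_warning(self, tmp_path, caplog):
        bed = tmp_path / "h.bed"
        bed.write_text("chr1\t100\t600\tH1\t0\t+\n")
        with caplog.at_level(logging.WARNING):
            (locus,) = read_herv_annotation(bed, "bed")
        assert (locus.family_name, locus.superfamily) == ("", "unclassified")
        assert "no family" in caplog.text


class TestSuperfamilyClassification:
    @pytest.mark.parametrize("raw,expected", [
        ("LTR/ERVL-MaLR", "ERVL-MaLR"),   # longest-match before ERVL
        ("LTR/ERVL", "ERVL"),
        ("LTR/ERVK", "ERVK"),
        ("LTR/ERV1", "ERV1"),
        ("LTR/Gypsy", "Gypsy"),
        ("ltr/ervl-malr?", "ERVL-MaLR"),  # case-insensitive
        ("ERV1", "ERV1"),                 # bare family, no class prefix
        ("", "unclassified"),
        ("LINE/L1", "unclassified"),
        ("DNA/hAT", "unclassified"),
    ])
    def test_known_mappings(self, raw, expected):
        assert classify_superfamily(raw) == expected

    @given(st.text(max_size=40))
    def test_total_on_arbitrary_strings(self, s):
        assert classify_superfamily(s) in SUPERFAMILIES


class TestBedRoundTrip:
    def test_write_then_read_preserves_intervals_and_strands(self, tmp_path):
        genes = [make_gene("G1", "chr1", 0, 500, "+"),
                 make_gene("G2", "chr2", 100, 900, "-")]
        hervs = [make_herv("H1", "chr1", 50, 60, "+", "LTR/ERVL-MaLR"),
                 make_herv("H2", "chr2", 5, 10, "-", "LTR/Gypsy")]
        write_bed(genes, tmp_path / "g.bed")
        write_bed(hervs, tmp_path / "h.bed")
        assert read_gene_annotation(tmp_path / "g.bed", "bed") == genes
        assert read_herv_annotation(tmp_path / "h.bed", "bed") == hervs


class TestGenomeAnnotationValidation:
    def test_interval_beyond_chromosome_length_raises(self):
        ann = GenomeAnnotation({"chr1": 1000},
                               genes={"G1": make_gene("G1", "chr1", 900, 1100, "+")})
        with pytest.raises(AnnotationError, match="exceeds"):
            ann.validate()

    def test_unknown_chromosome_raises(self):
        ann = GenomeAnnotation({"chr1": 1000},
                               genes={"G1": make_gene("G1", "chr9", 0, 10, "+")})
        with pytest.raises(AnnotationError, match="unknown chromosome"):
            ann.validate()

    def test_interval_invariants(self):
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 10, 10, "+")   # empty
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", -1, 10, "+")   # negative
        with pytest.raises(AnnotationError):
            GenomicInterval("chr1", 0, 10, "x")    # bad strand
        with pytest.raises(AnnotationError):
            GenomicInterval("", 0, 10, "+")        # empty chrom


class TestCounts:
    def _write(self, tmp_path, body):
        p = tmp_path / "c.tsv"
        p.write_text(body)
        return p

    def test_reads_and_orders_by_design(self, tmp_path):
        p = self._write(tmp_path,
                        "feature_id\ts1\ts2\ts3\ts4\n"
                        "F1\t1\t2\t3\t4\nF2\t5\t6\t7\t8\nF3\t0\t0\t1\t1\n")
        design = {"s1": "treated", "s2": "treated", "s3": "control", "s4": "control"}
        cm = read_counts(p, design)
        assert cm.feature_ids == ["F1", "F2", "F3"]
        assert cm.samples_for("treated") == ["s1", "s2"]

    def test_negative_entry_rejected(self, tmp_path):
        p = self._write(tmp_path, "feature_id\ts1\ts2\nF1\t1\t-2\n")
        with pytest.raises(CountsError):
            read_counts(p, {"s1": "a", "s2": "b"})

    def test_non_integer_entry_rejected(self, tmp_path):
        p = self._write(tmp_path, "feature_id\ts1\ts2\nF1\t1.5\t2\n")
        with pytest.raises(CountsError, match="non-integer"):
            read_counts(p, {"s1": "a", "s2": "b"})

    def test_design_sample_missing_from_file_is_configuration_error(self, tmp_path):
        p = self._write(tmp_path, "feature_id\ts1\ts2\nF1\t1\t2\n")
        with pytest.raises(CountsError, match="s9"):
            read_counts(p, {"s1": "a", "s9": "b"})

    def test_sample_without_condition_label_rejected(self):
        df = pd.DataFrame({"s1": [1], "s2": [2]}, index=["F1"]).astype("int64")
        with pytest.raises(CountsError, match="condition"):
            CountMatrix(df, {"s1": "a"})


class TestDesign:
    def test_yaml_mapping(self, tmp_path):
        p = tmp_path / "d.yaml"
        p.write_text("s1: treated\ns2: control\n")
        assert read_design(p) == {"s1": "treated", "s2": "control"}

    def test_tsv_two_columns(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("s1\ttreated\ns2\tcontrol\n")
        assert read_design(p) == {"s1": "treated", "s2": "control"}
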