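"""Readers/writers: region strings, GFF3, SEG, DE, Ct, reports."""

import json

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirnome import formats_io as fio
from mirnome.intervals import GenomicInterval


class TestRegionStrings:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("chr10:127622813-135506681", ("chr10", 127622813, 135506681)),
            ("chr7:229794-12384994", ("chr7", 229794, 12384994)),
            ("chr7:229794‐12384994", ("chr7", 229794, 12384994)),  # unicode hyphen
            ("chr14:101464256–102072149", ("chr14", 101464256, 102072149)),  # en-dash
            (" chr1 : 5 - 9 ", ("chr1", 5, 9)),
        ],
    )
    def test_parse_valid(self, s, expected):
        iv = fio.parse_region_string(s)
        assert (iv.chrom, iv.start, iv.end) == expected

    @pytest.mark.parametrize(
        "s", ["chr1:100-99", "chr1:abc-200", "chr1_100_200", "chr1:", "chr1:5.5-9"]
    )
    def test_parse_invalid_raises_naming_token(self, s):
        with pytest.raises(fio.RegionParseError) as exc:
            fio.parse_region_string(s)
        assert "region" in str(exc.value)

    @given(
        chrom=st.sampled_from(["chr1", "chrX", "scaffold_12"]),
        start=st.integers(1, 10**8),
        length=st.integers(0, 10**6),
    )
    @settings(max_examples=100, derandomize=True)
    def test_parse_format_roundtrip_identity(self, chrom, start, length):
        iv = GenomicInterval(chrom, start, start + length)
        s = fio.format_region_string(iv)
        assert fio.parse_region_string(s) == iv
        assert fio.format_region_string(fio.parse_region_string(s)) == s


GFF3_TOY = """##gff-version 3
chr1\t.\tmiRNA_primary_transcript\t1000\t1079\t.\t+\t.\tID=pre-1;Name=syn-mir-1
chr1\t.\tmiRNA\t1010\t1031\t.\t+\t.\tID=mat-1a;Name=syn-miR-1a;Derives_from=pre-1
chr1\t.\tmiRNA\t1050\t1071\t.\t+\t.\tID=mat-1b;Name=syn-miR-1b;Derives_from=pre-1
chr2\t.\tmiRNA_primary_transcript\t500\t579\t.\t-\t.\tID=pre-2;Name=syn-mir-2
chr2\t.\tmiRNA\t510\t531\t.\t-\t.\tID=mat-2;Name=syn-miR-2;Derives_from=pre-2
"""


class TestMirnaGff3:
    def test_toy_two_precursors_three_matures(self, tmp_path):
        path = tmp_path / "toy.gff3"
        path.write_text(GFF3_TOY)
        records = fio.read_mirna_gff3(path)
        assert len(records) == 3
        assert len({r.precursor_name for r in records}) == 2
        mat = {r.mature_name: r for r in records}
        assert mat["syn-miR-1a"].precursor_interval == GenomicInterval(
            "chr1", 1000, 1079, "+"
        )

    def test_missing_derives_from_kept_with_null_precursor(self, tmp_path, caplog):
        path = tmp_path / "orphan.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\t.\tmiRNA\t10\t31\t.\t+\t.\tID=mat-x;Name=syn-miR-x\n"
        )
        with caplog.at_level("WARNING"):
            records = fio.read_mirna_gff3(path)
        assert len(records) == 1 and records[0].precursor_interval is None
        assert any("Derives_from" in r.message for r in caplog.records)

    def test_duplicate_mature_ids_error_lists_them(self, tmp_path):
        path = tmp_path / "dup.gff3"
        path.write_text(
            "##gff-version 3\n"
            "chr1\t.\tmiRNA\t10\t31\t.\t+\t.\tID=mat-x;Name=a\n"
            "chr1\t.\tmiRNA\t50\t71\t.\t+\t.\tID=mat-x;Name=b\n"
        )
        with pytest.raises(fio.FormatError, match="mat-x"):
            fio.read_mirna_gff3(path)

    def test_non_gff3_content_rejected(self, tmp_path):
        path = tmp_path / "junk.gff3"
        path.write_text("this is not gff3 at all\n")
        with pytest.raises(fio.FormatError):
            fio.read_mirna_gff3(path)

    def test_generator_output_roundtrips_to_truth(self, zero_noise_study, tmp_path):
        from mirnome.synthetic_data import write_mirna_gff3

        path = tmp_path / "syn.gff3"
        write_mirna_gff3(zero_noise_study.truth.mirnas, path)
        records = fio.read_mirna_gff3(path)
        assert len(records) == len(zero_noise_study.truth.mirnas)
        by_name = {m.mature_name: m for m in zero_noise_study.truth.mirnas}
        for rec in records:
            truth = by_name[rec.mature_name]
            assert rec.mature_interval == truth.mature_interval
            assert rec.precursor_interval == truth.precursor_interval


class TestTabularReaders:
    def test_seg_toy(self, tmp_path):
        path = tmp_path / "toy.seg"
        path.write_text(
            "sample\tchrom\tstart\tend\tsegment_mean\n"
            "S1\tchr1\t100\t200\t-0.6\n"
            "S1\tchr2\t1\t50\t0.1\n"
            "S2\tchr1\t150\t400\t0.0\n"
        )
        records = fio.read_seg(path)
        assert len(records) == 3
        assert records[0].sample_id == "S1" and records[0].segment_mean == -0.6

    def test_seg_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("sample\tchrom\tstart\tend\n S1\tchr1\t1\t2\n")
        with pytest.raises(fio.FormatError, match="segment_mean"):
            fio.read_seg(path)

    def test_seg_non_numeric_reports_row(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text(
            "sample\tchrom\tstart\tend\tsegment_mean\nS1\tchr1\t1\t2\toops\n"
        )
        with pytest.raises(fio.FormatError, match="segment_mean"):
            fio.read_seg(path)

    def test_de_table_requires_precomputed_adjustment(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene\tlog2fc\tp\nA\t1.0\t0.001\nB\t-2.0\t0.04\n")
        with pytest.raises(fio.FormatError, match="adj_p"):
            fio.read_de_table(path, cohort="x")
        stats = fio.read_de_table(path, cohort="x", compute_bh=True)
        # BH on (0.001, 0.04): 0.002 and 0.04
        assert stats[0].adj_p == pytest.approx(0.002)
        assert stats[1].adj_p == pytest.approx(0.04)

    def test_de_table_na_cells_become_none(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene\tlog2fc\tp\tadj_p\nA\tNA\tNA\tNA\nB\t-1.5\t0.001\t0.004\n")
        stats = fio.read_de_table(path, cohort="lab")
        assert stats[0].log2fc is None and stats[0].adj_p is None
        assert stats[1].log2fc == -1.5

    def test_ct_table_rejects_bad_values(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text(
            "sample,group,assay,replicate,ct\nS1,tumour,T,1,25.0\nS1,tumour,T,2,-3\n"
        )
        with pytest.raises(fio.FormatError, match="Ct"):
            fio.read_ct_table(path)

    def test_ct_table_rejects_unknown_group(self, tmp_path):
        path = tmp_path / "ct.csv"
        path.write_text("sample,group,assay,replicate,ct\nS1,case,T,1,25.0\n")
        with pytest.raises(fio.FormatError, match="group"):
            fio.read_ct_table(path)


class TestReports:
    def test_report_roundtrip_idempotent(self, tmp_path):
        report = {
            "funnel": {"downregulated": 213, "predicted": 186, "gbm_up": 42},
            "genes": ["CDK4", "E2F2"],
            "fraction": 0.4,
        }
        path = tmp_path / "report.json"
        fio.write_report(report, path)
        assert fio.read_report(path) == report
        first = path.read_text()
        fio.write_report(fio.read_report(path), path)
        assert path.read_text() == first

    def test_report_serializes_sets_and_intervals(self, tmp_path):
        path = tmp_path / "r.json"
        fio.write_report(
            {"s": {"b", "a"}, "iv": GenomicInterval("chr1", 5, 9)}, path
        )
        data = json.loads(path.read_text())
        assert data == {"s": ["a", "b"], "iv": "chr1:5-9"}

    def test_generated_files_all_validate(self, study_dir):
        assert len(fio.read_mirna_gff3(study_dir["gff3"])) == 40
        assert len(fio.read_genes_bed(study_dir["bed"])) == 60
        assert len(fio.read_region_table(study_dir["catalog"])) == 12
        assert fio.read_seg(study_dir["seg"])
        assert fio.read_de_table(study_dir["de"], cohort="syn")
        assert len(fio.read_ct_table(study_dir["ct"])) > 0
        assert fio.read_predictions(study_dir["predictions"])
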