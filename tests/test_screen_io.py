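"""Deposit-schema reader/writer, expression table and dataset validation."""

import pandas as pd
import pytest

from sirnascreen import (ControlScheme, ScreenDataset, WellRecord, parse_well,
                         read_expression_table, read_screen_table,
                         validate_dataset, write_screen_table)
from sirnascreen.screen_io import (EMPTY, NTC, SAMPLE, IntegrityError,
                                   RecordError, SchemaError, ValidationError,
                                   format_well, normalize_anno,
                                   write_expression_table)


class TestWellCoordinates:
    @pytest.mark.parametrize("label, expected", [
        ("A1", ("A", 1)), ("A01", ("A", 1)), ("P24", ("P", 24)),
        ("h12", ("H", 12)),
    ])
    def test_parse_valid(self, label, expected):
        assert parse_well(label) == expected

    @pytest.mark.parametrize("label", ["Q25", "A0", "A25", "Z1", "11", "AA1"])
    def test_parse_out_of_range(self, label):
        with pytest.raises(RecordError):
            parse_well(label)

    def test_format_canonical(self):
        assert format_well("A", 1) == "A01"
        assert format_well("P", 24) == "P24"


class TestAnnotationVocabulary:
    @pytest.mark.parametrize("raw, canonical", [
        ("NTC5", NTC), ("ntc3", NTC), ("Sample", SAMPLE), ("SM", SAMPLE),
        ("TLR4", "siTLR4"), ("Renilla", "siRenilla"), ("mock", "lipid_only"),
        ("", EMPTY), ("TAK1", "siMAP3K7"),
    ])
    def test_case_insensitive_normalization(self, raw, canonical):
        assert normalize_anno(raw) == canonical

    def test_unknown_annotation_rejected(self):
        with pytest.raises(RecordError):
            normalize_anno("mystery_control")


class TestRoundTrip:
    def test_write_read_preserves_fields(self, tiny_dataset, tmp_path):
        path = tmp_path / "screen.csv"
        write_screen_table(tiny_dataset, path)
        back = read_screen_table(path, tier="primary")
        assert len(back) == 8
        assert back.equals(tiny_dataset)

    def test_read_write_is_fixed_point(self, tiny_dataset, tmp_path):
        p1 = tmp_path / "a.csv"
        p2 = tmp_path / "b.csv"
        write_screen_table(tiny_dataset, p1)
        write_screen_table(read_screen_table(p1, tier="primary"), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_generator_output_round_trips(self, primary_screen, tmp_path):
        ds, _ = primary_screen
        path = tmp_path / "sim.csv"
        write_screen_table(ds, path)
        assert read_screen_table(path, tier="primary").equals(ds)

    def test_empty_dataset_writes_header_only(self, tmp_path):
        ds = ScreenDataset.from_records("primary", [])
        path = write_screen_table(ds, tmp_path / "empty.csv")
        lines = path.read_text().splitlines()
        assert len(lines) == 1
        assert lines[0].startswith("PlateID,Well,GeneSymbol")


class TestReaderErrors:
    def _write(self, tmp_path, header, rows):
        path = tmp_path / "bad.csv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_missing_mandatory_column_named(self, tmp_path):
        path = self._write(
            tmp_path, "PlateID,Well,GeneSymbol,EntrezID,WellAnno,Rep1R1,Rep1R2",
            ["P1,A02,G1,1,sample,10,10"])
        with pytest.raises(SchemaError, match="siRNAID"):
            read_screen_table(path, tier="primary")

    def test_bad_well_coordinate_reports_row(self, tmp_path):
        path = self._write(
            tmp_path,
            "PlateID,Well,GeneSymbol,EntrezID,siRNAID,WellAnno,Rep1R1,Rep1R2",
            ["P1,B02,G1,1,s1,sample,10,10", "P1,Q25,G2,2,s2,sample,10,10"])
        with pytest.raises(RecordError, match="row 3"):
            read_screen_table(path, tier="primary")

    def test_duplicate_well_rejected(self, tmp_path):
        path = self._write(
            tmp_path,
            "PlateID,Well,GeneSymbol,EntrezID,siRNAID,WellAnno,Replicate,"
            "Rep1R1,Rep1R2",
            ["P1,B02,G1,1,s1,sample,1,10,10",
             "P1,B02,G1,1,s1,sample,1,11,10"])
        with pytest.raises(IntegrityError, match="duplicate"):
            read_screen_table(path, tier="primary")

    def test_unicode_minus_accepted(self, tmp_path):
        path = self._write(
            tmp_path,
            "PlateID,Well,GeneSymbol,EntrezID,siRNAID,WellAnno,Rep1R1,Rep1R2,"
            "Zscore",
            ["P1,B02,G1,1,s1,sample,10,10,−2.3"])
        ds = read_screen_table(path, tier="primary")
        assert ds.frame["zscore"].iloc[0] == pytest.approx(-2.3)


class TestWideSecondaryLayout:
    def test_rep_columns_expand_to_records(self, tmp_path):
        path = tmp_path / "wide.csv"
        path.write_text(
            "PlateID,Well,GeneSymbol,EntrezID,siRNAID,WellAnno,"
            "Rep1R1,Rep1R2,Rep2R1,Rep2R2,Rep3R1,Rep3R2\n"
            "S1,C03,G1,1,AMB-G1-s1,sample,10,5,12,6,8,4\n")
        ds = read_screen_table(path, tier="secondary")
        assert len(ds) == 3
        assert sorted(ds.frame["replicate"]) == [1, 2, 3]
        assert ds.frame.loc[ds.frame["replicate"] == 2, "r1"].iloc[0] == 12


class TestScoreExport:
    def test_score_columns_match_deposit_naming(self, tmp_path):
        records = [
            WellRecord("P1", "B02", "GENEA", 1001, "s1", "sample",
                       True, "LPS", 100.0, 50.0, 1),
            WellRecord("P1", "B03", "GENEB", 1002, "s2", "sample",
                       True, "LPS", 200.0, 50.0, 1),
            WellRecord("P1", "A10", "", None, "D-001210-05", "NTC",
                       True, "LPS", 150.0, 50.0, 1),
        ]
        ds = ScreenDataset.from_records("primary", records)
        ds.frame["zscore"] = [-2.3, 0.5, 0.0]
        ds.frame["activity_score"] = [75, 0, 0]
        ds.frame["outcome"] = [2, 1, 4]
        path = write_screen_table(ds, tmp_path / "scored.csv",
                                  include_scores=True)
        expected = (
            "PlateID,Well,GeneSymbol,EntrezID,siRNAID,WellAnno,Replicate,"
            "Stimulated,Stimulus,Rep1R1,Rep1R2,Rep1R1/R2,Zscore,"
            "ActivityScore,Outcome\n"
            "P1,B02,GENEA,1001,s1,sample,1,true,LPS,100,50,2,-2.3,75,2\n"
            "P1,B03,GENEB,1002,s2,sample,1,true,LPS,200,50,4,0.5,0,1\n"
            "P1,A10,,,D-001210-05,NTC,1,true,LPS,150,50,3,0,0,4\n")
        assert path.read_text() == expected


class TestExpressionTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "expr.csv"
        header = ("ProbeID,GeneSymbol,Log2Signal_noLPS,DetectionPval_noLPS,"
                  "Log2Signal_LPS,DetectionPval_LPS")
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_both_conditions_stored(self, tmp_path):
        path = self._write(tmp_path, ["pr1,G1,8.0,0.03,9.0,0.5"])
        expr = read_expression_table(path)
        assert expr.detection_p("G1") == (0.03, 0.5)

    def test_probes_collapse_by_min_p(self, tmp_path):
        path = self._write(tmp_path, ["pr1,G1,8.0,0.2,9.0,0.4",
                                      "pr2,G1,7.0,0.05,8.0,0.6"])
        expr = read_expression_table(path)
        assert expr.detection_p("G1") == (0.05, 0.4)

    def test_p_out_of_range_rejected(self, tmp_path):
        path = self._write(tmp_path, ["pr1,G1,8.0,1.5,9.0,0.5"])
        with pytest.raises(ValidationError):
            read_expression_table(path)

    def test_single_condition_rejected(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("GeneSymbol,DetectionPval_noLPS\nG1,0.05\n")
        with pytest.raises((SchemaError, ValidationError)):
            read_expression_table(path)

    def test_round_trip(self, tmp_path):
        path = self._write(tmp_path, ["pr1,G1,8.0,0.03,9.0,0.5",
                                      "pr2,G2,5.0,0.9,5.5,0.8"])
        expr = read_expression_table(path)
        out = tmp_path / "out.csv"
        write_expression_table(expr, out)
        back = read_expression_table(out)
        pd.testing.assert_frame_equal(back.frame, expr.frame)


class TestValidateDataset:
    def test_generator_plate_is_clean(self, primary_screen):
        ds, _ = primary_screen
        assert validate_dataset(ds).ok

    def test_three_well_smartpool_flagged(self, tiny_dataset):
        ds = ScreenDataset(
            tier="primary", frame=tiny_dataset.frame.iloc[1:].copy(),
            scheme=tiny_dataset.scheme)
        report = validate_dataset(ds)
        assert any("replicate count 3 != 4" in v for v in report.violations)

    def test_control_minimum_cited(self, primary_screen):
        ds, _ = primary_screen
        frame = ds.plate(ds.plates()[0]).copy()
        # leave only 2 of the siRenilla wells
        drop = frame[(frame["well_anno"] == "siRenilla")].index[:1]
        sub = ScreenDataset(tier="primary",
                            frame=frame.drop(index=drop),
                            scheme=ds.scheme)
        report = validate_dataset(sub)
        assert any("at-least-3" in v and "siRenilla" in v
                   for v in report.violations)

    def test_sample_outside_layout_flagged(self):
        rec = WellRecord("P1", "A10", "G1", 1, "s1", "sample", True, "LPS",
                         10.0, 10.0, 1)
        ds = ScreenDataset.from_records("primary", [rec])
        report = validate_dataset(ds)
        assert any("outside sample columns" in v for v in report.violations)


class TestControlScheme:
    def test_primary_layout_constants(self):
        s = ControlScheme.primary_default()
        assert s.sample_columns == frozenset(range(2, 10)) | frozenset(
            range(12, 24))
        assert s.control_columns == {10, 11, 24}
        assert "A01" in s.excluded_wells

    def test_secondary_outer_frame_excluded(self):
        s = ControlScheme.secondary_default()
        assert {"A01", "B12", "P24", "H01", "H24"} <= s.excluded_wells
        assert s.control_columns == {11, 12, 13, 22}

    def test_overlapping_columns_rejected(self):
        with pytest.raises(ValidationError):
            ControlScheme("primary", frozenset({2, 3}), frozenset({3, 4}))

    def test_yaml_round_trip(self, tmp_path):
        s = ControlScheme.secondary_default()
        s.to_yaml(tmp_path / "scheme.yaml")
        assert ControlScheme.from_yaml(tmp_path / "scheme.yaml") == s
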