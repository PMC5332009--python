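"""Threshold hit calling, expression filter, candidate selection, tertiary
confirmation and deposit activity-score binning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sirnascreen import (activity_score, call_primary_hits, expression_filter,
                         select_secondary_candidates, tertiary_classify)
from sirnascreen.hit_calling import (HitCallingError, hit_counts,
                                     read_gene_list, tertiary_frame)
from sirnascreen.screen_io import ExpressionTable


def primary_oracle(z):
    """Independently coded piecewise binning of the primary deposit text."""
    if z > 5 or z < -2.5:
        return 100
    if z > 4 or z < -2:
        return 75
    if z > 2.8 or z < -1.5:
        return 50
    if z > 1 or z < -1:
        return 25
    return 0


def secondary_oracle(z):
    if z > 2.5 or z < -2:
        return 100
    if z > 2 or z < -1.5:
        return 75
    if z > 1.5 or z < -1:
        return 50
    if z > 1 or z < -0.75:
        return 25
    return 0


class TestActivityScore:
    def test_printed_tlr4_score_bins_to_75(self):
        score, outcome = activity_score(-2.3, tier="primary")
        assert score == 75 and outcome == 2

    def test_zero_is_inactive(self):
        assert activity_score(0.0, tier="primary") == (0, 1)

    def test_strict_boundary_at_positive_cut(self):
        # exactly 2.8: ">2.8" fails but ">1" holds
        assert activity_score(2.8, tier="primary")[0] == 25

    def test_controls_bypass(self):
        assert activity_score(9.9, tier="primary", is_control=True) == (0, 4)

    @pytest.mark.parametrize("tier, oracle", [
        ("primary", primary_oracle), ("secondary", secondary_oracle)])
    def test_exhaustive_grid_matches_piecewise_oracle(self, tier, oracle):
        grid = np.linspace(-6, 6, 10_000)
        for z in grid:
            score, outcome = activity_score(float(z), tier=tier)
            assert score == oracle(z)
            assert outcome == (2 if score >= 50 else 1)

    def test_monotone_in_each_tail(self):
        zs = np.linspace(0, -6, 500)
        scores = [activity_score(float(z), "primary")[0] for z in zs]
        assert all(b >= a for a, b in zip(scores, scores[1:]))


class TestCallPrimaryHits:
    def test_inclusive_boundaries(self):
        table = call_primary_hits({"A": -1.6, "B": -1.5, "C": 2.8, "D": 0.0})
        assert table.loc["A", "call"] == "positive_regulator"
        assert table.loc["B", "call"] == "positive_regulator"
        assert table.loc["C", "call"] == "negative_regulator"
        assert table.loc["D", "call"] == "none"

    def test_strict_boundaries_flag(self):
        table = call_primary_hits({"B": -1.5, "C": 2.8},
                                  strict_boundaries=True)
        assert (table["call"] == "none").all()

    def test_zero_scores_give_zero_hits(self):
        table = call_primary_hits({g: 0.0 for g in "ABCDE"})
        counts = hit_counts(table)
        assert counts["positive_regulator"] == counts[
            "negative_regulator"] == 0

    def test_exclusion_list_flags_not_calls(self):
        table = call_primary_hits({"TLR4": -2.3, "NOVEL1": -2.3},
                                  exclusions=["TLR4"])
        assert table.loc["TLR4", "call"] == "none"
        assert table.loc["TLR4", "excluded_reason"] == "canonical_pathway"
        assert table.loc["NOVEL1", "call"] == "positive_regulator"

    @given(st.floats(-3.0, -1.5), st.lists(st.floats(-4, 4), min_size=3,
                                           max_size=20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_threshold_monotone(self, theta, scores):
        """Lowering theta_pos (more negative) never adds a positive hit."""
        scores = {f"G{i}": s for i, s in enumerate(scores)}
        loose = call_primary_hits(scores, theta_pos=theta)
        tight = call_primary_hits(scores, theta_pos=theta - 0.5)
        loose_pos = set(loose.index[loose["call"] == "positive_regulator"])
        tight_pos = set(tight.index[tight["call"] == "positive_regulator"])
        assert tight_pos <= loose_pos


def _expr(p_by_gene):
    frame = pd.DataFrame(
        {"p_noLPS": {g: p[0] for g, p in p_by_gene.items()},
         "p_LPS": {g: p[1] for g, p in p_by_gene.items()}})
    frame.index.name = "gene_symbol"
    return ExpressionTable(frame=frame)


class TestExpressionFilter:
    def test_one_condition_suffices(self):
        hits = call_primary_hits({"A": -2.0})
        out = expression_filter(hits, _expr({"A": (0.05, 0.5)}))
        assert out.loc["A", "call"] == "positive_regulator"

    def test_strict_boundary_at_p_cut(self):
        hits = call_primary_hits({"A": -2.0})
        out = expression_filter(hits, _expr({"A": (0.10, 0.10)}))
        assert out.loc["A", "call"] == "none"
        assert out.loc["A", "excluded_reason"] == "not_expressed"

    def test_clearly_absent_gene_removed(self):
        hits = call_primary_hits({"A": 3.0})
        out = expression_filter(hits, _expr({"A": (0.5, 0.5)}))
        assert out.loc["A", "excluded_reason"] == "not_expressed"

    def test_unmeasured_gene_passes_with_warning_flag(self):
        hits = call_primary_hits({"A": -2.0})
        out = expression_filter(hits, _expr({"B": (0.05, 0.5)}))
        assert out.loc["A", "call"] == "positive_regulator"
        assert bool(out.loc["A", "unmeasured_expression"])

    def test_uncalled_genes_untouched(self):
        hits = call_primary_hits({"A": 0.0})
        out = expression_filter(hits, _expr({"A": (0.9, 0.9)}))
        assert out.loc["A", "excluded_reason"] == "none"


class TestSelectSecondaryCandidates:
    def test_rank_selection(self):
        scores = {"A": -2.0, "B": -1.0, "C": 0.0, "D": 1.0, "E": 2.0}
        pos, neg = select_secondary_candidates(scores, n_pos=2, n_neg=1)
        assert pos == ["A", "B"] and neg == ["E"]

    def test_zero_requested_gives_empty(self):
        pos, neg = select_secondary_candidates({"A": -1.0, "B": 1.0},
                                               n_pos=0, n_neg=1)
        assert pos == [] and neg == ["B"]

    def test_exclusions_removed_before_ranking(self):
        scores = {"PSMA1": -3.0, "A": -2.0, "B": -1.0, "C": 2.0}
        pos, neg = select_secondary_candidates(scores, n_pos=2, n_neg=1,
                                               exclusions=["PSMA1"])
        assert pos == ["A", "B"] and neg == ["C"]
        assert len(pos) == 2 and len(neg) == 1

    def test_over_request_errors(self):
        with pytest.raises(HitCallingError):
            select_secondary_candidates({"A": 0.0, "B": 1.0}, n_pos=2,
                                        n_neg=1)

    def test_tie_break_by_support_then_symbol(self):
        scores = {"TIE1": -2.0, "TIE2": -2.0, "Z": 0.0}
        sirna = pd.DataFrame({
            "gene_symbol": ["TIE1"] * 6 + ["TIE2"] * 6,
            "score": [-2.0] * 2 + [0.0] * 4 + [-2.0] * 5 + [0.0] * 1,
        })
        pos, _ = select_secondary_candidates(scores, n_pos=1, n_neg=1,
                                             sirna_scores=sirna)
        assert pos == ["TIE2"]  # 5 supporting siRNAs beats 2
        # without support information the lexicographic fallback decides
        pos2, _ = select_secondary_candidates(scores, n_pos=1, n_neg=1)
        assert pos2 == ["TIE1"]

    def test_gene_list_file(self, tmp_path):
        path = tmp_path / "excl.txt"
        path.write_text("# proteasome\nPSMA1\n\nPSMB5\n")
        assert read_gene_list(path) == ["PSMA1", "PSMB5"]


class TestTertiaryClassify:
    def test_confirmation_via_non_lps_stimulus(self):
        readouts = pd.DataFrame(
            {"LPS": [0.5], "P3C": [0.65], "PGN": [0.9]}, index=["G1"])
        ntc = {"LPS": 1.0, "P3C": 1.0, "PGN": 1.0}
        res = tertiary_classify(readouts, ntc)[0]
        assert res.confirmed_positive
        assert res.supporting_stimuli == ["P3C"]

    def test_lps_alone_does_not_confirm(self):
        readouts = pd.DataFrame({"LPS": [0.4], "P3C": [0.95]}, index=["G1"])
        res = tertiary_classify(readouts, {"LPS": 1.0, "P3C": 1.0})[0]
        assert not res.confirmed_positive and not res.confirmed_negative

    def test_flat_fractions_unconfirmed(self):
        readouts = pd.DataFrame(
            {s: [1.0] for s in ("LPS", "P3C", "PGN", "R848")}, index=["G1"])
        ntc = {s: 1.0 for s in ("LPS", "P3C", "PGN", "R848")}
        res = tertiary_classify(readouts, ntc)[0]
        assert not res.confirmed_positive and not res.confirmed_negative

    def test_strict_cut_boundaries(self):
        # exactly 30% reduction / 25% increase are NOT ">30%" / ">25%"
        readouts = pd.DataFrame({"LPS": [1.0, 1.0], "P3C": [0.70, 1.25]},
                                index=["G1", "G2"])
        ntc = {"LPS": 1.0, "P3C": 1.0}
        res = tertiary_classify(readouts, ntc)
        assert not res[0].confirmed_positive
        assert not res[1].confirmed_negative

    def test_negative_confirmation(self):
        readouts = pd.DataFrame({"LPS": [2.0], "R848": [1.3]}, index=["G1"])
        res = tertiary_classify(readouts, {"LPS": 1.0, "R848": 1.0})[0]
        assert res.confirmed_negative and not res.confirmed_positive

    def test_missing_ntc_stimulus_dropped(self):
        readouts = pd.DataFrame({"LPS": [1.0], "P3C": [0.5], "PGN": [0.5]},
                                index=["G1"])
        res = tertiary_classify(readouts, {"LPS": 1.0, "P3C": 1.0,
                                           "PGN": 0.0})[0]
        assert res.dropped_stimuli == ["PGN"]
        assert res.confirmed_positive  # via P3C only

    def test_frame_export_columns(self):
        readouts = pd.DataFrame({"LPS": [0.5], "P3C": [0.6]}, index=["G1"])
        frame = tertiary_frame(tertiary_classify(
            readouts, {"LPS": 1.0, "P3C": 1.0}))
        assert {"GeneSymbol", "F_LPS", "F_P3C", "ConfirmedPositive",
                "ConfirmedNegative"} <= set(frame.columns)
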