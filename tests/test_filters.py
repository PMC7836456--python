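"""Hit filtering: pan-essential, multi-line, bidirectional, normal contrast."""

import numpy as np
import pandas as pd
import pytest

from isoscreen import filters
from isoscreen.promoters import PromoterRecord


def score_table(essential_fdrs: dict[str, float], gene_of=None):
    """Build a minimal per-line transcript score table."""
    pids = sorted(essential_fdrs)
    gene_of = gene_of or {}
    return pd.DataFrame(
        {
            "promoter_id": pids,
            "gene_id": [gene_of.get(p, p.split("_")[0]) for p in pids],
            "n_guides": 6,
            "rho": 0.5,
            "p_value": [essential_fdrs[p] for p in pids],
            "fdr": [essential_fdrs[p] for p in pids],
            "essential": [essential_fdrs[p] <= 0.1 for p in pids],
            "direction": "depletion",
        }
    )


@pytest.fixture
def three_line_scores():
    base = {"A_P1": 0.9, "B_P1": 0.9, "C_P1": 0.9, "PAN_P1": 0.9}
    return {
        "GC1": score_table({**base, "A_P1": 0.01, "B_P1": 0.02, "PAN_P1": 0.001}),
        "GC2": score_table({**base, "A_P1": 0.05, "PAN_P1": 0.001}),
        "NORM": score_table({**base, "C_P1": 0.01}),
    }


class TestPanEssential:
    def test_gene_in_list_flagged(self):
        df = score_table({"PAN_P1": 0.01})
        assert filters.flag_pan_essential(df, {"PAN"}).tolist() == [True]

    def test_case_mismatch_logged_not_flagged(self, caplog):
        df = score_table({"Pan_P1": 0.01}, gene_of={"Pan_P1": "Pan"})
        with caplog.at_level("WARNING"):
            flags = filters.flag_pan_essential(df, {"PAN"})
        assert flags.tolist() == [False]
        assert any("case-insensitively" in r.message for r in caplog.records)

    def test_empty_list_warns_all_false(self, caplog):
        df = score_table({"A_P1": 0.01})
        with caplog.at_level("WARNING"):
            flags = filters.flag_pan_essential(df, set())
        assert not flags.any()

    def test_flagged_transcripts_retained_in_hit_table(self, three_line_scores):
        hits = filters.intersect_lines(
            three_line_scores, normal_line="NORM", pan_list={"PAN"}
        )
        row = hits.set_index("promoter_id").loc["PAN_P1"]
        assert row["pan_essential"] and row["n_lines"] == 2 and not row["final_hit"]


class TestIntersectLines:
    def test_two_of_n_lines_retained(self, three_line_scores):
        hits = filters.intersect_lines(
            three_line_scores, min_lines=2, normal_line="NORM"
        ).set_index("promoter_id")
        assert hits.at["A_P1", "n_lines"] == 2 and hits.at["A_P1", "multi_line"]
        assert hits.at["B_P1", "n_lines"] == 1 and not hits.at["B_P1", "multi_line"]

    def test_normal_only_hit_excluded_from_count(self, three_line_scores):
        hits = filters.intersect_lines(three_line_scores, normal_line="NORM").set_index("promoter_id")
        assert hits.at["C_P1", "n_lines"] == 0
        assert hits.at["C_P1", "normal_line_essential"]

    def test_essential_nowhere_not_a_candidate(self, three_line_scores):
        hits = filters.intersect_lines(three_line_scores, normal_line="NORM")
        extra = hits.set_index("promoter_id")
        # B scores in one line only; a promoter scoring nowhere is no candidate
        assert not extra.at["C_P1", "final_hit"]

    def test_inconsistent_universes_united(self, three_line_scores, caplog):
        partial = dict(three_line_scores)
        partial["GC2"] = partial["GC2"][partial["GC2"]["promoter_id"] != "B_P1"]
        with caplog.at_level("WARNING"):
            hits = filters.intersect_lines(partial, normal_line="NORM")
        assert "B_P1" in set(hits["promoter_id"])


def tss_set(positions: dict[str, int], gene_of=None):
    gene_of = gene_of or {}
    return [
        PromoterRecord(pid, gene_of.get(pid, pid.split("_")[0]), "chr1", pos, "+")
        for pid, pos in positions.items()
    ]


class TestBidirectionalFilter:
    def _hits(self):
        scores = {"GC1": score_table({"A_P1": 0.01, "B_P1": 0.01, "C_P1": 0.01})}
        return filters.intersect_lines(scores, min_lines=1)

    @pytest.mark.parametrize("distance, flagged", [(1999, True), (2001, False), (2000, False)])
    def test_distance_boundary_strict(self, distance, flagged):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000, "C_P1": 90_000,
                       "X_P1": 10_000 + distance})
        out = filters.bidirectional_filter(hits, tss, max_distance=2000).set_index("promoter_id")
        assert (out.at["A_P1", "bidirectional_partner"] == "X_P1") is flagged

    def test_pan_essential_partner_clears_final_hit(self):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000, "C_P1": 90_000, "ESS_P1": 11_500})
        out = filters.bidirectional_filter(
            hits, tss, max_distance=2000, pan_list={"ESS"}
        ).set_index("promoter_id")
        assert out.at["A_P1", "partner_pan_essential"]
        assert not out.at["A_P1", "final_hit"]
        assert out.at["B_P1", "final_hit"]

    def test_non_pan_partner_flags_but_keeps_hit(self):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000, "C_P1": 90_000, "Y_P1": 11_500})
        out = filters.bidirectional_filter(hits, tss, max_distance=2000).set_index("promoter_id")
        assert out.at["A_P1", "bidirectional_partner"] == "Y_P1"
        assert out.at["A_P1", "final_hit"]

    def test_no_neighbor_no_partner(self):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000, "C_P1": 90_000})
        out = filters.bidirectional_filter(hits, tss).set_index("promoter_id")
        assert out["bidirectional_partner"].isna().all()

    def test_zero_distance_disables_filter(self):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 10_001, "C_P1": 10_002})
        out = filters.bidirectional_filter(hits, tss, max_distance=0)
        assert out["bidirectional_partner"].isna().all()
        assert (out["final_hit"] == hits["final_hit"]).all()

    def test_missing_promoter_unassessed_but_retained(self, caplog):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000})  # C_P1 absent
        with caplog.at_level("WARNING"):
            out = filters.bidirectional_filter(hits, tss).set_index("promoter_id")
        assert not out.at["C_P1", "bidirectional_assessed"]
        assert out.at["C_P1", "final_hit"]

    def test_idempotent(self):
        hits = self._hits()
        tss = tss_set({"A_P1": 10_000, "B_P1": 50_000, "C_P1": 90_000, "ESS_P1": 11_500})
        once = filters.bidirectional_filter(hits, tss, pan_list={"ESS"})
        twice = filters.bidirectional_filter(once, tss, pan_list={"ESS"})
        pd.testing.assert_frame_equal(once, twice)


class TestContrastNormal:
    def test_normal_essential_ranks_last_within_breadth(self):
        scores = {
            "GC1": score_table({"A_P1": 0.01, "B_P1": 0.01}),
            "GC2": score_table({"A_P1": 0.01, "B_P1": 0.01}),
            "NORM": score_table({"A_P1": 0.01, "B_P1": 0.9}),
        }
        hits = filters.intersect_lines(scores, normal_line="NORM")
        out = filters.contrast_normal(hits)
        assert out["promoter_id"].tolist()[0] == "B_P1"
        assert out.set_index("promoter_id").at["B_P1", "gc_selective"]
        assert not out.set_index("promoter_id").at["A_P1", "gc_selective"]

    def test_empty_hit_table(self):
        scores = {"GC1": score_table({"A_P1": 0.9})}
        hits = filters.intersect_lines(scores)
        out = filters.contrast_normal(hits)
        assert not out["final_hit"].any()

    def test_all_normal_essential_still_emitted(self):
        scores = {
            "GC1": score_table({"A_P1": 0.01}),
            "NORM": score_table({"A_P1": 0.01}),
        }
        hits = filters.intersect_lines(scores, normal_line="NORM")
        out = filters.contrast_normal(hits)
        assert len(out) == 1 and not out["gc_selective"].any()

    def test_filtering_pipeline_idempotent(self, three_line_scores):
        hits = filters.intersect_lines(three_line_scores, normal_line="NORM", pan_list={"PAN"})
        tss = tss_set({p: 10_000 + 40_000 * i for i, p in enumerate(sorted(hits["promoter_id"]))})
        once = filters.contrast_normal(filters.bidirectional_filter(hits, tss))
        twice = filters.contrast_normal(filters.bidirectional_filter(once, tss))
        pd.testing.assert_frame_equal(once, twice)
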