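"""Bin conversion, category totals, ranking and reports."""

import itertools
import random

import pandas as pd
import pytest

import mimorank as mr
from mimorank.errors import (
    BinningError,
    CalibrationError,
    CompletenessError,
    ConfigurationError,
)
from mimorank.fixtures import GOLDEN_SHORTLIST, golden_scorecards
from mimorank.propensity import RawScores
from mimorank.scoring import (
    CATEGORY_MEMBERS,
    NUMERIC_PARAMETERS,
    Scorecard,
    report_frame,
)


class TestConvertRaw:
    @pytest.mark.parametrize(
        "param, value, weight",
        [
            ("MHC_II", 2.0, 58),
            ("MHC_II", 4.66, 39),
            ("MHC_II", 9.29, 20),
            ("MHC_I", 30, 42),
            ("MHC_I", 200, 28),
            ("MHC_I", 5500, 14),
            ("SA", 2.80, 34),
            ("SA", 1.50, 12),
            ("HY", 3.50, 29),
            ("HY", 3.00, 19),
            ("HY", 2.00, 9),
            ("AT", 1.0, 19),
            ("AT", 0.999, 13),
            ("LE", 6.00, 12),
            ("LE", 3.00, 8),
            ("LE", 0.20, 4),
            ("RNA2", False, 6),
            ("RNA2", True, 4),
        ],
    )
    def test_bin_assignments(self, param, value, weight):
        assert mr.convert_raw(param, value) == weight

    def test_values_below_lowest_edge_are_clamped(self):
        assert mr.convert_raw("SA", 0.8) == 12
        assert mr.convert_raw("MHC_II", 0.005) == 58
        assert mr.convert_raw("HY", -1.0) == 9

    def test_clamping_can_be_disabled(self):
        table = mr.default_conversion_table(clamp=False)
        with pytest.raises(BinningError):
            mr.convert_raw("SA", 0.8, table)

    def test_non_finite_rejected(self):
        with pytest.raises(BinningError):
            mr.convert_raw("SA", float("nan"))

    def test_unknown_parameter(self):
        with pytest.raises(ConfigurationError):
            mr.convert_raw("TAP", 1.0)

    def test_monotone_across_every_boundary(self, conversion_table):
        """More favourable raw values never map to a smaller weight."""
        eps = 1e-6
        for param in NUMERIC_PARAMETERS:
            bins = conversion_table.bins[param]
            edges = sorted({b.lower for b in bins if b.lower != float("-inf")})
            sweep = sorted(
                {e + d for e in edges for d in (-eps, 0.0, eps)} | {min(edges) - 1, 1e6}
            )
            weights = [mr.convert_raw(param, v) for v in sweep]
            if conversion_table.lower_is_better[param]:
                assert weights == sorted(weights, reverse=True)
            else:
                assert weights == sorted(weights)


class TestCalibration:
    def test_reference_sa_range_reproduces_interior_boundaries(self):
        bins = mr.calibrate_equal_width_bins(1.294, 3.149, 3)
        assert bins[0][1] == pytest.approx(1.912, abs=1e-3)
        assert bins[1][1] == pytest.approx(2.530, abs=1e-3)

    def test_simple_terciles(self):
        assert mr.calibrate_equal_width_bins(0, 3, 3) == [(0, 1), (1, 2), (2, 3)]

    def test_equal_widths(self):
        bins = mr.calibrate_equal_width_bins(0.7, 9.4, 4)
        widths = {round(hi - lo, 12) for lo, hi in bins}
        assert len(widths) == 1

    def test_degenerate_range(self):
        with pytest.raises(CalibrationError):
            mr.calibrate_equal_width_bins(2.0, 2.0)

    def test_k_below_two(self):
        with pytest.raises(ConfigurationError):
            mr.calibrate_equal_width_bins(0, 1, 1)


def card(**converted):
    sc = Scorecard(candidate_id="c", converted=converted)
    return mr.category_totals(sc, require_all=False)


class TestCategoryTotals:
    def test_human_tcell_maximum(self):
        sc = card(MHC_II_human=58, MHC_I_human=42)
        assert sc.totals["tcell_human"] == 100

    def test_mouse_tcell_sum(self):
        sc = card(MHC_II_mouse=58, MHC_I_mouse=28)
        assert sc.totals["tcell_mouse"] == 86

    def test_bcell_sum(self):
        sc = card(SA=34, HY=29, AT=13, LE=12, RNA2=6)
        assert sc.totals["bcell"] == 94

    def test_partial_category_names_missing_field(self):
        with pytest.raises(CompletenessError, match="MHC_I_human"):
            card(MHC_II_human=58)

    def test_category_maxima_iff_all_top_bins(self, conversion_table):
        top = {p: conversion_table.bins[p][0].weight for p in NUMERIC_PARAMETERS}
        full_top = card(
            MHC_II_human=top["MHC_II"],
            MHC_I_human=top["MHC_I"],
            MHC_II_mouse=top["MHC_II"],
            MHC_I_mouse=top["MHC_I"],
            SA=top["SA"],
            HY=top["HY"],
            AT=top["AT"],
            LE=top["LE"],
            RNA2=conversion_table.rna_no_hairpin_weight,
        )
        assert full_top.totals == {
            "tcell_human": 100,
            "tcell_mouse": 100,
            "bcell": 100,
        }
        # dropping any single member below its top bin breaks the maximum
        demoted = card(
            MHC_II_human=39, MHC_I_human=top["MHC_I"], MHC_II_mouse=top["MHC_II"],
            MHC_I_mouse=top["MHC_I"], SA=top["SA"], HY=top["HY"], AT=top["AT"],
            LE=top["LE"], RNA2=conversion_table.rna_no_hairpin_weight,
        )
        assert demoted.totals["tcell_human"] < 100

    def test_totals_never_exceed_100(self, conversion_table):
        rng = random.Random(17)
        for _ in range(200):
            raw = RawScores(
                candidate_id="r",
                sa=rng.uniform(0, 5),
                hy=rng.uniform(-2, 8),
                at=rng.uniform(0.5, 1.5),
                le=rng.uniform(0, 8),
                rna_hairpin=rng.random() < 0.5,
                mhc1_human=rng.uniform(1, 6000),
                mhc2_human=rng.uniform(0.01, 20),
                mhc1_mouse=rng.uniform(1, 6000),
                mhc2_mouse=rng.uniform(0.01, 20),
            )
            sc = mr.score_raw(raw)
            assert all(v <= 100 for v in sc.totals.values())
            assert sc.grand_total == sum(sc.totals.values())


class TestGoldenRows:
    def test_all_23_reference_rows_total_exactly(self, golden_rows):
        """Converted weights drawn from the reference shortlist reproduce the
        reference category totals with no tolerance."""
        for row, sc in zip(golden_rows, golden_scorecards()):
            assert sc.totals["tcell_human"] == sum(row.human_tcell)
            assert sc.totals["tcell_mouse"] == sum(row.mouse_tcell)
            assert sc.totals["bcell"] == sum(row.bcell)

    def test_raw_values_in_implied_bins_reproduce_totals(self, golden_rows):
        """Feeding raw values from the bins implied by the reference weights
        yields the reference totals exactly."""
        # representative raw value inside each bin, per parameter and weight
        representative = {
            ("MHC_II", 58): 2.0, ("MHC_II", 39): 6.0, ("MHC_II", 20): 15.0,
            ("MHC_I", 42): 30.0, ("MHC_I", 28): 200.0, ("MHC_I", 14): 1200.0,
            ("SA", 34): 2.8, ("SA", 23): 2.2, ("SA", 12): 1.5,
            ("HY", 29): 3.5, ("HY", 19): 3.0, ("HY", 9): 2.0,
            ("AT", 19): 1.2, ("AT", 13): 0.9,
            ("LE", 12): 6.0, ("LE", 8): 3.0, ("LE", 4): 0.2,
        }
        for row in golden_rows:
            raw = RawScores(
                candidate_id=row.display_id,
                mhc2_human=representative[("MHC_II", row.human_tcell[0])],
                mhc1_human=representative[("MHC_I", row.human_tcell[1])],
                mhc2_mouse=representative[("MHC_II", row.mouse_tcell[0])],
                mhc1_mouse=representative[("MHC_I", row.mouse_tcell[1])],
                sa=representative[("SA", row.bcell[0])],
                hy=representative[("HY", row.bcell[1])],
                at=representative[("AT", row.bcell[2])],
                le=representative[("LE", row.bcell[3])],
                rna_hairpin=(row.bcell[4] == 4),
            )
            sc = mr.score_raw(raw)
            assert sc.totals["tcell_human"] == sum(row.human_tcell)
            assert sc.totals["tcell_mouse"] == sum(row.mouse_tcell)
            assert sc.totals["bcell"] == sum(row.bcell)


def full_card(cid, mhc2=58, mhc1=42, sa=34, hy=29, at=19, le=12, rna2=6):
    return card_with_id(
        cid,
        MHC_II_human=mhc2, MHC_I_human=mhc1, MHC_II_mouse=mhc2, MHC_I_mouse=mhc1,
        SA=sa, HY=hy, AT=at, LE=le, RNA2=rna2,
    )


def card_with_id(cid, **converted):
    sc = Scorecard(candidate_id=cid, converted=converted)
    return mr.category_totals(sc)


class TestRanking:
    def test_priority_breaks_grand_total_ties(self):
        # equal totals, but one is stronger on the top-priority parameter
        a = card_with_id(
            "a", MHC_II_human=58, MHC_I_human=28, MHC_II_mouse=20, MHC_I_mouse=28,
            SA=12, HY=9, AT=13, LE=4, RNA2=4,
        )
        b = card_with_id(
            "b", MHC_II_human=39, MHC_I_human=42, MHC_II_mouse=20, MHC_I_mouse=28,
            SA=12, HY=9, AT=13, LE=9, RNA2=4,
        )
        assert a.grand_total == b.grand_total
        ranked = mr.rank_candidates([b, a])
        assert [sc.candidate_id for sc in ranked] == ["a", "b"]

    def test_single_candidate(self):
        ranked = mr.rank_candidates([full_card("only")])
        assert len(ranked) == 1 and ranked.entries[0].candidate_id == "only"

    def test_permutation_invariance(self):
        cards = [full_card(f"c{i}", sa=[34, 23, 12][i % 3], le=[12, 8, 4][i % 3]) for i in range(9)]
        reference = [sc.candidate_id for sc in mr.rank_candidates(cards)]
        rng = random.Random(3)
        for _ in range(5):
            shuffled = cards[:]
            rng.shuffle(shuffled)
            assert [sc.candidate_id for sc in mr.rank_candidates(shuffled)] == reference

    def test_descending_in_ranking_key(self):
        cards = [full_card(f"c{i}", sa=s) for i, s in enumerate([12, 34, 23])]
        ranked = mr.rank_candidates(cards)
        totals = [sc.grand_total for sc in ranked]
        assert totals == sorted(totals, reverse=True)

    def test_id_breaks_remaining_ties(self):
        cards = [full_card("z"), full_card("a")]
        ranked = mr.rank_candidates(cards)
        assert [sc.candidate_id for sc in ranked] == ["a", "z"]

    def test_incomplete_scorecard_rejected(self):
        sc = Scorecard(candidate_id="x", converted={"SA": 34})
        with pytest.raises(CompletenessError):
            mr.rank_candidates([sc])

    def test_per_table_key(self):
        a = full_card("a", mhc2=58)
        b = full_card("b", mhc2=20)
        ranked = mr.rank_candidates([b, a], key="tcell_human")
        assert ranked.entries[0].candidate_id == "a"


class TestShortlist:
    def test_top_20_of_many(self):
        cards = [full_card(f"c{i:04d}", sa=34 if i < 30 else 12) for i in range(100)]
        top = mr.shortlist(mr.rank_candidates(cards), 20)
        assert len(top) == 20

    def test_n_larger_than_list(self):
        ranked = mr.rank_candidates([full_card("a"), full_card("b")])
        assert len(mr.shortlist(ranked, 50)) == 2

    def test_idempotent(self):
        ranked = mr.rank_candidates([full_card(f"c{i}") for i in range(30)])
        once = mr.shortlist(ranked, 10)
        twice = mr.shortlist(once, 10)
        assert [s.candidate_id for s in once] == [s.candidate_id for s in twice]

    def test_invalid_n(self):
        with pytest.raises(ConfigurationError):
            mr.shortlist(mr.rank_candidates([full_card("a")]), 0)


class TestReports:
    def test_bcell_style_has_ten_columns_in_order(self):
        ranked = mr.rank_candidates([full_card("a")])
        frame = report_frame(ranked, "bcell")
        assert list(frame.columns) == [
            "Sequence ID", "Full sequence", "KRAS mutation", "Modified residue",
            "SA", "HY", "AT", "LE", "RNA 2", "Total score",
        ]

    def test_write_then_reread_preserves_numbers(self, tmp_path):
        cards = [full_card("a"), full_card("b", sa=23, hy=19)]
        ranked = mr.rank_candidates(cards)
        path = tmp_path / "r.tsv"
        mr.write_report(ranked, "bcell", path)
        frame = pd.read_csv(path, sep="\t")
        assert list(frame["Total score"]) == [sc.totals["bcell"] for sc in ranked]
        assert list(frame["SA"]) == [sc.converted["SA"] for sc in ranked]

    def test_empty_shortlist_writes_header_only(self, tmp_path, caplog):
        ranked = mr.RankedTable(entries=(), ranking_key="grand_total", tie_break="")
        path = tmp_path / "empty.tsv"
        with caplog.at_level("WARNING"):
            mr.write_report(ranked, "bcell", path)
        lines = path.read_text().splitlines()
        assert len(lines) == 1 and lines[0].startswith("Sequence ID")
        assert any("header-only" in m for m in caplog.messages)

    def test_unknown_style(self):
        with pytest.raises(ConfigurationError):
            report_frame(mr.rank_candidates([full_card("a")]), "tables")
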