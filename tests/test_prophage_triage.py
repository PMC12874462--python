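"""Prophage completeness triage, quality gating and summary statistics."""

import pytest
from hypothesis import given, settings, strategies as st

from islandkit.examples import PROPHAGE_TABLE
from islandkit.model import FeatureError
from islandkit.prophages import (
    INCOMPLETE,
    INTACT,
    QUESTIONABLE,
    UNSCORED,
    ProphageRecord,
    classify_score,
    collapse_overlapping,
    gc_percent,
    passes_quality,
    read_quality_table,
    summarize,
    tally_classes,
    triage_records,
)


class TestClassifyScore:
    @pytest.mark.parametrize(
        "score, expected",
        [
            (69, INCOMPLETE),
            (69.999, INCOMPLETE),
            (70, QUESTIONABLE),
            (80, QUESTIONABLE),
            (90, QUESTIONABLE),
            (90.001, INTACT),
            (91, INTACT),
            (150, INTACT),
            (0, INCOMPLETE),
        ],
    )
    def test_boundaries(self, score, expected):
        assert classify_score(score) == expected

    def test_non_numeric_rejected(self):
        with pytest.raises(FeatureError):
            classify_score("high")
        with pytest.raises(FeatureError):
            classify_score(float("nan"))

    @given(st.floats(min_value=0, max_value=200, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_total_piecewise_constant(self, score):
        cls = classify_score(score)
        assert cls in (INCOMPLETE, QUESTIONABLE, INTACT)
        if cls == INCOMPLETE:
            assert score < 70
        elif cls == QUESTIONABLE:
            assert 70 <= score <= 90
        else:
            assert score > 90


class TestQualityGate:
    @pytest.mark.parametrize(
        "completeness, contamination, expected",
        [
            (95.0, 4.9, True),
            (90.0, 0.0, False),  # "more than 90 %" is strict
            (99.0, 5.0, False),  # "less than 5 %" is strict
            (90.001, 4.999, True),
            (100.0, 0.0, True),
            (90.0, 5.0, False),
        ],
    )
    def test_strict_inequalities(self, completeness, contamination, expected):
        assert passes_quality(completeness, contamination) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(FeatureError):
            passes_quality(101, 0)
        with pytest.raises(FeatureError):
            passes_quality(95, -1)

    @given(
        comp=st.floats(0, 100, allow_nan=False),
        cont=st.floats(0, 100, allow_nan=False),
        dc=st.floats(0, 5, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone(self, comp, cont, dc):
        """Raising completeness or lowering contamination never flips pass->fail."""
        if passes_quality(comp, cont):
            assert passes_quality(min(100.0, comp + dc), max(0.0, cont - dc))


class TestGcPercent:
    @pytest.mark.parametrize(
        "seq, expected",
        [("GGCC", 100.0), ("aatt", 0.0), ("ACGTN", 40.0), ("AcGt", 50.0)],
    )
    def test_values(self, seq, expected):
        assert gc_percent(seq) == pytest.approx(expected)

    def test_ambiguity_codes_count_in_denominator_only(self):
        # S (G|C) is not counted as GC under the stated rule
        assert gc_percent("GCSS") == pytest.approx(50.0)

    def test_errors(self):
        with pytest.raises(FeatureError):
            gc_percent("")
        with pytest.raises(FeatureError):
            gc_percent("ACGX")


class TestSummarize:
    def test_published_eight_prophages(self):
        s = summarize(PROPHAGE_TABLE)
        assert s.n == 8
        assert s.mean_length_kbp == pytest.approx(50.4125)
        assert s.mean_gc_pct == pytest.approx(56.36625)
        assert s.min_length_kbp == pytest.approx(36.9)  # Ph_Salpro3
        assert s.max_length_kbp == pytest.approx(60.6)  # Ph_Salpro2
        assert s.min_gc_pct == pytest.approx(39.81)  # Ph_Alpe
        assert s.max_gc_pct == pytest.approx(65.63)  # Ph_Salpro3

    def test_single_record(self):
        (r,) = PROPHAGE_TABLE[:1]
        s = summarize([r])
        assert s.mean_length_kbp == s.min_length_kbp == s.max_length_kbp == r.length_kbp

    def test_empty_is_an_error(self):
        with pytest.raises(FeatureError):
            summarize([])

    def test_concatenation_additivity(self):
        a, b = PROPHAGE_TABLE[:3], PROPHAGE_TABLE[3:]
        sa, sb, sab = summarize(a), summarize(b), summarize(PROPHAGE_TABLE)
        assert sab.n == sa.n + sb.n
        weighted = (sa.mean_length_kbp * sa.n + sb.mean_length_kbp * sb.n) / sab.n
        assert sab.mean_length_kbp == pytest.approx(weighted)


class TestTriage:
    def test_published_tally(self):
        records = (
            [ProphageRecord(f"i{k}", triage_class=INTACT) for k in range(15)]
            + [ProphageRecord(f"q{k}", triage_class=QUESTIONABLE) for k in range(10)]
            + [ProphageRecord(f"n{k}", triage_class=INCOMPLETE) for k in range(12)]
        )
        counts = tally_classes(records)
        assert counts == {"intact": 15, "questionable": 10, "incomplete": 12, "total": 37}

    def test_empty_and_singleton(self):
        assert tally_classes([]) == {"total": 0}
        assert tally_classes([ProphageRecord("p", triage_class=INTACT)]) == {
            "intact": 1,
            "total": 1,
        }

    def test_unscored_records_classified_not_rejected(self):
        out = triage_records([ProphageRecord("p1"), ProphageRecord("p2", score=95)])
        assert [r.triage_class for r in out] == [UNSCORED, INTACT]


class TestQualityTable:
    TSV = (
        "prophage_id\tgenome_id\tcontig_id\tstart\tend\tscore\tcompleteness_pct\tcontamination_pct\n"
        "p1\tg1\tc1\t1000\t45999\t95\t97.5\t1.2\n"
        "p2\tg1\tc1\t\t\t\t92.0\t0.0\n"
    )

    def test_missing_cells_are_none(self):
        r1, r2 = read_quality_table(self.TSV)
        assert r1.score == 95 and r1.length_kbp == pytest.approx(45.0)
        assert r2.score is None and r2.start is None
        assert r2.completeness_pct == 92.0

    def test_length_consistency_enforced(self):
        with pytest.raises(FeatureError):
            ProphageRecord("p", start=1, end=45_999, length_kbp=50.0)

    def test_collapse_overlapping_keeps_best(self):
        a = ProphageRecord("a", genome_id="g", contig_id="c", start=1_000, end=40_000,
                           completeness_pct=95.0)
        b = ProphageRecord("b", genome_id="g", contig_id="c", start=5_000, end=42_000,
                           completeness_pct=80.0)
        c = ProphageRecord("c", genome_id="g", contig_id="c", start=200_000, end=240_000,
                           completeness_pct=50.0)
        kept = collapse_overlapping([a, b, c])
        assert [r.prophage_id for r in kept] == ["a", "c"]
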