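"""Consensus engine: band summaries, decision rules, rankings."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from impact_tool import fixtures
from impact_tool.catalog import Tier
from impact_tool.consensus import (BandSummary, ConsensusError, ConsensusRule,
                                   Dimension, OUTSIDE_EXPERTISE, RankingTally,
                                   RatingMatrix, assign_tier, include_indicator,
                                   run_round, statement_agreed, summarize,
                                   winner_by_first_choice)


def matrix_from(values, item="x", dimension=Dimension.IMPORTANCE, round=1):
    m = RatingMatrix(study="t", round=round)
    for i, v in enumerate(values):
        m.add(f"p{i}", item, dimension, v)
    return m


class TestSummarize:
    def test_unanimous_top_band(self):
        m = matrix_from([6] * 14 + [7] * 15)
        s = summarize(m, "x", Dimension.IMPORTANCE)
        assert s.n_valid == 29
        assert s.pct_6_7 == 100.0
        assert s.median == 7  # 15 sevens out of 29

    def test_single_band_mass(self):
        s = summarize(matrix_from([4, 4, 4]), "x", Dimension.IMPORTANCE)
        assert s.pct_3_5 == 100.0 and s.pct_6_7 == 0.0 and s.median == 4

    def test_outside_expertise_excluded_from_denominator(self):
        m = matrix_from([6, 6, OUTSIDE_EXPERTISE, None])
        s = summarize(m, "x", Dimension.IMPORTANCE)
        assert s.n_valid == 2 and s.pct_6_7 == 100.0

    def test_even_n_median_is_midpoint(self):
        s = summarize(matrix_from([6, 6, 7, 7]), "x", Dimension.IMPORTANCE)
        assert s.median == 6.5

    def test_no_valid_responses_is_an_error(self):
        m = matrix_from([OUTSIDE_EXPERTISE, None])
        with pytest.raises(ConsensusError, match="no valid"):
            summarize(m, "x", Dimension.IMPORTANCE)

    def test_missing_item_is_an_error(self):
        with pytest.raises(ConsensusError, match="not present"):
            summarize(matrix_from([5]), "other", Dimension.IMPORTANCE)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_tally_on_random_matrices(self, seed):
        rng = random.Random(seed)
        n_p, n_i = rng.randint(5, 50), rng.randint(1, 50)
        m = RatingMatrix(study="t", round=1)
        raw = {}
        for i in range(n_i):
            for p in range(n_p):
                r = rng.random()
                v = (OUTSIDE_EXPERTISE if r < 0.1
                     else None if r < 0.15 else rng.randint(1, 7))
                m.add(f"p{p}", f"i{i}", Dimension.RISK, v)
                raw[(p, i)] = v
        item = f"i{rng.randrange(n_i)}"
        valid = [v for (p, i), v in raw.items()
                 if f"i{i}" == item and isinstance(v, int)]
        if not valid:
            return
        s = summarize(m, item, Dimension.RISK)
        assert s.n_valid == len(valid)
        for band, lo, hi in [("pct_1_2", 1, 2), ("pct_3_5", 3, 5),
                             ("pct_5_7", 5, 7), ("pct_6_7", 6, 7)]:
            brute = 100.0 * sum(lo <= v <= hi for v in valid) / len(valid)
            assert getattr(s, band) == pytest.approx(brute, abs=1e-12)


def t2_summary(row, round, dimension):
    for s in fixtures.table2_band_summaries(round, dimension):
        if s.item == str(row):
            return s
    raise KeyError(row)


def t4_summary(statement, round):
    for s in fixtures.table4_band_summaries(round):
        if s.item == str(statement):
            return s
    raise KeyError(statement)


class TestDecisionRules:
    def test_unanimous_importance_included(self):
        # clozapine, round 2: 100.0 / 100.0
        assert include_indicator(t2_summary(4, 2, Dimension.IMPORTANCE))

    def test_low_importance_not_included(self):
        # bisphosphonates, round 2: 0.0 / 0.0
        assert not include_indicator(t2_summary(123, 2, Dimension.IMPORTANCE))

    def test_inclusion_threshold_is_inclusive(self):
        s = BandSummary(item="b", dimension=Dimension.IMPORTANCE, round=1,
                        pct_5_7=75.0, pct_6_7=75.0)
        assert include_indicator(s)

    def test_57_route_alone_suffices(self):
        s = BandSummary(item="b", dimension=Dimension.IMPORTANCE, round=1,
                        pct_5_7=85.0, pct_6_7=10.0)
        assert include_indicator(s)

    def test_high_risk_band_gives_red(self):
        assert assign_tier(t2_summary(5, 2, Dimension.RISK)) is Tier.RED

    def test_middle_band_gives_amber(self):
        # contraceptives round 2: 3-5 = 89.3
        assert assign_tier(t2_summary(104, 2, Dimension.RISK)) is Tier.AMBER

    def test_low_band_gives_green(self):
        s = BandSummary(item="g", dimension=Dimension.RISK, round=1,
                        pct_1_2=80.0, pct_3_5=15.0, pct_6_7=5.0)
        assert assign_tier(s) is Tier.GREEN

    def test_majority_fallback_to_amber(self):
        s = BandSummary(item="f", dimension=Dimension.RISK, round=1,
                        pct_1_2=30.0, pct_3_5=40.0, pct_6_7=30.0)
        assert assign_tier(s) is Tier.AMBER
        strict = ConsensusRule(majority_fallback=False)
        assert assign_tier(s, strict) is Tier.UNASSIGNED

    def test_statement_agreement_examples(self):
        assert statement_agreed(t4_summary(1, 1))        # 100.0 / 96.9
        assert not statement_agreed(t4_summary(30, 2))   # 16.7 / 10.0
        assert statement_agreed(t4_summary(10, 1))       # 6-7 exactly 75.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConsensusError, match="importance"):
            include_indicator(t2_summary(5, 2, Dimension.RISK))


class TestRunRound:
    def test_proportion_is_exact_ratio(self):
        report = run_round(fixtures.table4_band_summaries(1),
                           decision="agreement")
        assert report.proportion_included == report.n_included / report.n_items

    def test_round2_additions_excluded_from_round1_denominator(self):
        assert len(fixtures.table2_band_summaries(1, Dimension.IMPORTANCE)) == 109
        assert len(fixtures.table2_band_summaries(2, Dimension.IMPORTANCE)) == 123

    def test_mixed_dimensions_rejected(self):
        mixed = [t2_summary(4, 2, Dimension.IMPORTANCE),
                 t2_summary(4, 2, Dimension.RISK)]
        with pytest.raises(ConsensusError, match="mixed"):
            run_round(mixed, decision="inclusion")

    def test_report_frame_has_one_row_per_item(self):
        report = run_round(fixtures.table4_band_summaries(2),
                           decision="agreement")
        df = report.to_frame()
        assert len(df) == 30
        assert df["included"].sum() == report.n_included


class TestRankings:
    def test_classification_winner_is_traffic_light(self):
        winner, votes = winner_by_first_choice(fixtures.classification_ranking())
        assert winner == "traffic_light" and votes == 17

    def test_medium_tier_tie_broken_at_rank_two(self):
        tally = fixtures.review_frequency_ranking(Tier.AMBER)
        # two options tie at 11 first choices; rank-2 counts 8 vs 7 decide
        assert tally.counts["every_2_4_days"][0] == tally.counts["twice_a_week"][0] == 11
        winner, votes = winner_by_first_choice(tally)
        assert winner == "every_2_4_days" and votes == 11

    def test_singleton_tally(self):
        t = RankingTally(counts={"only": (3, 1)})
        assert winner_by_first_choice(t) == ("only", 3)

    def test_empty_tally_rejected(self):
        with pytest.raises(ConsensusError, match="empty"):
            winner_by_first_choice(RankingTally(counts={}))

    def test_residual_tie_falls_back_to_id_order(self):
        t = RankingTally(counts={"b": (2, 2), "a": (2, 2)})
        assert winner_by_first_choice(t)[0] == "a"

    def test_rank_column_exceeding_panel_rejected(self):
        with pytest.raises(ConsensusError, match="n_rankers"):
            RankingTally(counts={"a": (3,), "b": (3,)}, n_rankers=5)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(counts=st.lists(st.integers(0, 20), min_size=7, max_size=7)
       .filter(lambda c: sum(c) > 0),
       bump=st.integers(0, 5))
def test_raising_a_rating_never_revokes_inclusion(counts, bump):
    """Monotonicity: moving one rating up a score cannot flip include->exclude."""
    s = BandSummary.from_counts("x", Dimension.IMPORTANCE, 1, counts)
    lower = next((i for i in range(bump, 7) if counts[i] > 0), None)
    if lower is None or lower == 6:
        return
    bumped = list(counts)
    bumped[lower] -= 1
    bumped[lower + 1] += 1
    s2 = BandSummary.from_counts("x", Dimension.IMPORTANCE, 1, bumped)
    if include_indicator(s):
        assert include_indicator(s2)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(counts=st.lists(st.integers(0, 20), min_size=7, max_size=7)
       .filter(lambda c: sum(c) > 0))
def test_red_and_amber_bands_mutually_exclusive(counts):
    """75% + 75% > 100%: at most one band can reach the tier threshold."""
    s = BandSummary.from_counts("x", Dimension.RISK, 1, counts)
    assert (s.pct_6_7 >= 75.0) + (s.pct_3_5 >= 75.0) + (s.pct_1_2 >= 75.0) <= 1
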