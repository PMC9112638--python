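from fractions import Fraction

import pytest

from polypsurv import IntervalRange, Recommendation, Status
from polypsurv.evaluation import (
    NO_FURTHER,
    SKIPPED,
    ClinicianGroup,
    ClinicianResponse,
    Direction,
    Grouping,
    PilotRecord,
    Score,
    Scorecard,
    build_scorecards,
    direction_breakdown,
    low_scorer_summary,
    pilot_summary,
    round_half_up_pct,
    score_response,
)
from polypsurv.fixtures import table2_synthetic_scorecards, table3_fixture


def interval_rec(lo, hi):
    return Recommendation(
        status=Status.INTERVAL,
        interval=IntervalRange(min_months=lo, max_months=hi),
        fired_rule_ids=("r",),
    )


OOS = Recommendation(status=Status.OUT_OF_SCOPE)


class TestScoreResponse:
    @pytest.mark.parametrize(
        "answer, rec, expected",
        [
            (60, interval_rec(36, 60), Score.CONCORDANT),  # inclusive upper bound
            (36, interval_rec(36, 60), Score.CONCORDANT),  # inclusive lower bound
            (36, interval_rec(60, 60), Score.DISCORDANT_SHORTER),
            (12, interval_rec(60, 120), Score.DISCORDANT_SHORTER),
            (120, interval_rec(36, 60), Score.DISCORDANT_LONGER),
            (NO_FURTHER, interval_rec(60, 60), Score.DISCORDANT_LONGER),
            (SKIPPED, interval_rec(60, 60), Score.INCORRECT_NO_DIRECTION),
            (60, OOS, Score.NOT_APPLICABLE),
        ],
    )
    def test_classification(self, answer, rec, expected):
        assert score_response(answer, rec) is expected

    def test_conservation_over_an_audit(self):
        rec = interval_rec(60, 60)
        answers = [60, 36, 120, SKIPPED, NO_FURTHER, 60]
        scores = [score_response(a, rec) for a in answers] + [score_response(60, OOS)]
        assert len(scores) == sum(
            scores.count(s) for s in Score
        ), "every response lands in exactly one category"


class TestScorecards:
    def make_responses(self, n_correct, n_total, cid="c1"):
        key = {f"s{i}": interval_rec(60, 60) for i in range(n_total)}
        answers = [60] * n_correct + [36] * (n_total - n_correct)
        responses = [
            ClinicianResponse(cid, ClinicianGroup.GASTROENTEROLOGIST, f"s{i}", a)
            for i, a in enumerate(answers)
        ]
        return responses, key

    def test_ten_of_twelve_is_not_a_low_scorer(self):
        responses, key = self.make_responses(10, 12)
        (card,) = build_scorecards(responses, key)
        assert card.n_correct == 10 and not card.low_scorer
        assert round_half_up_pct(Fraction(card.n_correct, card.n_scenarios)) == 83

    def test_zero_of_seven_is_a_low_scorer(self):
        responses, key = self.make_responses(0, 7)
        (card,) = build_scorecards(responses, key)
        assert card.low_scorer

    def test_exactly_half_counts_as_low(self):
        assert Scorecard("c", ClinicianGroup.PCP, n_correct=6, n_scenarios=12).low_scorer
        assert not Scorecard("c", ClinicianGroup.PCP, n_correct=7, n_scenarios=12).low_scorer

    def test_unknown_scenario_rejected(self):
        responses, key = self.make_responses(1, 1)
        key.pop("s0")
        with pytest.raises(KeyError):
            build_scorecards(responses, key)

    def test_skipped_counts_against_score(self):
        key = {"s0": interval_rec(60, 60), "s1": interval_rec(60, 60)}
        responses = [
            ClinicianResponse("c", ClinicianGroup.PCP, "s0", 60),
            ClinicianResponse("c", ClinicianGroup.PCP, "s1", SKIPPED),
        ]
        (card,) = build_scorecards(responses, key)
        assert (card.n_correct, card.n_scenarios) == (1, 2)


class TestLowScorerSummary:
    def test_seven_scenario_battery_totals(self):
        summary = low_scorer_summary(table2_synthetic_scorecards(7), Grouping.CLINICIAN_TYPE)
        assert (summary.n_low, summary.n_total) == (10, 19)
        assert summary.percent == 53
        assert summary.p_value == pytest.approx(0.86, abs=0.005)
        assert summary.alternative == "FREEMAN_HALTON"

    def test_twelve_scenario_battery_totals(self):
        summary = low_scorer_summary(table2_synthetic_scorecards(12), Grouping.CLINICIAN_TYPE)
        assert (summary.n_low, summary.n_total) == (5, 10)
        assert summary.percent == 50
        assert summary.p_value > 0.99

    def test_two_group_summary_uses_one_sided_fisher(self):
        cards = [
            Scorecard(f"m{i}", ClinicianGroup.PCP, n_correct=c, n_scenarios=7, gender="M")
            for i, c in enumerate([3, 3, 3, 3, 3, 3, 5, 5, 5, 5, 5, 5, 5])
        ] + [
            Scorecard(f"f{i}", ClinicianGroup.PCP, n_correct=c, n_scenarios=7, gender="F")
            for i, c in enumerate([3, 3, 3, 5, 5, 5])
        ]
        summary = low_scorer_summary(cards, Grouping.GENDER)
        assert summary.p_value == pytest.approx(0.63, abs=0.005)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            low_scorer_summary([])


class TestPilotSummary:
    def test_published_pilot_counts(self):
        summary = pilot_summary(table3_fixture())
        d = summary.as_dict()
        assert d["n_total"] == 58
        assert d["n_agree"] == 30 and d["n_disagree"] == 16
        assert d["n_issues"] == 12 and d["n_clean"] == 46
        assert d["agreement_all_pct"] == 52
        assert d["agreement_excluding_issues_pct"] == 65
        assert d["discordance_excluding_issues_pct"] == 35
        assert summary.issue_rate == Fraction(12, 58)

    def test_percentages_recompute_from_counts(self):
        summary = pilot_summary(table3_fixture())
        d = summary.as_dict()
        assert d["agreement_all_pct"] == round_half_up_pct(
            Fraction(d["n_agree"], d["n_total"])
        )
        assert d["issue_rate_pct"] == round_half_up_pct(
            Fraction(d["n_issues"], d["n_total"])
        )

    def test_all_agree_no_exclusions(self):
        records = [
            PilotRecord("E1", stated_agreement=True, chart_review_agreement=True)
            for _ in range(5)
        ]
        summary = pilot_summary(records)
        assert summary.agreement_all == 1


class TestDirectionBreakdown:
    def test_pilot_discordance_mostly_shorter(self):
        breakdown = direction_breakdown(table3_fixture())
        assert breakdown[Direction.SHORTER] == Fraction(11, 16)
        assert round_half_up_pct(breakdown[Direction.SHORTER]) == 69  # published as ~70%

    def test_scenario_errors_mostly_longer(self):
        # 58% of scenario-battery errors were longer than the guideline
        scores = [Score.DISCORDANT_LONGER] * 7 + [Score.DISCORDANT_SHORTER] * 5
        breakdown = direction_breakdown(scores)
        assert round_half_up_pct(breakdown[Direction.LONGER]) == 58

    def test_all_concordant_yields_empty_breakdown(self):
        assert direction_breakdown([Score.CONCORDANT, Score.NOT_APPLICABLE]) == {}
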