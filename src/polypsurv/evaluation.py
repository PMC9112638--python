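"""Concordance audits: clinician answers vs. guideline-engine recommendations.

Two audit shapes are supported.  Scenario audits score each clinician's
recommended interval against the engine's answer key and summarise who fell
at or below 50% agreement, with exact tests across clinician type and gender.
Pilot audits summarise in-practice use of the tool: per-colonoscopy agreement,
records excluded for tool-use issues, and the direction (shorter/longer) of
the discordant recommendations.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence, Union

from .exact import Alternative, ContingencyTable, fisher_2x2, freeman_halton
from .model import Recommendation, Status


class ClinicianGroup(str, enum.Enum):
    SURGEON = "SURGEON"
    GASTROENTEROLOGIST = "GASTROENTEROLOGIST"
    PCP = "PCP"
    RESIDENT = "RESIDENT"


class Score(str, enum.Enum):
    CONCORDANT = "CONCORDANT"
    DISCORDANT_SHORTER = "DISCORDANT_SHORTER"
    DISCORDANT_LONGER = "DISCORDANT_LONGER"
    INCORRECT_NO_DIRECTION = "INCORRECT_NO_DIRECTION"  # e.g. skipped question
    NOT_APPLICABLE = "NOT_APPLICABLE"


class Direction(str, enum.Enum):
    SHORTER = "SHORTER"
    LONGER = "LONGER"
    NA = "NA"


class PilotExclusion(str, enum.Enum):
    NONE = "NONE"
    INCORRECT_TOOL_USE = "INCORRECT_TOOL_USE"
    AGE_NO_FOLLOWUP = "AGE_NO_FOLLOWUP"
    NOT_APPLICABLE_OTHER = "NOT_APPLICABLE_OTHER"


#: Clinician answers: an interval in months, a no-further-colonoscopy call,
#: or a skipped question.
NO_FURTHER = "NO_FURTHER"
SKIPPED = "SKIPPED"
Answer = Union[int, str]


@dataclass(frozen=True)
class ClinicianResponse:
    clinician_id: str
    group: ClinicianGroup
    scenario_id: str
    answer: Answer
    gender: Optional[str] = None


@dataclass(frozen=True)
class PilotRecord:
    """One colonoscopy of the pilot study."""

    endoscopist_id: str
    stated_agreement: bool
    chart_review_agreement: Optional[bool] = None
    exclusion: PilotExclusion = PilotExclusion.NONE
    direction: Direction = Direction.NA
    would_change: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.direction is not Direction.NA and (
            self.exclusion is not PilotExclusion.NONE or self.stated_agreement
        ):
            raise ValueError("direction applies only to countable discordant records")


@dataclass(frozen=True)
class Scorecard:
    clinician_id: str
    group: ClinicianGroup
    n_correct: int
    n_scenarios: int
    gender: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_scenarios:
            raise ValueError("n_correct must lie in [0, n_scenarios]")

    @property
    def low_scorer(self) -> bool:
        """At or below 50% agreement with the guidelines."""
        return Fraction(self.n_correct, self.n_scenarios) <= Fraction(1, 2)


def round_half_up_pct(fraction: Fraction) -> int:
    """Display rounding used throughout the audit reports."""
    return int((fraction * 100) + Fraction(1, 2))


def score_response(answer: Answer, recommendation: Recommendation) -> Score:
    """Classify one clinician answer against the engine's recommendation.

    Concordance is inclusive at both interval bounds; a skipped question is
    incorrect with no direction; recommendations the tool declines to make
    (out of scope / case by case) are not scored.
    """
    if recommendation.status in (Status.OUT_OF_SCOPE, Status.CASE_BY_CASE):
        return Score.NOT_APPLICABLE
    if answer == SKIPPED:
        return Score.INCORRECT_NO_DIRECTION
    if recommendation.status is Status.NO_FURTHER:
        return Score.CONCORDANT if answer == NO_FURTHER else Score.DISCORDANT_SHORTER
    # status INTERVAL
    interval = recommendation.interval
    if answer == NO_FURTHER:
        return Score.DISCORDANT_LONGER
    if not isinstance(answer, int):
        raise ValueError(f"unrecognised answer {answer!r}")
    if answer < interval.min_months:
        return Score.DISCORDANT_SHORTER
    if answer > interval.max_months:
        return Score.DISCORDANT_LONGER
    return Score.CONCORDANT


def build_scorecards(
    responses: Sequence[ClinicianResponse],
    key: Mapping[str, Recommendation],
) -> list[Scorecard]:
    """Per-clinician concordance counts over the scenarios each one answered."""
    by_clinician: dict[str, list[ClinicianResponse]] = {}
    for resp in responses:
        if resp.scenario_id not in key:
            raise KeyError(f"unknown scenario id {resp.scenario_id!r}")
        by_clinician.setdefault(resp.clinician_id, []).append(resp)
    cards = []
    for cid, resps in by_clinician.items():
        scored = [score_response(r.answer, key[r.scenario_id]) for r in resps]
        applicable = [s for s in scored if s is not Score.NOT_APPLICABLE]
        cards.append(
            Scorecard(
                clinician_id=cid,
                group=resps[0].group,
                gender=resps[0].gender,
                n_correct=sum(s is Score.CONCORDANT for s in applicable),
                n_scenarios=len(applicable),
            )
        )
    return cards


class Grouping(str, enum.Enum):
    CLINICIAN_TYPE = "CLINICIAN_TYPE"
    GENDER = "GENDER"


@dataclass(frozen=True)
class LowScorerSummary:
    table: ContingencyTable  # rows: (group, n_low, n_not_low)
    n_low: int
    n_total: int
    p_value: float
    alternative: str

    @property
    def proportion(self) -> Fraction:
        return Fraction(self.n_low, self.n_total)

    @property
    def percent(self) -> int:
        return round_half_up_pct(self.proportion)


def summarize_low_scorer_counts(
    table: ContingencyTable,
    alternative: Alternative = Alternative.ONE_SIDED_MIN_TAIL,
) -> LowScorerSummary:
    """Overall low-scorer proportion and exact p for an r x 2 count table.

    Rows with zero total are dropped; two informative rows get a 2 x 2 Fisher
    test (one-sided min-tail by default), more rows the Freeman–Halton test.
    """
    t = table.informative()
    n_low = sum(low for _, low, _ in t.rows)
    n_total = sum(low + high for _, low, high in t.rows)
    if len(t.rows) == 2:
        p = fisher_2x2(t, alternative)
        alt = alternative.value
    else:
        p = freeman_halton(t)
        alt = "FREEMAN_HALTON"
    return LowScorerSummary(table=t, n_low=n_low, n_total=n_total, p_value=p, alternative=alt)


def low_scorer_summary(
    scorecards: Sequence[Scorecard],
    grouping: Grouping = Grouping.CLINICIAN_TYPE,
    alternative: Alternative = Alternative.ONE_SIDED_MIN_TAIL,
) -> LowScorerSummary:
    """Group scorecards, tabulate low scorers, and test for group differences."""
    if not scorecards:
        raise ValueError("no scorecards to summarise")
    if grouping is Grouping.CLINICIAN_TYPE:
        order = [g.value for g in ClinicianGroup]
        keyfn = lambda c: c.group.value  # noqa: E731
    else:
        order = sorted({c.gender for c in scorecards if c.gender is not None})
        keyfn = lambda c: c.gender  # noqa: E731
    rows = []
    for label in order:
        members = [c for c in scorecards if keyfn(c) == label]
        low = sum(c.low_scorer for c in members)
        rows.append((label, low, len(members) - low))
    return summarize_low_scorer_counts(
        ContingencyTable(tuple(rows)).informative(), alternative
    )


@dataclass(frozen=True)
class PilotSummary:
    n_total: int
    n_agree: int
    n_disagree: int
    n_incorrect_tool_use: int
    n_age_no_followup: int
    n_other_not_applicable: int

    @property
    def n_issues(self) -> int:
        return self.n_incorrect_tool_use + self.n_age_no_followup + self.n_other_not_applicable

    @property
    def n_clean(self) -> int:
        return self.n_total - self.n_issues

    @property
    def agreement_all(self) -> Fraction:
        return Fraction(self.n_agree, self.n_total)

    @property
    def agreement_excluding_issues(self) -> Fraction:
        return Fraction(self.n_agree, self.n_clean)

    @property
    def discordance_excluding_issues(self) -> Fraction:
        return Fraction(self.n_disagree, self.n_clean)

    @property
    def issue_rate(self) -> Fraction:
        return Fraction(self.n_issues, self.n_total)

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_agree": self.n_agree,
            "n_disagree": self.n_disagree,
            "n_incorrect_tool_use": self.n_incorrect_tool_use,
            "n_age_no_followup": self.n_age_no_followup,
            "n_other_not_applicable": self.n_other_not_applicable,
            "n_issues": self.n_issues,
            "n_clean": self.n_clean,
            "agreement_all_pct": round_half_up_pct(self.agreement_all),
            "agreement_excluding_issues_pct": round_half_up_pct(
                self.agreement_excluding_issues
            ),
            "discordance_excluding_issues_pct": round_half_up_pct(
                self.discordance_excluding_issues
            ),
            "issue_rate_pct": round_half_up_pct(self.issue_rate),
        }


def pilot_summary(records: Sequence[PilotRecord]) -> PilotSummary:
    """Tabulate a pilot audit the way the in-practice evaluation reports it."""
    if not records:
        raise ValueError("no pilot records")
    n_itu = n_age = n_other = n_agree = n_disagree = 0
    for r in records:
        if r.exclusion is PilotExclusion.INCORRECT_TOOL_USE:
            n_itu += 1
        elif r.exclusion is PilotExclusion.AGE_NO_FOLLOWUP:
            n_age += 1
        elif r.exclusion is PilotExclusion.NOT_APPLICABLE_OTHER:
            n_other += 1
        elif r.stated_agreement and r.chart_review_agreement is not False:
            n_agree += 1
        else:
            n_disagree += 1
    return PilotSummary(
        n_total=len(records),
        n_agree=n_agree,
        n_disagree=n_disagree,
        n_incorrect_tool_use=n_itu,
        n_age_no_followup=n_age,
        n_other_not_applicable=n_other,
    )


def direction_breakdown(
    items: Iterable[Union[PilotRecord, Score, Direction]],
) -> dict[Direction, Fraction]:
    """Shorter/longer proportions among discordant items carrying a direction.

    Accepts pilot records, response scores, or bare direction labels; items
    without a direction (concordant, skipped, not-applicable) are ignored.
    An input with no directed discordance yields an empty mapping.
    """
    counts = {Direction.SHORTER: 0, Direction.LONGER: 0}
    for item in items:
        if isinstance(item, PilotRecord):
            d = item.direction
        elif isinstance(item, Score):
            d = {
                Score.DISCORDANT_SHORTER: Direction.SHORTER,
                Score.DISCORDANT_LONGER: Direction.LONGER,
            }.get(item, Direction.NA)
        else:
            d = Direction(item)
        if d is not Direction.NA:
            counts[d] += 1
    total = sum(counts.values())
    if total == 0:
        return {}
    return {d: Fraction(n, total) for d, n in counts.items()}
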