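"""Conditional question flow that assembles engine inputs one answer at a time.

The flow mirrors how an endoscopist would be interviewed after a procedure:
one eligibility screener (screening age, no hereditary syndrome, no IBD), one
pathway question (first colonoscopy / surveillance / after CRC resection),
the findings block for the current exam, and a family-history question.
Numeric answers are bucketed at the rule-table boundaries (counts 1–2 / 3–4 /
5–10 / >10; sizes < 10 / 10–19 / >= 20 mm), so the complete answer alphabet —
and therefore the set of distinct interview paths — is finite and can be
enumerated exhaustively.

A completed assessment takes between 4 and 13 questions on the default flow;
an ineligible patient is screened out after the first question, which is
reported separately by :func:`enumerate_paths`.

``finalize`` hands the assembled profile and findings to
:func:`polypsurv.engine.recommend`, so an interview can never disagree with
the batch engine on the same inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Optional, Union

from .engine import recommend
from .model import (
    ColonoscopyFindings,
    ExamOrdinal,
    FamilyHistory,
    Histology,
    Location,
    PatientProfile,
    PolypGroup,
    Recommendation,
    Resection,
    Status,
)
from .rules import RuleSet


class AnswerKind(str, enum.Enum):
    YES_NO = "YES_NO"
    CHOICE = "CHOICE"
    INTEGER = "INTEGER"


Answer = Union[bool, str, int]


@dataclass(frozen=True)
class Question:
    id: str
    prompt: str
    answer_kind: AnswerKind
    choices: tuple[str, ...] = ()
    #: model field paths this answer populates (display wording is free-form)
    maps_to: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if (self.answer_kind is AnswerKind.CHOICE) != bool(self.choices):
            raise ValueError("choices present exactly for CHOICE questions")


QUESTIONS: dict[str, Question] = {
    q.id: q
    for q in [
        Question(
            "eligibility",
            "Does any of the following apply: age 75 or older, hereditary "
            "colorectal cancer syndrome, inflammatory bowel disease?",
            AnswerKind.CHOICE,
            ("none", "age_ge_75", "hereditary_syndrome", "ibd"),
            ("profile.age_years", "profile.hereditary_syndrome", "profile.ibd"),
        ),
        Question(
            "pathway",
            "Is this the patient's first colonoscopy, a surveillance "
            "colonoscopy after previous polyps, or follow-up after colorectal "
            "cancer resection?",
            AnswerKind.CHOICE,
            ("index", "surveillance", "post_crc"),
            ("profile.crc_history", "current.ordinal"),
        ),
        Question(
            "post_crc_count",
            "How many surveillance colonoscopies has the patient had since "
            "the cancer resection (not counting this one)?",
            AnswerKind.CHOICE,
            ("0", "1", "2_plus"),
            ("profile.post_resection_colonoscopy_count",),
        ),
        Question(
            "prior_risk",
            "On the previous colonoscopy, were findings normal, low-risk "
            "polyps only, or high-risk polyps?",
            AnswerKind.CHOICE,
            ("normal", "low_risk", "high_risk"),
            ("prior.polyp_groups",),
        ),
        Question(
            "polyps",
            "Were any polyps found and removed on this colonoscopy?",
            AnswerKind.YES_NO,
            maps_to=("current.polyp_groups",),
        ),
        Question(
            "adenoma_count",
            "How many adenomas (tubular, tubulovillous/villous, or with "
            "high-grade dysplasia) were removed?",
            AnswerKind.CHOICE,
            ("0", "1_2", "3_4", "5_10", "gt_10"),
            ("current.polyp_groups",),
        ),
        Question(
            "adenoma_size",
            "What was the size of the largest adenoma?",
            AnswerKind.CHOICE,
            ("lt10", "10_19", "ge20"),
            ("current.polyp_groups",),
        ),
        Question(
            "adenoma_advanced",
            "Did any adenoma show tubulovillous/villous histology or "
            "high-grade dysplasia?",
            AnswerKind.CHOICE,
            ("none", "villous", "hgd"),
            ("current.polyp_groups",),
        ),
        Question(
            "serrated_count",
            "How many sessile serrated polyps were removed?",
            AnswerKind.CHOICE,
            ("0", "1_2", "3_4", "5_10"),
            ("current.polyp_groups",),
        ),
        Question(
            "serrated_size",
            "What was the size of the largest sessile serrated polyp?",
            AnswerKind.CHOICE,
            ("lt10", "ge10"),
            ("current.polyp_groups",),
        ),
        Question(
            "serrated_type",
            "Any dysplasia within a sessile serrated polyp, or a traditional "
            "serrated adenoma?",
            AnswerKind.CHOICE,
            ("ssp", "ssp_dysplasia", "tsa"),
            ("current.polyp_groups",),
        ),
        Question(
            "hp",
            "Were hyperplastic polyps found, and if so where and how large?",
            AnswerKind.CHOICE,
            ("none", "rectosigmoid_lt10", "proximal_lt10", "ge10"),
            ("current.polyp_groups",),
        ),
        Question(
            "piecemeal",
            "Was the large (>= 20 mm) lesion removed piecemeal?",
            AnswerKind.YES_NO,
            maps_to=("current.polyp_groups",),
        ),
        Question(
            "family_history",
            "Family history in first-degree relatives: none; one relative with "
            "colorectal cancer diagnosed at 60 or older; or two or more "
            "relatives / any diagnosed before 60 / advanced adenoma before 60?",
            AnswerKind.CHOICE,
            ("none", "fdr_ge60", "high_risk"),
            ("profile.family_history",),
        ),
    ]
}


class InterviewError(ValueError):
    pass


@dataclass(frozen=True)
class SessionState:
    answered: tuple[tuple[str, Answer], ...] = ()
    terminal: Optional[Recommendation] = None
    ruleset: Optional[RuleSet] = field(default=None, compare=False)

    @property
    def answers(self) -> dict[str, Answer]:
        return dict(self.answered)


def start(ruleset: Optional[RuleSet] = None) -> SessionState:
    return SessionState(ruleset=ruleset)


def _next_question_id(answers: dict[str, Answer]) -> Optional[str]:
    """Pure flow logic: id of the next pending question, or None when done."""
    if "eligibility" not in answers:
        return "eligibility"
    # ineligible answers terminate before this is called
    if "pathway" not in answers:
        return "pathway"
    pathway = answers["pathway"]
    if pathway == "post_crc" and "post_crc_count" not in answers:
        return "post_crc_count"
    if pathway == "surveillance" and "prior_risk" not in answers:
        return "prior_risk"
    if "polyps" not in answers:
        return "polyps"
    if answers["polyps"]:
        if "adenoma_count" not in answers:
            return "adenoma_count"
        if answers["adenoma_count"] != "0":
            if "adenoma_size" not in answers:
                return "adenoma_size"
            if "adenoma_advanced" not in answers:
                return "adenoma_advanced"
        if "serrated_count" not in answers:
            return "serrated_count"
        if answers["serrated_count"] != "0":
            if "serrated_size" not in answers:
                return "serrated_size"
            if "serrated_type" not in answers:
                return "serrated_type"
        if "hp" not in answers:
            return "hp"
        if answers.get("adenoma_size") == "ge20" and "piecemeal" not in answers:
            return "piecemeal"
    if "family_history" not in answers:
        return "family_history"
    return None


def next_question(state: SessionState) -> Optional[Question]:
    """The unique pending question, or None once the session is terminal."""
    if state.terminal is not None:
        return None
    qid = _next_question_id(state.answers)
    return QUESTIONS[qid] if qid is not None else None


_COUNT_REPS = {"1_2": 1, "3_4": 3, "5_10": 5, "gt_10": 11}
_ADENOMA_SIZE_REPS = {"lt10": 5, "10_19": 10, "ge20": 20}
_SERRATED_SIZE_REPS = {"lt10": 5, "ge10": 10}
_PRIOR_REPS = {
    "normal": (),
    "low_risk": (
        PolypGroup(histology=Histology.TUBULAR_ADENOMA, count=1, max_size_mm=5),
    ),
    "high_risk": (
        PolypGroup(histology=Histology.TUBULAR_ADENOMA, count=1, max_size_mm=12),
    ),
}


def assemble_inputs(
    answers: dict[str, Answer],
) -> tuple[PatientProfile, Optional[ColonoscopyFindings], ColonoscopyFindings]:
    """Build representative engine inputs from bucketed answers.

    Representatives sit at band edges, so every rule predicate sees exactly
    the band the answer named; any representative of the same band yields the
    same recommendation.
    """
    pathway = answers["pathway"]
    crc = pathway == "post_crc"
    fh = {
        "none": FamilyHistory(),
        "fdr_ge60": FamilyHistory(fdr_crc_count=1, youngest_dx_age=65),
        "high_risk": FamilyHistory(fdr_crc_count=2, youngest_dx_age=55),
    }[answers["family_history"]]
    profile = PatientProfile(
        age_years=60,
        crc_history=crc,
        months_since_crc_resection=6 if crc else None,
        post_resection_colonoscopy_count={"0": 0, "1": 1, "2_plus": 2}.get(
            answers.get("post_crc_count", "0"), 0
        ),
        family_history=fh,
    )

    groups: list[PolypGroup] = []
    if answers["polyps"]:
        a_band = answers["adenoma_count"]
        if a_band != "0":
            hist = {
                "none": Histology.TUBULAR_ADENOMA,
                "villous": Histology.TUBULOVILLOUS_OR_VILLOUS,
                "hgd": Histology.ADENOMA_HGD,
            }[answers["adenoma_advanced"]]
            groups.append(
                PolypGroup(
                    histology=hist,
                    count=_COUNT_REPS[a_band],
                    max_size_mm=_ADENOMA_SIZE_REPS[answers["adenoma_size"]],
                    location=Location.PROXIMAL,
                    resection=Resection.PIECEMEAL
                    if answers.get("piecemeal")
                    else Resection.COMPLETE_ENBLOC,
                )
            )
        s_band = answers["serrated_count"]
        if s_band != "0":
            s_type = answers["serrated_type"]
            groups.append(
                PolypGroup(
                    histology=Histology.SSP_DYSPLASIA
                    if s_type == "ssp_dysplasia"
                    else Histology.SSP,
                    count=_COUNT_REPS[s_band],
                    max_size_mm=_SERRATED_SIZE_REPS[answers["serrated_size"]],
                    location=Location.PROXIMAL,
                )
            )
            if s_type == "tsa":
                groups.append(
                    PolypGroup(
                        histology=Histology.TSA,
                        count=1,
                        max_size_mm=5,
                        location=Location.RECTOSIGMOID,
                    )
                )
        hp = answers["hp"]
        if hp != "none":
            groups.append(
                PolypGroup(
                    histology=Histology.HYPERPLASTIC,
                    count=1,
                    max_size_mm=12 if hp == "ge10" else 5,
                    location=Location.RECTOSIGMOID
                    if hp == "rectosigmoid_lt10"
                    else Location.PROXIMAL,
                )
            )

    ordinal = (
        ExamOrdinal.SURVEILLANCE if pathway == "surveillance" else ExamOrdinal.INDEX
    )
    current = ColonoscopyFindings(polyp_groups=tuple(groups), ordinal=ordinal)
    prior = (
        ColonoscopyFindings(polyp_groups=_PRIOR_REPS[answers["prior_risk"]])
        if pathway == "surveillance"
        else None
    )
    return profile, prior, current


def submit_answer(state: SessionState, question_id: str, answer: Answer) -> SessionState:
    """Record one answer; computes the terminal recommendation when complete."""
    if state.terminal is not None:
        raise InterviewError("session already terminal")
    pending = next_question(state)
    if pending is None or question_id != pending.id:
        raise InterviewError(
            f"question {question_id!r} is not pending (expected {pending.id if pending else None!r})"
        )
    if pending.answer_kind is AnswerKind.YES_NO:
        if not isinstance(answer, bool):
            raise InterviewError(f"{question_id}: expected a yes/no answer")
    elif pending.answer_kind is AnswerKind.CHOICE:
        if answer not in pending.choices:
            raise InterviewError(
                f"{question_id}: {answer!r} not among {pending.choices}"
            )
    else:  # INTEGER
        if not isinstance(answer, int) or isinstance(answer, bool) or answer < 0:
            raise InterviewError(f"{question_id}: expected a non-negative integer")

    answered = state.answered + ((question_id, answer),)
    answers = dict(answered)

    if question_id == "eligibility" and answer != "none":
        reason = {
            "age_ge_75": "age >= 75",
            "hereditary_syndrome": "hereditary CRC syndrome",
            "ibd": "inflammatory bowel disease",
        }[answer]
        return replace(
            state,
            answered=answered,
            terminal=Recommendation(
                status=Status.OUT_OF_SCOPE, rationale=(f"out of scope: {reason}",)
            ),
        )

    if _next_question_id(answers) is None:
        profile, prior, current = assemble_inputs(answers)
        rec = recommend(profile, prior, current, state.ruleset)
        return replace(state, answered=answered, terminal=rec)
    return replace(state, answered=answered)


def finalize(state: SessionState) -> tuple[Recommendation, int]:
    """Terminal recommendation and the number of questions presented."""
    if state.terminal is None:
        raise InterviewError("incomplete session: questions remain")
    return state.terminal, len(state.answered)


def run_script(
    script: dict[str, Answer], ruleset: Optional[RuleSet] = None
) -> tuple[Recommendation, int]:
    """Replay a {question id: answer} mapping through the flow."""
    state = start(ruleset)
    while True:
        q = next_question(state)
        if q is None:
            return finalize(state)
        if q.id not in script:
            raise InterviewError(f"answer script missing question {q.id!r}")
        state = submit_answer(state, q.id, script[q.id])


@dataclass(frozen=True)
class PathStats:
    """Exhaustive enumeration summary of the flow graph."""

    min_questions: int
    max_questions: int
    n_paths: int
    n_screened_out: int
    screened_out_max_questions: int
    all_terminate: bool

    def as_dict(self) -> dict:
        return {
            "min_questions": self.min_questions,
            "max_questions": self.max_questions,
            "n_paths": self.n_paths,
            "n_screened_out": self.n_screened_out,
            "screened_out_max_questions": self.screened_out_max_questions,
            "all_terminate": self.all_terminate,
        }


#: hard stop for the termination check during enumeration
MAX_FLOW_DEPTH = 20


def enumerate_paths(
    ruleset: Optional[RuleSet] = None,
    check_consistency: bool = False,
) -> PathStats:
    """Walk every path over the bucketed answer alphabet.

    Path lengths are reported over completed assessments; eligibility
    short-circuits (OUT_OF_SCOPE after the screener) are counted separately.
    With ``check_consistency`` every terminal recommendation is recomputed by
    the batch engine on the assembled inputs and compared.
    """
    lengths: list[int] = []
    screened: list[int] = []
    stack: list[dict[str, Answer]] = [{}]
    while stack:
        answers = stack.pop()
        if len(answers) > MAX_FLOW_DEPTH:
            raise InterviewError("flow failed to terminate within the depth bound")
        if answers.get("eligibility", "none") != "none":
            screened.append(len(answers))
            continue
        qid = _next_question_id(answers)
        if qid is None:
            lengths.append(len(answers))
            if check_consistency:
                rec, _ = run_script(answers, ruleset)
                batch = recommend(*assemble_inputs(answers), ruleset)
                if rec != batch:
                    raise InterviewError(
                        f"interview and batch engine disagree on {answers}"
                    )
            continue
        q = QUESTIONS[qid]
        alphabet: tuple[Answer, ...] = (
            (True, False) if q.answer_kind is AnswerKind.YES_NO else q.choices
        )
        for a in alphabet:
            nxt = dict(answers)
            nxt[qid] = a
            stack.append(nxt)
    return PathStats(
        min_questions=min(lengths),
        max_questions=max(lengths),
        n_paths=len(lengths),
        n_screened_out=len(screened),
        screened_out_max_questions=max(screened) if screened else 0,
        all_terminate=True,
    )
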