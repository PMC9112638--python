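"""Declarative rule sets: schema, loading, validation and predicate evaluation.

A rule set is a YAML document with four sections — ``index_rules`` (row per
guideline category), ``surveillance_step`` (3x3 grid keyed by risk class of
the prior and current exam), ``post_crc_sequence`` and
``family_history_rules`` — plus an ``options`` block.  The engine is nothing
but interpretation of this table; swapping the file swaps the guideline.

Loading validates structure, uniqueness of rule ids, and *coverage*: every
findings signature in a systematic grid over the count/size/histology buckets
the rules can distinguish must match at least one index rule, so the engine
is total on eligible inputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import yaml

from .model import (
    ADENOMA_HISTOLOGIES,
    SERRATED_HISTOLOGIES,
    ColonoscopyFindings,
    Histology,
    IntervalRange,
    Location,
    PolypGroup,
    Resection,
    RiskClass,
)


class RulesetError(ValueError):
    """Structural problem in a rule-set configuration."""


class DuplicateRuleError(RulesetError):
    pass


class CoverageError(RulesetError):
    """Some findings signature matches no rule on its pathway."""


class NoMatchingRuleError(RulesetError):
    """Raised at evaluation time if findings slip past the coverage check."""


Bound = tuple[int, Optional[int]]  # closed; None = unbounded above

_PREDICATE_KEYS = {
    "no_polyps",
    "adenoma_count",
    "adenoma_max_size",
    "serrated_count",
    "serrated_max_size",
    "histology_present",
    "hp_max_size",
    "hp_location",
    "piecemeal_max_size",
}


@dataclass(frozen=True)
class FindingsSignature:
    """The aggregate features rule predicates can see, extracted once per exam."""

    no_polyps: bool
    adenoma_count: int
    adenoma_max_size: int
    serrated_count: int
    serrated_max_size: int
    histologies: frozenset[Histology]
    hp_max_size: int
    hp_all_rectosigmoid: bool
    hp_any_proximal: bool
    piecemeal_max_size: int

    @classmethod
    def from_findings(cls, findings: ColonoscopyFindings) -> "FindingsSignature":
        groups = findings.normalized().polyp_groups
        aden = [g for g in groups if g.histology in ADENOMA_HISTOLOGIES]
        serr = [g for g in groups if g.histology in SERRATED_HISTOLOGIES]
        hp = [g for g in groups if g.histology is Histology.HYPERPLASTIC]
        piecemeal = [g for g in groups if g.resection is Resection.PIECEMEAL]
        return cls(
            no_polyps=not groups,
            adenoma_count=sum(g.count for g in aden),
            adenoma_max_size=max((g.max_size_mm for g in aden), default=0),
            serrated_count=sum(g.count for g in serr),
            serrated_max_size=max((g.max_size_mm for g in serr), default=0),
            histologies=frozenset(g.histology for g in groups),
            hp_max_size=max((g.max_size_mm for g in hp), default=0),
            hp_all_rectosigmoid=bool(hp)
            and all(g.location is Location.RECTOSIGMOID for g in hp),
            # UNKNOWN location is treated as proximal (conservative reading)
            hp_any_proximal=any(g.location is not Location.RECTOSIGMOID for g in hp),
            piecemeal_max_size=max((g.max_size_mm for g in piecemeal), default=0),
        )


def _in_bound(value: int, bound: Bound) -> bool:
    lo, hi = bound
    return value >= lo and (hi is None or value <= hi)


@dataclass(frozen=True)
class Rule:
    """One predicate -> interval row of the index table."""

    id: str
    predicate: dict
    interval: IntervalRange

    def matches(self, sig: FindingsSignature) -> bool:
        p = self.predicate
        if p.get("no_polyps") and not sig.no_polyps:
            return False
        if "adenoma_count" in p and not _in_bound(sig.adenoma_count, p["adenoma_count"]):
            return False
        if "adenoma_max_size" in p and not _in_bound(
            sig.adenoma_max_size, p["adenoma_max_size"]
        ):
            return False
        if "serrated_count" in p and not _in_bound(sig.serrated_count, p["serrated_count"]):
            return False
        if "serrated_max_size" in p and not _in_bound(
            sig.serrated_max_size, p["serrated_max_size"]
        ):
            return False
        if "histology_present" in p and p["histology_present"] not in sig.histologies:
            return False
        if "hp_max_size" in p and not _in_bound(sig.hp_max_size, p["hp_max_size"]):
            return False
        if "hp_location" in p:
            if p["hp_location"] is Location.RECTOSIGMOID and not sig.hp_all_rectosigmoid:
                return False
            if p["hp_location"] is Location.PROXIMAL and not sig.hp_any_proximal:
                return False
        if "piecemeal_max_size" in p and not _in_bound(
            sig.piecemeal_max_size, p["piecemeal_max_size"]
        ):
            return False
        return True


@dataclass(frozen=True)
class RuleSet:
    id: str
    index_rules: tuple[Rule, ...]
    surveillance_step: dict[tuple[RiskClass, RiskClass], IntervalRange]
    post_crc_sequence: dict[int, IntervalRange]  # keyed by colonoscopy count; max key = floor
    fh_high_risk_cap: int
    fh_average_elevated_cap: int
    options: dict = field(default_factory=dict)

    def matching_index_rules(self, findings: ColonoscopyFindings) -> list[Rule]:
        sig = FindingsSignature.from_findings(findings)
        return [r for r in self.index_rules if r.matches(sig)]

    def post_crc_interval(self, colonoscopy_count: int) -> IntervalRange:
        key = min(colonoscopy_count, max(self.post_crc_sequence))
        return self.post_crc_sequence[key]


def _parse_bound(raw: object, ctx: str) -> Bound:
    if (
        not isinstance(raw, (list, tuple))
        or len(raw) != 2
        or not isinstance(raw[0], int)
        or not (raw[1] is None or isinstance(raw[1], int))
    ):
        raise RulesetError(f"{ctx}: bound must be [int, int|null], got {raw!r}")
    lo, hi = raw
    if hi is not None and hi < lo:
        raise RulesetError(f"{ctx}: contradictory bound {raw!r}")
    return (lo, hi)


def _parse_interval(raw: object, ctx: str) -> IntervalRange:
    if not isinstance(raw, (list, tuple)) or len(raw) != 2:
        raise RulesetError(f"{ctx}: interval must be [min_months, max_months]")
    try:
        return IntervalRange(min_months=raw[0], max_months=raw[1])
    except ValueError as exc:
        raise RulesetError(f"{ctx}: {exc}") from exc


def _parse_predicate(raw: object, ctx: str) -> dict:
    if not isinstance(raw, dict) or not raw:
        raise RulesetError(f"{ctx}: 'when' must be a non-empty mapping")
    out: dict = {}
    for key, value in raw.items():
        if key not in _PREDICATE_KEYS:
            raise RulesetError(f"{ctx}: unknown predicate key {key!r}")
        if key == "no_polyps":
            if value is not True:
                raise RulesetError(f"{ctx}: no_polyps must be true when present")
            out[key] = True
        elif key == "histology_present":
            try:
                out[key] = Histology(value)
            except ValueError as exc:
                raise RulesetError(f"{ctx}: unknown histology {value!r}") from exc
        elif key == "hp_location":
            if value not in ("RECTOSIGMOID", "PROXIMAL"):
                raise RulesetError(f"{ctx}: hp_location must be RECTOSIGMOID or PROXIMAL")
            out[key] = Location(value)
        else:
            out[key] = _parse_bound(value, f"{ctx}.{key}")
    return out


def coverage_grid() -> Iterator[ColonoscopyFindings]:
    """Systematic representatives of every findings signature the rules can see.

    Buckets follow the guideline boundaries: adenoma / serrated counts in
    {0, 1–2, 3–4, 5–10, >10}, sizes in {<10, 10–19, >=20} mm, one advanced
    histology flag per arm, hyperplastic polyps by location band, and the
    piecemeal-resection flag for large lesions.
    """
    count_reps = [0, 1, 3, 5, 11]
    size_reps = [5, 10, 20]
    for a_count in count_reps:
        for a_size in size_reps if a_count else [0]:
            for a_hist in (
                [
                    Histology.TUBULAR_ADENOMA,
                    Histology.TUBULOVILLOUS_OR_VILLOUS,
                    Histology.ADENOMA_HGD,
                ]
                if a_count
                else [None]
            ):
                for s_count in count_reps:
                    for s_size in [5, 10] if s_count else [0]:
                        for s_hist in (
                            [Histology.SSP, Histology.SSP_DYSPLASIA, Histology.TSA]
                            if s_count
                            else [None]
                        ):
                            for hp in [None, "rect_small", "prox_small", "large"]:
                                for pm in [False, True] if a_size >= 20 else [False]:
                                    groups: list[PolypGroup] = []
                                    if a_count:
                                        groups.append(
                                            PolypGroup(
                                                histology=a_hist,
                                                count=a_count,
                                                max_size_mm=a_size,
                                                location=Location.PROXIMAL,
                                                resection=Resection.PIECEMEAL
                                                if pm
                                                else Resection.COMPLETE_ENBLOC,
                                            )
                                        )
                                    if s_count:
                                        if s_hist is Histology.TSA:
                                            groups.append(
                                                PolypGroup(
                                                    histology=Histology.SSP,
                                                    count=s_count,
                                                    max_size_mm=s_size,
                                                    location=Location.PROXIMAL,
                                                )
                                            )
                                            groups.append(
                                                PolypGroup(
                                                    histology=Histology.TSA,
                                                    count=1,
                                                    max_size_mm=s_size,
                                                    location=Location.RECTOSIGMOID,
                                                )
                                            )
                                        else:
                                            groups.append(
                                                PolypGroup(
                                                    histology=s_hist,
                                                    count=s_count,
                                                    max_size_mm=s_size,
                                                    location=Location.PROXIMAL,
                                                )
                                            )
                                    if hp == "rect_small":
                                        groups.append(
                                            PolypGroup(
                                                histology=Histology.HYPERPLASTIC,
                                                count=1,
                                                max_size_mm=5,
                                                location=Location.RECTOSIGMOID,
                                            )
                                        )
                                    elif hp == "prox_small":
                                        groups.append(
                                            PolypGroup(
                                                histology=Histology.HYPERPLASTIC,
                                                count=1,
                                                max_size_mm=5,
                                                location=Location.UNKNOWN,
                                            )
                                        )
                                    elif hp == "large":
                                        groups.append(
                                            PolypGroup(
                                                histology=Histology.HYPERPLASTIC,
                                                count=1,
                                                max_size_mm=12,
                                                location=Location.PROXIMAL,
                                            )
                                        )
                                    yield ColonoscopyFindings(
                                        polyp_groups=tuple(groups)
                                    )


def _check_coverage(rules: Sequence[Rule]) -> None:
    for findings in coverage_grid():
        sig = FindingsSignature.from_findings(findings)
        if not any(r.matches(sig) for r in rules):
            raise CoverageError(
                "no index rule covers findings signature: "
                f"adenomas {sig.adenoma_count}x{sig.adenoma_max_size}mm, "
                f"serrated {sig.serrated_count}x{sig.serrated_max_size}mm, "
                f"histologies {sorted(h.value for h in sig.histologies)}, "
                f"hp {sig.hp_max_size}mm"
            )


def load_ruleset(text: str) -> RuleSet:
    """Parse, validate and return a rule set from YAML text."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise RulesetError(f"rule-set YAML does not parse: {exc}") from exc
    if not isinstance(doc, dict):
        raise RulesetError("rule-set document must be a mapping")
    for section in ("index_rules", "surveillance_step", "post_crc_sequence", "family_history_rules"):
        if section not in doc:
            raise RulesetError(f"missing section {section!r}")

    rules: list[Rule] = []
    seen_ids: set[str] = set()
    for i, raw in enumerate(doc["index_rules"]):
        ctx = f"index_rules[{i}]"
        if not isinstance(raw, dict) or "id" not in raw:
            raise RulesetError(f"{ctx}: each rule needs an 'id'")
        rid = str(raw["id"])
        if rid in seen_ids:
            raise DuplicateRuleError(f"duplicate rule id {rid!r}")
        seen_ids.add(rid)
        rules.append(
            Rule(
                id=rid,
                predicate=_parse_predicate(raw.get("when"), f"{ctx} ({rid})"),
                interval=_parse_interval(raw.get("months"), f"{ctx} ({rid})"),
            )
        )
    _check_coverage(rules)

    step: dict[tuple[RiskClass, RiskClass], IntervalRange] = {}
    for prior in RiskClass:
        row = doc["surveillance_step"].get(prior.value)
        if row is None:
            raise RulesetError(f"surveillance_step missing row {prior.value}")
        for current in RiskClass:
            if current.value not in row:
                raise RulesetError(
                    f"surveillance_step missing cell ({prior.value}, {current.value})"
                )
            step[(prior, current)] = _parse_interval(
                row[current.value], f"surveillance_step[{prior.value}][{current.value}]"
            )

    seq: dict[int, IntervalRange] = {}
    for i, raw in enumerate(doc["post_crc_sequence"]):
        if not isinstance(raw, dict) or "count" not in raw:
            raise RulesetError(f"post_crc_sequence[{i}]: needs 'count' and 'months'")
        seq[int(raw["count"])] = _parse_interval(raw.get("months"), f"post_crc_sequence[{i}]")
    if 0 not in seq:
        raise RulesetError("post_crc_sequence must include count 0")

    fh = doc["family_history_rules"]
    try:
        high_cap = int(fh["high_risk_cap_months"])
        avg_cap = int(fh["average_elevated_cap_months"])
    except (KeyError, TypeError, ValueError) as exc:
        raise RulesetError(f"family_history_rules malformed: {exc}") from exc

    return RuleSet(
        id=str(doc.get("id", "unnamed")),
        index_rules=tuple(rules),
        surveillance_step=step,
        post_crc_sequence=seq,
        fh_high_risk_cap=high_cap,
        fh_average_elevated_cap=avg_cap,
        options=doc.get("options") or {},
    )


def default_ruleset_text() -> str:
    return (
        importlib.resources.files("polypsurv.data")
        .joinpath("default_rules.yaml")
        .read_text(encoding="utf-8")
    )


def default_ruleset() -> RuleSet:
    """The bundled CAG/USMSTF transcription (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_ruleset(default_ruleset_text())
    return _DEFAULT


_DEFAULT: Optional[RuleSet] = None
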