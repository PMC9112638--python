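"""Deterministic mapping from patient + findings to a surveillance interval.

Pathways mirror clinical practice: an eligibility gate (screening-age,
non-hereditary, non-IBD patients only), then dispatch to the post-CRC-resection
sequence, the second-surveillance grid, or the index-colonoscopy table, with
the family-history cap applied last.  When several rules match, the most
conservative (elementwise-minimum) interval wins and every matching rule id is
reported, in rule-table order.
"""

from __future__ import annotations

from typing import Optional

from .model import (
    ADENOMA_HISTOLOGIES,
    SERRATED_HISTOLOGIES,
    ColonoscopyFindings,
    FamilyHistory,
    Histology,
    IntervalRange,
    PatientProfile,
    Recommendation,
    RiskClass,
    Status,
)
from .rules import NoMatchingRuleError, RuleSet, default_ruleset

#: Age (years) at and above which the tool declines to recommend.
SCREENING_AGE_LIMIT = 75


def check_eligibility(profile: PatientProfile) -> Optional[Recommendation]:
    """Return an OUT_OF_SCOPE recommendation, or None when the gate passes.

    The tool addresses average/familial-risk screening-age patients; decisions
    for patients aged >= 75 and for hereditary CRC syndromes or IBD are made
    case by case outside the tool.
    """
    reasons = []
    if profile.age_years >= SCREENING_AGE_LIMIT:
        reasons.append(f"age >= {SCREENING_AGE_LIMIT}")
    if profile.hereditary_syndrome:
        reasons.append("hereditary CRC syndrome")
    if profile.ibd:
        reasons.append("inflammatory bowel disease")
    if reasons:
        return Recommendation(
            status=Status.OUT_OF_SCOPE,
            rationale=tuple(f"out of scope: {r}" for r in reasons),
        )
    return None


def classify_risk(findings: ColonoscopyFindings, ruleset: Optional[RuleSet] = None) -> RiskClass:
    """Collapse one exam into NORMAL / LOW_RISK / HIGH_RISK for the step grid.

    High risk: any adenoma >= 10 mm, tubulovillous/villous histology, high-grade
    dysplasia, >= 5 adenomas, sessile serrated lesion >= 10 mm or with
    dysplasia, or a traditional serrated adenoma.  Thresholds are configurable
    through the rule-set options block.
    """
    ruleset = ruleset or default_ruleset()
    opts = (ruleset.options or {}).get("high_risk", {})
    aden_size = int(opts.get("adenoma_min_size_mm", 10))
    aden_count = int(opts.get("adenoma_min_count", 5))
    serr_size = int(opts.get("serrated_min_size_mm", 10))

    groups = findings.normalized().polyp_groups
    if not groups:
        return RiskClass.NORMAL
    adenomas = [g for g in groups if g.histology in ADENOMA_HISTOLOGIES]
    serrated = [g for g in groups if g.histology in SERRATED_HISTOLOGIES]
    high = (
        any(g.max_size_mm >= aden_size for g in adenomas)
        or any(
            g.histology in (Histology.TUBULOVILLOUS_OR_VILLOUS, Histology.ADENOMA_HGD)
            for g in groups
        )
        or sum(g.count for g in adenomas) >= aden_count
        or any(g.max_size_mm >= serr_size for g in serrated)
        or any(g.histology is Histology.SSP_DYSPLASIA for g in groups)
        or any(g.histology is Histology.TSA for g in groups)
    )
    return RiskClass.HIGH_RISK if high else RiskClass.LOW_RISK


def _quality_gate(findings: ColonoscopyFindings) -> Optional[Recommendation]:
    if not findings.cecum_reached or not findings.prep_adequate:
        return Recommendation(
            status=Status.CASE_BY_CASE,
            rationale=(
                "repeat/complete high-quality examination: guideline intervals "
                "assume a complete colonoscopy with adequate bowel preparation",
            ),
        )
    return None


def recommend_index(
    profile: PatientProfile,
    findings: ColonoscopyFindings,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Index-colonoscopy pathway: evaluate every matching rule, keep the minimum."""
    ruleset = ruleset or default_ruleset()
    gated = _quality_gate(findings)
    if gated is not None:
        return gated
    matches = ruleset.matching_index_rules(findings)
    if not matches:
        sig = findings.normalized().polyp_groups
        raise NoMatchingRuleError(
            f"no index rule matches findings with groups {[g.model_dump() for g in sig]}"
        )
    interval = matches[0].interval
    for rule in matches[1:]:
        interval = interval.combine_min(rule.interval)
    return Recommendation(
        status=Status.INTERVAL,
        interval=interval,
        fired_rule_ids=tuple(r.id for r in matches),
        rationale=tuple(
            f"{r.id}: {r.interval.pretty_years()}" for r in matches
        ),
    )


def recommend_surveillance(
    profile: PatientProfile,
    prior: ColonoscopyFindings,
    current: ColonoscopyFindings,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Second-surveillance pathway keyed by (prior, current) risk class."""
    ruleset = ruleset or default_ruleset()
    gated = _quality_gate(current)
    if gated is not None:
        return gated
    prior_risk = classify_risk(prior, ruleset)
    current_risk = classify_risk(current, ruleset)
    try:
        step_interval = ruleset.surveillance_step[(prior_risk, current_risk)]
    except KeyError as exc:  # load_ruleset guarantees the full grid; belt and braces
        raise NoMatchingRuleError(
            f"surveillance grid missing cell ({prior_risk.value}, {current_risk.value})"
        ) from exc
    step_id = f"step_{prior_risk.value}__{current_risk.value}"
    fired = [step_id]
    rationale = [
        f"{step_id}: prior exam {prior_risk.value}, current exam {current_risk.value} "
        f"-> {step_interval.pretty_years()}"
    ]
    interval = step_interval
    if not current.is_normal:
        index_rec = recommend_index(profile, current, ruleset)
        interval = interval.combine_min(index_rec.interval)
        fired.extend(index_rec.fired_rule_ids)
        rationale.extend(index_rec.rationale)
    return Recommendation(
        status=Status.INTERVAL,
        interval=interval,
        fired_rule_ids=tuple(fired),
        rationale=tuple(rationale),
    )


def recommend_post_crc(
    profile: PatientProfile,
    findings: ColonoscopyFindings,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Post-CRC-resection sequence (1 y, then 3 y, then every 5 y by default)."""
    if not profile.crc_history:
        raise ValueError("recommend_post_crc requires profile.crc_history")
    ruleset = ruleset or default_ruleset()
    gated = _quality_gate(findings)
    if gated is not None:
        return gated
    count = profile.post_resection_colonoscopy_count
    base = ruleset.post_crc_interval(count)
    step_id = f"post_crc_{min(count, max(ruleset.post_crc_sequence))}"
    fired = [step_id]
    rationale = [
        f"{step_id}: colonoscopy {count} after CRC resection -> {base.pretty_years()}"
    ]
    interval = base
    if not findings.is_normal:
        index_rec = recommend_index(profile, findings, ruleset)
        interval = interval.combine_min(index_rec.interval)
        fired.extend(index_rec.fired_rule_ids)
        rationale.extend(index_rec.rationale)
    return Recommendation(
        status=Status.INTERVAL,
        interval=interval,
        fired_rule_ids=tuple(fired),
        rationale=tuple(rationale),
    )


def _fh_cap(fh: FamilyHistory, ruleset: RuleSet) -> tuple[Optional[int], str]:
    if fh.is_empty:
        return None, ""
    young = fh.youngest_dx_age is not None and fh.youngest_dx_age < 60
    if fh.fdr_crc_count >= 2 or young:
        return (
            ruleset.fh_high_risk_cap,
            "high-risk family history (>= 2 FDRs with CRC, or FDR diagnosed < 60)",
        )
    return (
        ruleset.fh_average_elevated_cap,
        "family history: single FDR diagnosed at >= 60",
    )


def apply_family_history(
    base: Recommendation,
    fh: FamilyHistory,
    age_years: int,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Cap an interval recommendation by the familial-risk screening interval.

    The cap is an elementwise minimum, so it is idempotent and never loosens a
    recommendation already at least as tight.
    """
    if base.status is not Status.INTERVAL:
        raise ValueError("apply_family_history requires an INTERVAL recommendation")
    ruleset = ruleset or default_ruleset()
    cap, reason = _fh_cap(fh, ruleset)
    if cap is None:
        return base
    capped = base.interval.cap(cap)
    if capped == base.interval:
        return base
    return Recommendation(
        status=Status.INTERVAL,
        interval=capped,
        fired_rule_ids=base.fired_rule_ids + ("family_history_cap",),
        rationale=base.rationale + (f"family_history_cap: {reason} -> cap {cap} months",),
    )


def recommend(
    profile: PatientProfile,
    prior: Optional[ColonoscopyFindings],
    current: ColonoscopyFindings,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Top-level dispatcher; the single entry point batch callers need.

    Order: eligibility gate, then post-CRC pathway if the patient has had a
    CRC resection, then the second-surveillance pathway when a prior exam is
    given, else the index pathway; the family-history cap is applied last.
    """
    ruleset = ruleset or default_ruleset()
    gate = check_eligibility(profile)
    if gate is not None:
        return gate
    if profile.crc_history:
        rec = recommend_post_crc(profile, current, ruleset)
    elif prior is not None:
        rec = recommend_surveillance(profile, prior, current, ruleset)
    else:
        rec = recommend_index(profile, current, ruleset)
    if rec.status is Status.INTERVAL:
        rec = apply_family_history(rec, profile.family_history, profile.age_years, ruleset)
    return rec


def brute_force_recommend(
    profile: PatientProfile,
    prior: Optional[ColonoscopyFindings],
    current: ColonoscopyFindings,
    ruleset: Optional[RuleSet] = None,
) -> Recommendation:
    """Independent re-evaluation used as an oracle in tests.

    Tests every index-rule predicate one by one against the raw findings
    signature, folds the applicable pathway interval in by brute elementwise
    minimum, and applies the family-history cap arithmetically.  Shares no
    combination code with :func:`recommend`.
    """
    from .rules import FindingsSignature

    ruleset = ruleset or default_ruleset()
    gate = check_eligibility(profile)
    if gate is not None:
        return gate
    findings = current
    if not findings.cecum_reached or not findings.prep_adequate:
        return _quality_gate(findings)

    candidates: list[tuple[int, int]] = []
    ids: list[str] = []
    if profile.crc_history:
        count = min(
            profile.post_resection_colonoscopy_count, max(ruleset.post_crc_sequence)
        )
        iv = ruleset.post_crc_sequence[count]
        candidates.append((iv.min_months, iv.max_months))
        ids.append(f"post_crc_{count}")
        use_index = not findings.is_normal
    elif prior is not None:
        cell = (classify_risk(prior, ruleset), classify_risk(findings, ruleset))
        iv = ruleset.surveillance_step[cell]
        candidates.append((iv.min_months, iv.max_months))
        ids.append(f"step_{cell[0].value}__{cell[1].value}")
        use_index = not findings.is_normal
    else:
        use_index = True
    if use_index:
        sig = FindingsSignature.from_findings(findings)
        for rule in ruleset.index_rules:
            if rule.matches(sig):
                candidates.append((rule.interval.min_months, rule.interval.max_months))
                ids.append(rule.id)
    lo = min(c[0] for c in candidates)
    hi = min(c[1] for c in candidates)
    cap, _ = _fh_cap(profile.family_history, ruleset)
    if cap is not None and (cap < lo or cap < hi):
        lo, hi = min(lo, cap), min(hi, cap)
        ids.append("family_history_cap")
    return Recommendation(
        status=Status.INTERVAL,
        interval=IntervalRange(min_months=lo, max_months=hi),
        fired_rule_ids=tuple(ids),
    )
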