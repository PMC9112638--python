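"""Readers and writers for case records and recommendation reports.

JSON is the canonical format: one object per case with ``profile``, optional
``prior`` and ``current`` sections that mirror the pydantic models exactly,
so a JSON round trip is the identity on every record.

The CSV format is a flat convenience layout — one row per case with
per-histology count/size columns for the current and prior exam.  It cannot
carry per-group locations (except the hyperplastic column) or attribute a
piecemeal resection to a specific group; on read a recorded piecemeal size is
attached to the largest group.  Records expressible in those terms round-trip
exactly; richer records belong in JSON.
"""

from __future__ import annotations

import json
from typing import Optional, Sequence, TextIO

import pandas as pd

from .model import (
    ColonoscopyFindings,
    ExamOrdinal,
    Histology,
    Location,
    PatientProfile,
    PolypGroup,
    Recommendation,
    Resection,
)
from .simulate import CohortCase

_CSV_HISTOLOGY = {
    "ta": Histology.TUBULAR_ADENOMA,
    "tvv": Histology.TUBULOVILLOUS_OR_VILLOUS,
    "hgd": Histology.ADENOMA_HGD,
    "ssp": Histology.SSP,
    "sspd": Histology.SSP_DYSPLASIA,
    "tsa": Histology.TSA,
    "hp": Histology.HYPERPLASTIC,
}
_CSV_ABBREV = {h: a for a, h in _CSV_HISTOLOGY.items()}


def case_to_dict(case: CohortCase) -> dict:
    return {
        "profile": case.profile.model_dump(),
        "prior": case.prior.model_dump() if case.prior is not None else None,
        "current": case.current.model_dump(),
    }


def case_from_dict(doc: dict) -> CohortCase:
    return CohortCase(
        profile=PatientProfile.model_validate(doc["profile"]),
        prior=(
            ColonoscopyFindings.model_validate(doc["prior"])
            if doc.get("prior") is not None
            else None
        ),
        current=ColonoscopyFindings.model_validate(doc["current"]),
    )


def write_cases_json(cases: Sequence[CohortCase], fp: TextIO) -> None:
    json.dump([case_to_dict(c) for c in cases], fp, indent=2)
    fp.write("\n")


def read_cases_json(fp: TextIO) -> list[CohortCase]:
    docs = json.load(fp)
    if not isinstance(docs, list):
        docs = [docs]
    out = []
    for i, doc in enumerate(docs):
        try:
            out.append(case_from_dict(doc))
        except Exception as exc:
            raise ValueError(f"record {i}: {exc}") from exc
    return out


def _findings_to_row(findings: Optional[ColonoscopyFindings], prefix: str) -> dict:
    row: dict = {}
    if findings is None:
        return row
    norm = findings.normalized()
    by_hist: dict[Histology, list[PolypGroup]] = {}
    for g in norm.polyp_groups:
        by_hist.setdefault(g.histology, []).append(g)
    for abbrev, hist in _CSV_HISTOLOGY.items():
        groups = by_hist.get(hist, [])
        row[f"{prefix}_{abbrev}_count"] = sum(g.count for g in groups)
        row[f"{prefix}_{abbrev}_max_size"] = max(
            (g.max_size_mm for g in groups), default=0
        )
    hp_groups = by_hist.get(Histology.HYPERPLASTIC, [])
    row[f"{prefix}_hp_location"] = (
        hp_groups[0].location.value if hp_groups else ""
    )
    row[f"{prefix}_piecemeal_max_size"] = max(
        (g.max_size_mm for g in norm.polyp_groups if g.resection is Resection.PIECEMEAL),
        default=0,
    )
    row[f"{prefix}_cecum_reached"] = findings.cecum_reached
    row[f"{prefix}_prep_adequate"] = findings.prep_adequate
    return row


def _findings_from_row(row: dict, prefix: str, ordinal: ExamOrdinal) -> ColonoscopyFindings:
    groups: list[PolypGroup] = []
    for abbrev, hist in _CSV_HISTOLOGY.items():
        count = int(row.get(f"{prefix}_{abbrev}_count") or 0)
        if count <= 0:
            continue
        size = int(row.get(f"{prefix}_{abbrev}_max_size") or 0)
        loc = Location.UNKNOWN
        if hist is Histology.HYPERPLASTIC and row.get(f"{prefix}_hp_location"):
            loc = Location(row[f"{prefix}_hp_location"])
        groups.append(
            PolypGroup(histology=hist, count=count, max_size_mm=max(size, 1), location=loc)
        )
    pm = int(row.get(f"{prefix}_piecemeal_max_size") or 0)
    if pm > 0 and groups:
        largest = max(range(len(groups)), key=lambda i: groups[i].max_size_mm)
        groups[largest] = groups[largest].model_copy(
            update={"resection": Resection.PIECEMEAL}
        )
    def _flag(name: str, default: bool = True) -> bool:
        val = row.get(f"{prefix}_{name}")
        if val is None or val == "" or (isinstance(val, float) and pd.isna(val)):
            return default
        return str(val).strip().lower() in ("true", "1", "yes")
    return ColonoscopyFindings(
        polyp_groups=tuple(groups),
        ordinal=ordinal,
        cecum_reached=_flag("cecum_reached"),
        prep_adequate=_flag("prep_adequate"),
    )


def cases_to_frame(cases: Sequence[CohortCase]) -> pd.DataFrame:
    rows = []
    for case in cases:
        p = case.profile
        row = {
            "age_years": p.age_years,
            "crc_history": p.crc_history,
            "months_since_crc_resection": (
                "" if p.months_since_crc_resection is None else p.months_since_crc_resection
            ),
            "post_resection_colonoscopy_count": p.post_resection_colonoscopy_count,
            "hereditary_syndrome": p.hereditary_syndrome,
            "ibd": p.ibd,
            "fdr_crc_count": p.family_history.fdr_crc_count,
            "youngest_dx_age": (
                "" if p.family_history.youngest_dx_age is None
                else p.family_history.youngest_dx_age
            ),
            "fdr_advanced_adenoma": p.family_history.fdr_advanced_adenoma,
            "has_prior": case.prior is not None,
        }
        row.update(_findings_to_row(case.current, "cur"))
        row.update(_findings_to_row(case.prior, "prior"))
        rows.append(row)
    return pd.DataFrame(rows)


def write_cases_csv(cases: Sequence[CohortCase], fp: TextIO) -> None:
    cases_to_frame(cases).to_csv(fp, index=False)


def _int_or_none(value) -> Optional[int]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return int(value)


def read_cases_csv(fp: TextIO) -> list[CohortCase]:
    frame = pd.read_csv(fp)
    out: list[CohortCase] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            from .model import FamilyHistory

            profile = PatientProfile(
                age_years=int(row["age_years"]),
                crc_history=bool(row["crc_history"]),
                months_since_crc_resection=_int_or_none(
                    row.get("months_since_crc_resection")
                ),
                post_resection_colonoscopy_count=int(
                    row.get("post_resection_colonoscopy_count") or 0
                ),
                hereditary_syndrome=bool(row.get("hereditary_syndrome", False)),
                ibd=bool(row.get("ibd", False)),
                family_history=FamilyHistory(
                    fdr_crc_count=int(row.get("fdr_crc_count") or 0),
                    youngest_dx_age=_int_or_none(row.get("youngest_dx_age")),
                    fdr_advanced_adenoma=bool(row.get("fdr_advanced_adenoma", False)),
                ),
            )
            has_prior = str(row.get("has_prior", "")).strip().lower() in ("true", "1", "yes")
            prior = (
                _findings_from_row(row, "prior", ExamOrdinal.INDEX) if has_prior else None
            )
            ordinal = (
                ExamOrdinal.SURVEILLANCE if has_prior else ExamOrdinal.INDEX
            )
            current = _findings_from_row(row, "cur", ordinal)
            out.append(CohortCase(profile=profile, prior=prior, current=current))
        except Exception as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return out


def recommendation_to_dict(rec: Recommendation) -> dict:
    return {
        "status": rec.status.value,
        "min_months": rec.interval.min_months if rec.interval else None,
        "max_months": rec.interval.max_months if rec.interval else None,
        "interval_pretty": rec.interval.pretty_years() if rec.interval else None,
        "fired_rule_ids": list(rec.fired_rule_ids),
        "rationale": list(rec.rationale),
    }
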