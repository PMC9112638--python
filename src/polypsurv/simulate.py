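"""Seeded synthetic cohorts of screening-age colonoscopy cases.

The generator emulates a mixed colonoscopy practice: index exams, second
surveillance exams, and post-CRC-resection follow-ups, with polyp findings
spread over every histology, count band and size band the rule tables
distinguish.  Mixture weights are test scaffolding chosen so a modest cohort
(n >= 500) exercises every default index rule, including the rarer ones
(>10 adenomas, piecemeal resection of a >= 20 mm lesion); they do not model
real polyp-prevalence epidemiology.
"""

from __future__ import annotations

from typing import NamedTuple, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .model import (
    ColonoscopyFindings,
    ExamOrdinal,
    FamilyHistory,
    Histology,
    Location,
    PatientProfile,
    PolypGroup,
    Resection,
)


class CohortCase(NamedTuple):
    profile: PatientProfile
    prior: Optional[ColonoscopyFindings]
    current: ColonoscopyFindings


def _normalized(weights: dict) -> dict:
    total = sum(weights.values())
    return {k: v / total for k, v in weights.items()}


class CohortSpec(BaseModel):
    """Mixture specification for one synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    n: int = Field(ge=1)
    seed: int = 0
    pathway_weights: dict[str, float] = {"index": 0.5, "surveillance": 0.3, "post_crc": 0.2}
    #: probability a record trips the eligibility gate (split evenly between
    #: age >= 75, hereditary syndrome and IBD)
    exclusion_rate: float = Field(default=0.05, ge=0.0, le=1.0)
    #: adenoma count-band weights (keys: 0, 1_2, 3_4, 5_10, gt_10)
    adenoma_count_weights: dict[str, float] = {
        "0": 0.30, "1_2": 0.30, "3_4": 0.15, "5_10": 0.15, "gt_10": 0.10,
    }
    #: adenoma size-band weights (keys: lt10, 10_19, ge20)
    adenoma_size_weights: dict[str, float] = {"lt10": 0.55, "10_19": 0.25, "ge20": 0.20}
    #: advanced-histology weights for the adenoma arm (none / villous / hgd)
    adenoma_histology_weights: dict[str, float] = {"none": 0.6, "villous": 0.2, "hgd": 0.2}
    serrated_count_weights: dict[str, float] = {"0": 0.45, "1_2": 0.25, "3_4": 0.15, "5_10": 0.15}
    serrated_size_weights: dict[str, float] = {"lt10": 0.7, "ge10": 0.3}
    serrated_type_weights: dict[str, float] = {"ssp": 0.6, "ssp_dysplasia": 0.2, "tsa": 0.2}
    hp_weights: dict[str, float] = {
        "none": 0.45, "rectosigmoid_lt10": 0.25, "proximal_lt10": 0.15, "ge10": 0.15,
    }
    #: chance a >= 20 mm lesion was removed piecemeal
    piecemeal_rate: float = Field(default=0.5, ge=0.0, le=1.0)
    #: family-history mix (none / single FDR dx >= 60 / high risk)
    fh_weights: dict[str, float] = {"none": 0.7, "fdr_ge60": 0.15, "high_risk": 0.15}
    #: chance the current exam fails the quality gate (cecum/prep)
    poor_quality_rate: float = Field(default=0.0, ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _weights_valid(self) -> "CohortSpec":
        for name in (
            "pathway_weights", "adenoma_count_weights", "adenoma_size_weights",
            "adenoma_histology_weights", "serrated_count_weights",
            "serrated_size_weights", "serrated_type_weights", "hp_weights", "fh_weights",
        ):
            block = getattr(self, name)
            if any(v < 0 for v in block.values()):
                raise ValueError(f"{name}: weights must be non-negative")
            if sum(block.values()) <= 0:
                raise ValueError(f"{name}: weights must not all be zero")
        return self


def _pick(rng: np.random.Generator, weights: dict) -> str:
    w = _normalized(weights)
    keys = list(w)
    return keys[rng.choice(len(keys), p=list(w.values()))]


_COUNT_BANDS = {"0": (0, 0), "1_2": (1, 2), "3_4": (3, 4), "5_10": (5, 10), "gt_10": (11, 15)}
_SIZE_BANDS = {"lt10": (3, 9), "10_19": (10, 19), "ge20": (20, 35), "ge10": (10, 25)}


def _sample_findings(rng: np.random.Generator, spec: CohortSpec, ordinal: ExamOrdinal) -> ColonoscopyFindings:
    groups: list[PolypGroup] = []

    band = _pick(rng, spec.adenoma_count_weights)
    lo, hi = _COUNT_BANDS[band]
    a_count = int(rng.integers(lo, hi + 1)) if hi else 0
    if a_count:
        s_lo, s_hi = _SIZE_BANDS[_pick(rng, spec.adenoma_size_weights)]
        size = int(rng.integers(s_lo, s_hi + 1))
        hist = {
            "none": Histology.TUBULAR_ADENOMA,
            "villous": Histology.TUBULOVILLOUS_OR_VILLOUS,
            "hgd": Histology.ADENOMA_HGD,
        }[_pick(rng, spec.adenoma_histology_weights)]
        resection = (
            Resection.PIECEMEAL
            if size >= 20 and rng.random() < spec.piecemeal_rate
            else Resection.COMPLETE_ENBLOC
        )
        groups.append(
            PolypGroup(
                histology=hist,
                count=a_count,
                max_size_mm=size,
                location=Location.PROXIMAL if rng.random() < 0.6 else Location.RECTOSIGMOID,
                resection=resection,
            )
        )

    band = _pick(rng, spec.serrated_count_weights)
    lo, hi = _COUNT_BANDS[band]
    s_count = int(rng.integers(lo, hi + 1)) if hi else 0
    if s_count:
        s_lo, s_hi = _SIZE_BANDS[_pick(rng, spec.serrated_size_weights)]
        size = int(rng.integers(s_lo, s_hi + 1))
        stype = _pick(rng, spec.serrated_type_weights)
        hist = Histology.SSP_DYSPLASIA if stype == "ssp_dysplasia" else Histology.SSP
        groups.append(
            PolypGroup(
                histology=hist, count=s_count, max_size_mm=size, location=Location.PROXIMAL
            )
        )
        if stype == "tsa":
            groups.append(
                PolypGroup(
                    histology=Histology.TSA, count=1, max_size_mm=5,
                    location=Location.RECTOSIGMOID,
                )
            )

    hp = _pick(rng, spec.hp_weights)
    if hp != "none":
        loc = {
            "rectosigmoid_lt10": Location.RECTOSIGMOID,
            "proximal_lt10": Location.PROXIMAL,
            "ge10": Location.PROXIMAL,
        }[hp]
        size = int(rng.integers(10, 16)) if hp == "ge10" else int(rng.integers(2, 10))
        groups.append(
            PolypGroup(histology=Histology.HYPERPLASTIC, count=1, max_size_mm=size, location=loc)
        )

    poor = rng.random() < spec.poor_quality_rate
    return ColonoscopyFindings(
        polyp_groups=tuple(groups),
        ordinal=ordinal,
        cecum_reached=not poor,
        prep_adequate=True,
    )


def _sample_fh(rng: np.random.Generator, spec: CohortSpec) -> FamilyHistory:
    kind = _pick(rng, spec.fh_weights)
    if kind == "none":
        return FamilyHistory()
    if kind == "fdr_ge60":
        return FamilyHistory(fdr_crc_count=1, youngest_dx_age=int(rng.integers(60, 85)))
    if rng.random() < 0.5:
        return FamilyHistory(fdr_crc_count=2, youngest_dx_age=int(rng.integers(40, 80)))
    return FamilyHistory(fdr_crc_count=1, youngest_dx_age=int(rng.integers(35, 60)))


def generate_cohort(spec: CohortSpec) -> list[CohortCase]:
    """Deterministically (by seed) draw ``spec.n`` validated cases."""
    rng = np.random.default_rng(spec.seed)
    cases: list[CohortCase] = []
    for _ in range(spec.n):
        excluded = rng.random() < spec.exclusion_rate
        age = int(rng.integers(75, 95)) if excluded and rng.random() < 1 / 3 else int(
            rng.integers(50, 75)
        )
        hereditary = excluded and age < 75 and rng.random() < 0.5
        ibd = excluded and age < 75 and not hereditary

        pathway = _pick(rng, spec.pathway_weights)
        prior: Optional[ColonoscopyFindings] = None
        crc = pathway == "post_crc"
        if pathway == "surveillance":
            prior = _sample_findings(rng, spec, ExamOrdinal.INDEX)
            ordinal = ExamOrdinal.SURVEILLANCE
        else:
            ordinal = ExamOrdinal.INDEX
        current = _sample_findings(rng, spec, ordinal)
        profile = PatientProfile(
            age_years=age,
            crc_history=crc,
            months_since_crc_resection=int(rng.integers(6, 120)) if crc else None,
            post_resection_colonoscopy_count=int(rng.integers(0, 4)) if crc else 0,
            family_history=_sample_fh(rng, spec),
            hereditary_syndrome=hereditary,
            ibd=ibd,
        )
        cases.append(CohortCase(profile=profile, prior=prior, current=current))
    return cases
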