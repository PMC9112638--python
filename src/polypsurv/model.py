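"""Domain model for colonoscopy polyp-surveillance decisions.

The types here carry everything the guideline rule engine needs: a patient's
screening-relevant history, the polypectomy findings of one colonoscopy
(grouped by histology), and the engine's output — a recommended surveillance
interval expressed as a closed range in months.

All records validate on construction (pydantic); the engine may therefore
assume well-formed inputs everywhere downstream.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Histology(str, enum.Enum):
    """Histological category of a polyp group.

    The first three are conventional adenomas (tubular; tubulovillous or
    villous; any adenoma harbouring high-grade dysplasia).  SSP is a sessile
    serrated polyp, with or without cytological dysplasia; TSA a traditional
    serrated adenoma; HYPERPLASTIC the innocuous end of the serrated spectrum.
    """

    TUBULAR_ADENOMA = "TUBULAR_ADENOMA"
    TUBULOVILLOUS_OR_VILLOUS = "TUBULOVILLOUS_OR_VILLOUS"
    ADENOMA_HGD = "ADENOMA_HGD"
    SSP = "SSP"
    SSP_DYSPLASIA = "SSP_DYSPLASIA"
    TSA = "TSA"
    HYPERPLASTIC = "HYPERPLASTIC"


#: Histologies whose counts aggregate as "adenomas" in count-based rules.
ADENOMA_HISTOLOGIES = frozenset(
    {Histology.TUBULAR_ADENOMA, Histology.TUBULOVILLOUS_OR_VILLOUS, Histology.ADENOMA_HGD}
)
#: Histologies whose counts aggregate as "sessile serrated" in count-based rules.
SERRATED_HISTOLOGIES = frozenset({Histology.SSP, Histology.SSP_DYSPLASIA})


class Location(str, enum.Enum):
    RECTOSIGMOID = "RECTOSIGMOID"
    PROXIMAL = "PROXIMAL"
    UNKNOWN = "UNKNOWN"


class Resection(str, enum.Enum):
    COMPLETE_ENBLOC = "COMPLETE_ENBLOC"
    PIECEMEAL = "PIECEMEAL"
    INCOMPLETE = "INCOMPLETE"


class ExamOrdinal(str, enum.Enum):
    INDEX = "INDEX"
    SURVEILLANCE = "SURVEILLANCE"


class Status(str, enum.Enum):
    """Outcome class of a recommendation."""

    INTERVAL = "INTERVAL"
    NO_FURTHER = "NO_FURTHER"
    CASE_BY_CASE = "CASE_BY_CASE"
    OUT_OF_SCOPE = "OUT_OF_SCOPE"


class RiskClass(str, enum.Enum):
    """Collapsed risk stratum of one colonoscopy, keying second-surveillance rules."""

    NORMAL = "NORMAL"
    LOW_RISK = "LOW_RISK"
    HIGH_RISK = "HIGH_RISK"


class PolypGroup(BaseModel):
    """All polyps of one histology (and location) found at one colonoscopy."""

    model_config = ConfigDict(frozen=True)

    histology: Histology
    count: int = Field(ge=1)
    max_size_mm: int = Field(ge=1)
    location: Location = Location.UNKNOWN
    resection: Resection = Resection.COMPLETE_ENBLOC


_RESECTION_SEVERITY = {
    Resection.COMPLETE_ENBLOC: 0,
    Resection.PIECEMEAL: 1,
    Resection.INCOMPLETE: 2,
}


class ColonoscopyFindings(BaseModel):
    """Findings of one colonoscopy; an empty group list is a normal exam."""

    model_config = ConfigDict(frozen=True)

    polyp_groups: tuple[PolypGroup, ...] = ()
    cecum_reached: bool = True
    prep_adequate: bool = True
    ordinal: ExamOrdinal = ExamOrdinal.INDEX

    @property
    def is_normal(self) -> bool:
        return not self.polyp_groups

    def normalized(self) -> "ColonoscopyFindings":
        """Merge groups sharing (histology, location).

        Counts add, the maximum size wins, and the worst resection mode
        (incomplete > piecemeal > complete en-bloc) is kept, so merging never
        loses conservative information.
        """
        merged: dict[tuple[Histology, Location], PolypGroup] = {}
        for g in self.polyp_groups:
            key = (g.histology, g.location)
            if key in merged:
                prev = merged[key]
                merged[key] = PolypGroup(
                    histology=g.histology,
                    count=prev.count + g.count,
                    max_size_mm=max(prev.max_size_mm, g.max_size_mm),
                    location=g.location,
                    resection=max(
                        prev.resection, g.resection, key=_RESECTION_SEVERITY.__getitem__
                    ),
                )
            else:
                merged[key] = g
        return self.model_copy(update={"polyp_groups": tuple(merged.values())})


class FamilyHistory(BaseModel):
    """First-degree-relative (FDR) colorectal cancer / advanced adenoma history."""

    model_config = ConfigDict(frozen=True)

    fdr_crc_count: int = Field(default=0, ge=0)
    youngest_dx_age: Optional[int] = Field(default=None, ge=0)
    fdr_advanced_adenoma: bool = False

    @model_validator(mode="after")
    def _dx_age_presence(self) -> "FamilyHistory":
        relevant = self.fdr_crc_count >= 1 or self.fdr_advanced_adenoma
        if relevant and self.youngest_dx_age is None:
            raise ValueError(
                "youngest_dx_age is required when fdr_crc_count >= 1 "
                "or fdr_advanced_adenoma is set"
            )
        if not relevant and self.youngest_dx_age is not None:
            raise ValueError("youngest_dx_age given without any qualifying family history")
        return self

    @property
    def is_empty(self) -> bool:
        return self.fdr_crc_count == 0 and not self.fdr_advanced_adenoma


class PatientProfile(BaseModel):
    model_config = ConfigDict(frozen=True)

    age_years: int = Field(ge=0, le=130)
    crc_history: bool = False
    months_since_crc_resection: Optional[int] = Field(default=None, ge=0)
    post_resection_colonoscopy_count: int = Field(default=0, ge=0)
    family_history: FamilyHistory = FamilyHistory()
    hereditary_syndrome: bool = False
    ibd: bool = False

    @model_validator(mode="after")
    def _crc_fields(self) -> "PatientProfile":
        if self.crc_history and self.months_since_crc_resection is None:
            raise ValueError("months_since_crc_resection required when crc_history is set")
        if not self.crc_history and self.months_since_crc_resection is not None:
            raise ValueError("months_since_crc_resection given without crc_history")
        return self


class IntervalRange(BaseModel):
    """Closed recommended-interval range, in months."""

    model_config = ConfigDict(frozen=True)

    min_months: int = Field(gt=0)
    max_months: int = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "IntervalRange":
        if self.min_months > self.max_months:
            raise ValueError("min_months must not exceed max_months")
        return self

    def combine_min(self, other: "IntervalRange") -> "IntervalRange":
        """Most-conservative combination: elementwise minimum of the bounds."""
        return IntervalRange(
            min_months=min(self.min_months, other.min_months),
            max_months=min(self.max_months, other.max_months),
        )

    def cap(self, months: int) -> "IntervalRange":
        return IntervalRange(
            min_months=min(self.min_months, months),
            max_months=min(self.max_months, months),
        )

    def pretty_years(self) -> str:
        def fmt(m: int) -> str:
            return f"{m // 12} y" if m % 12 == 0 else f"{m} mo"

        if self.min_months == self.max_months:
            return fmt(self.min_months)
        return f"{fmt(self.min_months)}–{fmt(self.max_months)}"


class Recommendation(BaseModel):
    model_config = ConfigDict(frozen=True)

    status: Status
    interval: Optional[IntervalRange] = None
    fired_rule_ids: tuple[str, ...] = ()
    rationale: tuple[str, ...] = ()

    @model_validator(mode="after")
    def _interval_iff_status(self) -> "Recommendation":
        if (self.status is Status.INTERVAL) != (self.interval is not None):
            raise ValueError("interval must be present exactly when status is INTERVAL")
        if self.status is Status.INTERVAL and not self.fired_rule_ids:
            raise ValueError("an INTERVAL recommendation must cite the rules that fired")
        return self
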