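import pytest

from polypsurv import (
    ColonoscopyFindings,
    FamilyHistory,
    Histology,
    IntervalRange,
    Location,
    PatientProfile,
    Resection,
    RiskClass,
    Status,
    apply_family_history,
    check_eligibility,
    classify_risk,
    recommend,
    recommend_index,
    recommend_post_crc,
    recommend_surveillance,
)
from conftest import exam, group


class TestEligibilityGate:
    def test_age_75_and_over_is_out_of_scope(self):
        rec = check_eligibility(PatientProfile(age_years=80))
        assert rec.status is Status.OUT_OF_SCOPE
        assert any("age >= 75" in line for line in rec.rationale)

    @pytest.mark.parametrize("flags", [{"hereditary_syndrome": True}, {"ibd": True}])
    def test_hereditary_and_ibd_are_out_of_scope(self, flags):
        rec = check_eligibility(PatientProfile(age_years=55, **flags))
        assert rec.status is Status.OUT_OF_SCOPE

    def test_screening_age_patient_passes(self, screening_patient):
        assert check_eligibility(screening_patient) is None

    def test_boundary_74_passes_75_gated(self):
        assert check_eligibility(PatientProfile(age_years=74)) is None
        assert check_eligibility(PatientProfile(age_years=75)) is not None


class TestRiskClassifier:
    @pytest.mark.parametrize(
        "findings, expected",
        [
            (exam(), RiskClass.NORMAL),
            (exam(group(size=12)), RiskClass.HIGH_RISK),
            (exam(group(count=2, size=5)), RiskClass.LOW_RISK),
            (exam(group(Histology.TUBULOVILLOUS_OR_VILLOUS)), RiskClass.HIGH_RISK),
            (exam(group(Histology.ADENOMA_HGD)), RiskClass.HIGH_RISK),
            (exam(group(count=5)), RiskClass.HIGH_RISK),
            (exam(group(Histology.SSP, size=10)), RiskClass.HIGH_RISK),
            (exam(group(Histology.SSP, count=2, size=5)), RiskClass.LOW_RISK),
            (exam(group(Histology.SSP_DYSPLASIA)), RiskClass.HIGH_RISK),
            (exam(group(Histology.TSA)), RiskClass.HIGH_RISK),
            (exam(group(Histology.HYPERPLASTIC, size=12)), RiskClass.LOW_RISK),
        ],
    )
    def test_risk_strata(self, findings, expected):
        assert classify_risk(findings) is expected

    def test_counts_aggregate_across_adenoma_histologies(self):
        findings = exam(
            group(Histology.TUBULAR_ADENOMA, count=3, size=5),
            group(Histology.TUBULOVILLOUS_OR_VILLOUS, count=2, size=5),
        )
        assert classify_risk(findings) is RiskClass.HIGH_RISK  # 5 adenomas total


class TestIndexPathway:
    @pytest.mark.parametrize(
        "findings, expected",
        [
            (exam(), (120, 120)),  # normal exam -> 10 y
            (exam(group(Histology.SSP, count=2, size=5)), (60, 120)),  # 5-10 y
            (exam(group(count=2, size=5)), (84, 120)),
            (exam(group(count=3, size=5)), (36, 60)),
            (exam(group(count=5, size=5)), (36, 36)),
            (exam(group(count=11, size=5)), (12, 12)),
            (exam(group(Histology.TUBULOVILLOUS_OR_VILLOUS, size=5)), (36, 36)),
            (exam(group(Histology.SSP_DYSPLASIA, size=5)), (36, 36)),
            (exam(group(Histology.TSA, size=5)), (36, 36)),
            (exam(group(Histology.HYPERPLASTIC, size=12)), (36, 60)),
            (
                exam(group(Histology.HYPERPLASTIC, size=5, location=Location.RECTOSIGMOID)),
                (120, 120),
            ),
            (
                exam(group(Histology.HYPERPLASTIC, size=5, location=Location.PROXIMAL)),
                (60, 120),
            ),
            (
                exam(group(size=25, resection=Resection.PIECEMEAL)),
                (6, 6),  # large piecemeal resection dominates everything
            ),
        ],
    )
    def test_default_table_lookups(self, screening_patient, findings, expected):
        rec = recommend_index(screening_patient, findings)
        assert (rec.interval.min_months, rec.interval.max_months) == expected

    def test_most_conservative_rule_wins_and_all_matches_cited(self, screening_patient):
        findings = exam(
            group(size=12),
            group(count=2, size=5, location=Location.RECTOSIGMOID),
        )
        rec = recommend_index(screening_patient, findings)
        assert (rec.interval.min_months, rec.interval.max_months) == (36, 36)
        assert "adenoma_ge10mm" in rec.fired_rule_ids

    def test_unknown_location_hyperplastic_treated_as_proximal(self, screening_patient):
        rec = recommend_index(
            screening_patient,
            exam(group(Histology.HYPERPLASTIC, size=5, location=Location.UNKNOWN)),
        )
        assert "hp_proximal_lt10" in rec.fired_rule_ids

    @pytest.mark.parametrize("kw", [{"cecum_reached": False}, {"prep_adequate": False}])
    def test_incomplete_or_poor_prep_exam_is_case_by_case(self, screening_patient, kw):
        rec = recommend_index(screening_patient, ColonoscopyFindings(**kw))
        assert rec.status is Status.CASE_BY_CASE
        assert rec.interval is None


class TestSurveillancePathway:
    @pytest.mark.parametrize(
        "prior, current, expected",
        [
            (exam(group(size=12)), exam(), (60, 60)),  # prior high, now normal -> 5 y
            (exam(group(count=2, size=5)), exam(), (120, 120)),
            (exam(group(size=12)), exam(group(size=12)), (36, 36)),
        ],
    )
    def test_step_table(self, screening_patient, prior, current, expected):
        rec = recommend_surveillance(screening_patient, prior, current)
        assert (rec.interval.min_months, rec.interval.max_months) == expected

    def test_current_findings_tighten_the_step_interval(self, screening_patient):
        prior = exam(group(count=2, size=5))  # low risk
        current = exam(group(count=11, size=5))  # >10 adenomas -> 1 y index rule
        rec = recommend_surveillance(screening_patient, prior, current)
        assert rec.interval.max_months == 12
        assert "adenoma_gt10" in rec.fired_rule_ids


class TestPostCrcPathway:
    @pytest.mark.parametrize(
        "count, findings, expected",
        [
            (0, exam(), (12, 12)),
            (1, exam(), (36, 36)),
            (2, exam(), (60, 60)),
            (5, exam(), (60, 60)),  # sequence floor
            (2, exam(group(Histology.ADENOMA_HGD, size=5)), (36, 36)),
        ],
    )
    def test_sequence_and_findings_combination(self, count, findings, expected):
        profile = PatientProfile(
            age_years=60, crc_history=True, months_since_crc_resection=6,
            post_resection_colonoscopy_count=count,
        )
        rec = recommend_post_crc(profile, findings)
        assert (rec.interval.min_months, rec.interval.max_months) == expected

    def test_requires_crc_history(self, screening_patient, normal_exam):
        with pytest.raises(ValueError):
            recommend_post_crc(screening_patient, normal_exam)


class TestFamilyHistoryCap:
    def base(self, lo, hi):
        return recommend_index(PatientProfile(age_years=55), exam()).model_copy(
            update={"interval": IntervalRange(min_months=lo, max_months=hi)}
        )

    def test_high_risk_history_caps_at_five_years(self):
        fh = FamilyHistory(fdr_crc_count=1, youngest_dx_age=52)
        rec = apply_family_history(self.base(120, 120), fh, 55)
        assert (rec.interval.min_months, rec.interval.max_months) == (60, 60)
        assert rec.rationale[-1].startswith("family_history_cap")

    def test_cap_never_loosens_a_tighter_interval(self):
        fh = FamilyHistory(fdr_crc_count=1, youngest_dx_age=52)
        rec = apply_family_history(self.base(36, 36), fh, 55)
        assert (rec.interval.min_months, rec.interval.max_months) == (36, 36)

    def test_single_older_fdr_caps_at_ten_years(self):
        fh = FamilyHistory(fdr_crc_count=1, youngest_dx_age=70)
        rec = apply_family_history(self.base(84, 120), fh, 55)
        assert (rec.interval.min_months, rec.interval.max_months) == (84, 120)

    def test_empty_history_is_identity(self):
        base = self.base(120, 120)
        assert apply_family_history(base, FamilyHistory(), 55) == base

    def test_idempotent(self):
        fh = FamilyHistory(fdr_crc_count=2, youngest_dx_age=65)
        once = apply_family_history(self.base(120, 120), fh, 55)
        assert apply_family_history(once, fh, 55) == once


class TestDispatcher:
    def test_ineligible_profile_short_circuits(self):
        rec = recommend(PatientProfile(age_years=80), None, exam(group(size=12)))
        assert rec.status is Status.OUT_OF_SCOPE

    def test_index_dispatch_normal_exam(self, screening_patient, normal_exam):
        rec = recommend(screening_patient, None, normal_exam)
        assert (rec.interval.min_months, rec.interval.max_months) == (120, 120)

    def test_post_crc_dispatch(self, normal_exam):
        profile = PatientProfile(
            age_years=55, crc_history=True, months_since_crc_resection=2
        )
        rec = recommend(profile, None, normal_exam)
        assert (rec.interval.min_months, rec.interval.max_months) == (12, 12)

    def test_surveillance_dispatch_when_prior_given(self, screening_patient, normal_exam):
        rec = recommend(screening_patient, exam(group(size=12)), normal_exam)
        assert (rec.interval.min_months, rec.interval.max_months) == (60, 60)

    def test_fh_modifier_applied_last(self, normal_exam):
        profile = PatientProfile(
            age_years=55,
            family_history=FamilyHistory(fdr_crc_count=2, youngest_dx_age=55),
        )
        rec = recommend(profile, None, normal_exam)
        assert (rec.interval.min_months, rec.interval.max_months) == (60, 60)
        assert rec.fired_rule_ids[-1] == "family_history_cap"

    def test_emitted_ranges_within_sanity_bounds(self, screening_patient):
        for findings in [exam(), exam(group(size=25, resection=Resection.PIECEMEAL))]:
            rec = recommend(screening_patient, None, findings)
            assert 6 <= rec.interval.min_months <= rec.interval.max_months <= 120
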