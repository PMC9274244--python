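"""Inclusion-rule evaluation, subcohort selection, and the visit outcome."""

import datetime as dt

import pytest

from icees_lite.cohorts import (
    CriteriaConfig,
    Criterion,
    OutcomeSpec,
    dichotomize,
    evaluate_criterion,
    is_active,
    respiratory_visit_count,
    select_cf_subcohort,
    select_cohort,
    visit_histogram,
)
from icees_lite.model import (
    ClinicalDataset,
    ConditionRecord,
    ConfigError,
    DomainError,
    EncounterRecord,
    PatientRecord,
    ProcedureRecord,
    StudyPeriod,
)

PERIOD = StudyPeriod(dt.date(2020, 1, 1), dt.date(2020, 12, 31))


def events(conditions=(), encounters=(), procedures=()):
    return (list(conditions), list(encounters), list(procedures))


class TestEvaluateCriterion:
    def test_procedure_age_bound_met(self):
        patient = PatientRecord("p", dt.date(2015, 3, 1))
        c = Criterion("procedure", frozenset({"SINUS"}), age_at_event_max=6.0)
        proc = ProcedureRecord("p", "SINUS1", dt.date(2020, 6, 1))  # age ~5.25
        assert evaluate_criterion(events(procedures=[proc]), patient, c)

    def test_procedure_age_bound_exceeded(self):
        patient = PatientRecord("p", dt.date(2013, 3, 1))
        c = Criterion("procedure", frozenset({"SINUS"}), age_at_event_max=6.0)
        proc = ProcedureRecord("p", "SINUS1", dt.date(2020, 6, 1))  # age ~7.25
        assert not evaluate_criterion(events(procedures=[proc]), patient, c)

    def test_sub_year_bound_uses_day_arithmetic(self):
        patient = PatientRecord("p", dt.date(2019, 7, 15))
        c = Criterion("procedure", frozenset({"TYMP"}), age_at_event_max=1.0)
        at_11_months = ProcedureRecord("p", "TYMP1", dt.date(2020, 6, 15))
        assert evaluate_criterion(events(procedures=[at_11_months]), patient, c)
        at_13_months = ProcedureRecord("p", "TYMP1", dt.date(2020, 8, 20))
        assert not evaluate_criterion(events(procedures=[at_13_months]), patient, c)

    def test_nicu_gestational_age_floor(self):
        patient = PatientRecord("p", dt.date(2020, 1, 5))
        c = Criterion("nicu_admission", gestational_age_min_weeks=35.0)
        term = EncounterRecord("p", "NICU", dt.date(2020, 1, 6), gestational_age_weeks=38)
        preterm = EncounterRecord("p", "NICU", dt.date(2020, 1, 6), gestational_age_weeks=30)
        assert evaluate_criterion(events(encounters=[term]), patient, c)
        assert not evaluate_criterion(events(encounters=[preterm]), patient, c)

    def test_kind_field_mismatch_is_config_error(self):
        with pytest.raises(ConfigError):
            Criterion("diagnosis", frozenset({"J47"}), gestational_age_min_weeks=35.0)


def two_group_dataset():
    patients = [PatientRecord("loc", dt.date(2000, 1, 1)),
                PatientRecord("both", dt.date(2000, 1, 1)),
                PatientRecord("none", dt.date(2000, 1, 1))]
    encounters = [
        EncounterRecord("loc", "outpatient", dt.date(2020, 5, 1),
                        location_tag="adult_pulmonary_clinic"),
        EncounterRecord("both", "outpatient", dt.date(2020, 5, 1),
                        location_tag="adult_pulmonary_clinic"),
    ]
    conditions = [ConditionRecord("both", "J47.0", dt.date(2020, 4, 1))]
    return ClinicalDataset(patients=patients, encounters=encounters, conditions=conditions)


CFG = CriteriaConfig(
    location_criteria=(Criterion("visit_location", frozenset({"adult_pulmonary_clinic"})),),
    clinical_criteria=(Criterion("diagnosis", frozenset({"J47"})),),
)


class TestSelectCohort:
    def test_and_requires_both_groups(self):
        assert select_cohort(two_group_dataset(), CFG, PERIOD) == {"both"}

    def test_or_accepts_either(self):
        cfg = CriteriaConfig(CFG.location_criteria, CFG.clinical_criteria, combiner="OR")
        assert select_cohort(two_group_dataset(), cfg, PERIOD) == {"both", "loc"}

    def test_or_is_superset_of_and(self, small_population):
        ds, _, _ = small_population
        cfg_or = CriteriaConfig(CFG.location_criteria, CFG.clinical_criteria, combiner="OR")
        assert select_cohort(ds, CFG, PERIOD) <= select_cohort(ds, cfg_or, PERIOD)

    def test_empty_dataset(self):
        assert select_cohort(ClinicalDataset(), CFG, PERIOD) == set()

    def test_out_of_period_events_ignored(self):
        ds = two_group_dataset()
        for c in ds.conditions:
            c.date = dt.date(2019, 4, 1)
        assert select_cohort(ds, CFG, PERIOD) == set()

    def test_widening_age_bound_is_monotone(self, small_population):
        ds, _, _ = small_population
        narrow = CriteriaConfig(clinical_criteria=(
            Criterion("diagnosis", frozenset({"J45"}), age_at_event_max=10.0),))
        wide = CriteriaConfig(clinical_criteria=(
            Criterion("diagnosis", frozenset({"J45"}), age_at_event_max=60.0),))
        assert select_cohort(ds, narrow, PERIOD) <= select_cohort(ds, wide, PERIOD)

    def test_more_prefixes_is_monotone(self, small_population):
        ds, _, _ = small_population
        fewer = CriteriaConfig(clinical_criteria=(
            Criterion("diagnosis", frozenset({"J45"})),))
        more = CriteriaConfig(clinical_criteria=(
            Criterion("diagnosis", frozenset({"J45", "J47", "E84"})),))
        assert select_cohort(ds, fewer, PERIOD) <= select_cohort(ds, more, PERIOD)


class TestActiveAndCfSubcohort:
    def _dataset(self):
        return ClinicalDataset(
            patients=[PatientRecord("active-cf", dt.date(2000, 1, 1)),
                      PatientRecord("inactive-cf", dt.date(2000, 1, 1)),
                      PatientRecord("asthma-only", dt.date(2000, 1, 1))],
            conditions=[
                ConditionRecord("active-cf", "E84.0", dt.date(2020, 3, 3)),
                ConditionRecord("inactive-cf", "E84", dt.date(2020, 3, 3)),
                ConditionRecord("asthma-only", "J45.0", dt.date(2020, 3, 3)),
            ],
            encounters=[
                EncounterRecord("active-cf", "outpatient", dt.date(2020, 6, 6)),
                EncounterRecord("inactive-cf", "outpatient", dt.date(2019, 6, 6)),
                EncounterRecord("asthma-only", "outpatient", dt.date(2020, 6, 6)),
            ])

    def test_is_active(self):
        ds = self._dataset()
        assert is_active("active-cf", ds, PERIOD)
        assert not is_active("inactive-cf", ds, PERIOD)  # only prior-year visits
        with pytest.raises(DomainError):
            is_active("ghost", ds, PERIOD)

    def test_cf_subcohort_requires_code_and_activity(self):
        assert select_cf_subcohort(self._dataset(), PERIOD) == {"active-cf"}

    def test_subcohort_subset_of_active(self, small_population, period_2020):
        ds, _, _ = small_population
        cf = select_cf_subcohort(ds, period_2020)
        assert all(is_active(pid, ds, period_2020) for pid in cf)


class TestOutcome:
    SPEC = OutcomeSpec(period=PERIOD)

    def _dataset(self, encounters):
        return ClinicalDataset(patients=[PatientRecord("p", dt.date(2000, 1, 1))],
                               encounters=encounters)

    def test_counts_ed_visits_with_respiratory_reason(self):
        ds = self._dataset([
            EncounterRecord("p", "ED", dt.date(2020, 2, 2), reason_codes=["J18.9"]),
            EncounterRecord("p", "ED", dt.date(2020, 3, 3), reason_codes=["J45"]),
        ])
        assert respiratory_visit_count("p", ds, self.SPEC) == 2

    def test_inpatient_without_respiratory_reason_excluded(self):
        ds = self._dataset([
            EncounterRecord("p", "inpatient", dt.date(2020, 2, 2), reason_codes=["K21"])])
        assert respiratory_visit_count("p", ds, self.SPEC) == 0

    def test_outpatient_respiratory_visit_excluded(self):
        ds = self._dataset([
            EncounterRecord("p", "outpatient", dt.date(2020, 2, 2), reason_codes=["J45"])])
        assert respiratory_visit_count("p", ds, self.SPEC) == 0

    @pytest.mark.parametrize("count,expected", [(0, "better"), (1, "poor"), (35, "poor")])
    def test_dichotomize(self, count, expected):
        assert dichotomize(count) == expected

    def test_dichotomy_partitions_cohort(self, small_population, outcome_spec):
        ds, _, truth = small_population
        groups = [dichotomize(truth.visit_counts[p.patient_id]) for p in ds.patients]
        assert groups.count("better") + groups.count("poor") == len(ds.patients)


class TestVisitHistogram:
    def test_top_coding(self):
        hist = visit_histogram([0, 0, 1, 35])
        assert hist["0"] == 2 and hist["1"] == 1 and hist["9+"] == 1

    def test_empty_input(self):
        assert all(v == 0 for v in visit_histogram([]).values())

    def test_conservation(self, small_population):
        _, _, truth = small_population
        hist = visit_histogram(truth.visit_counts.values())
        assert sum(hist.values()) == len(truth.visit_counts)
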