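import math

import pytest

from pimscreen.engine import (
    Axis,
    aggregate_severity,
    evaluate_age_rule,
    report_counts,
    report_to_json,
    screen_patient,
)
from pimscreen.kb import (
    ALL_CRITERIA,
    AgeRule,
    Category,
    Criterion,
    REFERENCE,
)
from pimscreen.patient import MedicationRecord, Patient


@pytest.fixture
def ppi_rule(tiny_kb):
    (rule,) = tiny_kb.age_rules_for(Criterion.TIME_TO_STOPP, "ppi")
    return rule


@pytest.fixture
def asa_dose_rule(tiny_kb):
    rules = tiny_kb.age_rules_for(Criterion.BEERS_2019, "asa")
    return next(r for r in rules if r.max_dose_mg_per_day is not None)


class TestEvaluateAgeRule:
    def test_duration_rule_fires_with_90_day_default(self, ppi_rule):
        # unknown duration is assumed to be 90 days of chronic use > 8 weeks
        assert evaluate_age_rule(ppi_rule, MedicationRecord("ppi"), 80)

    def test_duration_rule_spares_short_use(self, ppi_rule):
        assert not evaluate_age_rule(ppi_rule, MedicationRecord("ppi", None, 30), 80)

    def test_dose_rule_fires_only_above_threshold(self, asa_dose_rule):
        assert not evaluate_age_rule(asa_dose_rule, MedicationRecord("asa", 100.0), 80)
        assert not evaluate_age_rule(asa_dose_rule, MedicationRecord("asa", 325.0), 80)
        assert evaluate_age_rule(asa_dose_rule, MedicationRecord("asa", 400.0), 80)

    def test_missing_dose_never_fires_a_dose_rule(self, asa_dose_rule):
        assert not evaluate_age_rule(asa_dose_rule, MedicationRecord("asa"), 80)

    def test_age_gate_is_inclusive_at_65(self, tiny_kb):
        (rule,) = tiny_kb.age_rules_for(Criterion.BEERS_2019, "quetiapine")
        rec = MedicationRecord("quetiapine")
        assert not evaluate_age_rule(rule, rec, 64)
        assert evaluate_age_rule(rule, rec, 65)

    def test_mismatched_drug_ids_are_a_usage_error(self, ppi_rule):
        with pytest.raises(ValueError):
            evaluate_age_rule(ppi_rule, MedicationRecord("asa"), 80)


class TestAggregateSeverity:
    def test_lattice_maximum(self):
        assert (
            aggregate_severity([Category.RISKY, Category.CONTRAINDICATED])
            is Category.CONTRAINDICATED
        )
        assert aggregate_severity([Category.NO_WARNING, Category.USABLE]) is Category.USABLE

    def test_empty_input_is_no_warning(self):
        assert aggregate_severity([]) is Category.NO_WARNING

    def test_sources_of_winners_are_deduplicated(self):
        cat, sources = aggregate_severity(
            [Category.USABLE, Category.USABLE, Category.NO_WARNING],
            [("a", "b"), ("b", "c"), ("zzz",)],
        )
        assert cat is Category.USABLE
        assert sources == ("a", "b", "c")

    def test_mixed_axis_enums_rejected(self):
        with pytest.raises(ValueError):
            aggregate_severity([Category.USABLE, Category.CONTRAINDICATED])

    def test_unknown_agent_has_no_severity(self):
        with pytest.raises(ValueError):
            aggregate_severity([Category.UNKNOWN_AGENT])


class TestScreenPatient:
    def test_evaluation_counts_follow_combinatorics(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb)
        m, d = 5, 2
        assert len(report.findings_on(Axis.DRUG_DRUG)) == m * (m - 1) // 2
        assert len(report.findings_on(Axis.DRUG_DISEASE)) == m * d
        # one finding per medication x (criterion + reference)
        assert len(report.findings_on(Axis.DRUG_AGE)) == m * (len(ALL_CRITERIA) + 1)

    def test_empty_medication_list_yields_no_findings(self, tiny_kb):
        p = Patient("p0", 80, diseases=frozenset({"dementia"}))
        report = screen_patient(p, tiny_kb)
        assert report.findings == ()
        assert report.counts["n_pim_reference"] == 0

    def test_quetiapine_with_dementia_is_contraindicated(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb)
        hits = [
            f for f in report.findings_on(Axis.DRUG_DISEASE)
            if f.subject == ("quetiapine", "dementia")
        ]
        assert len(hits) == 1
        assert hits[0].category is Category.CONTRAINDICATED
        assert hits[0].sources  # explainability: the warning cites its source

    def test_reference_finding_is_union_of_criteria(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb)
        per_criterion_union = set()
        for c in ALL_CRITERIA:
            per_criterion_union |= report.pim_drugs(c)
        assert report.pim_drugs(REFERENCE) == per_criterion_union
        # long-term PPI and quetiapine are the PIMs here; low-dose asa is not
        assert report.pim_drugs(REFERENCE) == {"ppi", "quetiapine"}

    def test_unknown_agent_reported_distinctly(self, tiny_kb):
        p = Patient("p0", 80, medications=(MedicationRecord("mystery"),))
        report = screen_patient(p, tiny_kb)
        cats = {f.category for f in report.findings_on(Axis.DRUG_AGE)}
        assert cats == {Category.UNKNOWN_AGENT}
        assert report.counts["n_unknown_agents"] == 1
        assert report.findings_on(Axis.DRUG_DRUG) == []

    def test_missing_dose_marks_finding_uncertain(self, tiny_kb):
        p = Patient("p0", 80, medications=(MedicationRecord("asa"),))
        report = screen_patient(p, tiny_kb)
        beers = [
            f for f in report.findings_on(Axis.DRUG_AGE)
            if f.criterion is Criterion.BEERS_2019
        ]
        assert beers[0].uncertain
        # the dose-conditioned rule did not fire: classification stays USABLE
        assert beers[0].category is Category.USABLE

    def test_report_is_invariant_under_medication_permutation(self, tiny_kb, polypharmacy_patient):
        p = polypharmacy_patient
        shuffled = Patient(
            p.patient_id, p.age_years, p.sex,
            tuple(reversed(p.medications)), p.diseases,
        )
        assert screen_patient(shuffled, tiny_kb) == screen_patient(p, tiny_kb)

    def test_adding_a_medication_never_removes_findings(self, tiny_kb, polypharmacy_patient):
        p = polypharmacy_patient
        base = screen_patient(p, tiny_kb)
        bigger = Patient(
            p.patient_id, p.age_years, p.sex,
            p.medications + (MedicationRecord("risperidone", 1.0, 60),),
            p.diseases,
        )
        grown = screen_patient(bigger, tiny_kb)
        assert set(base.findings) <= set(grown.findings)
        for key, value in base.counts.items():
            if key == "n_pim_by_criterion":
                for c, v in value.items():
                    assert grown.counts[key][c] >= v
            else:
                assert grown.counts[key] >= value

    def test_repeated_screening_is_byte_identical(self, tiny_kb, polypharmacy_patient):
        import json

        a = json.dumps(report_to_json(screen_patient(polypharmacy_patient, tiny_kb)))
        b = json.dumps(report_to_json(screen_patient(polypharmacy_patient, tiny_kb)))
        assert a == b

    def test_criteria_subset_restricts_findings(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb, [Criterion.BEERS_2019])
        assert report.criteria == (Criterion.BEERS_2019,)
        seen = {f.criterion for f in report.findings_on(Axis.DRUG_AGE)}
        assert seen == {Criterion.BEERS_2019, REFERENCE}


class TestReportCounts:
    def test_counts_equal_finding_subset_cardinalities(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb)
        counts = report_counts(report)
        assert counts["n_pim_reference"] == 2  # ppi (long-term) + quetiapine
        assert counts["n_ddi_risky"] == 1  # asa + warfarin
        assert counts["n_ddisease_contraindicated"] == 1  # quetiapine + dementia
        assert counts["n_ddisease_risky"] == 1  # metoprolol + hypertension

    def test_same_drug_risky_under_three_criteria_counts_once(self, tiny_kb):
        # quetiapine is risky under two criteria in the fixture; the reference
        # count is over distinct drugs, so it stays 1
        p = Patient("p0", 80, medications=(MedicationRecord("quetiapine"),))
        counts = screen_patient(p, tiny_kb).counts
        assert counts["n_pim_by_criterion"]["BEERS_2019"] == 1
        assert counts["n_pim_by_criterion"]["EU7_PIM"] == 1
        assert counts["n_pim_reference"] == 1

    def test_all_no_warning_report_counts_zero(self, tiny_kb):
        p = Patient("p0", 80, medications=(MedicationRecord("warfarin", 5.0),))
        counts = screen_patient(p, tiny_kb).counts
        assert counts["n_pim_reference"] == 0
        assert all(v == 0 for v in counts["n_pim_by_criterion"].values())

    def test_no_warning_rows_can_be_suppressed_in_output(self, tiny_kb, polypharmacy_patient):
        report = screen_patient(polypharmacy_patient, tiny_kb)
        full = report_to_json(report, include_no_warning=True)
        trimmed = report_to_json(report, include_no_warning=False)
        assert len(trimmed["findings"]) < len(full["findings"])
        assert all(f["category"] != "NO_WARNING" for f in trimmed["findings"])
        assert trimmed["counts"] == full["counts"]
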