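"""Deterministic, explainable screening of one patient against the knowledge base.

Screening evaluates three axes at once:

* **drug–age** — every medication is classified under every requested PIM
  criterion, honouring age, dose and duration conditions, plus a derived
  *reference* classification (severity maximum across criteria, i.e. the
  union method);
* **drug–drug** — every unordered pair of registered medications is looked up
  in the pair-rule table;
* **drug–disease** — every (registered medication, chronic disease)
  combination is looked up in the disease-rule table.

Absent rules yield explicit ``NO_WARNING`` findings — "no warning was found"
is a category in its own right, not silence.  Medications naming drugs absent
from the registry yield ``UNKNOWN_AGENT`` findings and are excluded from the
pairwise loops.  A report is a pure function of (patient, knowledge base,
criteria): repeated screening is byte-identical and the output ordering is
deterministic (axis, then subject, then criterion).

A dose-conditioned rule whose dose is not recorded on the medication cannot
fire; the emitted finding is annotated ``uncertain`` so the missing data is
auditable rather than silently alarming or silently ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .kb import (
    ALL_CRITERIA,
    Category,
    Criterion,
    KnowledgeBase,
    AgeRule,
    REFERENCE,
    canonical_pair,
)
from .patient import MedicationRecord, Patient, patient_flags

__all__ = [
    "Axis",
    "Finding",
    "ScreeningReport",
    "evaluate_age_rule",
    "aggregate_severity",
    "screen_patient",
    "screen_cohort",
    "report_counts",
    "report_to_json",
    "report_to_rows",
]


class Axis(str, Enum):
    DRUG_AGE = "DRUG_AGE"
    DRUG_DRUG = "DRUG_DRUG"
    DRUG_DISEASE = "DRUG_DISEASE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Severity lattice: CONTRAINDICATED > RISKY > USABLE > NO_WARNING.
_SEVERITY = {
    Category.NO_WARNING: 0,
    Category.USABLE: 1,
    Category.RISKY: 2,
    Category.CONTRAINDICATED: 3,
}

_AXIS_ORDER = {Axis.DRUG_AGE: 0, Axis.DRUG_DRUG: 1, Axis.DRUG_DISEASE: 2}


@dataclass(frozen=True)
class Finding:
    """One explainable warning (or explicit all-clear) for one subject.

    ``subject`` is a 1-tuple ``(drug_id,)`` on the drug–age axis, the
    canonical drug pair on the drug–drug axis, and ``(drug_id, disease_id)``
    on the drug–disease axis.  ``criterion`` is set on the drug–age axis only
    (one of the six criteria or ``"REFERENCE"``).
    """

    axis: Axis
    subject: tuple[str, ...]
    category: Category
    criterion: Criterion | str | None = None
    comment: str = ""
    sources: tuple[str, ...] = ()
    uncertain: bool = False


def evaluate_age_rule(rule: AgeRule, record: MedicationRecord, age_years: int) -> bool:
    """Does this drug–age rule fire for this medication at this age?

    A rule fires when the patient has reached the rule's age threshold and
    every recorded condition is exceeded: dose strictly above
    ``max_dose_mg_per_day`` (a missing dose never fires a dose condition) and
    effective duration strictly above ``max_duration_days`` (a missing
    duration defaults to 90 days).
    """
    if rule.drug_id != record.drug_id:
        raise ValueError(
            f"rule is for {rule.drug_id!r} but record is for {record.drug_id!r}"
        )
    if age_years < rule.min_age_years:
        return False
    if rule.max_dose_mg_per_day is not None:
        if record.dose_mg_per_day is None:
            return False  # conservative: absent dose cannot exceed a threshold
        if record.dose_mg_per_day <= rule.max_dose_mg_per_day:
            return False
    if rule.max_duration_days is not None:
        if record.effective_duration_days <= rule.max_duration_days:
            return False
    return True


def _rule_is_uncertain(rule: AgeRule, record: MedicationRecord, age_years: int) -> bool:
    """A dose-conditioned rule whose every other condition holds but whose dose
    is unrecorded: it *might* fire, we cannot tell."""
    if rule.max_dose_mg_per_day is None or record.dose_mg_per_day is not None:
        return False
    if age_years < rule.min_age_years:
        return False
    if rule.max_duration_days is not None and (
        record.effective_duration_days <= rule.max_duration_days
    ):
        return False
    return True


def _merge_sources(groups: Iterable[Sequence[str]]) -> tuple[str, ...]:
    out: list[str] = []
    for group in groups:
        for s in group:
            if s not in out:
                out.append(s)
    return tuple(out)


def aggregate_severity(
    categories: Iterable[Category],
    sources: Iterable[Sequence[str]] | None = None,
):
    """Severity maximum of categories from one axis's enum.

    Returns the maximal category (``NO_WARNING`` for empty input).  When
    ``sources`` is given (parallel to ``categories``), returns
    ``(category, merged_sources)`` where the sources of all maximal entries
    are concatenated and deduplicated, order-preserving.

    Mixing ``USABLE`` (drug–age axis) with ``CONTRAINDICATED`` (interaction
    axes) is a usage error, as is aggregating ``UNKNOWN_AGENT``.
    """
    cats = list(categories)
    src_list = None if sources is None else [tuple(s) for s in sources]
    if src_list is not None and len(src_list) != len(cats):
        raise ValueError("sources must parallel categories")
    if any(c not in _SEVERITY for c in cats):
        raise ValueError("UNKNOWN_AGENT has no severity and cannot be aggregated")
    if Category.USABLE in cats and Category.CONTRAINDICATED in cats:
        raise ValueError("categories mix the drug-age and interaction axes")
    if not cats:
        best = Category.NO_WARNING
    else:
        best = max(cats, key=_SEVERITY.__getitem__)
    if src_list is None:
        return best
    merged = _merge_sources(s for c, s in zip(cats, src_list) if c is best)
    return best, merged


def _age_finding_for_criterion(
    criterion: Criterion,
    rec: MedicationRecord,
    age: int,
    rules: Sequence[AgeRule],
) -> Finding:
    firing = [r for r in rules if evaluate_age_rule(r, rec, age)]
    uncertain = any(_rule_is_uncertain(r, rec, age) for r in rules)
    if not firing:
        return Finding(
            Axis.DRUG_AGE, (rec.drug_id,), Category.NO_WARNING,
            criterion=criterion, uncertain=uncertain,
        )
    category, merged = aggregate_severity(
        [r.category for r in firing], [r.sources for r in firing]
    )
    winners = [r for r in firing if r.category is category]
    comment = " | ".join(r.comment for r in winners if r.comment)
    return Finding(
        Axis.DRUG_AGE, (rec.drug_id,), category,
        criterion=criterion, comment=comment, sources=merged, uncertain=uncertain,
    )


@dataclass
class ScreeningReport:
    """All findings for one patient, with per-axis counts.

    The report is a pure function of (patient, knowledge base, criteria);
    counts always equal the cardinalities of the corresponding finding
    subsets (PIM counts are over *distinct medications*, not firing rules).
    """

    patient_id: str
    criteria: tuple[Criterion, ...]
    findings: tuple[Finding, ...]
    flags: dict[str, bool]

    def findings_on(self, axis: Axis) -> list[Finding]:
        return [f for f in self.findings if f.axis is axis]

    @property
    def counts(self) -> dict:
        return report_counts(self)

    # drugs with a RISKY drug-age finding under the given source
    def pim_drugs(self, source: Criterion | str = REFERENCE) -> set[str]:
        return {
            f.subject[0]
            for f in self.findings
            if f.axis is Axis.DRUG_AGE
            and f.criterion == source
            and f.category is Category.RISKY
        }


def screen_patient(
    patient: Patient,
    kb: KnowledgeBase,
    criteria: Sequence[Criterion] | None = None,
) -> ScreeningReport:
    """Screen one patient on all three axes; see the module docstring.

    ``criteria`` defaults to all six; the derived REFERENCE finding per
    medication is the severity maximum across the requested criteria with the
    winning criteria's sources merged.
    """
    criteria = tuple(ALL_CRITERIA if criteria is None else dict.fromkeys(criteria))
    findings: list[Finding] = []

    registered = [m for m in patient.medications if m.drug_id in kb.drugs]
    unknown = [m for m in patient.medications if m.drug_id not in kb.drugs]

    # drug–age axis: medication × criterion, plus the derived reference row
    for rec in patient.medications:
        if rec.drug_id not in kb.drugs:
            for criterion in (*criteria, REFERENCE):
                findings.append(
                    Finding(
                        Axis.DRUG_AGE, (rec.drug_id,), Category.UNKNOWN_AGENT,
                        criterion=criterion,
                        comment="agent not present in the drug registry",
                    )
                )
            continue
        per_criterion = [
            _age_finding_for_criterion(c, rec, patient.age_years, kb.age_rules_for(c, rec.drug_id))
            for c in criteria
        ]
        findings.extend(per_criterion)
        category, merged = aggregate_severity(
            [f.category for f in per_criterion], [f.sources for f in per_criterion]
        )
        winners = [f for f in per_criterion if f.category is category]
        comment = " | ".join(dict.fromkeys(f.comment for f in winners if f.comment))
        findings.append(
            Finding(
                Axis.DRUG_AGE, (rec.drug_id,), category,
                criterion=REFERENCE, comment=comment, sources=merged,
                uncertain=any(f.uncertain for f in per_criterion),
            )
        )

    # drug–drug axis: every unordered pair of registered medications
    for i, a in enumerate(registered):
        for b in registered[i + 1 :]:
            pair = canonical_pair(a.drug_id, b.drug_id)
            rule = kb.pair_rules.get(pair)
            if rule is None:
                findings.append(Finding(Axis.DRUG_DRUG, pair, Category.NO_WARNING))
            else:
                findings.append(
                    Finding(
                        Axis.DRUG_DRUG, pair, rule.category,
                        comment=rule.comment, sources=rule.sources,
                    )
                )

    # drug–disease axis: registered medication × chronic disease
    for rec in registered:
        for disease_id in sorted(patient.diseases):
            rule = kb.disease_rules.get((rec.drug_id, disease_id))
            subject = (rec.drug_id, disease_id)
            if rule is None:
                findings.append(Finding(Axis.DRUG_DISEASE, subject, Category.NO_WARNING))
            else:
                findings.append(
                    Finding(
                        Axis.DRUG_DISEASE, subject, rule.category,
                        comment=rule.comment, sources=rule.sources,
                    )
                )

    crit_order = {c: i for i, c in enumerate((*criteria, REFERENCE))}
    findings.sort(
        key=lambda f: (
            _AXIS_ORDER[f.axis],
            f.subject,
            crit_order.get(f.criterion, len(crit_order)),
        )
    )
    return ScreeningReport(
        patient_id=patient.patient_id,
        criteria=criteria,
        findings=tuple(findings),
        flags=patient_flags(patient),
    )


def screen_cohort(
    cohort, kb: KnowledgeBase, criteria: Sequence[Criterion] | None = None
) -> list[ScreeningReport]:
    return [screen_patient(p, kb, criteria) for p in cohort]


def report_counts(report: ScreeningReport) -> dict:
    """Count summary of a report.

    ``n_pim_reference`` counts distinct medications whose REFERENCE drug–age
    finding is RISKY; ``n_pim_by_criterion`` gives the per-criterion analogue.
    Interaction counts are by category; ``n_unknown_agents`` counts distinct
    unregistered drugs.
    """
    ddi = report.findings_on(Axis.DRUG_DRUG)
    dds = report.findings_on(Axis.DRUG_DISEASE)
    return {
        "n_pim_reference": len(report.pim_drugs(REFERENCE)),
        "n_pim_by_criterion": {
            c.value: len(report.pim_drugs(c)) for c in report.criteria
        },
        "n_ddi_risky": sum(f.category is Category.RISKY for f in ddi),
        "n_ddi_contraindicated": sum(f.category is Category.CONTRAINDICATED for f in ddi),
        "n_ddisease_risky": sum(f.category is Category.RISKY for f in dds),
        "n_ddisease_contraindicated": sum(
            f.category is Category.CONTRAINDICATED for f in dds
        ),
        "n_unknown_agents": len(
            {
                f.subject[0]
                for f in report.findings_on(Axis.DRUG_AGE)
                if f.category is Category.UNKNOWN_AGENT
            }
        ),
    }


def _finding_dict(f: Finding) -> dict:
    return {
        "axis": f.axis.value,
        "subject": list(f.subject),
        "category": f.category.value,
        "criterion": None
        if f.criterion is None
        else (f.criterion.value if isinstance(f.criterion, Criterion) else f.criterion),
        "comment": f.comment,
        "sources": list(f.sources),
        "uncertain": f.uncertain,
    }


def report_to_json(report: ScreeningReport, include_no_warning: bool = True) -> dict:
    """Report as a JSON-ready dict; optionally suppress NO_WARNING rows
    (counts are unaffected)."""
    findings = [
        _finding_dict(f)
        for f in report.findings
        if include_no_warning or f.category is not Category.NO_WARNING
    ]
    return {
        "patient_id": report.patient_id,
        "flags": dict(report.flags),
        "findings": findings,
        "counts": report_counts(report),
    }


def report_to_rows(report: ScreeningReport, include_no_warning: bool = True) -> pd.DataFrame:
    """Flat one-finding-per-row table for CSV export."""
    rows = []
    for f in report.findings:
        if not include_no_warning and f.category is Category.NO_WARNING:
            continue
        d = _finding_dict(f)
        d["subject"] = "|".join(f.subject)
        d["sources"] = ";".join(f.sources)
        d["patient_id"] = report.patient_id
        rows.append(d)
    return pd.DataFrame(
        rows,
        columns=[
            "patient_id", "axis", "subject", "category",
            "criterion", "comment", "sources", "uncertain",
        ],
    )
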