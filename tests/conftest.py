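import pytest

from pimscreen.kb import (
    AgeRule,
    Category,
    Criterion,
    Disease,
    DiseaseRule,
    DrugAgent,
    KnowledgeBase,
    PairRule,
)
from pimscreen.patient import MedicationRecord, Patient


def _src(*names):
    return tuple(f"fixture-ref:{n}" for n in names)


@pytest.fixture
def tiny_kb() -> KnowledgeBase:
    """Hand-built six-drug / two-disease knowledge base exercising every rule kind."""
    drugs = [
        DrugAgent("asa", "Acetylsalicylic acid", "B01AC06"),
        DrugAgent("ppi", "Proton pump inhibitor", "A02BC"),
        DrugAgent("metoprolol", "Metoprolol", "C07AB02"),
        DrugAgent("quetiapine", "Quetiapine", "N05AH04"),
        DrugAgent("risperidone", "Risperidone", "N05AX08"),
        DrugAgent("warfarin", "Warfarin", "B01AA03"),
    ]
    diseases = [
        Disease("dementia", "Dementia"),
        Disease("hypertension", "Hypertension"),
    ]
    age_rules = [
        # usable at ordinary doses, risky above 325 mg/day
        AgeRule(Criterion.BEERS_2019, "asa", Category.USABLE,
                comment="low-dose use acceptable", sources=_src("beers-asa")),
        AgeRule(Criterion.BEERS_2019, "asa", Category.RISKY,
                max_dose_mg_per_day=325.0,
                comment="risky above 325 mg/day", sources=_src("beers-asa-dose")),
        # risky beyond 8 weeks of use
        AgeRule(Criterion.TIME_TO_STOPP, "ppi", Category.RISKY,
                max_duration_days=56,
                comment="risky beyond 8 weeks", sources=_src("time-ppi")),
        # risky beyond 6 weeks of use
        AgeRule(Criterion.EU7_PIM, "risperidone", Category.RISKY,
                max_duration_days=42,
                comment="risky beyond 6 weeks", sources=_src("eu7-risperidone")),
        AgeRule(Criterion.BEERS_2019, "quetiapine", Category.RISKY,
                comment="unconditionally risky", sources=_src("beers-quetiapine")),
        AgeRule(Criterion.EU7_PIM, "quetiapine", Category.RISKY,
                comment="unconditionally risky", sources=_src("eu7-quetiapine")),
        AgeRule(Criterion.PRISCUS, "metoprolol", Category.USABLE,
                comment="listed usable", sources=_src("priscus-metoprolol")),
    ]
    pair_rules = [
        PairRule("asa", "warfarin", Category.RISKY,
                 comment="bleeding risk", sources=_src("prospectus-asa-warfarin")),
        PairRule("quetiapine", "risperidone", Category.CONTRAINDICATED,
                 comment="antipsychotic duplication", sources=_src("prospectus-qr")),
        PairRule("metoprolol", "ppi", Category.NO_WARNING),
    ]
    disease_rules = [
        DiseaseRule("quetiapine", "dementia", Category.CONTRAINDICATED,
                    comment="excess mortality in dementia", sources=_src("guide-qd")),
        DiseaseRule("metoprolol", "hypertension", Category.RISKY,
                    comment="not first line in the elderly", sources=_src("guide-mh")),
    ]
    return KnowledgeBase.build(drugs, diseases, age_rules, pair_rules, disease_rules)


@pytest.fixture
def tiny_kb_dir(tiny_kb, tmp_path):
    from pimscreen.kb import write_kb

    d = tmp_path / "kb"
    write_kb(tiny_kb, d)
    return d


@pytest.fixture
def polypharmacy_patient() -> Patient:
    """82-year-old woman with dementia on five drugs incl. long-term PPI."""
    return Patient(
        patient_id="p1",
        age_years=82,
        sex="F",
        medications=(
            MedicationRecord("asa", 100.0, 365),
            MedicationRecord("ppi"),  # duration unknown -> 90-day default
            MedicationRecord("quetiapine", 50.0, 180),
            MedicationRecord("metoprolol", 50.0, 365),
            MedicationRecord("warfarin", 5.0, 365),
        ),
        diseases=frozenset({"dementia", "hypertension"}),
    )
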