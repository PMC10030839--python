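# pimscreen

Rule-based medication review for geriatric patients: explainable, source-cited
screening of a patient's age, medication list and chronic diseases against a
three-table interaction knowledge base.

## The problem

Polypharmacy — the simultaneous use of five or more drugs — is the norm rather
than the exception in patients over 65, and its main complications are
potentially inappropriate medications (PIMs), drug–drug interactions and
drug–disease interactions.  Several published criteria flag PIMs (AGS Beers
2019, STOPP v2, TIME-to-STOPP, EU(7)-PIM, PRISCUS, US-FORTA), but each covers
only part of the agents in actual use and they overlap only partially, so a
clinician reviewing a medication list needs all of them at once, together with
pairwise interaction and comorbidity checks.

`pimscreen` is the inference engine for that review.  The clinical content
lives in a plain-CSV knowledge base with three rule tables:

* **drug–age**: per criterion, a drug is `USABLE`, `RISKY` or carries
  `NO_WARNING` for patients above an age threshold, optionally conditioned on
  daily dose (fires above `max_dose_mg_per_day`, e.g. aspirin > 325 mg/day) or
  duration (fires beyond `max_duration_days`, e.g. a proton-pump inhibitor
  beyond 8 weeks);
* **drug–drug**: one `RISKY`/`CONTRAINDICATED`/`NO_WARNING` rule per unordered
  drug pair;
* **drug–disease**: the same categories per (drug, chronic disease).

The **reference method** is the union of the six criteria: a drug is a
reference PIM if any criterion flags it, and a patient-level reference finding
is the severity maximum across criteria
(`CONTRAINDICATED > RISKY > USABLE > NO_WARNING`).  `consensus_pims`
generalises this to "flagged by at least *k* criteria".  Every warning carries
the rule's comment and bibliographic sources, and "no warning was found" is an
explicit finding, not silence.  Screening is a pure function of
(patient, knowledge base, criteria): reports are deterministic and
byte-identical across runs.

Cohort analytics reproduce the structure of a criteria-comparison study:
per-source PIM burden (mean count ± SD, rate of patients with ≥1 PIM, burden
among positives, most frequent PIM agents), paired t-tests of each criterion
against the reference method, coverage of the reference PIM set, and exact
exclusive-region Venn partitions of the per-criterion PIM-agent sets —
plus from-the-formulas implementations of the paired t-test,
Pearson/Spearman correlation, chi-square independence and
skewness/kurtosis moments, cross-checked against scipy in the test suite.

Because curated clinical databases are proprietary, the package ships seeded
generators for study-scale fixture knowledge bases (430 agents, 73 diseases,
controllable per-criterion overlap, with ground truth) and synthetic geriatric
cohorts emulating realistic marginals (74.3% female; ages 65–103; mean 3.62
chronic diseases and 5.33 drugs per patient; hypertension prevalence 69.5%;
…).  See `docs/methods.md` for the sampling model and its limits.  **The
bundled content is synthetic fixture data, not prescribing advice.**

## Worked example

```python
import json
from pimscreen import (
    KBConfig, Patient, MedicationRecord, gen_kb, screen_patient,
)
from pimscreen.engine import report_to_json

kb, truth = gen_kb(KBConfig(n_drugs=30, n_diseases=8, seed=42))

patient = Patient(
    patient_id="p001", age_years=82, sex="F",
    medications=(
        MedicationRecord("asa", dose_mg_per_day=100),
        MedicationRecord("ppi"),                      # duration unknown
        MedicationRecord("quetiapine", dose_mg_per_day=50, duration_days=180),
    ),
    diseases=frozenset({"dementia", "hypertension"}),
)

report = screen_patient(patient, kb)
print(json.dumps(report_to_json(report, include_no_warning=False), indent=2))
```

Selected output (warnings only):

```json
{
  "patient_id": "p001",
  "flags": {"polypharmacy": false, "multimorbidity": true},
  "findings": [
    {"axis": "DRUG_AGE", "subject": ["ppi"], "category": "RISKY",
     "criterion": "TIME_TO_STOPP",
     "comment": "use beyond 8 weeks without indication is potentially inappropriate",
     "sources": ["synthetic-anchor:time-to-stopp:ppi"], "uncertain": false},
    {"axis": "DRUG_AGE", "subject": ["quetiapine"], "category": "RISKY",
     "criterion": "BEERS_2019",
     "comment": "antipsychotic with unfavourable risk profile in the elderly",
     "sources": ["synthetic-anchor:beers-2019:quetiapine"], "uncertain": false},
    {"axis": "DRUG_DISEASE", "subject": ["quetiapine", "dementia"],
     "category": "CONTRAINDICATED",
     "comment": "antipsychotic use in dementia carries excess mortality risk",
     "sources": ["synthetic-anchor:prospectus:quetiapine+dementia"],
     "uncertain": false}
  ],
  "counts": {
    "n_pim_reference": 2,
    "n_pim_by_criterion": {"BEERS_2019": 1, "STOPP_V2": 0, "TIME_TO_STOPP": 1,
                           "EU7_PIM": 0, "PRISCUS": 0, "US_FORTA": 0},
    "n_ddisease_contraindicated": 1,
    "n_unknown_agents": 0
  }
}
```

Reading it: the PPI's unknown duration defaults to 90 days of assumed chronic
use, which exceeds the 8-week threshold, so it is a PIM under TIME-to-STOPP;
quetiapine is unconditionally risky under Beers 2019 and contraindicated with
this patient's dementia; aspirin at 100 mg/day stays below its 325 mg/day
threshold and is not flagged.  The reference method counts two distinct PIMs
(`n_pim_reference`), each criterion at most one.

## Command line

```bash
pimscreen synth-kb --out fixtures/kb --seed 7          # fixture KB + ground truth
pimscreen synth-cohort --out fixtures/cohort.csv --seed 7 --n 296
pimscreen validate-kb fixtures/kb
pimscreen screen --kb fixtures/kb --patients fixtures/cohort.csv --out reports.json
pimscreen cohort --kb fixtures/kb --cohort fixtures/cohort.csv \
    --stats-out stats.json --venn-out venn.json
```

Exit codes: 0 success, 1 validation/config error, 2 I/O error.  Logs go to
standard error; machine output only to the named files.

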