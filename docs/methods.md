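# Methods

## The screening model

`pimscreen` implements a deterministic, rule-based medication review for
patients aged 65 and over.  The clinical knowledge lives entirely in a
three-table knowledge base; the engine is pure inference, so every decision is
reproducible and traceable to a cited source.

**Drug–age table.**  Each of six published PIM criteria (AGS Beers 2019,
STOPP v2, TIME-to-STOPP, EU(7)-PIM, PRISCUS, US-FORTA) classifies a drug for
older patients as `USABLE`, `RISKY`, or — when the criterion says nothing —
`NO_WARNING`.  A rule may be conditioned on daily dose (fires only **above**
`max_dose_mg_per_day`) or on treatment duration (fires only **beyond**
`max_duration_days`); the classic patterns are aspirin above 325 mg/day,
proton-pump inhibitors beyond 8 weeks, risperidone beyond 6 weeks.  A
conditioned `RISKY` rule may coexist with one unconditional rule for the same
(criterion, drug): "usable at ordinary doses, risky above the threshold".

**Reference method.**  The union of the six criteria: a drug is a reference
PIM if *any* criterion flags it risky.  At the patient level the reference
finding per medication is the severity maximum of the per-criterion findings
(`CONTRAINDICATED > RISKY > USABLE > NO_WARNING`), with the winning criteria's
sources merged.  At the agent level (`reference_age_class`) any stored
`RISKY` rule counts, conditioned or not, because agent-level tallies classify
a drug as a PIM irrespective of the dose a particular patient takes.
`consensus_pims(kb, criteria, k)` generalises the union (`k=1`) through the
intersection (`k=len(criteria)`) and is antitone in `k`.

**Interaction tables.**  Drug–drug rules are stored once per unordered pair
under the lexicographically canonical key; drug–disease rules per
(drug, disease).  Both use `RISKY` / `CONTRAINDICATED` / `NO_WARNING`.

**Screening.**  For a patient with *m* registered medications and *d*
diseases the engine performs exactly `m × |criteria|` (+ *m* reference)
drug–age evaluations, `C(m,2)` pair lookups and `m × d` disease lookups.
Absent rules are materialised as explicit `NO_WARNING` findings ("no warning
was found" is a category, not silence); serialisers can suppress them behind
a flag.  Medications naming unregistered agents yield `UNKNOWN_AGENT`
findings (distinct from `NO_WARNING`) and are excluded from the pairwise
loops.  Output ordering is fixed (axis, subject, criterion), so reports are
byte-identical across runs.

### Handling missing dose and duration

* A missing **duration** defaults to 90 days, the assumption that a
  chronic-care patient has been on their medication for at least three
  months.  Duration-conditioned rules therefore fire by default when their
  threshold is below 90 days.
* A missing **dose** can never exceed a dose threshold, so dose-conditioned
  rules do not fire on it; the finding is annotated `uncertain: true` instead.
  This is deliberately conservative: absent data must not fabricate alarms,
  but the uncertainty has to stay auditable.

PIM counts are over **distinct medications**, not firing rules, so per-source
mean PIM counts are comparable across criteria.

## Cohort analytics

`criteria_comparison` assembles, per source (reference + each criterion):
mean PIM count ± SD over all patients, the rate of patients with ≥1 PIM, mean
± SD among PIM-positive patients, and the top-3 most frequent PIM agents
(ties broken lexicographically); a dependent-samples t-test of each
criterion's per-patient counts against the reference counts (pairs with
identically zero differences are reported as degenerate rather than an
infinite statistic); observed coverage of the reference PIM-agent set; and
the exact exclusive-region Venn partition of the per-criterion PIM-agent
sets (region labels are `&`-joined sorted source names; counts sum to the
union size by construction).

Statistical primitives are implemented from the standard formulas — paired t
with `df = n−1`; Pearson on raw values and Spearman on mid-ranks with the
`t = r√((n−2)/(1−r²))` p-value (an exact permutation p is available for
n ≤ 8); Pearson chi-square with margin-derived expected counts; skewness and
excess kurtosis in the bias-uncorrected population form (`m₃/m₂^{3/2}`,
`m₄/m₂²−3`).  Sample SDs use the n−1 denominator and every p-value is
two-sided.  The test suite cross-checks each primitive against
scipy.stats to 1e-9 on random inputs; scipy itself is used only for
distribution CDFs and rank computation.

## Synthetic data

The generators exist so the whole pipeline is testable without a proprietary
curated database or real patient records; they emulate structure, not
pharmacology.

**Cohort generator** (`CohortConfig`, defaults): n = 296 patients; 74.3%
female; ages truncated-normal in [65, 103] with mean 86 ± 7 (F) and 83 ± 8
(M), sampled by rejection and rounded to whole years; mean 3.62 chronic
diseases (≥1) and mean 5.33 medications (≤14) per patient; anchor disease
prevalences hypertension 0.695, chronic kidney disease 0.422, dementia 0.331,
diabetes 0.29; anchor drug frequencies ASA 0.523, PPI 0.465, HCTZ 0.407,
metoprolol 0.306, quetiapine 0.269.  Optional per-sex overrides of the count
means (women 4.0 diseases / 5.3 drugs, men 3.5 / 6.1) are available.

*Sampling model.*  Each disease and each drug is included **independently**
at its marginal prevalence; unnamed items share a common prevalence
calibrated so the expected count equals the configured mean (e.g. the 69
unnamed diseases each get (3.62 − 1.738)/69 ≈ 0.027).  This makes every
configured marginal — count means, item prevalences, sex mix — exact in
expectation, which is the property the calibration tests verify at
n = 10,000 within three standard errors.  The count *dispersion* is emergent
(≈1.65 SD for diseases, ≈2.1 for drugs) rather than prescribed: a
count-first scheme (draw a count, then weighted sampling without
replacement) can reproduce a target SD but provably cannot reproduce the
stated per-item prevalences at the same time, and the marginals are the
quantities the rest of the pipeline depends on.  The min-1-disease top-up
(≈1.2% of patients) and the 14-drug cap (<0.01%) bias the calibrated means
by <0.015, well inside three standard errors at n = 10,000.  Doses are drawn
from typical tablet strengths (missing with probability 0.15) and durations
from common course lengths (missing with probability 0.30) so both the
conditioned-rule and the uncertain-finding paths are exercised.  An optional
one-factor Gaussian copula (`coupling`) correlates disease and drug
inclusion to emulate the positive disease-count/drug-count correlation seen
in real geriatric cohorts; it is off by default because independence is the
minimal defensible model.

*What the generator does not emulate:* real prescribing patterns
(drug–indication coherence), comorbidity clustering, or any clinical content
of the rules.  Passing tests therefore demonstrate the correctness of the
machinery on realistic *structure*, not clinical validity on real data.

**Knowledge-base generator** (`KBConfig`, defaults): a study-scale registry
of 430 agents and 73 diseases.  A latent "PIM core" of 28% of drugs is
flagged by each criterion with probability 0.75; drugs outside the core with
probability 0.05; non-flagged slots receive an explicit `USABLE` rule with
probability 0.15.  These values are calibrated analytically so the expected
agent-level composition matches a curated geriatric database: ≈47% of agents
risky under at least one criterion, ≈32% usable, ≈21% without any warning —
while keeping per-criterion overlap partial, which is what gives the Venn
analytics non-trivial structure.  25% of risky drug–age rules carry a dose
or duration threshold drawn from typical values.  Pair and disease rules are
sampled at 2% of all possible keys (10% / 15% contraindicated, 5% explicit
no-warning).  Recognisable anchor rules (ASA > 325 mg/day, PPI > 56 days,
risperidone > 42 days, quetiapine unconditional and contraindicated with
dementia) are planted when the named ids are present so fixture screens
produce familiar findings.  The generator returns a `GroundTruth` object
recording exactly what was planted; tests verify that screening reproduces
it.

All randomness flows through one `numpy.random.Generator` seeded from the
config; nothing depends on dict-hash ordering, so a seed reproduces files
byte-for-byte across platforms.

## Numerical and design choices

* Age gate is inclusive at `min_age_years` (default 65): a 65-year-old is a
  geriatric patient.
* Dose/duration thresholds fire **strictly above** the threshold value
  (325 mg is not a violation; 326 mg is).
* Category tokens are case-insensitive on read, uppercase on write; sources
  are a `;`-separated cell, deduplicated order-preserving on merge.
* Knowledge-base and cohort writers emit rows in sorted key order so
  round-trips and seed-reproducibility are byte-exact.
* Duplicate medication entries collapse to the maximum dose and duration
  (worst case); normalisation is idempotent.
* One rule per drug pair and per (drug, disease): reconciling conflicting
  severities between bibliographic sources is a curation-time task, not an
  inference-time one.
* Problem sizes in the tests: the engine/oracle equivalence check runs 1,000
  random patients against a 60-drug fixture knowledge base; generator
  calibration runs n = 10,000; Venn exactness 200 random families.  The
  acceptance script screens a 296-patient cohort against the 430-agent
  fixture knowledge base and recalibrates marginals at n = 10,000.

## Known limitations

* Bundled and generated knowledge bases are **synthetic fixtures**; no
  clinically validated content for real agents is shipped, and the tool must
  not be used for actual prescribing decisions without a curated database.
* Prescription-omission screening (START-style), alternative-agent
  recommendation and free-text prospectus parsing are out of scope.
* The paired t-test on per-patient PIM counts treats counts as interval data,
  as is conventional in criteria-comparison studies; for heavily zero-inflated
  cohorts a paired non-parametric test would be more defensible.
* Spearman's exact permutation p is limited to n ≤ 8 (40,320 permutations).
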