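"""Seeded generators for synthetic geriatric cohorts and fixture knowledge bases.

The cohort generator emulates the marginal structure of a hospital-based
geriatric polypharmacy sample: ~74.3% female; ages truncated-normal within
65–103 years (mean 83 ± 8 for men, 86 ± 7 for women); on average 3.62 chronic
diseases (at least one) and 5.33 medications (at most 14) per patient; a few
highly prevalent anchor conditions (hypertension 69.5%, chronic kidney
disease 42.2%, dementia 33.1%, diabetes 29%) and anchor drugs
(acetylsalicylic acid 52.3%, proton-pump inhibitor 46.5%, hydrochlorothiazide
40.7%, metoprolol 30.6%, quetiapine 26.9%), with the remaining items
uniformly rare.

Diseases and drugs are included independently per patient, each at its
configured prevalence; the prevalence of unnamed items is calibrated so the
expected count matches the configured mean exactly.  This makes every
configured marginal (count means, prevalences, sex mix) exact in expectation;
the count dispersion is emergent rather than prescribed.  An optional shared
latent Gaussian factor couples disease and drug inclusion to emulate the
disease–drug count correlation seen in real cohorts (off by default).

The knowledge-base generator plants a latent "PIM core" of drugs that most
criteria flag, sprinkles criterion-specific flags outside it, conditions a
configurable share of risky drug–age rules on dose or duration thresholds,
and samples drug–drug / drug–disease rules at configurable densities.  It
returns the ground truth (per-criterion risky sets and all planted rules)
exactly consistent with the emitted tables, so screening results can be
checked against generator bookkeeping.

All randomness flows through a single :class:`numpy.random.Generator` seeded
from the config; nothing depends on hash ordering, so identical seeds give
byte-identical output on any platform.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .kb import (
    ALL_CRITERIA,
    AgeRule,
    Category,
    Criterion,
    Disease,
    DiseaseRule,
    DrugAgent,
    KnowledgeBase,
    PairRule,
    canonical_pair,
)
from .patient import Cohort, MedicationRecord, Patient

__all__ = [
    "ConfigError",
    "CohortConfig",
    "KBConfig",
    "GroundTruth",
    "gen_cohort",
    "gen_kb",
    "default_drug_ids",
    "default_disease_ids",
    "load_cohort_config",
    "load_kb_config",
]


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


# ---------------------------------------------------------------------------
# Default universes
# ---------------------------------------------------------------------------

#: Anchor drugs with real ATC classes; the study-scale registry has 430 agents.
_NAMED_DRUGS: tuple[tuple[str, str, str], ...] = (
    ("asa", "Acetylsalicylic acid", "B01AC06"),
    ("ppi", "Proton pump inhibitor", "A02BC"),
    ("hctz", "Hydrochlorothiazide", "C03AA03"),
    ("metoprolol", "Metoprolol", "C07AB02"),
    ("quetiapine", "Quetiapine", "N05AH04"),
    ("risperidone", "Risperidone", "N05AX08"),
)

_NAMED_DISEASES: tuple[tuple[str, str], ...] = (
    ("hypertension", "Hypertension"),
    ("ckd", "Chronic kidney disease"),
    ("dementia", "Dementia"),
    ("diabetes", "Diabetes mellitus"),
)

DEFAULT_N_DRUGS = 430
DEFAULT_N_DISEASES = 73

_ATC_LETTERS = "ABCDGHJLMNPRSV"


def default_drug_ids(n: int = DEFAULT_N_DRUGS) -> list[str]:
    named = [d for d, _, _ in _NAMED_DRUGS][: min(n, len(_NAMED_DRUGS))]
    return named + [f"drug{i:03d}" for i in range(len(named) + 1, n + 1)]


def default_disease_ids(n: int = DEFAULT_N_DISEASES) -> list[str]:
    named = [d for d, _ in _NAMED_DISEASES][: min(n, len(_NAMED_DISEASES))]
    return named + [f"disease{i:03d}" for i in range(len(named) + 1, n + 1)]


def _synthetic_atc(index: int) -> str:
    # deterministic, pattern-valid synthetic ATC level-5 code
    a = _ATC_LETTERS[index % len(_ATC_LETTERS)]
    b = _ATC_LETTERS[(index // 7) % len(_ATC_LETTERS)]
    c = _ATC_LETTERS[(index // 11) % len(_ATC_LETTERS)]
    return f"{a}{index % 100:02d}{b}{c}{(index * 3) % 100:02d}"


DEFAULT_DISEASE_PREVALENCES: dict[str, float] = {
    "hypertension": 0.695,
    "ckd": 0.422,
    "dementia": 0.331,
    "diabetes": 0.29,
}

DEFAULT_DRUG_FREQUENCIES: dict[str, float] = {
    "asa": 0.523,
    "ppi": 0.465,
    "hctz": 0.407,
    "metoprolol": 0.306,
    "quetiapine": 0.269,
}


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Distribution parameters for the synthetic cohort generator.

    ``disease_weights``/``drug_weights`` give marginal inclusion prevalences
    for named items; every other item in the universe receives a common
    prevalence calibrated so the expected per-patient count equals
    ``mean_diseases``/``mean_drugs``.  Per-sex count means, when given,
    recalibrate the unnamed-item prevalence per sex (named prevalences stay
    shared).  ``coupling`` in [0, 1) adds a shared latent Gaussian factor
    inducing positive correlation between a patient's disease and drug
    counts.
    """

    n: int = 296
    seed: int = 0
    p_female: float = 0.743
    age_mean_female: float = 86.0
    age_sd_female: float = 7.0
    age_mean_male: float = 83.0
    age_sd_male: float = 8.0
    age_min: int = 65
    age_max: int = 103
    mean_diseases: float = 3.62
    min_diseases: int = 1
    mean_drugs: float = 5.33
    max_drugs: int = 14
    mean_diseases_by_sex: Mapping[str, float] | None = None
    mean_drugs_by_sex: Mapping[str, float] | None = None
    disease_ids: tuple[str, ...] | None = None
    drug_ids: tuple[str, ...] | None = None
    disease_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DISEASE_PREVALENCES)
    )
    drug_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_FREQUENCIES)
    )
    coupling: float = 0.0
    p_dose_missing: float = 0.15
    p_duration_missing: float = 0.30
    dose_choices_mg: tuple[float, ...] = (25, 50, 100, 200, 325, 500)
    duration_choices_days: tuple[int, ...] = (14, 28, 56, 90, 180, 365)

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("n must be non-negative")
        for name in ("p_female", "coupling", "p_dose_missing", "p_duration_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.coupling >= 1.0:
            raise ConfigError("coupling must be < 1")
        if self.age_min > self.age_max:
            raise ConfigError("age truncation bounds must be ordered")
        for w in (*self.disease_weights.values(), *self.drug_weights.values()):
            if not 0.0 <= w <= 1.0:
                raise ConfigError(f"prevalence weights must be in [0, 1], got {w}")

    def resolved_disease_ids(self) -> list[str]:
        return list(self.disease_ids) if self.disease_ids else default_disease_ids()

    def resolved_drug_ids(self) -> list[str]:
        return list(self.drug_ids) if self.drug_ids else default_drug_ids()


def _inclusion_probs(
    ids: Sequence[str], named: Mapping[str, float], mean_count: float, what: str
) -> np.ndarray:
    """Per-item inclusion probabilities: named items keep their prevalence,
    unnamed items share a common value calibrated to the target mean count."""
    probs = np.zeros(len(ids))
    named_sum = 0.0
    unnamed = []
    for i, item in enumerate(ids):
        if item in named:
            probs[i] = named[item]
            named_sum += named[item]
        else:
            unnamed.append(i)
    rest = mean_count - named_sum
    if unnamed:
        p_u = rest / len(unnamed)
        if not 0.0 <= p_u <= 1.0:
            raise ConfigError(
                f"cannot calibrate {what}: mean {mean_count} implies unnamed "
                f"prevalence {p_u:.4f} outside [0, 1]"
            )
        probs[unnamed] = p_u
    elif abs(rest) > 1e-9:
        raise ConfigError(
            f"{what}: named prevalences sum to {named_sum}, inconsistent with mean {mean_count}"
        )
    return probs


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> np.ndarray:
    """Rejection sampling from N(mean, sd) truncated to [lo, hi]."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 16))
        keep = draw[(draw >= lo) & (draw <= hi)]
        take = min(keep.size, n - filled)
        out[filled : filled + take] = keep[:take]
        filled += take
    return out


def _inclusion_matrix(
    rng: np.random.Generator,
    probs_by_sex: dict[str, np.ndarray],
    sexes: np.ndarray,
    latent: np.ndarray | None,
    coupling: float,
) -> np.ndarray:
    """Bernoulli inclusion matrix (n_patients × n_items), optionally driven by
    a shared latent factor through a one-factor Gaussian copula."""
    n = sexes.size
    n_items = next(iter(probs_by_sex.values())).size
    if latent is None or coupling == 0.0:
        u = rng.random((n, n_items))
    else:
        eps = rng.standard_normal((n, n_items))
        from scipy.stats import norm

        z = coupling * latent[:, None] + np.sqrt(1.0 - coupling**2) * eps
        u = norm.cdf(z)
    thresholds = np.empty((n, n_items))
    for sex, probs in probs_by_sex.items():
        mask = sexes == sex
        thresholds[mask] = probs[None, :]
    return u < thresholds


def gen_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a reproducible synthetic cohort from ``cfg``.

    Ages are truncated-normal per sex, rounded to whole years.  Each disease
    and drug is included independently at its prevalence (see
    :class:`CohortConfig`); patients are guaranteed ``min_diseases`` diseases
    (topped up proportionally to prevalence when the draw comes up short) and
    at most ``max_drugs`` drugs (a uniform subset is kept on overflow) — both
    adjustments are rare and their bias on the calibrated means is <0.02.
    """
    rng = np.random.default_rng(cfg.seed)
    disease_ids = np.array(cfg.resolved_disease_ids())
    drug_ids = np.array(cfg.resolved_drug_ids())

    sexes = np.where(rng.random(cfg.n) < cfg.p_female, "F", "M")
    ages = np.empty(cfg.n)
    for sex, mean, sd in (("F", cfg.age_mean_female, cfg.age_sd_female),
                          ("M", cfg.age_mean_male, cfg.age_sd_male)):
        mask = sexes == sex
        ages[mask] = _truncated_normal(
            rng, int(mask.sum()), mean, sd, cfg.age_min, cfg.age_max
        )
    ages = np.clip(np.rint(ages), cfg.age_min, cfg.age_max).astype(int)

    def probs_by_sex(ids, named, overall_mean, by_sex, what):
        if by_sex:
            return {
                sex: _inclusion_probs(ids, named, by_sex.get(sex, overall_mean), what)
                for sex in ("F", "M")
            }
        shared = _inclusion_probs(ids, named, overall_mean, what)
        return {"F": shared, "M": shared}

    disease_probs = probs_by_sex(
        disease_ids, cfg.disease_weights, cfg.mean_diseases,
        cfg.mean_diseases_by_sex, "disease prevalences",
    )
    drug_probs = probs_by_sex(
        drug_ids, cfg.drug_weights, cfg.mean_drugs,
        cfg.mean_drugs_by_sex, "drug frequencies",
    )

    latent = rng.standard_normal(cfg.n) if cfg.coupling > 0 else None
    disease_inc = _inclusion_matrix(rng, disease_probs, sexes, latent, cfg.coupling)
    drug_inc = _inclusion_matrix(rng, drug_probs, sexes, latent, cfg.coupling)

    patients: list[Patient] = []
    for i in range(cfg.n):
        sex = str(sexes[i])
        diseases = set(disease_ids[disease_inc[i]])
        while len(diseases) < cfg.min_diseases:
            probs = disease_probs[sex].copy()
            for j, d in enumerate(disease_ids):
                if d in diseases:
                    probs[j] = 0.0
            probs /= probs.sum()
            diseases.add(str(rng.choice(disease_ids, p=probs)))

        included = list(drug_ids[drug_inc[i]])
        if len(included) > cfg.max_drugs:
            keep = rng.choice(len(included), size=cfg.max_drugs, replace=False)
            included = [included[k] for k in sorted(keep)]

        meds = []
        for drug in included:
            dose = None
            if rng.random() >= cfg.p_dose_missing:
                dose = float(rng.choice(cfg.dose_choices_mg))
            duration = None
            if rng.random() >= cfg.p_duration_missing:
                duration = int(rng.choice(cfg.duration_choices_days))
            meds.append(MedicationRecord(str(drug), dose, duration))

        patients.append(
            Patient(
                patient_id=f"p{i + 1:05d}",
                age_years=int(ages[i]),
                sex=sex,
                medications=tuple(meds),
                diseases=frozenset(diseases),
            )
        )
    return Cohort(patients)


# ---------------------------------------------------------------------------
# Knowledge-base generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KBConfig:
    """Density parameters for the fixture knowledge-base generator.

    A ``core_pim_fraction`` share of drugs form a latent PIM core flagged by
    each criterion with probability ``p_flag_core``; drugs outside the core
    are flagged with probability ``p_flag_outside`` — this reproduces the
    partially-overlapping structure of published PIM lists.  Non-flagged
    (criterion, drug) slots get an explicit USABLE rule with probability
    ``usable_probability``.  ``conditioned_fraction`` of risky drug–age rules
    carry a dose or duration threshold.  Interaction tables are sampled at
    ``ddi_density`` / ``ddisease_density`` of all possible keys.
    """

    # defaults reproduce the agent-level composition of a curated geriatric
    # database: ~47% of agents risky somewhere, ~32% usable, ~21% no warning
    n_drugs: int = DEFAULT_N_DRUGS
    n_diseases: int = DEFAULT_N_DISEASES
    seed: int = 0
    core_pim_fraction: float = 0.28
    p_flag_core: float = 0.75
    p_flag_outside: float = 0.05
    usable_probability: float = 0.15
    conditioned_fraction: float = 0.25
    ddi_density: float = 0.02
    ddi_contraindicated_fraction: float = 0.10
    ddisease_density: float = 0.02
    ddisease_contraindicated_fraction: float = 0.15
    explicit_no_warning_fraction: float = 0.05
    include_anchor_rules: bool = True

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_diseases < 1:
            raise ConfigError("n_drugs and n_diseases must be positive")
        for name in (
            "core_pim_fraction", "p_flag_core", "p_flag_outside",
            "usable_probability", "conditioned_fraction",
            "ddi_density", "ddi_contraindicated_fraction",
            "ddisease_density", "ddisease_contraindicated_fraction",
            "explicit_no_warning_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruth:
    """Generator bookkeeping, exactly consistent with the emitted tables."""

    core_drugs: set[str]
    risky_by_criterion: dict[str, set[str]]
    usable_by_criterion: dict[str, set[str]]
    conditioned_rules: list[AgeRule]
    pair_rules: dict[tuple[str, str], str]  # key -> category token
    disease_rules: dict[tuple[str, str], str]

    @property
    def reference_risky(self) -> set[str]:
        out: set[str] = set()
        for s in self.risky_by_criterion.values():
            out |= s
        return out

    def to_json(self) -> dict:
        return {
            "core_drugs": sorted(self.core_drugs),
            "risky_by_criterion": {
                k: sorted(v) for k, v in self.risky_by_criterion.items()
            },
            "usable_by_criterion": {
                k: sorted(v) for k, v in self.usable_by_criterion.items()
            },
            "reference_risky": sorted(self.reference_risky),
            "pair_rules": {
                f"{lo}|{hi}": cat for (lo, hi), cat in sorted(self.pair_rules.items())
            },
            "disease_rules": {
                f"{d}|{s}": cat for (d, s), cat in sorted(self.disease_rules.items())
            },
        }


_ANCHOR_COMMENTS = {
    "asa": "doses above 325 mg/day are potentially inappropriate in the elderly",
    "ppi": "use beyond 8 weeks without indication is potentially inappropriate",
    "risperidone": "use beyond 6 weeks is potentially inappropriate",
    "quetiapine": "antipsychotic with unfavourable risk profile in the elderly",
}


def _anchor_age_rules(drug_ids: set[str]) -> list[AgeRule]:
    rules = []
    if "asa" in drug_ids:
        rules.append(
            AgeRule(
                Criterion.BEERS_2019, "asa", Category.RISKY,
                max_dose_mg_per_day=325.0,
                comment=_ANCHOR_COMMENTS["asa"],
                sources=("synthetic-anchor:beers-2019:asa",),
            )
        )
    if "ppi" in drug_ids:
        rules.append(
            AgeRule(
                Criterion.TIME_TO_STOPP, "ppi", Category.RISKY,
                max_duration_days=56,
                comment=_ANCHOR_COMMENTS["ppi"],
                sources=("synthetic-anchor:time-to-stopp:ppi",),
            )
        )
    if "risperidone" in drug_ids:
        rules.append(
            AgeRule(
                Criterion.EU7_PIM, "risperidone", Category.RISKY,
                max_duration_days=42,
                comment=_ANCHOR_COMMENTS["risperidone"],
                sources=("synthetic-anchor:eu7-pim:risperidone",),
            )
        )
    if "quetiapine" in drug_ids:
        rules.append(
            AgeRule(
                Criterion.BEERS_2019, "quetiapine", Category.RISKY,
                comment=_ANCHOR_COMMENTS["quetiapine"],
                sources=("synthetic-anchor:beers-2019:quetiapine",),
            )
        )
    return rules


def gen_kb(cfg: KBConfig) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate a validated fixture knowledge base and its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    drug_ids = default_drug_ids(cfg.n_drugs)
    disease_ids = default_disease_ids(cfg.n_diseases)
    named_drugs = {d: (n, atc) for d, n, atc in _NAMED_DRUGS}
    named_diseases = dict(_NAMED_DISEASES)

    drugs = [
        DrugAgent(
            d,
            named_drugs[d][0] if d in named_drugs else f"Agent {d}",
            named_drugs[d][1] if d in named_drugs else _synthetic_atc(i + 1),
        )
        for i, d in enumerate(drug_ids)
    ]
    diseases = [
        Disease(d, named_diseases.get(d, f"Condition {d}")) for d in disease_ids
    ]

    # latent PIM core shared across criteria
    n_core = int(round(cfg.core_pim_fraction * cfg.n_drugs))
    core_idx = rng.choice(cfg.n_drugs, size=n_core, replace=False)
    core = {drug_ids[i] for i in core_idx}

    age_rules: list[AgeRule] = []
    risky: dict[str, set[str]] = {c.value: set() for c in ALL_CRITERIA}
    usable: dict[str, set[str]] = {c.value: set() for c in ALL_CRITERIA}
    conditioned: list[AgeRule] = []

    if cfg.include_anchor_rules:
        for rule in _anchor_age_rules(set(drug_ids)):
            age_rules.append(rule)
            risky[rule.criterion.value].add(rule.drug_id)
            if rule.conditioned:
                conditioned.append(rule)
    anchored = {(r.criterion, r.drug_id) for r in age_rules}

    dose_thresholds = (75.0, 100.0, 325.0, 500.0)
    duration_thresholds = (28, 42, 56, 90)

    for criterion in ALL_CRITERIA:
        for drug_id in drug_ids:
            if (criterion, drug_id) in anchored:
                continue
            p_flag = cfg.p_flag_core if drug_id in core else cfg.p_flag_outside
            if rng.random() < p_flag:
                kwargs: dict = {}
                if rng.random() < cfg.conditioned_fraction:
                    if rng.random() < 0.5:
                        kwargs["max_dose_mg_per_day"] = float(
                            rng.choice(dose_thresholds)
                        )
                    else:
                        kwargs["max_duration_days"] = int(
                            rng.choice(duration_thresholds)
                        )
                rule = AgeRule(
                    criterion, drug_id, Category.RISKY,
                    comment=f"flagged by {criterion.value} for patients over 65",
                    sources=(f"synthetic-ref:{criterion.value.lower()}:{drug_id}",),
                    **kwargs,
                )
                age_rules.append(rule)
                risky[criterion.value].add(drug_id)
                if rule.conditioned:
                    conditioned.append(rule)
            elif rng.random() < cfg.usable_probability:
                age_rules.append(
                    AgeRule(
                        criterion, drug_id, Category.USABLE,
                        comment=f"listed usable by {criterion.value}",
                        sources=(f"synthetic-ref:{criterion.value.lower()}:{drug_id}",),
                    )
                )
                usable[criterion.value].add(drug_id)

    # drug–drug rules over sampled canonical pairs
    pair_rules: list[PairRule] = []
    gt_pairs: dict[tuple[str, str], str] = {}
    if cfg.include_anchor_rules and "quetiapine" in set(drug_ids):
        pass  # the quetiapine anchor lives in the disease table
    all_pairs = [
        canonical_pair(drug_ids[i], drug_ids[j])
        for i in range(cfg.n_drugs)
        for j in range(i + 1, cfg.n_drugs)
    ]
    n_pair = int(round(cfg.ddi_density * len(all_pairs)))
    if n_pair:
        chosen = rng.choice(len(all_pairs), size=n_pair, replace=False)
        for idx in sorted(chosen):
            lo, hi = all_pairs[idx]
            u = rng.random()
            if u < cfg.explicit_no_warning_fraction:
                category, sources = Category.NO_WARNING, ()
            elif u < cfg.explicit_no_warning_fraction + cfg.ddi_contraindicated_fraction:
                category = Category.CONTRAINDICATED
                sources = (f"synthetic-prospectus:{lo}+{hi}",)
            else:
                category = Category.RISKY
                sources = (f"synthetic-prospectus:{lo}+{hi}",)
            pair_rules.append(
                PairRule(lo, hi, category, comment=f"interaction of {lo} with {hi}",
                         sources=sources)
            )
            gt_pairs[(lo, hi)] = category.value

    # drug–disease rules
    disease_rules: list[DiseaseRule] = []
    gt_disease: dict[tuple[str, str], str] = {}
    if cfg.include_anchor_rules and "quetiapine" in set(drug_ids) and "dementia" in set(disease_ids):
        anchor = DiseaseRule(
            "quetiapine", "dementia", Category.CONTRAINDICATED,
            comment="antipsychotic use in dementia carries excess mortality risk",
            sources=("synthetic-anchor:prospectus:quetiapine+dementia",),
        )
        disease_rules.append(anchor)
        gt_disease[anchor.key] = anchor.category.value
    all_dd = [(d, s) for d in drug_ids for s in disease_ids]
    n_dd = int(round(cfg.ddisease_density * len(all_dd)))
    if n_dd:
        chosen = rng.choice(len(all_dd), size=n_dd, replace=False)
        for idx in sorted(chosen):
            key = all_dd[idx]
            if key in gt_disease:
                continue
            u = rng.random()
            if u < cfg.explicit_no_warning_fraction:
                category, sources = Category.NO_WARNING, ()
            elif u < cfg.explicit_no_warning_fraction + cfg.ddisease_contraindicated_fraction:
                category = Category.CONTRAINDICATED
                sources = (f"synthetic-guideline:{key[0]}+{key[1]}",)
            else:
                category = Category.RISKY
                sources = (f"synthetic-guideline:{key[0]}+{key[1]}",)
            disease_rules.append(
                DiseaseRule(
                    key[0], key[1], category,
                    comment=f"use of {key[0]} with {key[1]}", sources=sources,
                )
            )
            gt_disease[key] = category.value

    kb = KnowledgeBase.build(drugs, diseases, age_rules, pair_rules, disease_rules)
    truth = GroundTruth(
        core_drugs=core,
        risky_by_criterion=risky,
        usable_by_criterion=usable,
        conditioned_rules=conditioned,
        pair_rules=gt_pairs,
        disease_rules=gt_disease,
    )
    return kb, truth


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def _load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"config file missing: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def _from_dict(cls, data: Mapping) -> object:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    coerced = {
        k: tuple(v) if isinstance(v, list) and k.endswith(("_ids", "_mg", "_days")) else v
        for k, v in data.items()
    }
    return cls(**coerced)


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Read a :class:`CohortConfig` from YAML or JSON."""
    return _from_dict(CohortConfig, _load_config_dict(path))


def load_kb_config(path: str | Path) -> KBConfig:
    """Read a :class:`KBConfig` from YAML or JSON."""
    return _from_dict(KBConfig, _load_config_dict(path))
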