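"""Three-table interaction knowledge base for geriatric medication screening.

The knowledge base holds a drug registry, a disease registry, and three rule
tables:

* **drug–age rules** — per published PIM criterion, classify a drug for
  patients above an age threshold as ``USABLE``, ``RISKY`` or ``NO_WARNING``,
  optionally conditioned on daily dose or treatment duration;
* **drug–drug rules** — one rule per unordered pair of drugs, classified
  ``RISKY``, ``CONTRAINDICATED`` or ``NO_WARNING``;
* **drug–disease rules** — one rule per (drug, chronic disease) pair with the
  same categories.

Six published PIM criteria are modelled (AGS Beers 2019, STOPP v2,
TIME-to-STOPP, EU(7)-PIM, PRISCUS, US-FORTA).  Their union — a drug is a PIM
if *any* criterion flags it — is the *reference method*; it is always derived,
never stored.

Every rule carries a free-text comment and a list of bibliographic source
strings so that downstream findings are explainable and citable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Criterion",
    "REFERENCE",
    "Category",
    "DrugAgent",
    "Disease",
    "AgeRule",
    "PairRule",
    "DiseaseRule",
    "KnowledgeBase",
    "KBError",
    "SchemaError",
    "CategoryValueError",
    "ReferentialError",
    "DuplicateRuleError",
    "SelfPairError",
    "canonical_pair",
    "load_kb",
    "write_kb",
    "reference_age_class",
    "consensus_pims",
    "criterion_coverage",
]

DEFAULT_MIN_AGE_YEARS = 65

#: ATC codes: full level-5 pattern (e.g. ``B01AC06``) or a shorter class
#: prefix (``A02BC``, ``N05A``, ...).
_ATC_RE = re.compile(r"^[A-Z]($|\d{2}($|[A-Z]($|[A-Z]($|\d{2}$))))")


class Criterion(str, Enum):
    """The six published PIM criteria backing the drug–age table."""

    BEERS_2019 = "BEERS_2019"
    STOPP_V2 = "STOPP_V2"
    TIME_TO_STOPP = "TIME_TO_STOPP"
    EU7_PIM = "EU7_PIM"
    PRISCUS = "PRISCUS"
    US_FORTA = "US_FORTA"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Pseudo-criterion naming the union of all six criteria ("reference method").
#: Never stored in rule tables; only derived.
REFERENCE = "REFERENCE"

ALL_CRITERIA: tuple[Criterion, ...] = tuple(Criterion)


class Category(str, Enum):
    """Classification categories across all three rule tables.

    Drug–age rules use ``USABLE``/``RISKY``/``NO_WARNING``; interaction rules
    use ``RISKY``/``CONTRAINDICATED``/``NO_WARNING``.  ``UNKNOWN_AGENT`` is a
    screening-time outcome (drug absent from the registry), never a stored
    rule category.
    """

    USABLE = "USABLE"
    RISKY = "RISKY"
    CONTRAINDICATED = "CONTRAINDICATED"
    NO_WARNING = "NO_WARNING"
    UNKNOWN_AGENT = "UNKNOWN_AGENT"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


AGE_CATEGORIES = frozenset({Category.USABLE, Category.RISKY, Category.NO_WARNING})
INTERACTION_CATEGORIES = frozenset(
    {Category.RISKY, Category.CONTRAINDICATED, Category.NO_WARNING}
)


class KBError(ValueError):
    """Base class for knowledge-base validation failures."""


class SchemaError(KBError):
    """A required column is missing from a table file."""


class CategoryValueError(KBError):
    """A rule row carries an unrecognised category or criterion token."""


class ReferentialError(KBError):
    """A rule references a drug or disease absent from the registries."""


class DuplicateRuleError(KBError):
    """Two rules share a key that must be unique."""


class SelfPairError(KBError):
    """A drug pair was built from a single drug."""


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Return the unordered drug pair ``(a, b)`` in canonical (sorted) form.

    Drug–drug interactions are symmetric, so pair rules are stored once under
    the lexicographically sorted key and all lookups normalise through here.

    Raises
    ------
    SelfPairError
        If ``a == b``.
    """
    if a == b:
        raise SelfPairError(f"cannot form an interaction pair of {a!r} with itself")
    return (a, b) if a < b else (b, a)


@dataclass(frozen=True)
class DrugAgent:
    """A pharmaceutical agent in the registry, optionally ATC-classified."""

    drug_id: str
    name: str
    atc_code: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_id or self.drug_id != self.drug_id.lower() or any(
            c.isspace() for c in self.drug_id
        ):
            raise KBError(
                f"drug_id must be a lowercase token without whitespace, got {self.drug_id!r}"
            )
        if self.atc_code is not None and not _ATC_RE.match(self.atc_code):
            raise KBError(f"invalid ATC code {self.atc_code!r} for drug {self.drug_id!r}")


@dataclass(frozen=True)
class Disease:
    """A chronic disease or medical condition in the registry."""

    disease_id: str
    name: str

    def __post_init__(self) -> None:
        if not self.disease_id or any(c.isspace() for c in self.disease_id):
            raise KBError(f"disease_id must be a token without whitespace, got {self.disease_id!r}")


@dataclass(frozen=True)
class AgeRule:
    """A per-criterion drug–age classification, optionally dose/duration-conditioned.

    A conditioned rule fires only above its threshold: ``max_dose_mg_per_day``
    means doses *above* that value are flagged, ``max_duration_days`` means use
    *longer* than that is flagged.
    """

    criterion: Criterion
    drug_id: str
    category: Category
    min_age_years: int = DEFAULT_MIN_AGE_YEARS
    max_dose_mg_per_day: float | None = None
    max_duration_days: int | None = None
    comment: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in AGE_CATEGORIES:
            raise CategoryValueError(
                f"drug-age rule category must be one of "
                f"{sorted(c.value for c in AGE_CATEGORIES)}, got {self.category!r}"
            )
        if self.category in (Category.RISKY, Category.USABLE) and not self.sources:
            raise KBError(
                f"{self.category.value} age rule for {self.drug_id!r} "
                f"({self.criterion.value}) must cite at least one source"
            )
        if self.max_dose_mg_per_day is not None and self.max_dose_mg_per_day <= 0:
            raise KBError("max_dose_mg_per_day must be positive when present")
        if self.max_duration_days is not None and self.max_duration_days <= 0:
            raise KBError("max_duration_days must be positive when present")

    @property
    def conditioned(self) -> bool:
        """True when the rule carries a dose or duration threshold."""
        return self.max_dose_mg_per_day is not None or self.max_duration_days is not None


@dataclass(frozen=True)
class PairRule:
    """A drug–drug interaction rule stored under the canonical pair key."""

    drug_lo: str
    drug_hi: str
    category: Category
    comment: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.drug_lo >= self.drug_hi:
            raise KBError(
                f"pair rule must be canonically ordered, got ({self.drug_lo!r}, {self.drug_hi!r})"
            )
        if self.category not in INTERACTION_CATEGORIES:
            raise CategoryValueError(
                f"pair rule category must be one of "
                f"{sorted(c.value for c in INTERACTION_CATEGORIES)}, got {self.category!r}"
            )
        if self.category is not Category.NO_WARNING and not self.sources:
            raise KBError(
                f"{self.category.value} pair rule ({self.drug_lo}, {self.drug_hi}) "
                "must cite at least one source"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_lo, self.drug_hi)


@dataclass(frozen=True)
class DiseaseRule:
    """A drug–disease interaction rule."""

    drug_id: str
    disease_id: str
    category: Category
    comment: str = ""
    sources: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in INTERACTION_CATEGORIES:
            raise CategoryValueError(
                f"disease rule category must be one of "
                f"{sorted(c.value for c in INTERACTION_CATEGORIES)}, got {self.category!r}"
            )
        if self.category is not Category.NO_WARNING and not self.sources:
            raise KBError(
                f"{self.category.value} disease rule ({self.drug_id}, {self.disease_id}) "
                "must cite at least one source"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.drug_id, self.disease_id)


@dataclass
class KnowledgeBase:
    """Validated registries plus the three rule tables.

    ``age_rules`` is a multimap keyed ``(criterion, drug_id)``: a conditioned
    RISKY rule may coexist with at most one unconditional rule for the same
    key (e.g. "usable, but risky above 325 mg/day").
    """

    drugs: dict[str, DrugAgent] = field(default_factory=dict)
    diseases: dict[str, Disease] = field(default_factory=dict)
    age_rules: dict[tuple[Criterion, str], list[AgeRule]] = field(default_factory=dict)
    pair_rules: dict[tuple[str, str], PairRule] = field(default_factory=dict)
    disease_rules: dict[tuple[str, str], DiseaseRule] = field(default_factory=dict)

    # -- construction -----------------------------------------------------

    @classmethod
    def build(
        cls,
        drugs: Iterable[DrugAgent],
        diseases: Iterable[Disease],
        age_rules: Iterable[AgeRule] = (),
        pair_rules: Iterable[PairRule] = (),
        disease_rules: Iterable[DiseaseRule] = (),
    ) -> "KnowledgeBase":
        """Assemble and fully validate a knowledge base from rule iterables."""
        kb = cls()
        for d in drugs:
            if d.drug_id in kb.drugs:
                raise DuplicateRuleError(f"duplicate drug_id {d.drug_id!r} in registry")
            kb.drugs[d.drug_id] = d
        for ds in diseases:
            if ds.disease_id in kb.diseases:
                raise DuplicateRuleError(f"duplicate disease_id {ds.disease_id!r} in registry")
            kb.diseases[ds.disease_id] = ds
        for r in age_rules:
            kb._add_age_rule(r)
        for r in pair_rules:
            kb._add_pair_rule(r)
        for r in disease_rules:
            kb._add_disease_rule(r)
        kb.validate()
        return kb

    def _add_age_rule(self, rule: AgeRule) -> None:
        key = (rule.criterion, rule.drug_id)
        bucket = self.age_rules.setdefault(key, [])
        if not rule.conditioned and any(not r.conditioned for r in bucket):
            raise DuplicateRuleError(
                f"two unconditional age rules share key ({rule.criterion.value}, {rule.drug_id!r})"
            )
        bucket.append(rule)

    def _add_pair_rule(self, rule: PairRule) -> None:
        if rule.key in self.pair_rules:
            raise DuplicateRuleError(f"duplicate pair rule for {rule.key!r}")
        self.pair_rules[rule.key] = rule

    def _add_disease_rule(self, rule: DiseaseRule) -> None:
        if rule.key in self.disease_rules:
            raise DuplicateRuleError(f"duplicate disease rule for {rule.key!r}")
        self.disease_rules[rule.key] = rule

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Check referential integrity of every rule against the registries."""
        dangling: list[str] = []
        for (criterion, drug_id) in self.age_rules:
            if drug_id not in self.drugs:
                dangling.append(drug_id)
        for (lo, hi) in self.pair_rules:
            dangling.extend(d for d in (lo, hi) if d not in self.drugs)
        for (drug_id, disease_id) in self.disease_rules:
            if drug_id not in self.drugs:
                dangling.append(drug_id)
            if disease_id not in self.diseases:
                dangling.append(disease_id)
        if dangling:
            raise ReferentialError(
                "rules reference unregistered ids: "
                + ", ".join(repr(k) for k in sorted(set(dangling)))
            )

    # -- queries -----------------------------------------------------------

    def age_rules_for(self, criterion: Criterion, drug_id: str) -> list[AgeRule]:
        return self.age_rules.get((criterion, drug_id), [])

    def pair_rule_for(self, a: str, b: str) -> PairRule | None:
        return self.pair_rules.get(canonical_pair(a, b))

    def disease_rule_for(self, drug_id: str, disease_id: str) -> DiseaseRule | None:
        return self.disease_rules.get((drug_id, disease_id))

    def risky_set(self, criterion: Criterion) -> set[str]:
        """Drugs with at least one RISKY age rule (conditional or not) under ``criterion``."""
        return {
            drug_id
            for (c, drug_id), rules in self.age_rules.items()
            if c is criterion and any(r.category is Category.RISKY for r in rules)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            self.drugs == other.drugs
            and self.diseases == other.diseases
            and {k: sorted(v, key=repr) for k, v in self.age_rules.items()}
            == {k: sorted(v, key=repr) for k, v in other.age_rules.items()}
            and self.pair_rules == other.pair_rules
            and self.disease_rules == other.disease_rules
        )


# ---------------------------------------------------------------------------
# Derived classifications
# ---------------------------------------------------------------------------


def reference_age_class(kb: KnowledgeBase, drug_id: str) -> Category:
    """Patient-independent reference-method classification of one drug.

    The reference method unions all six criteria: a drug is ``RISKY`` if any
    criterion holds any RISKY rule for it (conditioned or not — agent-level
    tallies count a drug as a PIM irrespective of dose), else ``USABLE`` if any
    criterion holds a USABLE rule, else ``NO_WARNING``.
    """
    if drug_id not in kb.drugs:
        raise KeyError(f"drug {drug_id!r} is not registered")
    seen_usable = False
    for criterion in ALL_CRITERIA:
        for rule in kb.age_rules_for(criterion, drug_id):
            if rule.category is Category.RISKY:
                return Category.RISKY
            if rule.category is Category.USABLE:
                seen_usable = True
    return Category.USABLE if seen_usable else Category.NO_WARNING


def consensus_pims(
    kb: KnowledgeBase, criteria: Sequence[Criterion], k: int
) -> set[str]:
    """Drugs flagged RISKY by at least ``k`` of the given criteria.

    ``k=1`` is the union (the reference method's PIM set restricted to
    ``criteria``); ``k=len(criteria)`` is the intersection.
    """
    criteria = list(dict.fromkeys(criteria))
    if not 1 <= k <= len(criteria):
        raise ValueError(f"k must be in [1, {len(criteria)}], got {k}")
    counts: dict[str, int] = {}
    for criterion in criteria:
        for drug_id in kb.risky_set(criterion):
            counts[drug_id] = counts.get(drug_id, 0) + 1
    return {drug_id for drug_id, n in counts.items() if n >= k}


def criterion_coverage(flagged: set[str], reference: set[str]) -> float:
    """Fraction of the reference PIM set that ``flagged`` detects."""
    if not reference:
        raise ValueError("coverage is undefined for an empty reference set")
    return len(flagged & reference) / len(reference)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_FILES = {
    "drugs": "drugs.csv",
    "diseases": "diseases.csv",
    "age_rules": "age_rules.csv",
    "pair_rules": "pair_rules.csv",
    "disease_rules": "disease_rules.csv",
}

_COLUMNS = {
    "drugs": ["drug_id", "name", "atc_code"],
    "diseases": ["disease_id", "name"],
    "age_rules": [
        "criterion",
        "drug_id",
        "category",
        "min_age_years",
        "max_dose_mg_per_day",
        "max_duration_days",
        "comment",
        "sources",
    ],
    "pair_rules": ["drug_a", "drug_b", "category", "comment", "sources"],
    "disease_rules": ["drug_id", "disease_id", "category", "comment", "sources"],
}


def _read_table(path: Path, table: str) -> pd.DataFrame:
    if not path.is_file():
        raise FileNotFoundError(f"knowledge-base file missing: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COLUMNS[table] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return df


def _parse_sources(cell: str) -> tuple[str, ...]:
    # ';'-separated inside one cell; deduplicated, order-preserving
    out: list[str] = []
    for tok in cell.split(";"):
        tok = tok.strip()
        if tok and tok not in out:
            out.append(tok)
    return tuple(out)


def _parse_category(cell: str, row: int, path_name: str, allowed: frozenset[Category]) -> Category:
    tok = cell.strip().upper()  # case-insensitive on read
    try:
        cat = Category(tok)
    except ValueError:
        cat = None
    if cat is None or cat not in allowed:
        raise CategoryValueError(
            f"{path_name} row {row}: unknown category {cell!r} "
            f"(allowed: {', '.join(sorted(c.value for c in allowed))})"
        )
    return cat


def _opt_float(cell: str) -> float | None:
    cell = cell.strip()
    return float(cell) if cell else None


def _opt_int(cell: str) -> int | None:
    cell = cell.strip()
    return int(float(cell)) if cell else None


def load_kb(dir_path: str | Path) -> KnowledgeBase:
    """Load and validate a knowledge base from its five CSV files.

    The directory must contain ``drugs.csv``, ``diseases.csv``,
    ``age_rules.csv``, ``pair_rules.csv`` and ``disease_rules.csv`` with the
    documented headers (UTF-8, comma-delimited, empty cell = absent value,
    ``;`` separates sources).  Loading is order-independent and idempotent.
    Row numbers in error messages are 1-based data rows (header excluded).
    """
    dir_path = Path(dir_path)

    drugs_df = _read_table(dir_path / _FILES["drugs"], "drugs")
    drugs = [
        DrugAgent(row.drug_id, row.name, row.atc_code.strip() or None)
        for row in drugs_df.itertuples()
    ]

    dis_df = _read_table(dir_path / _FILES["diseases"], "diseases")
    diseases = [Disease(row.disease_id, row.name) for row in dis_df.itertuples()]

    age_df = _read_table(dir_path / _FILES["age_rules"], "age_rules")
    age_rules = []
    for i, row in enumerate(age_df.itertuples(), start=1):
        crit_tok = row.criterion.strip().upper()
        try:
            criterion = Criterion(crit_tok)
        except ValueError:
            raise CategoryValueError(
                f"age_rules.csv row {i}: unknown criterion {row.criterion!r}"
            ) from None
        age_rules.append(
            AgeRule(
                criterion=criterion,
                drug_id=row.drug_id,
                category=_parse_category(row.category, i, "age_rules.csv", AGE_CATEGORIES),
                min_age_years=_opt_int(row.min_age_years) or DEFAULT_MIN_AGE_YEARS,
                max_dose_mg_per_day=_opt_float(row.max_dose_mg_per_day),
                max_duration_days=_opt_int(row.max_duration_days),
                comment=row.comment,
                sources=_parse_sources(row.sources),
            )
        )

    pair_df = _read_table(dir_path / _FILES["pair_rules"], "pair_rules")
    pair_rules = []
    for i, row in enumerate(pair_df.itertuples(), start=1):
        lo, hi = canonical_pair(row.drug_a, row.drug_b)
        pair_rules.append(
            PairRule(
                drug_lo=lo,
                drug_hi=hi,
                category=_parse_category(row.category, i, "pair_rules.csv", INTERACTION_CATEGORIES),
                comment=row.comment,
                sources=_parse_sources(row.sources),
            )
        )

    dr_df = _read_table(dir_path / _FILES["disease_rules"], "disease_rules")
    disease_rules = []
    for i, row in enumerate(dr_df.itertuples(), start=1):
        disease_rules.append(
            DiseaseRule(
                drug_id=row.drug_id,
                disease_id=row.disease_id,
                category=_parse_category(
                    row.category, i, "disease_rules.csv", INTERACTION_CATEGORIES
                ),
                comment=row.comment,
                sources=_parse_sources(row.sources),
            )
        )

    return KnowledgeBase.build(drugs, diseases, age_rules, pair_rules, disease_rules)


def write_kb(kb: KnowledgeBase, dir_path: str | Path) -> None:
    """Write a knowledge base to its five CSV files (inverse of :func:`load_kb`).

    Rows are emitted in sorted key order so identical knowledge bases produce
    byte-identical files; categories are emitted uppercase.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"drug_id": d.drug_id, "name": d.name, "atc_code": d.atc_code or ""}
            for d in sorted(kb.drugs.values(), key=lambda d: d.drug_id)
        ],
        columns=_COLUMNS["drugs"],
    ).to_csv(dir_path / _FILES["drugs"], index=False)

    pd.DataFrame(
        [
            {"disease_id": d.disease_id, "name": d.name}
            for d in sorted(kb.diseases.values(), key=lambda d: d.disease_id)
        ],
        columns=_COLUMNS["diseases"],
    ).to_csv(dir_path / _FILES["diseases"], index=False)

    age_rows = []
    for key in sorted(kb.age_rules, key=lambda k: (k[0].value, k[1])):
        for r in sorted(kb.age_rules[key], key=repr):
            age_rows.append(
                {
                    "criterion": r.criterion.value,
                    "drug_id": r.drug_id,
                    "category": r.category.value,
                    "min_age_years": r.min_age_years,
                    "max_dose_mg_per_day": "" if r.max_dose_mg_per_day is None else r.max_dose_mg_per_day,
                    "max_duration_days": "" if r.max_duration_days is None else r.max_duration_days,
                    "comment": r.comment,
                    "sources": ";".join(r.sources),
                }
            )
    pd.DataFrame(age_rows, columns=_COLUMNS["age_rules"]).to_csv(
        dir_path / _FILES["age_rules"], index=False
    )

    pair_rows = [
        {
            "drug_a": r.drug_lo,
            "drug_b": r.drug_hi,
            "category": r.category.value,
            "comment": r.comment,
            "sources": ";".join(r.sources),
        }
        for key, r in sorted(kb.pair_rules.items())
    ]
    pd.DataFrame(pair_rows, columns=_COLUMNS["pair_rules"]).to_csv(
        dir_path / _FILES["pair_rules"], index=False
    )

    dr_rows = [
        {
            "drug_id": r.drug_id,
            "disease_id": r.disease_id,
            "category": r.category.value,
            "comment": r.comment,
            "sources": ";".join(r.sources),
        }
        for key, r in sorted(kb.disease_rules.items())
    ]
    pd.DataFrame(dr_rows, columns=_COLUMNS["disease_rules"]).to_csv(
        dir_path / _FILES["disease_rules"], index=False
    )
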