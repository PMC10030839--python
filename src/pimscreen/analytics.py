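"""Cohort-level analytics: PIM burden, criteria comparison, Venn coverage,
and the supporting statistical tests.

The comparison of the six PIM criteria against the reference (union) method
mirrors the structure of a criteria-comparison study: per-source PIM-burden
summaries (mean PIM count ± SD over everyone, rate of patients with ≥1 PIM,
mean ± SD among PIM-positive patients, most frequent PIM agents), a dependent
two-sample t-test of each criterion's per-patient PIM counts against the
reference method, and an exclusive-region Venn partition of the per-criterion
PIM agent sets.

The statistical primitives (paired t, Pearson/Spearman correlation,
chi-square independence, skewness/kurtosis moments) are implemented directly
from the standard formulas; p-values come from the corresponding reference
distributions.  Sample standard deviations use the n−1 denominator and all
p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .engine import ScreeningReport
from .kb import REFERENCE, Criterion
from .patient import Cohort

__all__ = [
    "BurdenSummary",
    "CohortStats",
    "pim_burden",
    "venn_partition",
    "venn_label",
    "paired_t",
    "correlation",
    "chi_square_independence",
    "moments",
    "criteria_comparison",
    "cohort_correlations",
    "stats_to_table",
]


# ---------------------------------------------------------------------------
# Statistical primitives
# ---------------------------------------------------------------------------


def paired_t(x: Sequence[float], y: Sequence[float]) -> dict:
    """Dependent-samples t-test on paired observations.

    t = mean(d) / (sd(d)/sqrt(n)) with d = x − y elementwise, df = n − 1,
    two-sided p from Student's t.  Degenerate (constant-difference) pairs are
    an error rather than an infinite statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired_t requires two equal-length 1-D samples")
    n = x.size
    if n < 2:
        raise ValueError("paired_t requires n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate differences: sd(x - y) is zero")
    t = d.mean() / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * _sps.t.sf(abs(t), df)
    return {"t": float(t), "df": df, "p": float(p)}


def _pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(xc @ yc) / denom


def _r_to_p(r: float, n: int) -> float:
    # two-sided p via t = r*sqrt((n-2)/(1-r^2))
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * _sps.t.sf(abs(t), n - 2))


def correlation(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "pearson",
    exact: bool = False,
) -> dict:
    """Pearson product-moment or Spearman rank correlation with two-sided p.

    Spearman is Pearson on mid-ranks (ties receive average ranks); its p uses
    the t-approximation, or an exact permutation enumeration when
    ``exact=True`` and n ≤ 8.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("correlation requires two equal-length 1-D samples")
    n = x.size
    if n < 3:
        raise ValueError("correlation requires n >= 3")
    if method == "pearson":
        r = _pearson_r(x, y)
        return {"r": r, "p": _r_to_p(r, n)}
    if method != "spearman":
        raise ValueError(f"unknown correlation method {method!r}")
    rx = _sps.rankdata(x)
    ry = _sps.rankdata(y)
    r = _pearson_r(rx, ry)
    if exact:
        if n > 8:
            raise ValueError("exact permutation p is supported for n <= 8 only")
        hits = 0
        total = 0
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson_r(rx, np.asarray(perm))) >= abs(r) - 1e-12:
                hits += 1
        return {"r": r, "p": hits / total}
    return {"r": r, "p": _r_to_p(r, n)}


def chi_square_independence(table: Sequence[Sequence[float]]) -> dict:
    """Pearson chi-square test of independence on an r × c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("chi-square requires a 2-D table with >= 2 rows and columns")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError("every row and column margin must be positive")
    expected = np.outer(row, col) / obs.sum()
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(_sps.chi2.sf(chi2, df))
    return {"chi2": chi2, "df": df, "p": p}


def moments(x: Sequence[float]) -> dict:
    """Skewness and excess kurtosis (bias-uncorrected population form).

    skewness = m3 / m2^(3/2), excess kurtosis = m4 / m2² − 3, with mj the
    j-th central sample moment (1/n denominators).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValueError("moments require a 1-D sample with n >= 4")
    c = x - x.mean()
    m2 = float((c**2).mean())
    if m2 == 0:
        raise ValueError("moments undefined for a constant sample")
    skew = float((c**3).mean()) / m2**1.5
    kurt = float((c**4).mean()) / m2**2 - 3.0
    return {"skewness": skew, "excess_kurtosis": kurt}


# ---------------------------------------------------------------------------
# Venn partition
# ---------------------------------------------------------------------------


def venn_label(labels: Iterable[str]) -> str:
    """Canonical region label: '&'-joined sorted set labels."""
    return "&".join(sorted(labels))


def venn_partition(labeled_sets: Mapping[str, set]) -> dict[str, int]:
    """Exact exclusive-region counts over all nonempty label subsets.

    For n labelled sets, returns a map from every one of the 2ⁿ − 1 region
    labels (elements in exactly those sets and no others) to its count.
    Counts sum to the size of the union.
    """
    labels = list(labeled_sets)
    if not 2 <= len(labels) <= 7:
        raise ValueError("venn_partition requires between 2 and 7 sets")
    regions = {
        venn_label(combo): 0
        for r in range(1, len(labels) + 1)
        for combo in itertools.combinations(labels, r)
    }
    union = set().union(*labeled_sets.values())
    for element in union:
        signature = [lab for lab in labels if element in labeled_sets[lab]]
        regions[venn_label(signature)] += 1
    return regions


# ---------------------------------------------------------------------------
# PIM burden and criteria comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BurdenSummary:
    """Per-source PIM burden over a cohort of screening reports."""

    source: str
    n: int
    mean_pim_all: float
    sd_pim_all: float | None
    rate_at_least_one_pim: float
    mean_pim_among_positive: float | None
    sd_pim_among_positive: float | None
    top_agents: tuple[tuple[str, int], ...] = ()


def _counts_for_source(reports: Sequence[ScreeningReport], source) -> np.ndarray:
    return np.array([len(r.pim_drugs(source)) for r in reports], dtype=float)


def _mean_sd(v: np.ndarray) -> tuple[float, float | None]:
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else None
    return mean, sd


def pim_burden(
    reports: Sequence[ScreeningReport],
    source: Criterion | str = REFERENCE,
    top_k: int = 3,
) -> BurdenSummary:
    """Mean PIM count, ≥1-PIM rate, and positives-only burden for one source.

    Sample SDs use n − 1 (absent for n = 1); the positives-only mean is absent
    when no patient has a PIM under this source.  The ``top_k`` most frequent
    PIM agents are reported with patient counts, ties broken lexicographically.
    """
    if not reports:
        raise ValueError("pim_burden requires at least one report")
    counts = _counts_for_source(reports, source)
    mean_all, sd_all = _mean_sd(counts)
    positive = counts[counts >= 1]
    if positive.size:
        mean_pos, sd_pos = _mean_sd(positive)
    else:
        mean_pos, sd_pos = None, None
    freq: dict[str, int] = {}
    for r in reports:
        for drug in r.pim_drugs(source):
            freq[drug] = freq.get(drug, 0) + 1
    top = tuple(sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))[:top_k])
    name = source.value if isinstance(source, Criterion) else str(source)
    return BurdenSummary(
        source=name,
        n=len(reports),
        mean_pim_all=mean_all,
        sd_pim_all=sd_all,
        rate_at_least_one_pim=float((counts >= 1).mean()),
        mean_pim_among_positive=mean_pos,
        sd_pim_among_positive=sd_pos,
        top_agents=top,
    )


@dataclass
class CohortStats:
    """Assembled criteria-comparison statistics for one screened cohort."""

    n_patients: int
    burdens: dict[str, BurdenSummary]
    paired_t_vs_reference: dict[str, dict]
    venn: dict[str, int]
    coverage_vs_reference: dict[str, float]
    correlations: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "n_patients": self.n_patients,
            "burdens": {
                k: {
                    "n": b.n,
                    "mean_pim_all": b.mean_pim_all,
                    "sd_pim_all": b.sd_pim_all,
                    "rate_at_least_one_pim": b.rate_at_least_one_pim,
                    "mean_pim_among_positive": b.mean_pim_among_positive,
                    "sd_pim_among_positive": b.sd_pim_among_positive,
                    "top_agents": [list(t) for t in b.top_agents],
                }
                for k, b in self.burdens.items()
            },
            "paired_t_vs_reference": self.paired_t_vs_reference,
            "venn": self.venn,
            "coverage_vs_reference": self.coverage_vs_reference,
            "correlations": self.correlations,
        }


def cohort_correlations(
    reports: Sequence[ScreeningReport], cohort: Cohort
) -> dict[str, dict]:
    """Pairwise Pearson and Spearman correlations of per-patient quantities.

    Variables: age, number of medications, number of chronic diseases,
    reference PIM count, drug–drug and drug–disease warning counts.  Constant
    variables are skipped (their correlations are undefined).
    """
    by_id = {p.patient_id: p for p in cohort}
    variables = {
        "age_years": [],
        "n_medications": [],
        "n_diseases": [],
        "n_pim_reference": [],
        "n_ddi_warnings": [],
        "n_ddisease_warnings": [],
    }
    for r in reports:
        p = by_id[r.patient_id]
        c = r.counts
        variables["age_years"].append(p.age_years)
        variables["n_medications"].append(p.n_medications)
        variables["n_diseases"].append(p.n_diseases)
        variables["n_pim_reference"].append(c["n_pim_reference"])
        variables["n_ddi_warnings"].append(c["n_ddi_risky"] + c["n_ddi_contraindicated"])
        variables["n_ddisease_warnings"].append(
            c["n_ddisease_risky"] + c["n_ddisease_contraindicated"]
        )
    out: dict[str, dict] = {}
    names = list(variables)
    for a, b in itertools.combinations(names, 2):
        va = np.asarray(variables[a], dtype=float)
        vb = np.asarray(variables[b], dtype=float)
        if va.std() == 0 or vb.std() == 0 or va.size < 3:
            continue
        out[f"{a}~{b}"] = {
            "pearson": correlation(va, vb, "pearson"),
            "spearman": correlation(va, vb, "spearman"),
        }
    return out


def criteria_comparison(
    reports: Sequence[ScreeningReport],
    cohort: Cohort | None = None,
    top_k: int = 3,
) -> CohortStats:
    """Compare each criterion's PIM detection against the reference method.

    Produces per-source burden summaries, a paired t-test of each criterion's
    per-patient PIM counts against the reference counts (flagged degenerate
    when the counts coincide everywhere), observed coverage of the reference
    PIM agent set, and the Venn partition of per-criterion PIM agent sets.
    With ``cohort`` given, per-patient correlation structure is included.
    """
    if not reports:
        raise ValueError("criteria_comparison requires at least one report")
    criteria = reports[0].criteria
    sources: list = [REFERENCE, *criteria]

    burdens = {
        (s.value if isinstance(s, Criterion) else s): pim_burden(reports, s, top_k)
        for s in sources
    }

    ref_counts = _counts_for_source(reports, REFERENCE)
    paired: dict[str, dict] = {}
    for c in criteria:
        counts = _counts_for_source(reports, c)
        try:
            paired[c.value] = paired_t(ref_counts, counts)
        except ValueError:
            paired[c.value] = {"t": None, "df": len(reports) - 1, "p": None,
                               "degenerate": True}

    # observed PIM agent sets over the whole cohort
    agents_by_criterion = {
        c.value: set().union(*(r.pim_drugs(c) for r in reports)) for c in criteria
    }
    reference_agents = set().union(*(r.pim_drugs(REFERENCE) for r in reports))
    coverage = {}
    if reference_agents:
        for c in criteria:
            coverage[c.value] = len(
                agents_by_criterion[c.value] & reference_agents
            ) / len(reference_agents)
    venn = (
        venn_partition(agents_by_criterion)
        if len(agents_by_criterion) >= 2
        else {}
    )

    correlations = (
        cohort_correlations(reports, cohort) if cohort is not None else {}
    )
    return CohortStats(
        n_patients=len(reports),
        burdens=burdens,
        paired_t_vs_reference=paired,
        venn=venn,
        coverage_vs_reference=coverage,
        correlations=correlations,
    )


def stats_to_table(stats: CohortStats) -> pd.DataFrame:
    """Wide per-source table: one column per source, burden metrics as rows."""
    cols = {}
    for name, b in stats.burdens.items():
        cols[name] = {
            "mean_pim_all": b.mean_pim_all,
            "sd_pim_all": b.sd_pim_all,
            "rate_at_least_one_pim_pct": 100.0 * b.rate_at_least_one_pim,
            "mean_pim_among_positive": b.mean_pim_among_positive,
            "sd_pim_among_positive": b.sd_pim_among_positive,
            "coverage_of_reference_pct": (
                100.0 * stats.coverage_vs_reference.get(name)
                if name in stats.coverage_vs_reference
                else (100.0 if name == REFERENCE else None)
            ),
            "paired_t_vs_reference": (
                stats.paired_t_vs_reference.get(name, {}).get("t")
            ),
            "p_vs_reference": stats.paired_t_vs_reference.get(name, {}).get("p"),
        }
    return pd.DataFrame(cols)
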