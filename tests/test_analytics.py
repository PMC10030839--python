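import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from pimscreen.analytics import (
    chi_square_independence,
    cohort_correlations,
    correlation,
    criteria_comparison,
    moments,
    paired_t,
    pim_burden,
    stats_to_table,
    venn_partition,
)
from pimscreen.engine import screen_cohort
from pimscreen.kb import ALL_CRITERIA, REFERENCE
from pimscreen.synthetic import CohortConfig, KBConfig, gen_cohort, gen_kb


class TestPairedT:
    def test_hand_computed_example(self):
        # d = [1, 2, 3]: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = paired_t([2, 4, 6], [1, 2, 3])
        assert res["t"] == pytest.approx(3.4641, abs=1e-4)
        assert res["df"] == 2

    def test_degenerate_differences_raise(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            paired_t([1.0], [2.0])

    def test_antisymmetry(self):
        a, b = [2.0, 5.0, 1.0, 7.0], [1.0, 9.0, 2.0, 3.0]
        assert paired_t(a, b)["t"] == pytest.approx(-paired_t(b, a)["t"])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=12)
            y = x + rng.normal(size=12)
            ours = paired_t(x, y)
            ref = sps.ttest_rel(x, y)
            assert ours["t"] == pytest.approx(ref.statistic, abs=1e-9)
            assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-9)


class TestCorrelation:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlation(x, 2 * x + 1)["r"] == pytest.approx(1.0)

    def test_reversed_order_gives_spearman_minus_one(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert correlation(x, -x, method="spearman")["r"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # covariance 3 over variance 5 in both margins -> r = 3/5
        assert correlation([1, 2, 3, 4], [2, 1, 4, 3])["r"] == pytest.approx(0.6)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            correlation([1, 1, 1, 1], [1, 2, 3, 4])

    def test_agrees_with_scipy_including_ties(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.integers(0, 6, size=15).astype(float)  # ties likely
            y = x + rng.integers(0, 4, size=15)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            ours = correlation(x, y, "spearman")
            ref = sps.spearmanr(x, y)
            assert ours["r"] == pytest.approx(ref.statistic, abs=1e-9)
            ours_p = correlation(x, y, "pearson")
            ref_p = sps.pearsonr(x, y)
            assert ours_p["r"] == pytest.approx(ref_p.statistic, abs=1e-9)
            assert ours_p["p"] == pytest.approx(ref_p.pvalue, abs=1e-9)

    def test_exact_permutation_p_for_tiny_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        res = correlation(x, y, "spearman", exact=True)
        # independent oracle: enumerate every permutation of y and count
        # scipy-computed rank correlations at least as extreme
        observed = abs(sps.spearmanr(x, y).statistic)
        perms = [
            abs(sps.spearmanr(x, perm).statistic)
            for perm in itertools.permutations(y)
        ]
        expected = sum(p >= observed - 1e-12 for p in perms) / len(perms)
        assert res["p"] == pytest.approx(expected, abs=1e-12)
        with pytest.raises(ValueError):
            correlation(list(range(9)), list(range(9)), "spearman", exact=True)


class TestChiSquare:
    def test_independent_table_has_zero_statistic(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res["chi2"] == pytest.approx(0.0)
        assert res["df"] == 1

    def test_hand_computed_example(self):
        # margins 30/30; expected 15 in every cell -> chi2 = 4*25/15 = 6.667
        res = chi_square_independence([[20, 10], [10, 20]])
        assert res["chi2"] == pytest.approx(20 / 3, abs=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence([[0, 0], [10, 20]])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4))
            ours = chi_square_independence(table)
            ref = sps.chi2_contingency(table, correction=False)
            assert ours["chi2"] == pytest.approx(ref.statistic, abs=1e-9)
            assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-9)


class TestMoments:
    def test_symmetric_sample_has_zero_skewness(self):
        res = moments([-2.0, -1.0, 0.0, 1.0, 2.0])
        assert res["skewness"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_rejected(self):
        with pytest.raises(ValueError):
            moments([3.0, 3.0, 3.0, 3.0])

    def test_matches_direct_moment_formula_and_scipy(self):
        rng = np.random.default_rng(9)
        x = rng.gamma(2.0, size=50)
        res = moments(x)
        c = x - x.mean()
        assert res["skewness"] == pytest.approx(
            (c**3).mean() / (c**2).mean() ** 1.5, abs=1e-12
        )
        assert res["skewness"] == pytest.approx(sps.skew(x, bias=True), abs=1e-9)
        assert res["excess_kurtosis"] == pytest.approx(
            sps.kurtosis(x, fisher=True, bias=True), abs=1e-9
        )


class TestVennPartition:
    def test_two_set_example(self):
        regions = venn_partition({"A": {"x", "y"}, "B": {"y"}})
        assert regions == {"A": 1, "B": 0, "A&B": 1}

    def test_identical_sets_occupy_one_region(self):
        sets = {f"S{i}": set(range(10)) for i in range(6)}
        regions = venn_partition(sets)
        full = "&".join(sorted(sets))
        assert regions[full] == 10
        assert sum(regions.values()) == 10

    def test_matches_membership_signature_tally(self):
        rng = np.random.default_rng(21)
        labels = ["a", "b", "c", "d"]
        sets = {lab: set(rng.choice(40, size=rng.integers(0, 25))) for lab in labels}
        regions = venn_partition(sets)
        union = set().union(*sets.values())
        assert sum(regions.values()) == len(union)
        for element in union:
            sig = "&".join(sorted(l for l in labels if element in sets[l]))
            assert regions[sig] >= 1

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            venn_partition({"A": {1}})


class TestPimBurden:
    def _reports(self, counts):
        # minimal stand-in reports exposing pim_drugs()
        class _R:
            def __init__(self, i, k):
                self.patient_id = f"p{i}"
                self._k = k

            def pim_drugs(self, source=REFERENCE):
                return {f"d{j}" for j in range(self._k)}

        return [_R(i, k) for i, k in enumerate(counts)]

    def test_arithmetic_on_small_example(self):
        b = pim_burden(self._reports([2, 0, 1]))
        assert b.mean_pim_all == pytest.approx(1.0)
        assert b.rate_at_least_one_pim == pytest.approx(2 / 3)
        assert b.mean_pim_among_positive == pytest.approx(1.5)

    def test_all_zero_counts(self):
        b = pim_burden(self._reports([0, 0, 0]))
        assert b.rate_at_least_one_pim == 0.0
        assert b.mean_pim_among_positive is None

    def test_single_patient_has_no_sd(self):
        b = pim_burden(self._reports([3]))
        assert b.mean_pim_all == 3.0
        assert b.sd_pim_all is None
        assert b.rate_at_least_one_pim == 1.0

    def test_empty_report_list_rejected(self):
        with pytest.raises(ValueError):
            pim_burden([])


@pytest.fixture(scope="module")
def screened():
    kb, truth = gen_kb(KBConfig(n_drugs=60, n_diseases=10, seed=31))
    cohort = gen_cohort(
        CohortConfig(
            n=120, seed=32,
            drug_ids=tuple(kb.drugs), disease_ids=tuple(kb.diseases),
            mean_diseases=3.0, mean_drugs=5.0,
        )
    )
    return kb, truth, cohort, screen_cohort(cohort, kb)


class TestCriteriaComparison:

    def test_coverage_matches_ground_truth_sets(self, screened):
        kb, truth, cohort, reports = screened
        stats = criteria_comparison(reports, cohort)
        observed_ref = set().union(*(r.pim_drugs(REFERENCE) for r in reports))
        for c in ALL_CRITERIA:
            observed_c = set().union(*(r.pim_drugs(c) for r in reports))
            expected = len(observed_c & observed_ref) / len(observed_ref)
            assert stats.coverage_vs_reference[c.value] == pytest.approx(expected)
            # every observed per-criterion PIM is in the ground-truth risky set
            assert observed_c <= truth.risky_by_criterion[c.value]

    def test_per_criterion_rate_never_exceeds_reference(self, screened):
        _, _, cohort, reports = screened
        stats = criteria_comparison(reports)
        ref_rate = stats.burdens["REFERENCE"].rate_at_least_one_pim
        for c in ALL_CRITERIA:
            burden = stats.burdens[c.value]
            assert burden.rate_at_least_one_pim <= ref_rate
            assert burden.mean_pim_all <= stats.burdens["REFERENCE"].mean_pim_all

    def test_venn_counts_sum_to_union(self, screened):
        _, _, cohort, reports = screened
        stats = criteria_comparison(reports)
        union = set().union(*(r.pim_drugs(REFERENCE) for r in reports))
        assert sum(stats.venn.values()) == len(union)

    def test_degenerate_self_comparison_is_flagged(self, screened):
        _, _, _, reports = screened
        stats = criteria_comparison(reports)
        # a criterion whose counts coincide with the reference everywhere
        # cannot produce a t statistic and must be marked degenerate
        for name, res in stats.paired_t_vs_reference.items():
            if res.get("degenerate"):
                assert res["t"] is None
            else:
                assert res["p"] <= 1.0

    def test_table_export_has_one_column_per_source(self, screened):
        _, _, cohort, reports = screened
        table = stats_to_table(criteria_comparison(reports, cohort))
        assert list(table.columns) == ["REFERENCE"] + [c.value for c in ALL_CRITERIA]
        assert table.loc["coverage_of_reference_pct", "REFERENCE"] == 100.0

    def test_correlations_present_with_cohort(self, screened):
        _, _, cohort, reports = screened
        stats = criteria_comparison(reports, cohort)
        key = "n_medications~n_ddi_warnings"
        assert key in stats.correlations
        assert -1.0 <= stats.correlations[key]["pearson"]["r"] <= 1.0
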