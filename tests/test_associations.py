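"""Association-suite tests: standardized regressions, BH step-up, rank tests,
allostatic composite and hierarchical variance partitioning, each against
hand-worked or enumerative oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from brainpad import (
    allostatic_load,
    fdr_adjust,
    fitness_association_table,
    hierarchical_partition,
    null_association_battery,
    rank_sum_test,
    spearman,
    standardized_regression,
)
from brainpad.config import ALLOSTATIC_COMPONENTS


class TestStandardizedRegression:
    def test_self_regression_gives_unit_beta(self, rng):
        d = pd.DataFrame({"x": rng.normal(size=50)})
        d["y"] = d["x"]
        res = standardized_regression(d, "y", exposure="x", covariates=())
        assert res.standardized_beta == pytest.approx(1.0)
        assert res.p < 1e-20

    def test_matches_normal_equations_oracle(self, rng):
        d = pd.DataFrame({
            "y": rng.normal(size=6), "x": rng.normal(size=6),
            "male": [0, 1, 0, 1, 1, 0],
        })
        res = standardized_regression(d, "y", exposure="x", covariates=("male",))
        zy = (d.y - d.y.mean()) / d.y.std(ddof=0)
        zx = (d.x - d.x.mean()) / d.x.std(ddof=0)
        design = np.column_stack([np.ones(6), zx, d.male])
        beta = np.linalg.solve(design.T @ design, design.T @ zy)
        assert res.standardized_beta == pytest.approx(beta[1], abs=1e-10)

    def test_zero_variance_outcome_rejected(self):
        d = pd.DataFrame({"y": np.ones(20), "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="zero-variance"):
            standardized_regression(d, "y", exposure="x", covariates=())

    def test_fitness_table_uses_one_fdr_family_of_five(self, small_test_cohort):
        table = fitness_association_table(small_test_cohort.phenotypes)
        assert len(table) == 5
        assert table.p_fdr.min() >= table.p.min()


class TestFDR:
    def test_hand_worked_step_up_example(self):
        # p = (.01, .02, .03, .04, .9), q=.05: max k with p(k) <= k q / 5 is 4
        flags, _ = fdr_adjust([0.01, 0.02, 0.03, 0.04, 0.9], q=0.05)
        assert flags.tolist() == [True, True, True, True, False]

    def test_all_tiny_all_significant_and_all_one_none(self):
        flags, _ = fdr_adjust([1e-5] * 4)
        assert flags.all()
        flags, _ = fdr_adjust([1.0] * 4)
        assert not flags.any()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=10), st.floats(0.01, 0.2))
    def test_flags_match_step_up_definition(self, pvals, q):
        flags, _ = fdr_adjust(pvals, q=q)
        m = len(pvals)
        order = np.argsort(pvals)
        sorted_p = np.asarray(pvals)[order]
        k_max = 0
        for k in range(1, m + 1):
            if sorted_p[k - 1] <= k * q / m:
                k_max = k
        expected = np.zeros(m, bool)
        expected[order[:k_max]] = True
        assert flags.tolist() == expected.tolist()


def enumerate_ranksum_p(a, b):
    """Full enumeration oracle for the two-sided exact rank-sum p-value."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = len(a)
    w_obs = ranks[:n1].sum()
    sums = [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.asarray(sums)
    lo = np.mean(sums <= w_obs + 1e-9)
    hi = np.mean(sums >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestRankSum:
    def test_textbook_example(self):
        res = rank_sum_test([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == 3.0
        # one-sided enumeration gives 1/6; two-sided doubles it
        assert res.p == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_identical_groups_give_p_one(self):
        res = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0

    def test_extreme_separation_attains_minimal_p(self):
        a = np.arange(5.0) + 1000.0
        b = np.arange(5.0)
        res = rank_sum_test(a, b)
        assert res.p == pytest.approx(2 / math.comb(10, 5))

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.integers(1, 6), st.integers(1, 6), st.integers(0, 10_000))
    def test_exact_p_matches_full_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        # half-integer grid induces frequent ties
        a = np.round(rng.uniform(0, 4, n1) * 2) / 2
        b = np.round(rng.uniform(0, 4, n2) * 2) / 2
        res = rank_sum_test(a, b)
        assert res.p == pytest.approx(enumerate_ranksum_p(a, b), abs=1e-9)

    def test_matches_scipy_exact_without_ties(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(size=9) + 0.5
        res = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        a = rng.normal(size=300)
        b = rng.normal(size=280) + 0.3
        res = rank_sum_test(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.p == pytest.approx(ref.pvalue, rel=0.02)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSpearman:
    def test_monotone_transform_gives_unit_rho(self, rng):
        x = rng.normal(size=30)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_hand_ranked_five_point_example(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 2.0, 4.0, 3.0, 5.0]  # one adjacent swap
        rho, _ = spearman(x, y)
        # Pearson correlation of the hand-assigned ranks
        assert rho == pytest.approx(np.corrcoef([1, 2, 3, 4, 5], [1, 2, 4, 3, 5])[0, 1])

    def test_constant_input_flagged_as_nan(self):
        rho, p = spearman(np.ones(10), np.arange(10.0))
        assert math.isnan(rho) and math.isnan(p)


class TestAllostaticLoad:
    def _cohort_components(self, rng, n=200):
        return pd.DataFrame({
            name: rng.normal(mean, sd, n)
            for name, (mean, sd, _) in ALLOSTATIC_COMPONENTS.items()
        })

    def test_composite_is_standardized(self, rng):
        comp = allostatic_load(self._cohort_components(rng))
        assert comp.composite.mean() == pytest.approx(0.0, abs=1e-12)
        assert comp.composite.std() == pytest.approx(1.0, abs=1e-12)

    def test_single_crp_shift_moves_composite_linearly(self, rng):
        table = self._cohort_components(rng)
        base_signed = np.column_stack([
            ALLOSTATIC_COMPONENTS[c][2]
            * (table[c] - table[c].mean()) / table[c].std(ddof=0)
            for c in ALLOSTATIC_COMPONENTS
        ]).mean(axis=1)
        bumped = table.copy()
        bumped.loc[0, "crp"] += 2 * table["crp"].std(ddof=0)
        new_signed = np.column_stack([
            ALLOSTATIC_COMPONENTS[c][2]
            * (bumped[c] - bumped[c].mean()) / bumped[c].std(ddof=0)
            for c in ALLOSTATIC_COMPONENTS
        ]).mean(axis=1)
        # before re-standardization the mean composite moves by ~2/11 sd
        # for the bumped subject relative to everyone else
        shift = (new_signed[0] - base_signed[0]) - (new_signed[1:] - base_signed[1:]).mean()
        assert shift == pytest.approx(2 / 11, rel=0.05)

    def test_hdl_direction_is_protective(self, rng):
        table = self._cohort_components(rng)
        res = allostatic_load(table)
        hdl_z = (table.hdl - table.hdl.mean()) / table.hdl.std(ddof=0)
        # composite must fall as HDL rises, all else equal
        assert np.corrcoef(hdl_z, res.composite)[0, 1] < 0
        flipped = allostatic_load(table, directions={**res.directions, "hdl": +1})
        assert np.corrcoef(hdl_z, flipped.composite)[0, 1] > np.corrcoef(
            hdl_z, res.composite)[0, 1]

    def test_missing_component_listed(self, rng):
        table = self._cohort_components(rng).drop(columns=["il6"])
        with pytest.raises(KeyError, match="il6"):
            allostatic_load(table)


class TestHierarchicalPartition:
    def test_orthogonal_predictors_get_their_marginal_r2(self):
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 2 * x1 + x2
        d = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        part = hierarchical_partition(d, "y", ["x1", "x2"])
        marg1 = hierarchical_partition(d, "y", ["x1"]).total_r2
        assert part.independent["x1"] == pytest.approx(marg1, abs=1e-10)

    def test_single_predictor_gets_full_r2(self, rng):
        d = pd.DataFrame({"y": rng.normal(size=30), "x": rng.normal(size=30)})
        part = hierarchical_partition(d, "y", ["x"])
        assert part.independent["x"] == pytest.approx(part.total_r2)

    def test_three_predictor_ordering_enumeration_oracle(self, rng):
        d = pd.DataFrame(rng.normal(size=(25, 4)), columns=["y", "a", "b", "c"])
        d["y"] = d.a + 0.5 * d.b + rng.normal(size=25)
        part = hierarchical_partition(d, "y", ["a", "b", "c"])

        def r2(cols):
            if not cols:
                return 0.0
            X = np.column_stack([np.ones(25)] + [d[c] for c in cols])
            resid = d.y - X @ np.linalg.lstsq(X, d.y, rcond=None)[0]
            return 1 - (resid @ resid) / ((d.y - d.y.mean()) ** 2).sum()

        for target in ["a", "b", "c"]:
            contribs = []
            for order in itertools.permutations(["a", "b", "c"]):
                pos = order.index(target)
                before = list(order[:pos])
                contribs.append(r2(before + [target]) - r2(before))
            assert part.independent[target] == pytest.approx(
                np.mean(contribs), abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 5), st.integers(0, 10_000))
    def test_independent_contributions_sum_to_total_r2(self, k, seed):
        rng = np.random.default_rng(seed)
        d = pd.DataFrame(rng.normal(size=(30, k + 1)),
                         columns=["y"] + [f"x{i}" for i in range(k)])
        part = hierarchical_partition(d, "y", [f"x{i}" for i in range(k)])
        assert sum(part.independent.values()) == pytest.approx(
            part.total_r2, abs=1e-6)

    def test_too_many_predictors_refused(self, rng):
        d = pd.DataFrame(rng.normal(size=(40, 10)),
                         columns=["y"] + [f"x{i}" for i in range(9)])
        with pytest.raises(ValueError, match="1-8"):
            hierarchical_partition(d, "y", [f"x{i}" for i in range(9)])


class TestNullBattery:
    def test_runs_on_generated_cohort_and_reports_each_factor(self, small_test_cohort):
        table = null_association_battery(small_test_cohort.phenotypes)
        assert set(table.factor) >= {"cvd", "diabetes", "stroke"}
        assert table.p.between(0, 1).all()

    def test_missing_columns_listed(self, small_test_cohort):
        with pytest.raises(KeyError, match="wmh_volume"):
            null_association_battery(small_test_cohort.phenotypes,
                                     factors=("cvd", "wmh_volume"))

    def test_unadjusted_battery_supported(self, small_test_cohort):
        table = null_association_battery(small_test_cohort.phenotypes,
                                         factors=("cvd",), covariates=())
        assert len(table) == 1

    def test_injected_association_detected_at_scale(self):
        # power check: tying morbidity to brain-PAD makes the battery flag it
        rng = np.random.default_rng(0)
        n = 4000
        pad = rng.normal(0, 8.7, n)
        cvd = (rng.random(n) < 1 / (1 + np.exp(-(pad - 2) / 4))).astype(int)
        d = pd.DataFrame({"brain_pad": pad, "cvd": cvd,
                          "male": rng.integers(0, 2, n)})
        table = null_association_battery(d, factors=("cvd",))
        assert table.loc[0, "p"] < 1e-6
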