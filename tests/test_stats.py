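import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from sulcalpits import (
    age_regression,
    ai_group_tests,
    asymmetry_index,
    asymmetry_table,
    bh_fdr,
    group_age_regression,
    per_cluster_tests,
    subtype_comparison,
    within_group_hemisphere_test,
)

from oracles import bh_stepup, paired_t


def make_records(n_case, n_control, rng, subtypes=False):
    groups = ["case"] * n_case + ["control"] * n_control
    ages = rng.uniform(7, 14, n_case + n_control)
    sub = ["none"] * (n_case + n_control)
    if subtypes:
        sub = [
            ("combined" if rng.uniform() < 0.5 else "inattentive")
            if g == "case" else "none"
            for g in groups
        ]
    return pd.DataFrame({"group": groups, "age": ages, "subtype": sub})


class TestGroupAgeRegression:
    def test_constant_outcome_degenerate(self):
        rng = np.random.default_rng(0)
        rec = make_records(5, 5, rng)
        res = group_age_regression(np.full(10, 4.0), rec)
        assert res.effect == 0.0 and res.p_value == 1.0 and res.degenerate

    def test_pure_age_effect_no_group_effect(self):
        rng = np.random.default_rng(1)
        rec = make_records(10, 10, rng)
        y = 3.0 * rec["age"].to_numpy()
        res = group_age_regression(y, rec)
        assert abs(res.effect) < 1e-8

    def test_known_effect_recovery(self):
        # injected -2.0 pit difference, sd-1 noise: within +/-0.5 in >=95%
        hits = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rec = make_records(60, 60, rng)
            y = rng.normal(10, 1, 120) - 2.0 * (rec["group"] == "case")
            res = group_age_regression(y, rec)
            hits += abs(res.effect - (-2.0)) <= 0.5
        assert hits >= 190

    def test_too_few_subjects_rejected(self):
        rng = np.random.default_rng(2)
        rec = make_records(2, 5, rng)
        with pytest.raises(ValueError):
            group_age_regression(np.zeros(7), rec)

    def test_unknown_group_label_rejected(self):
        rec = pd.DataFrame({"group": ["case", "weird"], "age": [8, 9]})
        with pytest.raises(ValueError):
            group_age_regression(np.zeros(2), rec)


class TestAgeRegression:
    def test_constant_count_zero_slope(self):
        rng = np.random.default_rng(3)
        rec = make_records(5, 5, rng)
        res = age_regression(np.full(10, 5.0), rec)
        assert res.effect == 0.0 and res.p_value == 1.0

    def test_two_point_exact_slope(self):
        rec = pd.DataFrame({"group": ["case", "control"], "age": [8.0, 12.0]})
        res = age_regression(np.array([4.0, 8.0]), rec)
        assert np.isclose(res.effect, 1.0)

    def test_slope_recovery(self):
        rng = np.random.default_rng(4)
        rec = make_records(50, 50, rng)
        y = 2.0 * rec["age"].to_numpy() + rng.normal(0, 0.1, 100)
        res = age_regression(y, rec)
        assert 1.9 <= res.effect <= 2.1


class TestBH:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2])
        q = bh_fdr(p)
        assert np.allclose(q, [0.05, 0.05, 0.05, 0.05, 0.2])
        assert np.all(q[:4] <= 0.05)

    def test_all_ones_nothing_significant(self):
        q = bh_fdr(np.ones(10))
        assert np.all(q == 1.0)

    def test_family_of_one_q_equals_p(self):
        assert np.isclose(bh_fdr(np.array([0.03]))[0], 0.03)

    def test_matches_stepup_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            m = rng.integers(1, 40)
            p = rng.uniform(size=m)
            assert np.allclose(bh_fdr(p), bh_stepup(p), atol=1e-12)

    def test_family_padding_matches_oracle_with_larger_m(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=10)
        fam = 25
        ours = bh_fdr(p, family_size=fam)
        oracle = bh_stepup(np.concatenate([p, np.ones(fam - 10)]), m=fam)[:10]
        assert np.allclose(ours, oracle, atol=1e-12)

    def test_nan_aware(self):
        p = np.array([0.01, np.nan, 0.04])
        q = bh_fdr(p, family_size=3)
        assert np.isnan(q[1]) and np.isfinite(q[0])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=30)
        assert np.all(bh_fdr(p) >= p - 1e-15)


class TestAsymmetryIndex:
    def test_endpoints(self):
        assert asymmetry_index(0.0, 3.0) == -1.0
        assert asymmetry_index(3.0, 0.0) == 1.0

    def test_symmetric_zero(self):
        assert asymmetry_index(2.0, 2.0) == 0.0

    def test_undefined_when_sum_nonpositive(self):
        assert np.isnan(asymmetry_index(0.0, 0.0))

    @settings(max_examples=200, derandomize=True)
    @given(
        hst.floats(0.0, 100.0, allow_nan=False),
        hst.floats(0.0, 100.0, allow_nan=False),
    )
    def test_bounds_and_antisymmetry(self, left, right):
        ai = asymmetry_index(left, right)
        if left + right > 0:
            assert -1.0 <= ai <= 1.0
            assert np.isclose(ai, -asymmetry_index(right, left))

    def test_table_missing_handling(self):
        L = pd.DataFrame({1: [2.0, np.nan], 2: [0.0, 1.0]})
        R = pd.DataFrame({1: [2.0, 1.0], 2: [0.0, 3.0]})
        ai = asymmetry_table(L, R)
        assert ai.loc[0, 1] == 0.0
        assert np.isnan(ai.loc[1, 1])  # missing L
        assert np.isnan(ai.loc[0, 2])  # L + R == 0
        assert np.isclose(ai.loc[1, 2], -0.5)


class TestPerClusterTests:
    def test_injected_effect_detected_and_null_controlled(self):
        rng = np.random.default_rng(8)
        rec = make_records(40, 40, rng)
        case = (rec["group"] == "case").to_numpy()
        table = pd.DataFrame(
            {c: rng.normal(5, 0.3, 80) for c in range(1, 11)}
        )
        table[3] = table[3] + 1.0 * case
        res = per_cluster_tests(table, rec)
        assert res.loc[3, "significant"]
        assert res.loc[3, "effect"] == pytest.approx(1.0, abs=0.3)

    def test_small_cluster_skipped_but_in_family(self):
        rng = np.random.default_rng(9)
        rec = make_records(10, 10, rng)
        table = pd.DataFrame({1: rng.normal(5, 1, 20), 2: rng.normal(5, 1, 20)})
        table.loc[3:, 2] = np.nan  # only 3 observations left
        with pytest.warns(UserWarning):
            res = per_cluster_tests(table, rec, family_size=2)
        assert np.isnan(res.loc[2, "p"])
        # q of cluster 1 reflects family of 2, not 1
        assert res.loc[1, "q"] >= res.loc[1, "p"]

    def test_mismatched_lengths_rejected(self):
        rng = np.random.default_rng(10)
        rec = make_records(5, 5, rng)
        with pytest.raises(ValueError):
            per_cluster_tests(pd.DataFrame({1: np.zeros(4)}), rec)


class TestAIGroupTests:
    def test_identical_hemispheres_no_effect(self):
        rng = np.random.default_rng(11)
        rec = make_records(20, 20, rng)
        L = pd.DataFrame({c: rng.normal(5, 0.5, 40) for c in range(1, 4)})
        res = ai_group_tests(L, L.copy(), rec)
        assert not res["significant"].any()

    def test_injected_lateralization_detected(self):
        # delta = 1.0 added to L in cases only, one cluster: >=90% power
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            rec = make_records(60, 60, rng)
            case = (rec["group"] == "case").to_numpy()
            L = pd.DataFrame({c: rng.normal(5, 0.2, 120) for c in (1, 2, 3)})
            R = pd.DataFrame({c: rng.normal(5, 0.2, 120) for c in (1, 2, 3)})
            L[2] = L[2] + 1.0 * case
            res = ai_group_tests(L, R, rec)
            if res.loc[2, "significant"] and res.loc[2, "effect"] > 0:
                detected += 1
        assert detected >= 90


class TestWithinGroupHemisphereTest:
    def _tables(self, rng, n=50, shift=0.0, noise=0.5):
        rec = make_records(n, n, rng)
        L = pd.DataFrame({1: rng.normal(5, 1, 2 * n)})
        R = L + rng.normal(0, noise, (2 * n, 1)) + shift
        return L, R, rec

    def test_identical_hemispheres_null(self):
        rng = np.random.default_rng(12)
        rec = make_records(10, 10, rng)
        L = pd.DataFrame({1: rng.normal(5, 1, 20)})
        res = within_group_hemisphere_test(L, L.copy(), rec, "control")
        assert res.loc[1, "F"] == 0.0 and res.loc[1, "p"] == 1.0

    def test_constant_difference_degenerate(self):
        rec = pd.DataFrame(
            {"group": ["control"] * 3, "age": [8.0, 9.0, 10.0]}
        )
        L = pd.DataFrame({1: [2.0, 3.0, 4.0]})
        R = pd.DataFrame({1: [1.0, 2.0, 3.0]})
        res = within_group_hemisphere_test(L, R, rec, "control")
        assert res.loc[1, "degenerate"]
        assert res.loc[1, "p"] == 0.0

    def test_f_equals_paired_t_squared(self):
        rng = np.random.default_rng(13)
        L, R, rec = self._tables(rng, shift=0.3)
        res = within_group_hemisphere_test(L, R, rec, "case")
        keep = (rec["group"] == "case").to_numpy()
        t, p = paired_t(L.loc[keep, 1], R.loc[keep, 1])
        assert np.isclose(res.loc[1, "F"], t**2, rtol=1e-10)
        assert np.isclose(res.loc[1, "p"], p, rtol=1e-8)

    def test_shift_detection_rate(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            L, R, rec = self._tables(rng, shift=0.3)
            res = within_group_hemisphere_test(L, R, rec, "control")
            detected += bool(res.loc[1, "significant"])
        assert detected >= 90

    def test_few_pairs_skipped(self):
        rng = np.random.default_rng(14)
        rec = make_records(3, 3, rng)
        L = pd.DataFrame({1: [1.0, np.nan, np.nan, 2.0, 3.0, np.nan]})
        R = pd.DataFrame({1: [1.0, 1.0, 1.0, 1.0, np.nan, 1.0]})
        res = within_group_hemisphere_test(L, R, rec, "case")
        assert np.isnan(res.loc[1, "p"])


class TestSubtypeComparison:
    def test_null_rejection_rate(self):
        rej = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            rec = make_records(40, 10, rng, subtypes=True)
            y = rng.normal(20, 2, 50)
            res = subtype_comparison(y, rec)
            rej += res.p_value < 0.05
        assert 0.01 <= rej / 200 <= 0.10

    def test_injected_subtype_effect_power(self):
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            groups = ["case"] * 80 + ["control"] * 5
            subt = ["combined"] * 40 + ["inattentive"] * 40 + ["none"] * 5
            rec = pd.DataFrame(
                {"group": groups, "subtype": subt,
                 "age": rng.uniform(7, 14, 85)}
            )
            y = rng.normal(20, 1, 85)
            y[:40] += 2.0
            detected += subtype_comparison(y, rec).p_value < 0.05
        assert detected >= 90

    def test_single_subtype_rejected(self):
        rng = np.random.default_rng(15)
        rec = make_records(10, 5, rng)
        rec.loc[rec["group"] == "case", "subtype"] = "combined"
        with pytest.raises(ValueError):
            subtype_comparison(np.zeros(15), rec)
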