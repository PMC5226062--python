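"""Statistical primitives against hand computations and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tractometry.stats import (
    ComparisonPlan,
    chi_square_2x2,
    cohens_d,
    fdr_adjust,
    roi_average,
    run_group_comparison,
    sectionwise_t,
    two_sample_t,
)
from tractometry.synthetic import GeneratorConfig, generate_profile_cohort


class TestRoiAverage:
    def test_ramp_profile(self):
        means = roi_average(np.arange(1.0, 101.0))
        np.testing.assert_allclose(means, [10.5, 30.5, 50.5, 70.5, 90.5])

    def test_constant_profile(self):
        np.testing.assert_allclose(roi_average(np.full(100, 0.82)), 0.82)

    def test_matches_block_means(self, rng):
        v = rng.normal(size=100)
        brute = [v[20 * k : 20 * (k + 1)].mean() for k in range(5)]
        np.testing.assert_allclose(roi_average(v), brute, atol=1e-12)

    @settings(max_examples=30, derandomize=True)
    @given(
        a=st.floats(-3, 3), b=st.floats(-1, 1),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=100), r.normal(size=100)
        np.testing.assert_allclose(
            roi_average(a * x + b * y),
            a * roi_average(x) + b * roi_average(y),
            atol=1e-9,
        )

    def test_incomplete_profile_rejected(self):
        v = np.arange(100.0)
        v[3] = np.nan
        with pytest.raises(ValueError):
            roi_average(v)


class TestTwoSampleT:
    def test_identical_samples_null(self):
        t, df, p = two_sample_t([1.0, 2, 3], [1.0, 2, 3])
        assert t == 0.0 and p == 1.0

    def test_hand_computed_example(self):
        # pooled SD = 1, SE = sqrt(2/3) => t = -3/0.8165
        t, df, p = two_sample_t([1.0, 2, 3], [4.0, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)
        assert df == 4

    def test_sign_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        t1, _, p1 = two_sample_t(a, b)
        t2, _, p2 = two_sample_t(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)
        assert cohens_d(a, b) == pytest.approx(-cohens_d(b, a))

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo: the test rejects ~5% of null datasets at alpha=0.05."""
        r = np.random.default_rng(1234)
        n_sim, n = 10_000, 15
        from scipy import stats as sps

        a = r.normal(size=(n_sim, n))
        b = r.normal(size=(n_sim, n))
        p = sps.ttest_ind(a, b, axis=1).pvalue
        rate = (p <= 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_zero_variance_unequal_means(self):
        t, _, p = two_sample_t([1.0, 1, 1], [2.0, 2, 2])
        assert t == -np.inf and p == 0.0


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2, 3], [3.0, 2, 1]) == 0.0

    def test_one_pooled_sd_difference(self, rng):
        a = rng.normal(0, 1, 2000)
        a = (a - a.mean()) / a.std(ddof=1)  # unit sample SD
        b = a + 1.0  # same variance, shift of exactly one pooled SD
        assert cohens_d(b, a) == pytest.approx(1.0, abs=1e-9)

    def test_hand_computed_example(self):
        assert cohens_d([1.0, 2, 3], [4.0, 5, 6]) == pytest.approx(-3.0)

    def test_zero_pooled_sd_missing(self):
        assert np.isnan(cohens_d([1.0, 1, 1], [1.0, 1, 1]))


def brute_force_bh(p, alpha):
    """Direct transcription of the BH step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = min(running, 1.0)
    return q, q <= alpha


class TestFDR:
    def test_stepup_traced_by_hand(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.05]
        q, sig = fdr_adjust(p, alpha=0.05)
        assert sig.all()  # largest p equals m/m * alpha exactly
        assert q[-1] == pytest.approx(0.05)

    def test_single_p(self):
        q, sig = fdr_adjust([0.04], alpha=0.05)
        assert q[0] == pytest.approx(0.04) and sig[0]

    def test_empty(self):
        q, sig = fdr_adjust([], alpha=0.05)
        assert len(q) == 0 and len(sig) == 0

    def test_against_brute_force_definition(self):
        r = np.random.default_rng(7)
        for _ in range(1000):
            m = int(r.integers(1, 40))
            p = r.uniform(size=m) ** r.uniform(0.5, 3)
            q, sig = fdr_adjust(p, alpha=0.05)
            q2, sig2 = brute_force_bh(p, alpha=0.05)
            np.testing.assert_allclose(q, q2, atol=1e-12)
            np.testing.assert_array_equal(sig, sig2)

    def test_q_monotone_in_sorted_order(self, rng):
        for _ in range(50):
            p = rng.uniform(size=30)
            q, _ = fdr_adjust(p, 0.05)
            assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
        # q >= p always
        p = rng.uniform(size=200)
        q, _ = fdr_adjust(p, 0.05)
        assert np.all(q >= p - 1e-12)


class TestSectionwise:
    def test_null_flag_rate(self):
        r = np.random.default_rng(3)
        count = tot = 0
        for _ in range(200):
            a = r.normal(size=(30, 100))
            b = r.normal(size=(30, 100))
            res = sectionwise_t(a, b, correction="none")
            count += (np.abs(res["t"]) > 1.98).sum()
            tot += 100
        assert count / tot == pytest.approx(0.05, abs=0.01)

    def test_shift_recovery_localised(self):
        r = np.random.default_rng(5)
        a = r.normal(size=(20, 100))
        a[:, :60] += 1.5
        b = r.normal(size=(20, 100))
        res = sectionwise_t(a, b)
        flagged = res.loc[res["significant"], "node"].to_numpy()
        assert len(flagged) > 0
        assert (flagged <= 60).mean() >= 0.90

    def test_single_node_dominance(self, rng):
        a = rng.normal(size=(10, 100))
        b = rng.normal(size=(10, 100))
        a[:, 42] += 10.0
        res = sectionwise_t(a, b)
        assert res["t"].idxmax() == 42  # node 43, 0-based row 42


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[8, 14], [15, 6]], 5.3),
            ([[11, 11], [16, 5]], 3.2),
            ([[16, 6], [14, 7]], 0.2),
            ([[20, 2, 0], [17, 4, 0]], 0.9),
        ],
    )
    def test_reported_contingency_values(self, table, expected):
        chi2, _ = chi_square_2x2(np.array(table))
        assert round(chi2, 1) == expected

    def test_febrile_value_two_decimals(self):
        chi2, _ = chi_square_2x2(np.array([[15, 7], [14, 7]]))
        assert round(chi2, 2) == 0.01

    def test_independent_table_zero(self):
        chi2, _ = chi_square_2x2(np.array([[10, 10], [10, 10]]))
        assert chi2 == pytest.approx(0.0)

    def test_zero_margin_missing(self):
        chi2, p = chi_square_2x2(np.array([[0, 0], [5, 6]]))
        assert np.isnan(chi2) and np.isnan(p)


class TestGroupComparison:
    @pytest.fixture(scope="class")
    def cohort(self):
        cfg = GeneratorConfig(seed=11, n_controls=20, n_ilae1=20, n_ilae2plus=20)
        return generate_profile_cohort(cfg)

    def test_poor_outcome_only_regions_flagged(self, cohort):
        """Default effects: dorsal fornix / contralateral parahippocampal
        ROIs 1-3 separate only the poor-outcome group from controls."""
        res = run_group_comparison(cohort.profiles)
        md = res[res["metric"] == "MD"].set_index(
            ["group_a", "group_b", "tract", "laterality", "roi"]
        )
        for tract, lat in (
            ("fimbria_fornix", "ipsilateral"),
            ("parahippocampal_wmb", "contralateral"),
        ):
            for roi in (1, 2, 3):
                assert md.loc[("ILAE2plus", "control", tract, lat, roi), "significant"]
        # shared uncinate effect: significant for both patient groups
        for ga in ("ILAE1", "ILAE2plus"):
            for roi in (1, 3, 5):
                assert md.loc[(ga, "control", "uncinate", "ipsilateral", roi), "significant"]

    def test_effect_sign_convention(self, cohort):
        res = run_group_comparison(cohort.profiles)
        cell = res[
            (res["group_a"] == "ILAE2plus") & (res["group_b"] == "control")
            & (res["tract"] == "uncinate") & (res["laterality"] == "ipsilateral")
            & (res["metric"] == "MD")
        ]
        assert (cell["d"] > 0).all()  # patients exceed controls in MD

    def test_empty_group_skipped(self, cohort):
        profiles = cohort.profiles[cohort.profiles["group"] != "ILAE1"]
        res = run_group_comparison(profiles)
        assert not ((res["group_a"] == "ILAE1") | (res["group_b"] == "ILAE1")).any()
        assert len(res) > 0

    def test_q_at_least_p(self, cohort):
        res = run_group_comparison(cohort.profiles)
        assert (res["q"] >= res["p"] - 1e-12).all()
        assert res["q"].between(0, 1).all()
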