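"""Unit tests for sample-level statistics and population-level corrections.

The central check is the exhaustive-enumeration oracle: averaging the
finite-Q corrected CE over every possible species subset must reproduce the
full-community CE exactly, and the corrected SE must average to Q times
the Bessel-form population covariance.
"""
import itertools

import numpy as np
import pytest

from befpartition import (
    CommunitySample,
    aggregate_heterogeneous,
    estimate_population,
    partition,
    sample_statistics,
)
from befpartition.partition import compute_delta_ry


def exhaustive_subset_means(community, n_sub, correction):
    """Oracle: average the estimator over every C(N, n_sub) subset."""
    ce_vals, se_vals = [], []
    for idx in itertools.combinations(range(community.n_species), n_sub):
        est = estimate_population(community.subset(idx), correction=correction)
        ce_vals.append(est.ce_pop_hat)
        se_vals.append(est.se_pop_hat)
    return float(np.mean(ce_vals)), float(np.mean(se_vals))


class TestSampleStatistics:
    def test_hand_example_pool10(self, two_species_pool10):
        ce_s, se_s = sample_statistics(two_species_pool10)
        # dRY = [0.65, 0.15]; CE^S = 2 * 0.4 * 3; SE^S = 2 * cov_{N-1} = 2 * 0.5
        assert ce_s == pytest.approx(2.4, rel=1e-12)
        assert se_s == pytest.approx(1.0, rel=1e-12)

    def test_full_pool_sample_uses_bessel_denominator(self, community_q10):
        community, _ = community_q10
        q = community.pool_size
        _, se_s = sample_statistics(community)
        pop = partition(community, convention="partition")
        assert se_s == pytest.approx(pop.se * q / (q - 1), rel=1e-12)

    def test_constant_dry_gives_zero_sample_se(self):
        m = np.array([2.0, 5.0, 9.0])
        q = 6
        y = m * (0.3 + 1 / q)  # dRY = 0.3 for every species
        sample = CommunitySample.from_arrays(m, y, pool_size=q)
        _, se_s = sample_statistics(sample)
        assert se_s == pytest.approx(0.0, abs=1e-12)

    def test_single_species_is_an_error(self):
        sample = CommunitySample.from_arrays([5.0], [1.0], pool_size=4)
        with pytest.raises(ValueError, match="N >= 2"):
            sample_statistics(sample)


class TestEstimatePopulation:
    def test_direct_formula_evaluation(self):
        # community engineered so CE^S = 1.0 and SE^S = 0.5 at N=2, Q=10:
        # mean(dRY)*mean(M) = 0.25*2 = 0.5 and cov_{N-1}(dRY, M) = 0.25
        m = np.array([1.0, 3.0])
        dry = np.array([0.125, 0.375])
        y = m * (dry + 1 / 10)
        sample = CommunitySample.from_arrays(m, y, pool_size=10)
        ce_s, se_s = sample_statistics(sample)
        assert ce_s == pytest.approx(1.0, rel=1e-12)
        assert se_s == pytest.approx(0.5, rel=1e-12)
        finite = estimate_population(sample, correction="finite_Q")
        assert finite.ce_pop_hat == pytest.approx(4.0, rel=1e-12)
        assert finite.se_pop_hat == pytest.approx(2.5, rel=1e-12)
        large = estimate_population(sample, correction="large_Q")
        assert large.ce_pop_hat == pytest.approx(10 * 0.5 * (1.0 - 0.25), rel=1e-12)

    def test_full_sample_collapses_to_sample_statistics(self, community_q10):
        community, _ = community_q10
        est = estimate_population(community, correction="finite_Q")
        assert est.ce_pop_hat == pytest.approx(est.ce_sample, rel=1e-12)
        assert est.se_pop_hat == pytest.approx(est.se_sample, rel=1e-12)
        # and the finite-Q CE equals the population CE exactly at N = Q
        pop = partition(community, convention="partition")
        assert est.ce_pop_hat == pytest.approx(pop.ce, rel=1e-12)

    def test_unknown_correction_rejected(self, two_species_pool10):
        with pytest.raises(ValueError, match="correction"):
            estimate_population(two_species_pool10, correction="bootstrap")

    @pytest.mark.parametrize("n_sub", [2, 3, 4, 5])
    def test_exhaustive_unbiasedness_small_community(self, community_q10, n_sub):
        """Mean over all C(Q, n) subsets hits the population values exactly."""
        community, _ = community_q10
        q = community.pool_size
        pop = partition(community, convention="partition")
        dry = compute_delta_ry(community)
        s_xz = float(np.cov(dry, community.monoculture, ddof=1)[0, 1])
        ce_mean, se_mean = exhaustive_subset_means(community, n_sub, "finite_Q")
        assert ce_mean == pytest.approx(pop.ce, rel=1e-9)
        assert se_mean == pytest.approx(q * s_xz, rel=1e-9)

    def test_large_q_correction_converges_to_finite_q(self):
        """The two corrections agree as Q grows with N fixed."""
        m = np.array([1.0, 4.0, 9.0])
        y = np.array([0.5, 3.0, 2.0])
        ratios = []
        for q in (10, 100, 10_000):
            sample = CommunitySample.from_arrays(m, y, pool_size=q)
            finite = estimate_population(sample, "finite_Q").ce_pop_hat
            large = estimate_population(sample, "large_Q").ce_pop_hat
            ratios.append(large / finite)
        assert abs(ratios[-1] - 1) < abs(ratios[0] - 1)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)


class TestAggregateHeterogeneous:
    def test_identical_estimates(self, two_species_pool10):
        est = estimate_population(two_species_pool10)
        summary = aggregate_heterogeneous([est] * 5)
        assert summary.loc["ce_pop_hat", "mean"] == pytest.approx(est.ce_pop_hat)
        assert summary.loc["ce_pop_hat", "sd"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc["ce_pop_hat", "n"] == 5

    def test_two_point_summary(self, two_species_pool10):
        base = estimate_population(two_species_pool10)
        pair = [
            base.__class__(**{**base.__dict__, "ce_pop_hat": 3.0}),
            base.__class__(**{**base.__dict__, "ce_pop_hat": 5.0}),
        ]
        summary = aggregate_heterogeneous(pair)
        assert summary.loc["ce_pop_hat", "mean"] == pytest.approx(4.0)
        assert summary.loc["ce_pop_hat", "sd"] == pytest.approx(np.sqrt(2.0))

    def test_single_estimate_reports_missing_sd(self, two_species_pool10):
        summary = aggregate_heterogeneous([estimate_population(two_species_pool10)])
        assert np.isnan(summary.loc["se_pop_hat", "sd"])

    def test_mixed_pool_sizes_rejected(self):
        a = estimate_population(
            CommunitySample.from_arrays([4.0, 2.0], [3.0, 0.5], pool_size=10)
        )
        b = estimate_population(
            CommunitySample.from_arrays([4.0, 2.0], [3.0, 0.5], pool_size=12)
        )
        with pytest.raises(ValueError, match="pool sizes"):
            aggregate_heterogeneous([a, b])
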