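"""Unit tests for subset drawing, bias experiments and error intervals."""
import itertools

import numpy as np
import pandas as pd
import pytest

from befpartition import (
    CommunityModel,
    SubsamplingDesign,
    draw_subsets,
    generate_community,
    partition,
    predicted_bias,
    sampling_error_interval,
    subsampling_experiment,
)
from befpartition.community import CommunitySample


class TestDrawSubsets:
    def test_exhaustive_enumerates_every_combination_once(self, community_q10):
        community, _ = community_q10
        small = community.subset(range(6))
        subsets = draw_subsets(small, n_sub=3, n_draws=1, exhaustive=True)
        assert len(subsets) == 20  # C(6,3)
        seen = {tuple(sorted(s.species_ids)) for s in subsets}
        assert len(seen) == 20

    def test_full_size_draws_are_the_whole_community(self, community_q10):
        community, _ = community_q10
        subsets = draw_subsets(community, n_sub=10, n_draws=3, seed=1)
        for s in subsets:
            assert sorted(s.species_ids) == sorted(community.species_ids)
            assert s.pool_size == community.pool_size

    def test_seed_reproducibility(self, community_q10):
        community, _ = community_q10
        a = draw_subsets(community, 4, 50, seed=123)
        b = draw_subsets(community, 4, 50, seed=123)
        assert [s.species_ids for s in a] == [s.species_ids for s in b]

    def test_subsets_keep_pool_size(self, community_q10):
        community, _ = community_q10
        for s in draw_subsets(community, 3, 5, seed=0):
            assert s.pool_size == community.pool_size
            assert s.n_species == 3

    def test_oversized_subset_rejected(self, community_q10):
        community, _ = community_q10
        with pytest.raises(ValueError, match="subset size"):
            draw_subsets(community, 11, 1)


class TestPredictedBias:
    def test_direct_evaluation(self):
        # Q=10, N=5, S_xz=1 -> (5/10) * (1/5) = 0.1
        assert predicted_bias(10.0, 5, 10) == pytest.approx(0.1, rel=1e-12)

    def test_vanishes_at_full_sample_and_zero_selection(self):
        assert predicted_bias(7.3, 10, 10) == 0.0
        assert all(predicted_bias(0.0, n, 20) == 0.0 for n in range(2, 21))

    def test_matches_exhaustive_mean_bias(self, community_q10):
        """Analytic prediction vs brute-force enumeration of all subsets."""
        community, _ = community_q10
        q = community.pool_size
        m = community.monoculture
        dry = community.mixture / m - 1 / q
        ce_pop = q * dry.mean() * m.mean()
        s_xz = float(np.cov(dry, m, ddof=1)[0, 1])
        for n_sub in (2, 4, 7):
            vals = []
            for idx in itertools.combinations(range(q), n_sub):
                sub_m, sub_d = m[list(idx)], dry[list(idx)]
                vals.append(sub_d.mean() * sub_m.mean() - ce_pop / q)
            assert np.mean(vals) == pytest.approx(
                predicted_bias(q * s_xz, n_sub, q), rel=1e-9
            )


class TestSubsamplingExperiment:
    def test_requires_fully_observed_community(self, community_q10):
        community, _ = community_q10
        partial = community.subset(range(6))
        with pytest.raises(ValueError, match="fully observed"):
            subsampling_experiment(partial, SubsamplingDesign(n_grid=(2,), n_draws=10))

    def test_exhaustive_mean_bias_is_exact_zero_for_corrected_ce(self, community_q10):
        community, _ = community_q10
        design = SubsamplingDesign(n_grid=(2, 5, 10), n_draws=100, seed=0)
        curve = subsampling_experiment(community, design)
        t = curve.select("ce_corrected")
        assert bool(t["exhaustive"].all())
        scale = abs(curve.ce_pop)
        assert (t["mean_bias"].abs() < 1e-9 * scale).all()

    def test_sd_is_zero_at_full_sample(self, community_q10):
        community, _ = community_q10
        design = SubsamplingDesign(n_grid=(10,), n_draws=50, seed=0)
        curve = subsampling_experiment(community, design)
        assert (curve.table["sd"] == 0.0).all()
        assert (curve.table["mean_bias"].abs() < 1e-9 * abs(curve.ce_pop)).all()

    def test_monte_carlo_converges_to_exhaustive_oracle(self):
        """MC mean bias approaches the exact enumeration within 3 MC SEs."""
        community, _ = generate_community(CommunityModel(pool_size=12, seed=9))
        exact = subsampling_experiment(
            community, SubsamplingDesign(n_grid=(4,), n_draws=1, seed=0)
        )
        mc = subsampling_experiment(
            community,
            SubsamplingDesign(n_grid=(4,), n_draws=40_000, seed=1, exhaustive_threshold=0),
        )
        for variant in ("ce_uncorrected", "ce_corrected", "se_corrected"):
            row_ex = exact.select(variant).iloc[0]
            row_mc = mc.select(variant).iloc[0]
            assert not row_mc["exhaustive"] and row_ex["exhaustive"]
            assert abs(row_mc["mean_bias"] - row_ex["mean_bias"]) < 3 * row_mc["mc_se"]

    def test_tidy_csv_round_trip(self, community_q10, tmp_path):
        community, _ = community_q10
        curve = subsampling_experiment(
            community, SubsamplingDesign(n_grid=(3, 5), n_draws=50, seed=2)
        )
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        back = pd.read_csv(path)
        assert set(back.columns) >= {"N", "variant", "n_het", "mean_bias", "sd", "predicted_bias"}
        assert len(back) == len(curve.table)


class TestSamplingErrorInterval:
    def test_degenerate_community_has_zero_interval(self):
        # identical M and identical dRY across species: no between-species
        # variation, so sub-subsampling sees no spread at all
        m = np.full(8, 5.0)
        y = m * (0.2 + 1 / 12)
        sample = CommunitySample.from_arrays(m, y, pool_size=12)
        sd_ce, sd_se = sampling_error_interval(sample, n_resamples=50, seed=0)
        assert sd_ce == pytest.approx(0.0, abs=1e-12)
        assert sd_se == pytest.approx(0.0, abs=1e-12)

    def test_full_community_has_no_sampling_error(self, community_q10):
        community, _ = community_q10
        sd_ce, sd_se = sampling_error_interval(community, n_resamples=50, seed=0)
        assert sd_ce == 0.0 and sd_se == 0.0

    def test_convergence_in_number_of_resamples(self):
        sample, _ = generate_community(CommunityModel(pool_size=40, seed=3))
        sub = sample.subset(range(20))
        a = sampling_error_interval(sub, n_resamples=2000, seed=10)
        b = sampling_error_interval(sub, n_resamples=4000, seed=11)
        # SD of an SD estimate from k resamples is ~ sd/sqrt(2k); allow 10x
        assert a[0] == pytest.approx(b[0], rel=0.25)
        assert a[1] == pytest.approx(b[1], rel=0.25)

    def test_too_few_species_rejected(self):
        sample = CommunitySample.from_arrays([1.0, 2.0], [1.0, 1.0], pool_size=5)
        with pytest.raises(ValueError, match="N = 3"):
            sampling_error_interval(sample)


class TestHeterogeneousReplicationSummary:
    def test_block_sd_shrinks_with_replication(self):
        """SD over means of n-draw blocks drops roughly as 1/sqrt(n)."""
        community, _ = generate_community(CommunityModel(pool_size=30, seed=4))
        design = SubsamplingDesign(
            n_grid=(5,), n_draws=3000, n_het_reps=(1, 10, 30), seed=6,
            exhaustive_threshold=0,
        )
        curve = subsampling_experiment(community, design)
        sds = {
            n: curve.select("ce_corrected", n_het=n)["sd"].iloc[0] for n in (1, 10, 30)
        }
        assert sds[1] > sds[10] > sds[30]
        assert sds[10] == pytest.approx(sds[1] / np.sqrt(10), rel=0.5)
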