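"""Rank-sum statistic, permuted-time-point test, and Mantel test."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from gutdyn import (
    SampleMetadata,
    mantel_test,
    permute_timepoint_test,
    wilcoxon_rank_sum,
)
from gutdyn.dissimilarity import DistanceMatrix


class TestWilcoxonRankSum:
    def test_hand_ranking(self):
        assert wilcoxon_rank_sum([1, 2], [3, 4]) == 3

    def test_identical_multisets_hit_tie_expectation(self):
        x = [1.0, 2.0, 3.0]
        assert wilcoxon_rank_sum(x, x) == 3 * (3 + 3 + 1) / 2

    def test_all_tied_values_midrank(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5]) == 2 * (2 + 3 + 1) / 2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_rank_sums_of_both_groups_partition_total(self):
        # W_x + W_y == N(N+1)/2 for every input, ties included
        from hypothesis import given, settings, strategies as st

        @settings(max_examples=50, deadline=None, derandomize=True)
        @given(
            st.lists(st.integers(0, 5), min_size=1, max_size=12),
            st.lists(st.integers(0, 5), min_size=1, max_size=12),
        )
        def check(x, y):
            n = len(x) + len(y)
            total = wilcoxon_rank_sum(x, y) + wilcoxon_rank_sum(y, x)
            assert total == pytest.approx(n * (n + 1) / 2)

        check()

    def test_matches_brute_force_rank_computation(self, rng):
        # independent midrank computation by sorting and averaging tied runs
        for _ in range(30):
            nx, ny = rng.integers(1, 16, size=2)
            pool = rng.integers(0, 8, size=nx + ny).astype(float)
            x, y = pool[:nx], pool[nx:]
            order = np.argsort(pool, kind="stable")
            ranks = np.empty(len(pool))
            i = 0
            srt = pool[order]
            while i < len(pool):
                j = i
                while j < len(pool) and srt[j] == srt[i]:
                    j += 1
                ranks[order[i:j]] = (i + 1 + j) / 2
                i = j
            assert wilcoxon_rank_sum(x, y) == pytest.approx(ranks[:nx].sum())


def _monthly_dm(values, months, individual="P1"):
    n = len(months)
    ids = [f"s{j}" for j in range(n)]
    md = [SampleMetadata(ids[j], individual, months[j]) for j in range(n)]
    return DistanceMatrix(ids, values), md


class TestPermuteTimepointTest:
    def _simulated(self, seed, drift):
        from gutdyn import SimConfig, bray_curtis, simulate_cohort
        months = [24202 + m for m in range(30)]
        cfg = SimConfig(n_individuals=1, n_taxa=25, months=[months],
                        drift_sd=drift, bloom_prob=0, retention_decay=0,
                        seq_depth=1000, rng_seed=seed)
        t, md, _ = simulate_cohort(cfg)
        return bray_curtis(t.to_relative()), md

    def test_deterministic_under_seed(self):
        dm, md = self._simulated(0, 0.3)
        a = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 100, rng_seed=5)
        b = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 100, rng_seed=5)
        assert a.observed_W == b.observed_W
        assert np.array_equal(a.null_W, b.null_W)
        assert a.p_value == b.p_value

    def test_observed_statistic_matches_independent_rebinning(self):
        # recompute W from scratch: enumerate pairs, bin by interval,
        # rank-sum of the later group over the pooled M1+Y3 values
        from gutdyn import bray_curtis, enumerate_pairs
        from gutdyn.dissimilarity import group_values

        dm, md = self._simulated(1, 0.3)
        res = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 50,
                                     rng_seed=2)
        gv = group_values(enumerate_pairs(dm, md))
        assert res.observed_W == pytest.approx(
            wilcoxon_rank_sum(gv["Y3"], gv["M1"]))

    def test_strong_drift_detected(self):
        dm, md = self._simulated(3, 0.6)
        res = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 300,
                                     rng_seed=7)
        assert res.p_value < 0.05

    def test_add_one_estimator_never_zero(self):
        dm, md = self._simulated(4, 0.6)
        res = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 100,
                                     rng_seed=8)
        assert 0 < res.p_value <= 1

    def test_pooled_runs_over_all_individuals(self):
        from gutdyn import SimConfig, bray_curtis, simulate_cohort
        months = [24202 + m for m in range(28)]
        cfg = SimConfig(n_individuals=3, n_taxa=25, months=[months] * 3,
                        drift_sd=0.4, bloom_prob=0, retention_decay=0,
                        seq_depth=1000, rng_seed=0)
        t, md, _ = simulate_cohort(cfg)
        res = permute_timepoint_test(bray_curtis(t.to_relative()), md, None,
                                     ("M1", "Y3"), 200, rng_seed=1)
        assert res.individual_id == "pooled"
        assert res.p_value < 0.05

    def test_sparse_schedule_without_contrast_rejected(self):
        months = [24202, 24203, 24204]  # no Y3 pairs possible
        n = len(months)
        vals = np.zeros((n, n))
        dm, md = _monthly_dm(vals, months)
        with pytest.raises(ValueError, match="M1.*Y3|Y3.*M1"):
            permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 50, rng_seed=0)

    def test_critical_values_are_null_percentiles(self):
        dm, md = self._simulated(5, 0.3)
        res = permute_timepoint_test(dm, md, "P1", ("M1", "Y3"), 200,
                                     rng_seed=3)
        for q in (90, 95, 99):
            assert res.critical_values[q] == pytest.approx(
                np.percentile(res.null_W, q))
        assert res.critical_values[90] <= res.critical_values[99]


class TestMantel:
    def _dm(self, mat):
        ids = [f"s{j}" for j in range(mat.shape[0])]
        return DistanceMatrix(ids, mat)

    def test_self_correlation_is_one(self, rng):
        pts = rng.normal(size=(6, 1))
        mat = np.abs(pts - pts.T)
        res = mantel_test(self._dm(mat), pts.ravel(), "numeric", reps=99,
                          rng_seed=0)
        assert res.r == pytest.approx(1.0)

    def test_constant_factor_flagged_undefined(self):
        mat = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        res = mantel_test(self._dm(mat), [2.0, 2.0, 2.0], "numeric", reps=99)
        assert res.undefined and np.isnan(res.r)

    def test_categorical_distance_is_mismatch_indicator(self):
        from gutdyn.longitudinal_stats import factor_distance_matrix
        f = factor_distance_matrix(["a", "a", "b"], "categorical")
        np.testing.assert_array_equal(
            f, [[0, 0, 1], [0, 0, 1], [1, 1, 0]])

    def test_permutation_p_matches_exhaustive_enumeration(self, rng):
        # 4-sample instance: sampled p (10^4 reps) vs all 24 relabelings
        pts = rng.normal(size=4)
        noise = rng.normal(scale=0.5, size=(4, 4))
        noise = np.abs(noise + noise.T)
        np.fill_diagonal(noise, 0)
        mat = np.abs(pts[:, None] - pts[None, :]) + noise
        dm = self._dm(mat)
        exact = mantel_test(dm, pts, "numeric", exact=True)
        sampled = mantel_test(dm, pts, "numeric", reps=10_000, rng_seed=1)
        assert abs(sampled.p_value - exact.p_value) < 0.02

    def test_independent_factor_p_roughly_uniform(self, rng):
        # under the null, p<=0.2 should occur ~20% of the time over seeds
        pts = rng.normal(size=(8, 2))
        mat = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        dm = self._dm(mat)
        hits = 0
        n_seeds = 100
        for s in range(n_seeds):
            f = np.random.default_rng(1000 + s).normal(size=8)
            res = mantel_test(dm, f, "numeric", reps=99, rng_seed=s)
            hits += res.p_value <= 0.2
        assert abs(hits / n_seeds - 0.2) < 0.12

    def test_matches_scikit_bio_r(self, rng):
        # independent implementation of the same statistic
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel

        pts = rng.normal(size=(7, 2))
        d1 = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        f = rng.normal(size=7)
        res = mantel_test(self._dm(d1), f, "numeric", reps=99, rng_seed=0)
        d2 = np.abs(f[:, None] - f[None, :])
        r_ref, _, _ = skbio_mantel(
            skbio.DistanceMatrix(d1), skbio.DistanceMatrix(d2),
            permutations=0)
        assert res.r == pytest.approx(r_ref, abs=1e-12)
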