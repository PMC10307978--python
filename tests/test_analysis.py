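"""Correlation structure, response distances, and decoding analyses."""

import numpy as np
import pytest
from itertools import combinations
from scipy import stats

from stec.analysis import (
    DECODERS,
    PositionResponseSet,
    adjacent_position_correlation,
    build_decoding_sets,
    centered_positions,
    collect_position_responses,
    compare_conditions_ranksum,
    decode,
    fit_and_score,
    make_decoder,
    moving_vs_moving_decode,
    offset_distance_profile,
    static_vs_moving_distance,
    unit_trajectory_correlations,
)
from stec.network import Architecture, init_params, run_batch
from stec.stimuli import N_POSITIONS, rasterize_bar

ARCH = Architecture(frame_shape=(64, 64), n_lower=8, n_upper=8)


def pset(responses, movement="smooth_fwd", hierarchy="lower", orientation=0.0):
    return PositionResponseSet(
        condition="test", hierarchy=hierarchy, orientation=orientation,
        movement=movement, responses=responses,
    )


class TestCollectResponses:
    def test_smooth_forward_rows_match_run_steps(self):
        params = init_params(ARCH, seed=0)
        got = collect_position_responses(params, 0.0, "smooth_fwd", "lower")
        bars = np.stack([rasterize_bar(0.0, p).pixels for p in range(N_POSITIONS)])
        traj = run_batch(params, bars[None])
        assert np.array_equal(got.responses, traj.lower[:, 0])

    def test_backward_rows_are_position_indexed(self):
        params = init_params(ARCH, seed=0)
        fwd_bars = np.stack([rasterize_bar(0.0, p).pixels for p in range(N_POSITIONS)])
        traj = run_batch(params, fwd_bars[::-1][None])
        got = collect_position_responses(params, 0.0, "smooth_bwd", "lower")
        # position p is displayed at step 40 - p in the backward run
        assert np.array_equal(got.responses[5], traj.lower[N_POSITIONS - 1 - 5, 0])

    def test_static_rows_deterministic_and_fixed_point_for_zero_weights(self):
        params = init_params(ARCH, seed=1)
        for name in params.weight_names():
            getattr(params, name)[...] = 0.0
        params.b_l[...] = 1.0
        got = collect_position_responses(params, 0.0, "static", "lower")
        expected = 1.0 / (1.0 + np.exp(-1.0))
        assert np.allclose(got.responses, expected)
        again = collect_position_responses(params, 0.0, "static", "lower")
        assert np.array_equal(got.responses, again.responses)

    def test_steady_state_readout_matches_final_for_settled_runs(self):
        # small-norm weights settle well within 41 steps, so the converged
        # readout agrees with the final step
        params = init_params(ARCH, seed=3)
        for name in params.weight_names():
            getattr(params, name)[...] *= 0.2
        final = collect_position_responses(params, 0.0, "static", "lower")
        steady = collect_position_responses(
            params, 0.0, "static", "lower", static_readout="steady_state"
        )
        assert np.allclose(steady.responses, final.responses, atol=1e-5)
        with pytest.raises(ValueError, match="static_readout"):
            collect_position_responses(
                params, 0.0, "static", "lower", static_readout="converged"
            )


class TestAdjacentPositionCorrelation:
    def test_diagonal_and_symmetry(self):
        rng = np.random.default_rng(0)
        C = adjacent_position_correlation(pset(rng.random((N_POSITIONS, 8))))
        assert np.allclose(np.diagonal(C), 1.0)
        assert np.allclose(C, C.T)

    def test_three_position_toy_matches_direct_formula(self):
        X = np.zeros((N_POSITIONS, 4))
        X[:3] = [[0.1, 0.4, 0.3, 0.9], [0.2, 0.3, 0.5, 0.8], [0.9, 0.1, 0.2, 0.4]]
        X[3:] = np.random.default_rng(1).random((N_POSITIONS - 3, 4))
        C = adjacent_position_correlation(pset(X))
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            assert np.isclose(C[i, j], stats.pearsonr(X[i], X[j]).statistic)

    def test_zero_variance_row_marked_nan(self):
        X = np.random.default_rng(2).random((N_POSITIONS, 4))
        X[7] = 0.5
        C = adjacent_position_correlation(pset(X))
        assert np.isnan(C[7]).all() and np.isnan(C[:, 7]).all()


class TestUnitTrajectoryCorrelations:
    def test_identical_units_fully_positively_correlated(self):
        t = np.linspace(0, 1, 41)
        X = np.stack([t, t], axis=1)
        res = unit_trajectory_correlations(X)
        assert res["positive_significant_fraction"] == 1.0
        assert np.allclose(res["abs_correlations"], 1.0)

    def test_sign_flipped_pair_excluded_from_positive_fraction(self):
        t = np.linspace(0, 1, 41)
        X = np.stack([t, -t + 1.0], axis=1)
        res = unit_trajectory_correlations(X)
        assert res["positive_significant_fraction"] == 0.0
        assert np.isclose(res["correlations"][0], -1.0)

    def test_five_step_toy_matches_scipy_pearsonr(self):
        X = np.array(
            [[0.1, 0.9], [0.3, 0.7], [0.2, 0.6], [0.6, 0.3], [0.9, 0.2]]
        )
        res = unit_trajectory_correlations(X)
        ref = stats.pearsonr(X[:, 0], X[:, 1])
        assert np.isclose(res["correlations"][0], ref.statistic)
        assert np.isclose(res["p_values"][0], ref.pvalue)

    def test_constant_units_excluded_and_counted(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 5))
        X[:, 2] = 0.4
        res = unit_trajectory_correlations(X)
        assert res["n_pairs"] == 6  # C(4,2) remaining pairs
        assert res["n_excluded_pairs"] == 4

    def test_pair_count_for_64_units(self):
        X = np.random.default_rng(4).random((41, 64))
        assert unit_trajectory_correlations(X)["n_pairs"] == 64 * 63 // 2


class TestRankSum:
    def test_identical_samples_not_significant(self):
        a = np.arange(10, dtype=float)
        res = compare_conditions_ranksum(a, a.copy())
        assert res.pvalue > 0.9

    def test_disjoint_samples_reach_minimal_ranksum(self):
        # all of A below all of B: A's rank sum is the minimal 1+2+...+8 = 36;
        # verified against explicit enumeration of the pooled ranks
        a = np.arange(8, dtype=float)
        b = np.arange(8, dtype=float) + 100.0
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)[:8]
        assert ranks.sum() == 36.0
        res = compare_conditions_ranksum(a, b)
        exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert exact.pvalue == pytest.approx(2 / 12870)
        assert res.pvalue < 0.001 and res.statistic < 0

    def test_order_swap_flips_sign_not_pvalue(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(12), rng.random(12) + 0.3
        r1 = compare_conditions_ranksum(a, b)
        r2 = compare_conditions_ranksum(b, a)
        assert np.isclose(r1.statistic, -r2.statistic)
        assert np.isclose(r1.pvalue, r2.pvalue)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions_ranksum(np.array([]), np.array([1.0]))


class TestDistances:
    def test_self_distance_zero_diagonal(self):
        X = np.random.default_rng(6).random((N_POSITIONS, 8))
        D = static_vs_moving_distance(pset(X, "static"), pset(X))
        assert np.allclose(np.diagonal(D), 0.0)

    def test_pythagorean_toy(self):
        A = np.zeros((N_POSITIONS, 2))
        B = np.zeros((N_POSITIONS, 2))
        B[0] = [3.0, 4.0]
        D = static_vs_moving_distance(pset(A, "static"), pset(B))
        assert np.isclose(D[0, 0], 5.0)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(7)
        A, B = rng.random((N_POSITIONS, 8)), rng.random((N_POSITIONS, 8))
        D = static_vs_moving_distance(pset(A, "static"), pset(B))
        for i in range(0, N_POSITIONS, 7):
            for j in range(0, N_POSITIONS, 5):
                assert np.isclose(D[i, j], np.sqrt(((A[i] - B[j]) ** 2).sum()))

    def test_mismatched_sets_rejected(self):
        X = np.random.default_rng(8).random((N_POSITIONS, 8))
        with pytest.raises(ValueError, match="orientation"):
            static_vs_moving_distance(
                pset(X, "static", orientation=0.0), pset(X, orientation=np.pi / 8)
            )

    def test_offset_profile_band_means(self):
        D = np.abs(np.subtract.outer(np.arange(41.0), np.arange(41.0)))
        prof = offset_distance_profile(D, max_offset=3)
        assert np.allclose(prof, [0.0, 1.0, 2.0, 3.0])


class TestDecoding:
    def test_centered_positions(self):
        assert centered_positions(9) == list(range(16, 25))
        assert centered_positions(3) == [19, 20, 21]

    def test_separable_toy_is_memorized_by_lda(self):
        rng = np.random.default_rng(9)
        X = np.repeat(np.eye(4), 25, axis=0) + rng.normal(0, 0.01, (100, 4))
        y = np.repeat(np.arange(4), 25)
        assert fit_and_score((X, y), (X, y), "lda") == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        rng = np.random.default_rng(10)
        n, k = 2700, 9
        X = rng.normal(size=(n, 8))
        y = rng.integers(0, k, size=n)
        acc = fit_and_score((X, y), (X, rng.permutation(y)), "lda")
        # binomial error around chance 1/9 at n=2700
        assert abs(acc - 1.0 / k) < 4 * np.sqrt((1 / k) * (1 - 1 / k) / n)

    def test_single_class_task_is_perfect(self):
        X = np.random.default_rng(11).random((50, 4))
        y = np.zeros(50, dtype=int)
        assert fit_and_score((X, y), (X, y), "naive_bayes") == 1.0

    def test_unknown_decoder_and_task_rejected(self):
        params = init_params(ARCH, seed=0)
        with pytest.raises(ValueError, match="decoder"):
            decode(params, "position", "nearest_centroid", 0.1, seed=0)
        with pytest.raises(ValueError, match="task"):
            build_decoding_sets(params, "speed", "lower", "static", 0.1, 0, "train")

    def test_all_decoder_families_instantiable(self):
        for name in DECODERS:
            assert make_decoder(name, seed=0) is not None

    def test_decoding_set_sizes_and_labels(self):
        params = init_params(ARCH, seed=1)
        X, y = build_decoding_sets(
            params, "position", "lower", "static", 0.1, 0, "train", n_samples=5
        )
        assert X.shape == (45, ARCH.n_lower)
        assert sorted(set(y)) == centered_positions(9)
        X, y = build_decoding_sets(
            params, "orientation", "lower", "moving", 0.1, 0, "test", n_samples=4
        )
        assert X.shape == (8 * 3 * 4, ARCH.n_lower)
        assert sorted(set(y)) == list(range(8))

    def test_static_to_moving_decode_end_to_end(self):
        params = init_params(ARCH, seed=2)
        res = decode(params, "position", "naive_bayes", 0.1, seed=3, n_samples=10)
        assert 0.0 <= res.accuracy <= 1.0
        assert res.n_train == 90 and res.n_test == 90

    def test_moving_vs_moving_leakage_guard(self):
        params = init_params(ARCH, seed=2)
        with pytest.raises(ValueError, match="test_seed"):
            moving_vs_moving_decode(params, "position", "lda", 0.1, seed=5, test_seed=5)

    def test_train_and_test_noise_streams_differ(self):
        params = init_params(ARCH, seed=2)
        Xa, _ = build_decoding_sets(
            params, "position", "lower", "static", 0.1, 0, "train", n_samples=3
        )
        Xb, _ = build_decoding_sets(
            params, "position", "lower", "static", 0.1, 0, "test", n_samples=3
        )
        assert not np.allclose(Xa, Xb)
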