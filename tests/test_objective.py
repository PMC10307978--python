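"""Objective terms, closed-form gradients, and training behaviour."""

import numpy as np
import pandas as pd
import pytest

from stec.network import Architecture, BatchTrajectory, init_params, run_batch
from stec.objective import (
    LossReport,
    ObjectiveConfig,
    TrainingConfig,
    compensation_density,
    discrete_kl,
    loss_and_grads,
    soft_histogram,
    spatial_loss,
    temporal_loss,
    total_loss,
    train,
)

TINY = Architecture(frame_shape=(2, 2), n_lower=3, n_upper=3)
SMALL = Architecture(frame_shape=(16, 16), n_lower=16, n_upper=16)


def make_traj(lower, upper, gen, stim):
    as3 = lambda a: np.asarray(a, dtype=float)[:, None, :]
    return BatchTrajectory(
        lower=as3(lower), upper=as3(upper), generated_input=as3(gen), stimulus=as3(stim)
    )


class TestTemporalLoss:
    def test_constant_trajectory_with_perfect_generation_is_zero(self):
        c = [[0.3, 0.6]] * 4
        traj = make_traj(c, c, c, c)
        assert temporal_loss(traj) == 0.0

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        traj = make_traj(*(rng.random((4, 2)) for _ in range(4)))
        assert temporal_loss(traj) >= 0.0

    def test_two_step_toy_matches_hand_arithmetic(self):
        # one hierarchy moves (0.5,0.5) -> (0.7,0.5); everything else
        # constant and the generated input perfect. The lower-level term is
        # the squared norm of the change, 0.2^2 = 0.04; averaged over the
        # three levels: 0.04/3.
        lower = [[0.5, 0.5], [0.7, 0.5]]
        const = [[0.4, 0.4], [0.4, 0.4]]
        traj = make_traj(lower, const, const, const)
        assert np.isclose(temporal_loss(traj), 0.04 / 3.0, atol=1e-15)

    def test_length_one_trajectory_rejected(self):
        c = [[0.5, 0.5]]
        with pytest.raises(ValueError):
            temporal_loss(make_traj(c, c, c, c))


class TestSpatialLoss:
    def test_uniform_histogram_against_uniform_compensation_is_zero(self):
        # closed-form discrete KL: identical distributions have divergence 0
        assert discrete_kl([0.25] * 4, [0.25] * 4) == 0.0

    def test_point_mass_against_uniform_is_log_nbins(self):
        assert np.isclose(discrete_kl([1, 0, 0, 0], [0.25] * 4), np.log(4.0))

    def test_soft_histogram_is_normalized_and_localized(self):
        v = np.full((200, 1), 0.5)
        p = soft_histogram(v, n_bins=16)
        assert np.allclose(p.sum(axis=-1), 1.0)
        assert p[0].argmax() in (7, 8)  # mass concentrated at the centre bins

    def test_spatial_loss_nonnegative_and_zero_only_at_match(self):
        rng = np.random.default_rng(1)
        q = compensation_density("uniform", 8)
        z = rng.random((500, 4))
        assert spatial_loss(z, q) >= 0.0
        # responses piled near zero diverge more from uniform than uniform
        # samples do
        sparse = rng.random((500, 4)) * 0.1
        assert spatial_loss(sparse, q) > spatial_loss(z, q)

    def test_sparse_compensation_prefers_near_zero_responses(self):
        rng = np.random.default_rng(2)
        q = compensation_density("sparse", 16)
        near_zero = rng.random((500, 4)) * 0.2
        spread = rng.random((500, 4))
        assert spatial_loss(near_zero, q) < spatial_loss(spread, q)

    def test_out_of_range_responses_rejected(self):
        q = compensation_density("uniform", 4)
        with pytest.raises(ValueError):
            spatial_loss(np.array([[1.5, 0.2]]), q)


class TestTotalLoss:
    def _random_traj(self, seed=0):
        rng = np.random.default_rng(seed)
        params = init_params(TINY, seed=seed)
        return run_batch(params, rng.random((3, 5, 2, 2)))

    def test_lambda_zero_reduces_to_temporal(self):
        traj = self._random_traj()
        rep = total_loss(traj, None, ObjectiveConfig(lambda_=0.0, n_bins=4))
        assert rep.total == rep.temporal

    def test_additivity_invariant(self):
        traj = self._random_traj(1)
        cfg = ObjectiveConfig(lambda_=5.0, n_bins=8)
        rep = total_loss(traj, None, cfg)
        assert abs(rep.total - (rep.temporal + 5.0 * rep.spatial_sum)) < 1e-10

    def test_arithmetic_of_combination(self):
        rep = LossReport(total=0.0, temporal=0.2, spatial={"lower": 0.04}, lambda_=5.0)
        assert np.isclose(rep.temporal + rep.lambda_ * rep.spatial_sum, 0.4)


class TestGradients:
    def test_temporal_and_spatial_gradients_match_finite_differences(self):
        # central finite differences of the full objective through the
        # unrolled dynamics, against the closed-form BPTT gradients
        rng = np.random.default_rng(3)
        params = init_params(TINY, seed=4)
        frames = rng.random((3, 4, 2, 2))
        for cfg in (
            ObjectiveConfig(lambda_=0.0, n_bins=4),      # temporal term alone
            ObjectiveConfig(lambda_=100.0, n_bins=4),    # spatial term dominant
            ObjectiveConfig(lambda_=2.0, n_bins=4),      # combined
        ):
            _, grads = loss_and_grads(params, frames, cfg, bptt=True)
            for name, g in grads.items():
                arr = getattr(params, name)
                for _ in range(12):
                    ix = tuple(rng.integers(0, s) for s in arr.shape)
                    eps = 1e-6
                    old = arr[ix]
                    arr[ix] = old + eps
                    lp = total_loss(run_batch(params, frames), None, cfg).total
                    arr[ix] = old - eps
                    lm = total_loss(run_batch(params, frames), None, cfg).total
                    arr[ix] = old
                    fd = (lp - lm) / (2 * eps)
                    denom = max(1e-8, abs(fd), abs(g[ix]))
                    assert abs(fd - g[ix]) / denom <= 1e-4, (cfg.lambda_, name, ix)

    def test_truncated_gradient_keeps_only_direct_terms(self):
        # on a 2-frame batch there is no through-time path, so truncated
        # and full gradients must coincide exactly
        rng = np.random.default_rng(5)
        params = init_params(TINY, seed=6)
        frames = rng.random((2, 2, 2, 2))
        cfg = ObjectiveConfig(lambda_=1.0, n_bins=4)
        _, g_trunc = loss_and_grads(params, frames, cfg, bptt=False)
        _, g_full = loss_and_grads(params, frames, cfg, bptt=True)
        for name in g_trunc:
            assert np.allclose(g_trunc[name], g_full[name], atol=1e-14)


class TestTraining:
    def _config(self, seed, iters=300, **kw):
        return TrainingConfig(
            iterations_per_repetition=iters, repetitions=1, minibatch=10,
            n_scenes=6, master_seed=seed, trace_every=10, **kw,
        )

    def test_zero_iterations_returns_initialization(self):
        obj = ObjectiveConfig.from_preset("stec")
        trn = self._config(0, iters=0)
        params, trace = train(obj, trn, SMALL)
        ref = init_params(SMALL, seed=trn.master_seed)
        for name in params.weight_names():
            assert np.array_equal(getattr(params, name), getattr(ref, name))
        assert trace.empty

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases_during_training(self, seed):
        obj = ObjectiveConfig.from_preset("stec")
        params, trace = train(obj, self._config(seed), SMALL)
        assert trace.iloc[-1].total < trace.iloc[0].total

    def test_objective_tradeoff_between_regimes(self):
        # matched seeds: spatial-only training reaches a lower spatial term,
        # balanced training a lower temporal term
        for seed in (0, 1, 2):
            _, tr_stec = train(ObjectiveConfig.from_preset("stec"), self._config(seed, iters=800), SMALL)
            _, tr_sec = train(ObjectiveConfig.from_preset("sec"), self._config(seed, iters=800), SMALL)
            spatial = lambda t: t.iloc[-1].spatial_lower + t.iloc[-1].spatial_upper
            assert spatial(tr_sec) < spatial(tr_stec)
            assert tr_stec.iloc[-1].temporal < tr_sec.iloc[-1].temporal

    def test_sparseness_and_smoothness_orderings(self):
        # (a) the near-zero compensation density makes the upper hierarchy
        #     sparser than the lower; (b) mean per-step response change is
        #     ordered TEC <= STEC <= SEC
        probe = np.random.default_rng(99).random((8, 9, 16, 16))
        changes = {}
        for preset in ("tec", "stec", "sec"):
            means_l, means_u, ch = [], [], []
            for seed in (0, 1, 2):
                params, _ = train(
                    ObjectiveConfig.from_preset(preset), self._config(seed), SMALL
                )
                traj = run_batch(params, probe)
                means_l.append(traj.lower[1:].mean())
                means_u.append(traj.upper[1:].mean())
                ch.append(np.mean((traj.lower[2:] - traj.lower[1:-1]) ** 2)
                          + np.mean((traj.upper[2:] - traj.upper[1:-1]) ** 2))
            changes[preset] = np.mean(ch)
            if preset == "stec":
                assert np.mean(means_u) < np.mean(means_l)
        assert changes["tec"] <= changes["stec"] <= changes["sec"]

    def test_restart_resets_optimizer_but_not_weights(self):
        obj = ObjectiveConfig.from_preset("stec")
        one_rep = TrainingConfig(
            iterations_per_repetition=20, repetitions=1, minibatch=4,
            n_scenes=4, master_seed=7,
        )
        two_rep = TrainingConfig(
            iterations_per_repetition=10, repetitions=2, minibatch=4,
            n_scenes=4, master_seed=7,
        )
        p1, _ = train(obj, one_rep, TINY)
        p2, _ = train(obj, two_rep, TINY)
        # same total number of updates but a moment reset in between:
        # trajectories diverge, yet both remain finite and trained
        assert all(np.isfinite(getattr(p2, n)).all() for n in p2.weight_names())
        assert not np.allclose(p1.W_il, p2.W_il)
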