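"""Latent-state analyses: teacher forcing, probing, PCA, decoding, priming."""

import numpy as np
import pytest

from banditlab.bandit_task import generate_schedule
from banditlab.cohort import rich_memory_teacher, simulate_block
from banditlab.interpret import (LatentTrajectory, closed_loop_latents,
                                 decode_history, inject_pc_activity,
                                 pca_states, prime_and_probe,
                                 probe_reward_module)
from banditlab.rl_models import BEST_RL, RLParams, TabularModel
from conftest import make_block


@pytest.fixture(scope="module")
def teacher():
    return rich_memory_teacher()


class TestClosedLoop:
    def test_open_and_closed_loop_latents_agree_exactly(self):
        """Teacher-forcing a model on its own open-loop behaviour must
        reproduce the generating run's latent trajectories bit-exactly."""
        model = TabularModel(BEST_RL)
        params = model.params_from_values(
            RLParams(alpha=0.4, beta=5.0, f=0.2, kappa=0.3, b=0.02, q_init=0.55))
        sch = generate_schedule(seed=21, n_trials=60)
        block, gen_latents = simulate_block(model, params, sch, seed=3,
                                            return_latents=True)
        traj = closed_loop_latents(model, params, [block])[0]
        np.testing.assert_array_equal(traj.q, gen_latents["q"])
        np.testing.assert_array_equal(traj.c, gen_latents["c"])

    def test_closed_loop_is_deterministic(self, teacher, rng):
        model, params = teacher
        blk = make_block(rng.integers(0, 4, 40), rng.integers(1, 101, 40))
        a = closed_loop_latents(model, params, [blk])[0]
        b = closed_loop_latents(model, params, [blk])[0]
        np.testing.assert_array_equal(a.s_r, b.s_r)

    def test_out_of_range_actions_rejected(self, teacher):
        model, params = teacher
        blk = make_block([0, 5, 1])
        with pytest.raises(ValueError):
            closed_loop_latents(model, params, [blk])


class TestProbe:
    def test_tabular_probe_recovers_the_delta_rule_plane_exactly(self):
        model = TabularModel(BEST_RL)
        p = RLParams(alpha=0.3, beta=4.0, f=0.1, kappa=0.1, b=0.05, q_init=0.5)
        params = model.params_from_values(p)
        rewards = np.linspace(0.01, 1.0, 21)
        q_axis = np.linspace(0.1, 0.9, 5)
        probe = probe_reward_module(model, params, rewards, q_values=q_axis)
        for i, q_a in enumerate(q_axis):
            expected = q_a + p.alpha * (rewards - q_a) + p.b
            np.testing.assert_allclose(probe.q_out[i], expected, atol=1e-12)

    def test_memory_module_probe_is_monotone_in_reward(self, teacher, rng):
        model, params = teacher
        blocks = [make_block(rng.integers(0, 4, 80), rng.integers(1, 101, 80))]
        traj = closed_loop_latents(model, params, blocks)
        basis = pca_states(traj)
        scores = basis.scores(np.vstack([t.s_r for t in traj]))
        sd = scores[:, 0].std()
        probe = probe_reward_module(model, params,
                                    reward_grid=np.linspace(0.01, 1.0, 21),
                                    state_samples=np.linspace(-1.5, 1.5, 7) * sd,
                                    basis=basis)
        diffs = np.diff(probe.q_out, axis=1)
        assert (diffs >= -1e-9).all()    # non-decreasing along each state slice

    def test_probe_is_a_pure_function(self, teacher):
        model, params = teacher
        a = probe_reward_module(model, params, np.linspace(0, 1, 5))
        b = probe_reward_module(model, params, np.linspace(0, 1, 5))
        np.testing.assert_array_equal(a.q_out, b.q_out)

    def test_empty_grid_rejected(self, teacher):
        model, params = teacher
        with pytest.raises(ValueError):
            probe_reward_module(model, params, np.array([]))


def _traj_from_states(states, rewards):
    T = len(rewards)
    return LatentTrajectory(participant_id="p", block_id="b",
                            q=np.zeros((T, 4)), c=np.zeros((T, 4)),
                            s_r=states, s_a=None, rewards=rewards,
                            actions=np.zeros(T, dtype=int),
                            valid=np.ones(T, dtype=bool))


class TestPCA:
    def test_orthonormal_components_with_ordered_variance(self, rng):
        states = rng.standard_normal((300, 6)) * np.array([3, 2, 1, .5, .2, .1])
        traj = _traj_from_states(states, rng.random(300))
        basis = pca_states([traj])
        gram = basis.components @ basis.components.T
        np.testing.assert_allclose(gram, np.eye(len(gram)), atol=1e-10)
        evr = basis.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)

    def test_states_on_a_line_have_one_component(self, rng):
        t = rng.standard_normal(100)
        direction = np.array([1.0, -2.0, 0.5])
        traj = _traj_from_states(np.outer(t, direction), rng.random(100))
        basis = pca_states([traj])
        assert basis.components.shape[0] == 1
        assert basis.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_full_basis_reconstructs_states(self, rng):
        states = rng.standard_normal((200, 5))
        traj = _traj_from_states(states, rng.random(200))
        basis = pca_states([traj])
        recon = basis.reconstruct(basis.scores(states))
        np.testing.assert_allclose(recon, states, atol=1e-10)

    def test_pc1_oriented_toward_previous_reward(self, rng):
        # states literally carry an exponential trace of rewards: PC1 score
        # must correlate positively with the reward just consumed
        rewards = rng.random(500)
        trace = np.zeros(500)
        for t in range(1, 500):
            trace[t] = 0.7 * trace[t - 1] + 0.3 * (rewards[t - 1] - 0.5)
        states = np.column_stack([trace, 0.1 * rng.standard_normal(500)])
        traj = _traj_from_states(states, rewards)
        basis = pca_states([traj])
        scores = basis.scores(states)
        corr = np.corrcoef(scores[1:, 0], rewards[:-1])[0, 1]
        assert corr > 0


class TestDecodeHistory:
    def test_states_carrying_only_lag_one_reward(self, rng):
        rewards = rng.random(2000)
        states = np.column_stack([np.concatenate([[0], rewards[:-1]]),
                                  rng.standard_normal(2000) * 0.01])
        traj = _traj_from_states(states, rewards)
        basis = pca_states([traj])
        coef = decode_history([traj], basis, max_lag=5)
        assert abs(coef[0, 0]) > 5 * np.nanmax(np.abs(coef[0, 1:]))

    def test_reward_independent_states_decode_nothing(self, rng):
        states = rng.standard_normal((2000, 3))
        traj = _traj_from_states(states, rng.random(2000))
        basis = pca_states([traj])
        coef = decode_history([traj], basis, max_lag=5)
        assert np.nanmax(np.abs(coef)) < 0.05

    def test_running_mean_states_decay_slowly_across_lags(self, rng):
        rewards = rng.random(4000)
        trace = np.zeros(4000)
        for t in range(1, 4000):
            trace[t] = 0.9 * trace[t - 1] + 0.1 * rewards[t - 1]
        traj = _traj_from_states(np.column_stack([trace, trace * 0.5]), rewards)
        basis = pca_states([traj])
        coef = decode_history([traj], basis, max_lag=10)
        k = coef[0]
        assert k[0] > 0 and k[4] > 0
        assert k[0] > k[4] > k[9] > 0     # geometric-ish decay over lags


class TestPrimingAndInjection:
    def test_matched_prime_and_test_is_continuous(self, teacher):
        model, params = teacher
        q = prime_and_probe(model, params, 0.6, 20, 0.6, 20)
        # no perturbation at the switch: steps around it change smoothly
        pre, post = q[18], q[21]
        assert abs(post - pre) < 0.05 * max(1.0, abs(pre))

    def test_different_priming_levels_converge_after_switch(self, teacher):
        model, params = teacher
        q_low = prime_and_probe(model, params, 0.2, 100, 0.5, 250)
        q_high = prime_and_probe(model, params, 0.8, 100, 0.5, 250)
        gap = np.abs(q_low[100:] - q_high[100:])
        assert gap[0] > 0.1           # the primed states answer differently
        assert gap[200] < 0.1 * gap[0]  # and the effect washes out over trials

    def test_zero_weight_module_is_constant(self):
        from banditlab.hybrid_models import MemoryANN
        model = MemoryANN(hidden_size=4)
        params = {k: np.zeros_like(v)
                  for k, v in model.init_params(np.random.default_rng(0)).items()}
        q = prime_and_probe(model, params, 0.9, 10, 0.1, 10)
        assert np.allclose(q, q[0])

    def test_zero_magnitude_injection_changes_nothing(self, teacher, rng):
        model, params = teacher
        blocks = [make_block(rng.integers(0, 4, 60), rng.integers(1, 101, 60))]
        basis = pca_states(closed_loop_latents(model, params, blocks))
        base, pert = inject_pc_activity(model, params, basis, 0, 0.0,
                                        np.full(30, 0.5))
        np.testing.assert_array_equal(base, pert)

    def test_opposite_injections_perturb_with_opposite_sign(self, teacher, rng):
        model, params = teacher
        blocks = [make_block(rng.integers(0, 4, 60), rng.integers(1, 101, 60))]
        basis = pca_states(closed_loop_latents(model, params, blocks))
        base, up = inject_pc_activity(model, params, basis, 0, 0.01,
                                      np.full(30, 0.5), inject_at=5)
        _, down = inject_pc_activity(model, params, basis, 0, -0.01,
                                     np.full(30, 0.5), inject_at=5)
        d_up = up[5] - base[5]
        d_down = down[5] - base[5]
        assert d_up == pytest.approx(-d_down, rel=0.05)
        assert abs(d_up) > 0

    def test_injection_outside_rank_rejected(self, teacher, rng):
        model, params = teacher
        blocks = [make_block(rng.integers(0, 4, 30), rng.integers(1, 101, 30))]
        basis = pca_states(closed_loop_latents(model, params, blocks))
        with pytest.raises(IndexError):
            inject_pc_activity(model, params, basis, 99, 1.0, np.full(5, 0.5))
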