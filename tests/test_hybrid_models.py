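"""Neural architectures: forward oracles, nesting, architectural separations."""

import numpy as np
import pytest

from banditlab.autodiff import Tensor
from banditlab.fitting import _as_tensors, _unroll, stack_blocks
from banditlab.hybrid_models import (ContextANN, MemoryANN, RLANN, VanillaRNN,
                                     load_weights, make_model, mlp_forward,
                                     save_weights, NetworkWeights)
from banditlab.interpret import closed_loop_latents, reward_module_step
from conftest import make_block


class TestMLPForward:
    def test_matches_hand_coded_matrix_oracle(self, rng):
        W1, b1 = rng.standard_normal((3, 7)), rng.standard_normal(7)
        W2, b2 = rng.standard_normal((7, 2)), rng.standard_normal(2)
        x = rng.standard_normal((5, 3))
        out, hidden = mlp_forward(W1, b1, W2, b2, x)
        # independent elementwise oracle
        exp_h = np.array([[np.tanh(sum(x[i, k] * W1[k, j] for k in range(3)) + b1[j])
                           for j in range(7)] for i in range(5)])
        exp_o = np.array([[sum(exp_h[i, j] * W2[j, m] for j in range(7)) + b2[m]
                           for m in range(2)] for i in range(5)])
        np.testing.assert_allclose(hidden, exp_h, atol=1e-12)
        np.testing.assert_allclose(out, exp_o, atol=1e-12)

    def test_zero_weights_give_zero_everything(self):
        out, hidden = mlp_forward(np.zeros((2, 4)), np.zeros(4),
                                  np.zeros((4, 1)), np.zeros(1), np.ones((3, 2)))
        assert np.all(out == 0) and np.all(hidden == 0)

    def test_zero_first_layer_makes_hidden_input_independent(self, rng):
        b1 = rng.standard_normal(4)
        for x in (np.zeros((1, 2)), rng.standard_normal((1, 2))):
            _, hidden = mlp_forward(np.zeros((2, 4)), b1, np.zeros((4, 1)),
                                    np.zeros(1), x)
            np.testing.assert_allclose(hidden[0], np.tanh(b1))


class TestRLANN:
    def test_linear_regime_weights_emulate_delta_rule(self):
        """An RL-ANN reward module hand-built in the tanh linear regime
        reproduces Q <- Q + alpha*(r - Q) to 1e-3."""
        alpha, eps = 0.5, 1e-3
        model = RLANN(hidden_size=1)
        params = model.init_params(np.random.default_rng(0))
        params["W1r"] = np.array([[eps * (1 - alpha)], [eps * alpha]])
        params["b1r"] = np.zeros(1)
        params["W2r"] = np.array([[1.0 / eps]])
        params["b2r"] = np.zeros(1)
        for q_a in (0.1, 0.4, 0.9):
            for r in (0.05, 0.5, 1.0):
                got, _ = reward_module_step(model, params, [r], q_a=np.array([q_a]))
                assert got[0] == pytest.approx(q_a + alpha * (r - q_a), abs=1e-3)

    def test_zero_reward_module_writes_output_bias(self, rng):
        model = RLANN(hidden_size=3)
        params = model.init_params(rng)
        params["W2r"] = np.zeros((3, 1))
        params["b2r"] = np.array([0.77])
        blk = make_block([2, 2, 1], [50, 80, 30])
        traj = closed_loop_latents(model, params, [blk])[0]
        # after trial 1's update consumed (a=2, r): chosen arm's Q is b2r
        assert traj.q[1, 2] == pytest.approx(0.77)

    def test_step_is_deterministic(self, rng):
        model = RLANN(hidden_size=4)
        params = model.init_params(rng)
        blk = make_block([0, 1, 2, 3, 0], [10, 90, 40, 60, 20])
        t1 = closed_loop_latents(model, params, [blk])[0]
        t2 = closed_loop_latents(model, params, [blk])[0]
        np.testing.assert_array_equal(t1.q, t2.q)
        np.testing.assert_array_equal(t1.c, t2.c)


class TestContextANN:
    def _padded_context_params(self, rl_params, H):
        """Embed RL-ANN weights in a Context-ANN with zero context columns."""
        ctx = dict(rl_params)
        W1r = np.zeros((6, H))
        W1r[:2] = rl_params["W1r"]          # [Q(a), r] rows shared
        ctx["W1r"] = W1r
        W1a = np.zeros((5, H))
        W1a[:1] = rl_params["W1a"]
        ctx["W1a"] = W1a
        return ctx

    def test_zero_context_columns_reduce_to_rl_ann(self, rng):
        H = 6
        rl = RLANN(hidden_size=H)
        rl_params = rl.init_params(rng)
        ctx = ContextANN(hidden_size=H)
        ctx_params = self._padded_context_params(rl_params, H)
        blk = make_block(rng.integers(0, 4, 25), rng.integers(1, 101, 25))
        arrays = stack_blocks([blk])
        nll_rl = _unroll(rl, _as_tensors(rl_params, False), arrays, per_block=True)[0]
        nll_ctx = _unroll(ctx, _as_tensors(ctx_params, False), arrays, per_block=True)[0]
        np.testing.assert_allclose(nll_ctx, nll_rl, atol=1e-10)

    def test_context_columns_make_output_depend_on_unchosen_values(self, rng):
        model = ContextANN(hidden_size=4)
        params = model.init_params(rng)
        r = np.array([0.6])
        q_a = np.array([0.4])
        out1, _ = reward_module_step(model, params, r, q_a=q_a,
                                     q_ctx=np.array([[0.4, 0.1, 0.1, 0.1]]))
        out2, _ = reward_module_step(model, params, r, q_a=q_a,
                                     q_ctx=np.array([[0.4, 0.9, 0.9, 0.9]]))
        assert abs(out1[0] - out2[0]) > 1e-6


class TestMemoryANN:
    def test_zero_weights_keep_constant_outputs(self):
        model = MemoryANN(hidden_size=3)
        params = {k: np.zeros_like(v)
                  for k, v in model.init_params(np.random.default_rng(0)).items()}
        params["q_init"] = np.array(0.5)
        blk = make_block([0, 1, 2, 0], [90, 10, 50, 70])
        traj = closed_loop_latents(model, params, [blk])[0]
        assert np.allclose(traj.s_r, 0) and np.allclose(traj.c, 0)

    def test_reward_module_state_carries_history(self, rng):
        """Different priming histories yield different responses to the
        same test reward (state dependence)."""
        model = MemoryANN(hidden_size=6)
        params = model.init_params(rng)
        params["W1r"] = rng.standard_normal((7, 6))   # trained-like scale
        s_low = s_high = np.zeros((1, 6))
        for _ in range(10):
            _, s_low = reward_module_step(model, params, [0.1], s=s_low)
            _, s_high = reward_module_step(model, params, [0.9], s=s_high)
        q_low, _ = reward_module_step(model, params, [0.5], s=s_low)
        q_high, _ = reward_module_step(model, params, [0.5], s=s_high)
        assert abs(q_low[0] - q_high[0]) > 1e-8

    def test_reward_side_blind_to_action_relabelling(self, rng):
        """Swapping action labels leaves s^(r) and the written values
        untouched; the action-side state changes (architectural separation)."""
        model = MemoryANN(hidden_size=5)
        params = model.init_params(rng)
        actions = rng.integers(0, 4, 30)
        rewards = rng.integers(1, 101, 30)
        perm = np.array([2, 3, 1, 0])
        blk = make_block(actions, rewards)
        blk_perm = make_block(perm[actions], rewards)
        t1 = closed_loop_latents(model, params, [blk])[0]
        t2 = closed_loop_latents(model, params, [blk_perm])[0]
        np.testing.assert_allclose(t2.s_r, t1.s_r, atol=1e-12)
        # Q vector permutes with the labels (same update for every arm)
        np.testing.assert_allclose(t2.q[:, perm], t1.q, atol=1e-12)
        assert not np.allclose(t2.s_a, t1.s_a)

    def test_action_side_blind_to_rewards(self, rng):
        model = MemoryANN(hidden_size=5)
        params = model.init_params(rng)
        actions = rng.integers(0, 4, 30)
        t1 = closed_loop_latents(model, params,
                                 [make_block(actions, np.full(30, 90))])[0]
        t2 = closed_loop_latents(model, params,
                                 [make_block(actions, np.full(30, 10))])[0]
        np.testing.assert_allclose(t1.s_a, t2.s_a, atol=1e-12)
        np.testing.assert_allclose(t1.c, t2.c, atol=1e-12)


class TestVanillaRNN:
    def test_matches_hand_rolled_recurrence_oracle(self, rng):
        model = VanillaRNN(hidden_size=3)
        params = model.init_params(rng)
        actions = [0, 2, 1, 3, 2]
        rewards = [20, 80, 50, 10, 60]
        blk = make_block(actions, rewards)
        traj = closed_loop_latents(model, params, [blk])[0]

        s = np.zeros(3)
        for t in range(5):
            if t == 0:
                oh, r = np.zeros(4), 0.5
            else:
                oh = np.eye(4)[actions[t - 1]]
                r = rewards[t - 1] / 100.0
            x = np.concatenate([oh, [r], s])
            s = np.tanh(x @ params["W1"] + params["b1"])
            np.testing.assert_allclose(traj.s_r[t], s, atol=1e-12)

    def test_zero_weights_emit_constant_output_bias(self, rng):
        model = VanillaRNN(hidden_size=3)
        params = {k: np.zeros_like(v) for k, v in model.init_params(rng).items()}
        params["b2"] = np.array([1.0, 2.0, 3.0, 4.0])
        arrays = stack_blocks([make_block([0, 1, 2], [50, 50, 50])])
        pt = _as_tensors(params, False)
        ctx = model.prepare(pt)
        state = model.init_state(ctx, 1)
        for t in range(3):
            logits = model.logits(ctx, state)
            np.testing.assert_allclose(logits.data[0], [1, 2, 3, 4])

    def test_zero_recurrent_weights_are_memoryless(self, rng):
        model = VanillaRNN(hidden_size=3)
        params = model.init_params(rng)
        params["W1"][5:] = 0.0   # zero the recurrent block of W1
        blk_a = make_block([0, 1, 2, 2], [50, 20, 80, 80])
        blk_b = make_block([3, 0, 2, 1], [90, 70, 80, 10])  # same trial-2 events
        ta = closed_loop_latents(model, params, [blk_a])[0]
        tb = closed_loop_latents(model, params, [blk_b])[0]
        np.testing.assert_allclose(ta.s_r[3], tb.s_r[3], atol=1e-12)


def test_weights_json_round_trip(tmp_path, rng):
    model = MemoryANN(hidden_size=4)
    params = model.init_params(rng)
    w = NetworkWeights(arch="memory_ann", hidden_size=4, params=params, seed=7)
    save_weights(w, tmp_path / "w.json")
    back = load_weights(tmp_path / "w.json")
    assert back.arch == "memory_ann" and back.seed == 7
    for k in params:
        np.testing.assert_allclose(back.params[k], params[k])


def test_make_model_resolves_the_full_ladder():
    names = ["simple_rl", "best_rl", "rl_ann", "context_ann", "memory_ann",
             "vanilla_rnn", "variant:simple_rl"]
    for n in names:
        assert make_model(n, hidden_size=4) is not None
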