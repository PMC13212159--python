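"""Hybrid neural-cognitive architectures and the unconstrained RNN baseline.

Four architectures of increasing flexibility, all behind the same step
interface as the tabular models:

* ``RLANN`` — the Best-RL architecture with both handcrafted update rules
  replaced by two-layer MLPs: a reward module mapping
  [Q_{t-1}(a), r_{t-1}] -> Q_t(a) for the chosen arm, and an action module
  mapping the previous action -> a perseveration vector c_t.  Unchosen-arm
  values decay exponentially toward a trainable Q_init at trainable rate f.
* ``ContextANN`` — adds context inputs: the reward module also sees the
  full value vector Q_{t-1}, the action module also sees c_{t-1}.
* ``MemoryANN`` — replaces the context inputs by the modules' own previous
  hidden activations s^(r), s^(a) (turning each MLP into an RNN) and drops
  the Q_{t-1}(a) input, separating memory variables from choice variables.
  Reward processing never sees actions and action processing never sees
  rewards; unchosen values still decay strictly exponentially.
* ``VanillaRNN`` — one fully connected recurrent network over
  [one-hot action, reward, state]; logits are a linear readout of state.

ANN logits are Q_t + c_t with no inverse temperature (the scale is
absorbed into the readout weights); the RNN's logits are its readout.
Rewards are on the points/100 scale.  The previous action enters size-1
action modules as the scalar (a+1)/4, with 0 meaning "no previous action".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, concat
from .models_base import N_ARMS, PolicyModel

__all__ = [
    "mlp_forward", "NetworkWeights", "RLANN", "ContextANN", "MemoryANN",
    "VanillaRNN", "save_weights", "load_weights", "make_model",
    "DEFAULT_HIDDEN_SIZE",
]

DEFAULT_HIDDEN_SIZE = 32
ACTION_CODES = (np.arange(N_ARMS) + 1.0) / N_ARMS  # 0.25 .. 1.0; 0 = none


def mlp_forward(W1: np.ndarray, b1: np.ndarray, W2: np.ndarray, b2: np.ndarray,
                x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-layer MLP: hidden = tanh(x W1 + b1); output = hidden W2 + b2.

    ``x`` may be a single input vector or a (batch, in) matrix; weights use
    the (in, hidden) / (hidden, out) layout.  No output nonlinearity, so
    outputs can be read as values/logits.  Returns (output, hidden).
    """
    x = np.asarray(x, dtype=float)
    hidden = np.tanh(x @ W1 + b1)
    return hidden @ W2 + b2, hidden


@dataclass
class NetworkWeights:
    """Portable container for a trained model's arrays.

    ``params`` maps parameter names to arrays; ``arch`` is the architecture
    tag (``rl_ann`` etc.) and ``hidden_size`` the module width.
    """

    arch: str
    hidden_size: int
    params: dict[str, np.ndarray]
    seed: int | None = None


def save_weights(weights: NetworkWeights, path: str | Path) -> None:
    """Serialize weights as JSON (shapes + nested lists)."""
    payload = {
        "arch": weights.arch,
        "hidden_size": weights.hidden_size,
        "seed": weights.seed,
        "params": {k: v.tolist() for k, v in weights.params.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_weights(path: str | Path) -> NetworkWeights:
    payload = json.loads(Path(path).read_text())
    params = {k: np.asarray(v, dtype=float) for k, v in payload["params"].items()}
    return NetworkWeights(arch=payload["arch"], hidden_size=payload["hidden_size"],
                          params=params, seed=payload.get("seed"))


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    return rng.standard_normal((n_in, n_out)) / np.sqrt(n_in)


def _action_scalar(oh: Tensor) -> Tensor:
    """(B,4) one-hot -> (B,1) scalar code (a+1)/4; zeros map to 0."""
    return oh @ Tensor(ACTION_CODES[:, None])


class _ModularANN(PolicyModel):
    """Shared machinery for the reward-module + action-module architectures."""

    name = "modular_ann"
    reward_in: int
    action_in: int
    recurrent = False

    def __init__(self, hidden_size: int = DEFAULT_HIDDEN_SIZE,
                 decay_scope: str = "unchosen"):
        if decay_scope not in ("unchosen", "all"):
            raise ValueError(f"unknown decay scope {decay_scope!r}")
        self.hidden_size = hidden_size
        self.decay_scope = decay_scope

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H = self.hidden_size
        return {
            "W1r": _glorot(rng, self.reward_in, H), "b1r": np.zeros(H),
            "W2r": _glorot(rng, H, 1), "b2r": np.zeros(1),
            "W1a": _glorot(rng, self.action_in, H), "b1a": np.zeros(H),
            "W2a": _glorot(rng, H, N_ARMS), "b2a": np.zeros(N_ARMS),
            "f_raw": np.array(-2.0),   # sigmoid(-2) ~ 0.12 initial decay
            "q_init": np.array(0.5),
        }

    def decay_param_names(self) -> set[str]:
        return {"W1r", "W2r", "W1a", "W2a"}

    def prepare(self, params: dict[str, Tensor]) -> dict:
        ctx = dict(params)
        ctx["f"] = params["f_raw"].sigmoid()   # transform once per unroll
        return ctx

    def init_state(self, params, batch: int) -> dict[str, Tensor]:
        state = {
            "q": params["q_init"] * Tensor(np.ones((batch, N_ARMS))),
            "c": Tensor(np.zeros((batch, N_ARMS))),
        }
        if self.recurrent:
            state["s_r"] = Tensor(np.zeros((batch, self.hidden_size)))
            state["s_a"] = Tensor(np.zeros((batch, self.hidden_size)))
        return state

    def logits(self, params, state) -> Tensor:
        return state["q"] + state["c"]

    # -- architecture hooks ---------------------------------------------

    def _reward_input(self, params, state, q_dec, q_a, r) -> Tensor:
        raise NotImplementedError

    def _action_input(self, params, state, oh) -> Tensor:
        raise NotImplementedError

    def update(self, params, state, oh, r, m):
        q, c = state["q"], state["c"]
        f = params["f"]
        q_init = params["q_init"]

        if self.decay_scope == "unchosen":
            q_dec = q + Tensor(1.0 - oh.data) * f * (q_init - q)
        else:
            q_dec = q + f * (q_init - q)
        q_a = (q_dec * oh).sum(axis=1, keepdims=True)

        x_r = self._reward_input(params, state, q_dec, q_a, r)
        h_r = (x_r @ params["W1r"] + params["b1r"]).tanh()
        q_out = h_r @ params["W2r"] + params["b2r"]          # (B, 1)
        q_next = q_dec + oh * (q_out - q_a)                  # overwrite chosen arm

        x_a = self._action_input(params, state, oh)
        h_a = (x_a @ params["W1a"] + params["b1a"]).tanh()
        c_next = h_a @ params["W2a"] + params["b2a"]          # (B, 4)

        new_state = {
            "q": m * q_next + (1.0 - m) * q,
            "c": m * c_next + (1.0 - m) * c,
        }
        if self.recurrent:
            new_state["s_r"] = m * h_r + (1.0 - m) * state["s_r"]
            new_state["s_a"] = m * h_a + (1.0 - m) * state["s_a"]
        return new_state


class RLANN(_ModularANN):
    """Best-RL's architecture with MLP update rules."""

    name = "rl_ann"
    reward_in = 2      # [Q_{t-1}(a), r_{t-1}]
    action_in = 1      # scalar-coded a_{t-1}

    def _reward_input(self, params, state, q_dec, q_a, r):
        return concat([q_a, r], axis=1)

    def _action_input(self, params, state, oh):
        return _action_scalar(oh)


class ContextANN(_ModularANN):
    """RL-ANN plus context: modules also see Q_{t-1} and c_{t-1}."""

    name = "context_ann"
    reward_in = 2 + N_ARMS   # [Q_{t-1}(a), r_{t-1}, Q_{t-1}]
    action_in = 1 + N_ARMS   # [a_{t-1}, c_{t-1}]

    def _reward_input(self, params, state, q_dec, q_a, r):
        return concat([q_a, r, q_dec], axis=1)

    def _action_input(self, params, state, oh):
        return concat([_action_scalar(oh), state["c"]], axis=1)


class MemoryANN(_ModularANN):
    """Recurrent modules: hidden states replace choice-variable inputs."""

    name = "memory_ann"
    recurrent = True

    def __init__(self, hidden_size: int = DEFAULT_HIDDEN_SIZE,
                 decay_scope: str = "unchosen"):
        super().__init__(hidden_size=hidden_size, decay_scope=decay_scope)
        self.reward_in = 1 + hidden_size   # [r_{t-1}, s^(r)_{t-1}]
        self.action_in = 1 + hidden_size   # [a_{t-1}, s^(a)_{t-1}]

    def _reward_input(self, params, state, q_dec, q_a, r):
        return concat([r, state["s_r"]], axis=1)

    def _action_input(self, params, state, oh):
        return concat([_action_scalar(oh), state["s_a"]], axis=1)


class VanillaRNN(PolicyModel):
    """Fully connected recurrent network over [one-hot action, reward, state]."""

    name = "vanilla_rnn"

    def __init__(self, hidden_size: int = DEFAULT_HIDDEN_SIZE):
        self.hidden_size = hidden_size

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        H = self.hidden_size
        n_in = N_ARMS + 1 + H
        return {
            "W1": _glorot(rng, n_in, H), "b1": np.zeros(H),
            "W2": _glorot(rng, H, N_ARMS), "b2": np.zeros(N_ARMS),
        }

    def decay_param_names(self) -> set[str]:
        return {"W1", "W2"}

    def init_state(self, params, batch: int) -> dict[str, Tensor]:
        return {"s": Tensor(np.zeros((batch, self.hidden_size)))}

    def update(self, params, state, oh, r, m):
        x = concat([oh, r, state["s"]], axis=1)
        s_next = (x @ params["W1"] + params["b1"]).tanh()
        return {"s": m * s_next + (1.0 - m) * state["s"]}

    def logits(self, params, state) -> Tensor:
        return state["s"] @ params["W2"] + params["b2"]


def make_model(name: str, hidden_size: int = DEFAULT_HIDDEN_SIZE) -> PolicyModel:
    """Model factory over the full ladder (tabular names included)."""
    from .rl_models import TabularModel, variant_by_name

    neural = {"rl_ann": RLANN, "context_ann": ContextANN, "memory_ann": MemoryANN}
    if name in neural:
        return neural[name](hidden_size=hidden_size)
    if name == "vanilla_rnn":
        return VanillaRNN(hidden_size=hidden_size)
    if name.startswith("variant:"):
        name = name.split(":", 1)[1]
    return TabularModel(variant_by_name(name))
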