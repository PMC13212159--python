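"""Probing, PCA and decoding machinery for fitted models.

Closed-loop (teacher-forced) runs expose the latent trajectories a fitted
model assigns to observed behaviour: value vector Q, choice kernel c and,
for recurrent architectures, the module hidden states s^(r) and s^(a).
PCA over pooled reward-module states yields interpretable axes (PC1 is
conventionally oriented to correlate non-negatively with the previous
trial's reward, i.e. "reward sensitivity").  Probing feeds a module the
full grid of inputs and records its outputs; priming and activity
injection characterize how the hidden state shapes the reward-to-value
mapping over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .autodiff import Tensor
from .bandit_task import SessionBlock
from .fitting import _step_inputs, stack_blocks
from .hybrid_models import ContextANN, MemoryANN, RLANN, mlp_forward
from .models_base import N_ARMS, PolicyModel
from .rl_models import RLParams, TabularModel

__all__ = [
    "LatentTrajectory", "PCBasis", "ProbeResult", "closed_loop_latents",
    "probe_reward_module", "pca_states", "decode_history",
    "prime_and_probe", "inject_pc_activity", "reward_module_step",
]


@dataclass
class LatentTrajectory:
    """Per-trial latent variables for one block under teacher forcing."""

    participant_id: str
    block_id: str
    q: np.ndarray                  # (T, 4)
    c: np.ndarray                  # (T, 4)
    s_r: np.ndarray | None         # (T, H) reward-module states, if recurrent
    s_a: np.ndarray | None         # (T, H)
    rewards: np.ndarray            # (T,) scaled rewards actually observed
    actions: np.ndarray            # (T,)
    valid: np.ndarray              # (T,) bool


@dataclass
class PCBasis:
    """Orthonormal principal axes over pooled hidden states."""

    components: np.ndarray          # (k, H), rows orthonormal
    explained_variance_ratio: np.ndarray
    mean: np.ndarray                # (H,)
    sign_flipped: np.ndarray        # which axes were re-oriented

    def scores(self, states: np.ndarray) -> np.ndarray:
        return (states - self.mean) @ self.components.T

    def reconstruct(self, scores: np.ndarray) -> np.ndarray:
        return scores @ self.components + self.mean


@dataclass
class ProbeResult:
    """Module outputs over an input grid."""

    rewards: np.ndarray             # (R,) scaled reward axis
    state_axis: np.ndarray          # (S,) coordinate along the probed axis
    q_out: np.ndarray               # (S, R) chosen-arm values
    s_out: np.ndarray | None        # (S, R, H) next hidden states, if recurrent
    axis_kind: str                  # "pc", "q", or "constant"


def closed_loop_latents(model: PolicyModel, params: dict[str, np.ndarray],
                        blocks: list[SessionBlock]) -> list[LatentTrajectory]:
    """Teacher forcing: replay observed actions/rewards, record latents."""
    arrays = stack_blocks(blocks)
    if arrays["actions"].max() >= N_ARMS or \
            arrays["actions"][arrays["valid"] > 0].min() < 0:
        raise ValueError("actions outside the four-arm range")
    B, T = arrays["actions"].shape
    params_t = {k: Tensor(v) for k, v in params.items()}
    ctx = model.prepare(params_t)
    state = model.init_state(ctx, B)
    rec: dict[str, list[np.ndarray]] = {k: [] for k in state}
    for t in range(T):
        oh, r, m = _step_inputs(arrays, t)
        state = model.update(ctx, state, Tensor(oh), Tensor(r), Tensor(m))
        for k, v in state.items():
            rec[k].append(v.data.copy())
    stacked = {k: np.stack(v, axis=1) for k, v in rec.items()}   # (B, T, .)
    out = []
    for i, blk in enumerate(blocks):
        out.append(LatentTrajectory(
            participant_id=blk.participant_id, block_id=blk.block_id,
            q=stacked.get("q", np.zeros((B, T, N_ARMS)))[i],
            c=stacked.get("c", np.zeros((B, T, N_ARMS)))[i],
            s_r=stacked["s_r"][i] if "s_r" in stacked else
                (stacked["s"][i] if "s" in stacked else None),
            s_a=stacked["s_a"][i] if "s_a" in stacked else None,
            rewards=arrays["rewards"][i], actions=arrays["actions"][i],
            valid=arrays["valid"][i].astype(bool)))
    return out


# ---------------------------------------------------------------------------
# module-level forward passes (numpy, probe-friendly)

def reward_module_step(model: PolicyModel, params: dict[str, np.ndarray],
                       r, s=None, q_a=None, q_ctx=None):
    """One reward-module evaluation; returns (q_out, hidden).

    Input layout depends on the architecture: RL-ANN [Q(a), r];
    Context-ANN [Q(a), r, Q]; Memory-ANN [r, s].  For a tabular model the
    closed-form biased delta rule is evaluated (hidden is None).
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if isinstance(model, TabularModel):
        p = model.constrained(params) if not isinstance(params, RLParams) else params
        if q_a is None:
            raise ValueError("tabular probe needs q_a")
        return q_a + p.alpha * (r - q_a) + p.b, None
    if isinstance(model, MemoryANN):
        if s is None:
            s = np.zeros((len(r), model.hidden_size))
        x = np.column_stack([r, np.atleast_2d(s)])
    elif isinstance(model, ContextANN):
        x = np.column_stack([q_a, r, np.atleast_2d(q_ctx)])
    elif isinstance(model, RLANN):
        x = np.column_stack([q_a, r])
    else:
        raise TypeError(f"no reward module on {model.name}")
    out, hidden = mlp_forward(params["W1r"], params["b1r"],
                              params["W2r"], params["b2r"], x)
    return out[:, 0], hidden


def probe_reward_module(model: PolicyModel, params: dict[str, np.ndarray],
                        reward_grid: np.ndarray,
                        state_samples: np.ndarray | None = None,
                        basis: PCBasis | None = None, pc_index: int = 0,
                        q_values: np.ndarray | None = None) -> ProbeResult:
    """Evaluate the reward module over a reward x state (or reward x Q) grid.

    For recurrent modules, ``state_samples`` are coordinates along PC
    ``pc_index`` of ``basis`` (e.g. +-1.5 SD of the observed scores).  For
    feedforward modules and tabular models, ``q_values`` spans the
    previous-value axis instead.
    """
    rewards = np.asarray(reward_grid, dtype=float)
    if rewards.size == 0:
        raise ValueError("empty probe grid")
    if state_samples is not None:
        if basis is None:
            raise ValueError("state sampling requires a fitted PCBasis")
        axis = np.asarray(state_samples, dtype=float)
        q_rows, s_rows = [], []
        for coord in axis:
            s = basis.mean + coord * basis.components[pc_index]
            q_out, hidden = reward_module_step(
                model, params, rewards, s=np.tile(s, (len(rewards), 1)))
            q_rows.append(q_out)
            s_rows.append(hidden)
        return ProbeResult(rewards=rewards, state_axis=axis,
                           q_out=np.stack(q_rows),
                           s_out=np.stack(s_rows), axis_kind="pc")
    if q_values is not None:
        axis = np.asarray(q_values, dtype=float)
        q_rows = []
        for q_a in axis:
            qa = np.full(len(rewards), q_a)
            ctx = np.tile(np.full(N_ARMS, q_a), (len(rewards), 1))
            q_out, _ = reward_module_step(model, params, rewards, q_a=qa,
                                          q_ctx=ctx)
            q_rows.append(q_out)
        return ProbeResult(rewards=rewards, state_axis=axis,
                           q_out=np.stack(q_rows), s_out=None, axis_kind="q")
    q_out, hidden = reward_module_step(model, params, rewards)
    return ProbeResult(rewards=rewards, state_axis=np.zeros(1),
                       q_out=q_out[None, :],
                       s_out=None if hidden is None else hidden[None],
                       axis_kind="constant")


# ---------------------------------------------------------------------------
# PCA and decoding

def pca_states(trajectories: list[LatentTrajectory], field: str = "s_r",
               min_explained: float = 0.0) -> PCBasis:
    """Mean-centred PCA over pooled per-trial hidden states.

    Components are orthonormal with non-increasing explained variance;
    each axis is oriented so its score correlates non-negatively with the
    previous trial's reward.  Zero-variance directions are truncated.
    """
    states = np.vstack([getattr(tr, field) for tr in trajectories])
    # align each state with the reward consumed by the update that produced
    # it (the previous trial's reward): drop each block's first state
    sign_states = np.vstack([getattr(tr, field)[1:] for tr in trajectories
                             if len(tr.rewards) > 1])
    sign_rewards = np.concatenate([tr.rewards[:-1] for tr in trajectories
                                   if len(tr.rewards) > 1])
    if states.shape[0] < 2:
        raise ValueError("need at least two pooled states")
    n_comp = min(states.shape[0], states.shape[1])
    pca = PCA(n_components=n_comp)
    pca.fit(states)
    keep = pca.explained_variance_ > 1e-12
    if min_explained > 0:
        keep &= pca.explained_variance_ratio_ >= min_explained
    comps = pca.components_[keep]
    flips = np.zeros(comps.shape[0], dtype=bool)
    aligned_scores = (sign_states - pca.mean_) @ comps.T
    for j in range(comps.shape[0]):
        corr = np.corrcoef(aligned_scores[:, j], sign_rewards)[0, 1]
        if np.isfinite(corr) and corr < 0:
            comps[j] = -comps[j]
            flips[j] = True
    return PCBasis(components=comps,
                   explained_variance_ratio=pca.explained_variance_ratio_[keep],
                   mean=pca.mean_, sign_flipped=flips)


def decode_history(trajectories: list[LatentTrajectory], basis: PCBasis,
                   max_lag: int = 20, field: str = "s_r") -> np.ndarray:
    """Regression of lagged rewards on current PC scores.

    Entry [pc, lag-1] is the slope of the univariate regression predicting
    r_{t-lag} from the PC score at t, pooled over blocks.  Cells without
    enough overlap are NaN.
    """
    n_pc = basis.components.shape[0]
    coef = np.full((n_pc, max_lag), np.nan)
    per_lag_scores: list[list[np.ndarray]] = [[] for _ in range(max_lag)]
    per_lag_rewards: list[list[np.ndarray]] = [[] for _ in range(max_lag)]
    for tr in trajectories:
        scores = basis.scores(getattr(tr, field))
        for lag in range(1, max_lag + 1):
            if len(tr.rewards) <= lag:
                continue
            per_lag_scores[lag - 1].append(scores[lag:])
            per_lag_rewards[lag - 1].append(tr.rewards[:-lag])
    for lag in range(1, max_lag + 1):
        if not per_lag_scores[lag - 1]:
            continue
        s = np.vstack(per_lag_scores[lag - 1])
        r = np.concatenate(per_lag_rewards[lag - 1])
        if len(r) < 3:
            continue
        for j in range(n_pc):
            x = s[:, j]
            var = x.var()
            if var > 1e-15:
                coef[j, lag - 1] = np.cov(x, r)[0, 1] / var
    return coef


# ---------------------------------------------------------------------------
# priming and causal injection

def _iterate_reward_module(model, params, reward_seq, s0=None,
                           inject: tuple[int, np.ndarray] | None = None):
    """Drive the reward module alone with a reward sequence; record Q and s."""
    if not isinstance(model, MemoryANN):
        raise TypeError("reward-module iteration requires a recurrent module")
    s = np.zeros(model.hidden_size) if s0 is None else np.array(s0, dtype=float)
    qs, ss = [], []
    for t, r in enumerate(reward_seq):
        if inject is not None and t == inject[0]:
            s = s + inject[1]
        q_out, hidden = reward_module_step(model, params, [r], s=s[None, :])
        s = hidden[0]
        qs.append(q_out[0])
        ss.append(s.copy())
    return np.asarray(qs), np.asarray(ss)


def prime_and_probe(model, params, r_prime: float, n_prime: int,
                    r_test: float, n_test: int) -> np.ndarray:
    """Prime a fresh reward module, then switch rewards; return the Q trace.

    The module starts from the zero state, observes ``r_prime`` (scaled)
    for ``n_prime`` steps and ``r_test`` for ``n_test`` steps; the written
    chosen-arm value is recorded at every step.
    """
    seq = [r_prime] * n_prime + [r_test] * n_test
    qs, _ = _iterate_reward_module(model, params, seq)
    return qs


def inject_pc_activity(model, params, basis: PCBasis, pc_index: int,
                       magnitude: float, r_sequence,
                       inject_at: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Causal probe: add activity along one PC mid-run, compare trajectories.

    Returns (baseline Q trace, perturbed Q trace) for the same reward
    sequence, where the perturbed run has ``magnitude * component`` added
    to the hidden state just before trial ``inject_at``.
    """
    if not (0 <= pc_index < basis.components.shape[0]):
        raise IndexError("pc_index outside the basis rank")
    base_q, _ = _iterate_reward_module(model, params, r_sequence)
    pert = (inject_at, magnitude * basis.components[pc_index])
    pert_q, _ = _iterate_reward_module(model, params, r_sequence, inject=pert)
    return base_q, pert_q
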