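"""Likelihood-based training and held-out evaluation for all choice models.

Models are fitted by behavioural cloning: the negative log-likelihood (NLL,
equivalently cross-entropy) of the observed choices under the model's
trial-by-trial policy is minimized with Adam over batches of blocks sampled
with replacement from the training split.  Checkpoints are selected by
validation NLL, and held-out performance is summarized per block as the
trial-wise prediction accuracy

    acc = 100 * exp(-L / n_valid_trials),

the geometric-mean probability assigned to the observed choices (uniform
policy -> 25% on a four-armed task).  Missed trials are excluded from the
loss and from the per-block normalizer.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .autodiff import Tensor, logsumexp
from .bandit_task import SessionBlock
from .models_base import MID_REWARD, N_ARMS, PolicyModel

__all__ = [
    "TrainingConfig", "FitResult", "stack_blocks", "nll_loss",
    "per_block_nll", "accuracy_from_loss", "train", "sweep",
    "evaluate_and_compare", "DESK_CONFIG", "FULL_SCALE_CONFIG",
]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and architecture hyperparameters for one fit."""

    step_size: float = 1e-2       # Adam step size
    weight_decay: float = 1e-4    # L2 decay on network weights
    batch_size: int = 32          # blocks per gradient step
    max_steps: int = 2000
    hidden_size: int = 32         # neural models only
    eval_every: int = 100         # validation cadence (steps)
    seed: int = 0

    def __post_init__(self):
        if min(self.step_size, self.batch_size, self.max_steps,
               self.hidden_size, self.eval_every) <= 0 or self.weight_decay < 0:
            raise ValueError("training hyperparameters must be positive")


# problem sizes: a desk-scale default for interactive use, and the
# published-protocol preset retained for reference
DESK_CONFIG = TrainingConfig()
FULL_SCALE_CONFIG = TrainingConfig(step_size=1e-3, weight_decay=1e-4, batch_size=64,
                              max_steps=1_000_000, hidden_size=32, eval_every=5000)


@dataclass
class FitResult:
    """Trained parameters plus the bookkeeping needed to evaluate them."""

    model_name: str
    params: dict[str, np.ndarray]
    config: TrainingConfig
    val_curve: list[tuple[int, float]] = field(default_factory=list)
    best_step: int = 0
    best_val_nll: float = np.inf
    seed: int = 0


# ---------------------------------------------------------------------------
# block batching and the unrolled likelihood

def stack_blocks(blocks: list[SessionBlock]) -> dict[str, np.ndarray]:
    """Stack equal-length blocks into (B, T) action/reward/valid arrays."""
    if not blocks:
        raise ValueError("empty block list")
    n_trials = {b.n_trials for b in blocks}
    if len(n_trials) != 1:
        raise ValueError("blocks in a batch must share a trial count")
    return {
        "actions": np.stack([b.actions for b in blocks]),
        "rewards": np.stack([b.scaled_rewards() for b in blocks]),
        "valid": np.stack([b.valid for b in blocks]).astype(float),
    }


def _step_inputs(arrays: dict[str, np.ndarray], t: int):
    """Previous-trial inputs for trial t: one-hot action, reward, mask."""
    B = arrays["actions"].shape[0]
    if t == 0:
        oh = np.zeros((B, N_ARMS))
        r = np.full((B, 1), MID_REWARD)
        m = np.ones((B, 1))
    else:
        a = arrays["actions"][:, t - 1]
        v = arrays["valid"][:, t - 1]
        oh = np.zeros((B, N_ARMS))
        taken = v > 0
        oh[taken, a[taken]] = 1.0
        r = np.where(taken, arrays["rewards"][:, t - 1], MID_REWARD)[:, None]
        m = v[:, None].astype(float)
    return oh, r, m


def _all_step_inputs(arrays: dict[str, np.ndarray]):
    """Vectorized precomputation of _step_inputs for every trial."""
    A, V = arrays["actions"], arrays["valid"] > 0
    B, T = A.shape
    oh = np.zeros((T, B, N_ARMS))
    b_idx, t_idx = np.nonzero(V[:, :T - 1])
    oh[t_idx + 1, b_idx, A[b_idx, t_idx]] = 1.0
    r = np.full((T, B, 1), MID_REWARD)
    r[t_idx + 1, b_idx, 0] = arrays["rewards"][b_idx, t_idx]
    m = np.ones((T, B, 1))
    m[1:, :, 0] = V[:, :T - 1].T
    return oh, r, m


def _unroll(model: PolicyModel, params_t: dict[str, Tensor],
            arrays: dict[str, np.ndarray], per_block: bool = False):
    """Run the model over a stacked batch; return the summed NLL.

    With ``per_block`` the (non-differentiable) per-block NLL vector and
    valid-trial counts are returned instead of a loss tensor.
    """
    B, T = arrays["actions"].shape
    ctx = model.prepare(params_t)
    state = model.init_state(ctx, B)
    loss = Tensor(0.0)
    block_nll = np.zeros(B)
    oh_all, r_all, m_all = _all_step_inputs(arrays)
    # weight of each (block, trial, arm) in the loss: one-hot of the chosen
    # action on valid trials, zero elsewhere
    w_all = np.zeros((T, B, N_ARMS))
    b_idx, t_idx = np.nonzero(arrays["valid"] > 0)
    w_all[t_idx, b_idx, arrays["actions"][b_idx, t_idx]] = 1.0
    for t in range(T):
        state = model.update(ctx, state, Tensor(oh_all[t]), Tensor(r_all[t]),
                             Tensor(m_all[t]))
        logits = model.logits(ctx, state)
        logp = logits - logsumexp(logits, axis=1, keepdims=True)
        chosen_lp = (logp * Tensor(w_all[t])).sum(axis=1)      # (B,)
        if per_block:
            block_nll -= chosen_lp.data
        else:
            loss = loss - chosen_lp.sum()
    if per_block:
        return block_nll, arrays["valid"].sum(axis=1)
    return loss


def _as_tensors(params: dict[str, np.ndarray], requires_grad: bool) -> dict[str, Tensor]:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in params.items()}


def nll_loss(model: PolicyModel, params: dict[str, np.ndarray],
             blocks: list[SessionBlock]) -> float:
    """Total NLL of the observed valid choices, summed over blocks."""
    nll, _ = per_block_nll(model, params, blocks)
    return float(nll.sum())


def per_block_nll(model: PolicyModel, params: dict[str, np.ndarray],
                  blocks: list[SessionBlock]) -> tuple[np.ndarray, np.ndarray]:
    """Per-block NLL and valid-trial counts (no gradients)."""
    arrays = stack_blocks(blocks)
    nll, n_valid = _unroll(model, _as_tensors(params, False), arrays, per_block=True)
    if not np.all(np.isfinite(nll)):
        bad = int(np.flatnonzero(~np.isfinite(nll))[0])
        raise FloatingPointError(
            f"non-finite likelihood in block {blocks[bad].participant_id}/"
            f"{blocks[bad].block_id}")
    return nll, n_valid


def accuracy_from_loss(L: float, n_trials_total: float) -> float:
    """Trial-wise prediction accuracy in percent: 100*exp(-L/n)."""
    if n_trials_total < 1:
        raise ValueError("need at least one trial")
    return float(100.0 * np.exp(-L / n_trials_total))


# ---------------------------------------------------------------------------
# training

def train(model: PolicyModel, dataset, config: TrainingConfig,
          n_starts: int = 1) -> FitResult:
    """Fit ``model`` to ``dataset``'s training split by Adam on the NLL.

    Batches of ``config.batch_size`` blocks are drawn with replacement; the
    gradient is taken of the batch NLL normalized by the batch size.  The
    checkpoint with the lowest validation NLL is returned.  ``n_starts``
    restarts from fresh initializations (distinct sub-seeds) guard tabular
    fits against local minima; the best validation NLL wins.
    """
    from .optim import Adam

    train_blocks = dataset.split_blocks("train")
    val_blocks = dataset.split_blocks("validation")
    if not train_blocks or not val_blocks:
        raise ValueError("dataset needs non-empty train and validation splits")
    arrays = stack_blocks(train_blocks)
    n_train = len(train_blocks)
    batch_size = min(config.batch_size, n_train)

    best_fit: FitResult | None = None
    for start in range(n_starts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, start]))
        params = model.init_params(rng)
        opt = Adam(params, step_size=config.step_size,
                   weight_decay=config.weight_decay,
                   decay_names=model.decay_param_names())
        fit = FitResult(model_name=model.name,
                        params={k: v.copy() for k, v in params.items()},
                        config=config, seed=config.seed)
        for step in range(1, config.max_steps + 1):
            idx = rng.integers(0, n_train, size=batch_size)
            batch = {k: v[idx] for k, v in arrays.items()}
            params_t = _as_tensors(params, requires_grad=True)
            loss = _unroll(model, params_t, batch) * (1.0 / batch_size)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at step {step}")
            loss.backward()
            opt.step({k: t.grad for k, t in params_t.items() if t.grad is not None})
            if step % config.eval_every == 0 or step == config.max_steps:
                val_nll = nll_loss(model, params, val_blocks)
                fit.val_curve.append((step, val_nll))
                if val_nll < fit.best_val_nll:
                    fit.best_val_nll = val_nll
                    fit.best_step = step
                    fit.params = {k: v.copy() for k, v in params.items()}
        if best_fit is None or fit.best_val_nll < best_fit.best_val_nll:
            best_fit = fit
    return best_fit


def sweep(model_name: str, dataset, grid: dict[str, list] | list[TrainingConfig],
          base: TrainingConfig = DESK_CONFIG, n_replicates: int = 1):
    """Grid search over training hyperparameters; argmin validation NLL.

    ``grid`` is either an explicit list of configs or a mapping
    field -> candidate values expanded factorially over ``base``.
    Replicates rerun each cell with distinct seeds; the best replicate's
    validation NLL scores the cell.  Returns (best config, best FitResult).
    """
    from .hybrid_models import make_model

    if isinstance(grid, dict):
        keys = list(grid)
        configs = [replace(base, **dict(zip(keys, combo)))
                   for combo in itertools.product(*(grid[k] for k in keys))]
    else:
        configs = list(grid)
    if not configs:
        raise ValueError("empty hyperparameter grid")

    best: tuple[TrainingConfig, FitResult] | None = None
    for cfg in configs:
        for rep in range(n_replicates):
            cfg_rep = replace(cfg, seed=cfg.seed + rep)
            model = make_model(model_name, hidden_size=cfg_rep.hidden_size)
            try:
                fit = train(model, dataset, cfg_rep)
            except FloatingPointError:
                continue  # diverged cell
            if best is None or fit.best_val_nll < best[1].best_val_nll:
                best = (cfg, fit)
    if best is None:
        raise RuntimeError("all sweep cells diverged")
    return best


# ---------------------------------------------------------------------------
# held-out comparison

def evaluate_and_compare(fits: dict[str, tuple[PolicyModel, dict[str, np.ndarray]]],
                         test_blocks: list[SessionBlock]):
    """Per-block held-out losses/accuracies and pairwise paired t-tests.

    ``fits`` maps a label to (model, fitted params).  All models are scored
    on the identical block set.  Returns (per-block frame, pairwise frame).
    """
    if not fits:
        raise ValueError("need at least one fitted model")
    rows = []
    acc: dict[str, np.ndarray] = {}
    for label, (model, params) in fits.items():
        nll, n_valid = per_block_nll(model, params, test_blocks)
        a = 100.0 * np.exp(-nll / n_valid)
        acc[label] = a
        for blk, L, nv, av in zip(test_blocks, nll, n_valid, a):
            rows.append({"model": label, "participant_id": blk.participant_id,
                         "block_id": blk.block_id, "nll": L,
                         "n_valid": int(nv), "accuracy": av})
    per_block = pd.DataFrame(rows)

    pair_rows = []
    labels = list(fits)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            diff = acc[la] - acc[lb]
            n = len(diff)
            if n > 1 and diff.std(ddof=1) > 0:
                t, p = stats.ttest_rel(acc[la], acc[lb])
            else:  # degenerate: identical predictions (e.g. a model vs itself)
                t, p = 0.0, 1.0
            se = diff.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            ci = stats.t.ppf(0.975, n - 1) * se if n > 1 else np.nan
            pair_rows.append({
                "model_a": la, "model_b": lb,
                "mean_acc_a": acc[la].mean(), "mean_acc_b": acc[lb].mean(),
                "mean_diff": diff.mean(), "ci95_lo": diff.mean() - ci,
                "ci95_hi": diff.mean() + ci, "t": float(t), "p": float(p),
                "n_blocks": n,
            })
    return per_block, pd.DataFrame(pair_rows)
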