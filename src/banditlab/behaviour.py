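"""Model-free behavioural statistics for choice sequences.

The battery applies identically to human-format and simulated blocks:

* stay probability after repeated choices, binned by reward change,
* mean maximal-run (repeat-streak) length — chance for iid uniform
  four-arm choice is 4/3,
* cyclic responses: overlapping length-4 windows visiting every arm once
  (chance expectation for an n-trial iid sequence is (n-3) * 4!/4^4),
* Lempel-Ziv-Welch (LZW) sequence compressibility: the random-baseline
  code count divided by the observed sequence's code count, higher = more
  temporal structure,
* lagged logistic regression of choice on reward history (20 lags of
  "bandit-reward" and "other-reward" regressors per bandit, coefficients
  averaged over the four per-bandit models).

Missed trials are dropped from the sequences before any sequence metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .bandit_task import SessionBlock
from .models_base import N_ARMS

__all__ = [
    "CompressibilityResult", "LaggedRegressionResult",
    "stay_vs_reward_change", "repeat_streaks", "cyclic_responses",
    "lzw_compress", "lzw_decompress", "compressibility_ratio",
    "lagged_choice_regression",
]


def _valid_sequences(block: SessionBlock) -> tuple[np.ndarray, np.ndarray]:
    v = block.valid
    return block.actions[v], block.rewards[v]


# ---------------------------------------------------------------------------
# stay analysis

def stay_vs_reward_change(blocks: list[SessionBlock], bin_width: float = 10.0) -> pd.DataFrame:
    """P(repeat at t+1) after choosing the same arm at t-1 and t, by r_t - r_{t-1}.

    Qualifying triplets require the same action on two consecutive valid
    trials; the outcome is whether the next valid trial repeats it again.
    Returns a frame with bin centres, stay probabilities and counts.
    """
    changes, stays = [], []
    for block in blocks:
        a, r = _valid_sequences(block)
        for t in range(1, len(a) - 1):
            if a[t] == a[t - 1]:
                changes.append(float(r[t]) - float(r[t - 1]))
                stays.append(1.0 if a[t + 1] == a[t] else 0.0)
    if not changes:
        return pd.DataFrame(columns=["bin_centre", "stay_prob", "n"])
    changes = np.asarray(changes)
    stays = np.asarray(stays)
    bins = np.floor(changes / bin_width + 0.5) * bin_width
    rows = [{"bin_centre": c, "stay_prob": stays[bins == c].mean(),
             "n": int((bins == c).sum())}
            for c in np.unique(bins)]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# streaks and cycles

def repeat_streaks(blocks: list[SessionBlock]) -> float:
    """Mean maximal-run length of the action sequences (runs of length 1 count)."""
    lengths: list[int] = []
    for block in blocks:
        a, _ = _valid_sequences(block)
        if len(a) == 0:
            continue
        change = np.flatnonzero(np.diff(a) != 0)
        bounds = np.concatenate([[-1], change, [len(a) - 1]])
        lengths.extend(np.diff(bounds).tolist())
    if not lengths:
        raise ValueError("no valid trials")
    return float(np.mean(lengths))


def cyclic_responses(blocks: list[SessionBlock]) -> np.ndarray:
    """Per block: count of overlapping 4-windows that visit every arm once."""
    counts = []
    for block in blocks:
        a, _ = _valid_sequences(block)
        n = 0
        for t in range(len(a) - 3):
            window = a[t:t + 4]
            if len(np.unique(window)) == N_ARMS:
                n += 1
        counts.append(n)
    return np.asarray(counts)


# ---------------------------------------------------------------------------
# LZW compressibility

def lzw_compress(sequence) -> list[int]:
    """LZW code stream for a sequence over a finite alphabet.

    The dictionary is initialized with the single symbols (sorted order);
    the compressed "length" used throughout is the number of emitted codes.
    """
    seq = [int(s) for s in sequence]
    if not seq:
        return []
    alphabet = sorted(set(seq))
    table: dict[tuple, int] = {(s,): i for i, s in enumerate(alphabet)}
    codes: list[int] = []
    current: tuple = ()
    for s in seq:
        candidate = current + (s,)
        if candidate in table:
            current = candidate
        else:
            codes.append(table[current])
            table[candidate] = len(table)
            current = (s,)
    codes.append(table[current])
    return codes


def lzw_decompress(codes: list[int], alphabet) -> list[int]:
    """Inverse of :func:`lzw_compress` (exact round-trip)."""
    if not codes:
        return []
    alphabet = sorted(alphabet)
    table: dict[int, tuple] = {i: (s,) for i, s in enumerate(alphabet)}
    prev = table[codes[0]]
    out = list(prev)
    for code in codes[1:]:
        if code in table:
            entry = table[code]
        else:  # the one special case in LZW: code refers to the phrase being built
            entry = prev + (prev[0],)
        out.extend(entry)
        table[len(table)] = prev + (entry[0],)
        prev = entry
    return out


@dataclass
class CompressibilityResult:
    l_lzw: int        # code count of the observed sequence
    b_lzw: float      # mean code count of matched random sequences
    ratio: float      # b_lzw / l_lzw
    n_random: int
    seed: int


def compressibility_ratio(block: SessionBlock, n_random: int = 100,
                          seed: int = 0) -> CompressibilityResult:
    """Random-baseline LZW code count over the block's code count."""
    a, _ = _valid_sequences(block)
    if len(a) == 0:
        raise ValueError("empty block")
    l_lzw = len(lzw_compress(a))
    rng = np.random.default_rng(seed)
    baseline = np.mean([
        len(lzw_compress(rng.integers(0, N_ARMS, size=len(a))))
        for _ in range(n_random)
    ])
    return CompressibilityResult(l_lzw=l_lzw, b_lzw=float(baseline),
                                 ratio=float(baseline / l_lzw),
                                 n_random=n_random, seed=seed)


# ---------------------------------------------------------------------------
# lagged regression

@dataclass
class LaggedRegressionResult:
    coefficients: pd.DataFrame   # columns: regressor kind, lag, coefficient
    intercept: float
    n_lags: int
    n_observations: int


def lagged_choice_regression(blocks: list[SessionBlock], n_lags: int = 20,
                             ridge: float = 1e-3) -> LaggedRegressionResult:
    """History kernels: logistic regression of choice on lagged rewards.

    For each bandit, the indicator of choosing it is regressed on
    ``n_lags`` bandit-reward regressors (reward at lag i when that bandit
    was chosen, else 0) and ``n_lags`` other-reward regressors (reward at
    lag i when another bandit was chosen), 2*n_lags columns in total.
    Pre-block lags are zero-padded; rows whose target trial is missed are
    dropped.  The four per-bandit fits are averaged.  A small L2 (ridge)
    penalty keeps coefficients finite under separation.
    """
    X_parts, y_parts = [], []
    for block in blocks:
        a, r = _valid_sequences(block)
        T = len(a)
        if T == 0:
            continue
        rows = np.zeros((T, 2 * n_lags))
        scaled = r / 100.0
        for lag in range(1, n_lags + 1):
            src = np.arange(T) - lag
            ok = src >= 0
            rows[ok, lag - 1] = scaled[src[ok]]              # reward at lag
            rows[ok, n_lags + lag - 1] = a[src[ok]]          # action at lag (id)
        X_parts.append(rows)
        y_parts.append(a)
    if not X_parts:
        raise ValueError("no valid trials")
    raw = np.vstack(X_parts)
    actions = np.concatenate(y_parts)
    n_obs = len(actions)

    coef_sum = np.zeros(2 * n_lags)
    intercept_sum = 0.0
    for bandit in range(N_ARMS):
        X = np.zeros_like(raw)
        same = raw[:, n_lags:] == bandit
        lag_rewards = raw[:, :n_lags]
        X[:, :n_lags] = lag_rewards * same                       # bandit-reward
        X[:, n_lags:] = lag_rewards * (~same) * (lag_rewards > 0)  # other-reward
        y = (actions == bandit).astype(int)
        if y.min() == y.max():
            continue  # bandit never / always chosen: no separable target
        clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=1000)
        clf.fit(X, y)
        coef_sum += clf.coef_[0]
        intercept_sum += float(clf.intercept_[0])

    coef = coef_sum / N_ARMS
    frame = pd.DataFrame({
        "kind": ["bandit_reward"] * n_lags + ["other_reward"] * n_lags,
        "lag": list(range(1, n_lags + 1)) * 2,
        "coefficient": coef,
    })
    return LaggedRegressionResult(coefficients=frame,
                                  intercept=intercept_sum / N_ARMS,
                                  n_lags=n_lags, n_observations=n_obs)
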