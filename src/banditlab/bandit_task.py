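"""Restless four-armed bandit: reward schedules and schedule-relative performance.

The task is a drifting (restless) bandit.  Each arm ``i`` carries a latent
mean reward mu[t, i] that follows a mean-reverting Gaussian random walk,

    mu[0, i] ~ Uniform(1, 100)
    mu[t, i] ~ Normal(lam * mu[t-1, i] + (1 - lam) * 50, sigma_d)

and the reward actually shown on a trial is a noisy, integer-valued
observation of the chosen arm's mean,

    r[t, i] ~ Normal(mu[t, i], sigma_o), rounded and clipped to [1, 100].

Defaults lam=0.9836, sigma_d=2.8, sigma_o=4 give slowly drifting arms whose
long-run mean is 50 points.  The latent means are never clipped; only the
displayed integer rewards are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "BanditSchedule",
    "SessionBlock",
    "generate_schedule",
    "relative_reward",
    "schedules_to_frame",
    "schedules_from_frame",
    "blocks_to_frame",
    "blocks_from_frame",
]

DEFAULT_LAM = 0.9836
DEFAULT_SIGMA_D = 2.8
DEFAULT_SIGMA_O = 4.0
WALK_CENTRE = 50.0
REWARD_MIN, REWARD_MAX = 1, 100


@dataclass
class BanditSchedule:
    """Per-trial, per-arm latent means and realized integer rewards."""

    n_trials: int
    n_arms: int
    lam: float
    sigma_d: float
    sigma_o: float
    mu: np.ndarray        # (n_trials, n_arms) latent means, unclipped
    rewards: np.ndarray   # (n_trials, n_arms) integer points in [1, 100]
    seed: int

    def __post_init__(self):
        if self.mu.shape != self.rewards.shape:
            raise ValueError("mu and rewards must have identical shape")
        if self.mu.shape != (self.n_trials, self.n_arms):
            raise ValueError("schedule matrices must be (n_trials, n_arms)")


@dataclass
class SessionBlock:
    """One participant-block: actions, rewards and a valid-trial mask."""

    participant_id: str
    block_id: str
    actions: np.ndarray   # int arm indices in {0..3}; -1 on missed trials
    rewards: np.ndarray   # integer points; 0 on missed trials
    valid: np.ndarray     # boolean mask
    schedule: BanditSchedule | None = field(default=None, repr=False)

    def __post_init__(self):
        n = len(self.actions)
        if not (len(self.rewards) == len(self.valid) == n):
            raise ValueError("actions, rewards, valid must share a length")

    @property
    def n_trials(self) -> int:
        return len(self.actions)

    def scaled_rewards(self) -> np.ndarray:
        """Rewards on the model scale, points/100 (in [0.01, 1])."""
        return self.rewards / 100.0


def generate_schedule(lam: float = DEFAULT_LAM, sigma_d: float = DEFAULT_SIGMA_D,
                      sigma_o: float = DEFAULT_SIGMA_O, n_trials: int = 150,
                      n_arms: int = 4, seed: int = 0,
                      mu0: np.ndarray | None = None) -> BanditSchedule:
    """Simulate one reward schedule from the Gaussian random walk.

    ``mu0`` overrides the uniform initialization of the trial-0 means (used
    by fixed-point and recovery tests).
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if sigma_d < 0 or sigma_o < 0:
        raise ValueError("sigma_d and sigma_o must be non-negative")
    if n_trials < 1 or n_arms < 1:
        raise ValueError("n_trials and n_arms must be positive")

    rng = np.random.default_rng(seed)
    mu = np.empty((n_trials, n_arms))
    if mu0 is None:
        mu[0] = rng.uniform(REWARD_MIN, REWARD_MAX, size=n_arms)
    else:
        mu[0] = np.asarray(mu0, dtype=float)
    for t in range(1, n_trials):
        drift = lam * mu[t - 1] + (1.0 - lam) * WALK_CENTRE
        mu[t] = drift + sigma_d * rng.standard_normal(n_arms)
    rewards = mu + sigma_o * rng.standard_normal((n_trials, n_arms))
    rewards = np.clip(np.rint(rewards), REWARD_MIN, REWARD_MAX).astype(int)
    return BanditSchedule(n_trials=n_trials, n_arms=n_arms, lam=lam,
                          sigma_d=sigma_d, sigma_o=sigma_o, mu=mu,
                          rewards=rewards, seed=seed)


def relative_reward(block: SessionBlock, schedule: BanditSchedule | None = None) -> float:
    """Mean per-trial reward normalized between random (0) and best arm (1).

    Each valid trial contributes (r_t - mean(p_t)) / (max(p_t) - mean(p_t)),
    where p_t is that trial's four-arm reward vector.  Trials on which all
    arms pay the same (max == mean) carry no information and are skipped.
    """
    if schedule is None:
        schedule = block.schedule
    if schedule is None:
        raise ValueError("block has no schedule attached; pass one explicitly")
    if block.n_trials != schedule.n_trials:
        raise ValueError("block and schedule trial counts differ")
    p = schedule.rewards.astype(float)
    p_max = p.max(axis=1)
    p_mean = p.mean(axis=1)
    spread = p_max - p_mean
    use = block.valid & (spread > 0)
    if not use.any():
        raise ValueError("relative reward undefined: no usable valid trials")
    r = block.rewards[use].astype(float)
    return float(np.mean((r - p_mean[use]) / spread[use]))


# -- delimited-text I/O (0-based trial and arm indices) ------------------

def schedules_to_frame(schedules: dict[str, BanditSchedule]) -> pd.DataFrame:
    """Long-format frame: ``schedule_id,trial,arm,mu,reward``."""
    rows = []
    for sid, sch in schedules.items():
        t_idx, a_idx = np.meshgrid(np.arange(sch.n_trials), np.arange(sch.n_arms),
                                   indexing="ij")
        rows.append(pd.DataFrame({
            "schedule_id": sid,
            "trial": t_idx.ravel(),
            "arm": a_idx.ravel(),
            "mu": sch.mu.ravel(),
            "reward": sch.rewards.ravel(),
        }))
    return pd.concat(rows, ignore_index=True)


def schedules_from_frame(frame: pd.DataFrame, lam: float = DEFAULT_LAM,
                         sigma_d: float = DEFAULT_SIGMA_D,
                         sigma_o: float = DEFAULT_SIGMA_O) -> dict[str, BanditSchedule]:
    out: dict[str, BanditSchedule] = {}
    for sid, grp in frame.groupby("schedule_id", sort=False):
        n_trials = int(grp["trial"].max()) + 1
        n_arms = int(grp["arm"].max()) + 1
        mu = np.empty((n_trials, n_arms))
        rewards = np.empty((n_trials, n_arms), dtype=int)
        mu[grp["trial"], grp["arm"]] = grp["mu"]
        rewards[grp["trial"], grp["arm"]] = grp["reward"]
        out[str(sid)] = BanditSchedule(n_trials=n_trials, n_arms=n_arms, lam=lam,
                                       sigma_d=sigma_d, sigma_o=sigma_o, mu=mu,
                                       rewards=rewards, seed=-1)
    return out


def blocks_to_frame(blocks: list[SessionBlock]) -> pd.DataFrame:
    """Long-format frame: ``participant_id,block_id,trial,action,reward,valid``."""
    rows = []
    for blk in blocks:
        rows.append(pd.DataFrame({
            "participant_id": blk.participant_id,
            "block_id": blk.block_id,
            "trial": np.arange(blk.n_trials),
            "action": blk.actions,
            "reward": blk.rewards,
            "valid": blk.valid.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)


def blocks_from_frame(frame: pd.DataFrame) -> list[SessionBlock]:
    blocks = []
    for (pid, bid), grp in frame.groupby(["participant_id", "block_id"], sort=False):
        grp = grp.sort_values("trial")
        blocks.append(SessionBlock(
            participant_id=str(pid), block_id=str(bid),
            actions=grp["action"].to_numpy(dtype=int),
            rewards=grp["reward"].to_numpy(dtype=int),
            valid=grp["valid"].to_numpy(dtype=bool),
        ))
    return blocks
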