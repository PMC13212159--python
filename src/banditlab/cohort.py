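"""Synthetic cohorts: heterogeneous agents on per-participant schedules.

Stands in for a human corpus with the same structure: N participants x B
blocks x 150 trials, a fresh reward schedule for every participant-block,
participant-level train/validation/test splits (a participant's blocks
never straddle splits) and optional missed trials.

Two teacher generators are provided:

* a Best-RL population with per-participant parameters drawn from
  documented priors (the default for recovery studies), and
* a hand-constructed Memory-ANN "rich-memory teacher" whose reward module
  tracks fast and slow reward traces (with saturation-based gain control)
  and whose action module emits a perseveration bump — behaviour that
  models with access only to choice variables cannot fully imitate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .bandit_task import (BanditSchedule, SessionBlock, blocks_from_frame,
                          blocks_to_frame, generate_schedule,
                          schedules_from_frame, schedules_to_frame,
                          DEFAULT_LAM, DEFAULT_SIGMA_D, DEFAULT_SIGMA_O)
from .models_base import MID_REWARD, N_ARMS, PolicyModel
from .rl_models import RLParams, TabularModel

__all__ = [
    "CohortSpec", "Dataset", "sample_agent_params", "simulate_block",
    "build_dataset", "save_dataset", "load_dataset", "rich_memory_teacher",
    "DEFAULT_PARAM_PRIOR",
]

# parameter support used for prior validation
_SUPPORT = {
    "alpha": (0.0, 1.0), "alpha_init": (0.0, 1.0), "f": (0.0, 1.0),
    "w": (0.0, 1.0), "b": (-1.0, 1.0), "kappa": (-1.0, 1.0),
    "beta": (0.0, np.inf), "q_init": (-np.inf, np.inf),
}

# Default Best-RL population prior for recovery studies.  Means sit at
# plausible bandit-task values (moderate learning rate, soft-greedy choice,
# mild forgetting and perseveration); spreads keep agents heterogeneous but
# inside interpretable ranges.
DEFAULT_PARAM_PRIOR: dict[str, dict] = {
    "alpha": {"family": "beta", "mean": 0.35, "concentration": 20},
    "beta": {"family": "lognormal", "mean_log": np.log(6.0), "sd_log": 0.3},
    "f": {"family": "beta", "mean": 0.15, "concentration": 30},
    "kappa": {"family": "point", "value": 0.1},
    "b": {"family": "point", "value": 0.0},
    "q_init": {"family": "normal", "mean": 0.5, "sd": 0.05},
}


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic dataset."""

    n_participants: int = 200
    blocks_per_participant: int = 2
    n_trials: int = 150
    generator_model: str = "best_rl"
    param_prior: dict = field(default_factory=lambda: dict(DEFAULT_PARAM_PRIOR))
    miss_rate: float = 0.0
    split_fracs: tuple[float, float, float] = (0.8, 0.1, 0.1)
    lam: float = DEFAULT_LAM
    sigma_d: float = DEFAULT_SIGMA_D
    sigma_o: float = DEFAULT_SIGMA_O
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split_fracs) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not (0.0 <= self.miss_rate < 1.0):
            raise ValueError("miss_rate must be in [0, 1)")


@dataclass
class Dataset:
    """Blocks, their schedules and the participant-level split assignment."""

    blocks: list[SessionBlock]
    schedules: dict[str, BanditSchedule]
    split_assignment: dict[str, str]   # participant_id -> train/validation/test
    provenance: CohortSpec | str = "external"

    def split_blocks(self, split: str) -> list[SessionBlock]:
        return [b for b in self.blocks
                if self.split_assignment[b.participant_id] == split]

    def participants(self) -> list[str]:
        seen = dict.fromkeys(b.participant_id for b in self.blocks)
        return list(seen)


def sample_agent_params(param_prior: dict[str, dict], seed) -> RLParams:
    """Draw one agent's constrained parameters from per-parameter priors.

    Families: ``point`` (value), ``beta`` (mean, concentration; support
    (0,1)), ``uniform`` (lo, hi; must sit inside the parameter's support),
    ``lognormal`` (mean_log, sd_log; positive parameters) and ``normal``
    (mean, sd; unbounded parameters only).
    """
    rng = np.random.default_rng(seed)
    values = {}
    for name, spec in param_prior.items():
        if name not in _SUPPORT:
            raise ValueError(f"unknown parameter {name!r}")
        lo, hi = _SUPPORT[name]
        fam = spec["family"]
        if fam == "point":
            x = float(spec["value"])
            if not (lo <= x <= hi):
                raise ValueError(f"point mass {x} outside support of {name}")
        elif fam == "beta":
            if (lo, hi) != (0.0, 1.0):
                raise ValueError(f"beta prior requires (0,1) support, not {name}")
            mean, conc = spec["mean"], spec["concentration"]
            x = float(rng.beta(mean * conc, (1 - mean) * conc))
        elif fam == "uniform":
            u_lo, u_hi = spec["lo"], spec["hi"]
            if u_lo < lo or u_hi > hi:
                raise ValueError(f"uniform({u_lo},{u_hi}) exceeds support of {name}")
            x = float(rng.uniform(u_lo, u_hi))
        elif fam == "lognormal":
            if lo < 0:
                raise ValueError(f"lognormal prior invalid for signed {name}")
            x = float(rng.lognormal(spec["mean_log"], spec["sd_log"]))
        elif fam == "normal":
            if np.isfinite(lo) or np.isfinite(hi):
                raise ValueError(f"normal prior invalid for bounded {name}")
            x = float(rng.normal(spec["mean"], spec["sd"]))
        else:
            raise ValueError(f"unknown prior family {fam!r}")
        values[name] = x
    return RLParams(**values)


def simulate_block(model: PolicyModel, params: dict[str, np.ndarray],
                   schedule: BanditSchedule, miss_rate: float = 0.0,
                   seed=0, participant_id: str = "sim",
                   block_id: str = "b0", return_latents: bool = False):
    """Open-loop simulation: the model samples its own actions.

    On each trial the action is drawn from the model's softmax policy and
    the reward is read from the schedule.  Missed trials occur with
    probability ``miss_rate``; the latent update for a missed trial is
    skipped (state carried forward unchanged).  With ``return_latents`` the
    per-trial state arrays of the generating run are returned alongside the
    block (for open/closed-loop consistency checks).
    """
    rng = np.random.default_rng(seed)
    T = schedule.n_trials
    params_t = {k: Tensor(v) for k, v in params.items()}
    ctx = model.prepare(params_t)
    state = model.init_state(ctx, 1)
    actions = np.full(T, -1, dtype=int)
    rewards = np.zeros(T, dtype=int)
    valid = np.zeros(T, dtype=bool)
    prev = (np.zeros((1, N_ARMS)), np.full((1, 1), MID_REWARD), np.ones((1, 1)))
    latents: dict[str, list[np.ndarray]] = {}
    for t in range(T):
        state = model.update(ctx, state, Tensor(prev[0]), Tensor(prev[1]),
                             Tensor(prev[2]))
        if return_latents:
            for k, v in state.items():
                latents.setdefault(k, []).append(v.data[0].copy())
        logits = model.logits(ctx, state).data[0]
        z = logits - logits.max()
        p = np.exp(z)
        p /= p.sum()
        if rng.random() < miss_rate:
            prev = (np.zeros((1, N_ARMS)), np.full((1, 1), MID_REWARD),
                    np.zeros((1, 1)))
            continue
        a = int(rng.choice(N_ARMS, p=p))
        actions[t] = a
        rewards[t] = schedule.rewards[t, a]
        valid[t] = True
        oh = np.zeros((1, N_ARMS))
        oh[0, a] = 1.0
        prev = (oh, np.array([[rewards[t] / 100.0]]), np.ones((1, 1)))
    block = SessionBlock(participant_id=participant_id, block_id=block_id,
                         actions=actions, rewards=rewards, valid=valid,
                         schedule=schedule)
    if return_latents:
        return block, {k: np.stack(v) for k, v in latents.items()}
    return block


def _teacher(spec: CohortSpec):
    """Resolve the generator model named in a cohort spec."""
    if spec.generator_model == "rich_memory":
        model, params = rich_memory_teacher()
        return model, (lambda seed: params)
    from .rl_models import variant_by_name
    model = TabularModel(variant_by_name(spec.generator_model))

    def params_for(seed):
        agent = sample_agent_params(spec.param_prior, seed)
        return model.params_from_values(agent)
    return model, params_for


def build_dataset(spec: CohortSpec) -> Dataset:
    """Generate a full dataset: schedules, behaviour, splits."""
    n_test = max(1, round(spec.n_participants * spec.split_fracs[2]))
    n_val = max(1, round(spec.n_participants * spec.split_fracs[1]))
    n_train = spec.n_participants - n_test - n_val
    if n_train < 1:
        raise ValueError("too few participants for non-empty splits")

    root = np.random.SeedSequence(spec.seed)
    split_rng = np.random.default_rng(root.spawn(1)[0])
    model, params_for = _teacher(spec)

    pids = [f"P{i:04d}" for i in range(spec.n_participants)]
    order = split_rng.permutation(spec.n_participants)
    split_assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            split_assignment[pids[idx]] = "train"
        elif rank < n_train + n_val:
            split_assignment[pids[idx]] = "validation"
        else:
            split_assignment[pids[idx]] = "test"

    blocks: list[SessionBlock] = []
    schedules: dict[str, BanditSchedule] = {}
    child = root.spawn(spec.n_participants)
    for i, pid in enumerate(pids):
        seeds = child[i].generate_state(2 * spec.blocks_per_participant + 1)
        agent_params = params_for(int(seeds[-1] % 2**31))
        for blk in range(spec.blocks_per_participant):
            sched_seed = int(seeds[2 * blk] % 2**31)
            sim_seed = int(seeds[2 * blk + 1] % 2**31)
            sched = generate_schedule(spec.lam, spec.sigma_d, spec.sigma_o,
                                      spec.n_trials, N_ARMS, seed=sched_seed)
            bid = f"{pid}-B{blk}"
            schedules[bid] = sched
            blocks.append(simulate_block(model, agent_params, sched,
                                         miss_rate=spec.miss_rate, seed=sim_seed,
                                         participant_id=pid, block_id=bid))
    return Dataset(blocks=blocks, schedules=schedules,
                   split_assignment=split_assignment, provenance=spec)


# ---------------------------------------------------------------------------
# directory I/O: blocks CSV + schedules CSV + JSON manifest

def save_dataset(dataset: Dataset, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    blocks_to_frame(dataset.blocks).to_csv(outdir / "blocks.csv", index=False)
    schedules_to_frame(dataset.schedules).to_csv(outdir / "schedules.csv",
                                                 index=False)
    prov = dataset.provenance
    manifest = {
        "split_assignment": dataset.split_assignment,
        "spec": asdict(prov) if isinstance(prov, CohortSpec) else prov,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_dataset(outdir: str | Path) -> Dataset:
    import pandas as pd

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    spec = manifest["spec"]
    if isinstance(spec, dict):
        spec["split_fracs"] = tuple(spec["split_fracs"])
        spec = CohortSpec(**spec)
    blocks = blocks_from_frame(pd.read_csv(outdir / "blocks.csv"))
    schedules = schedules_from_frame(pd.read_csv(outdir / "schedules.csv"))
    for blk in blocks:
        blk.schedule = schedules.get(blk.block_id)
    return Dataset(blocks=blocks, schedules=schedules,
                   split_assignment=manifest["split_assignment"],
                   provenance=spec)


# ---------------------------------------------------------------------------
# the rich-memory teacher

def rich_memory_teacher(kappa: float = 1.0, scale: float = 8.0):
    """A hand-constructed Memory-ANN with genuine multi-timescale memory.

    Reward module (8 hidden units; inputs [r, s]):

    All reward traces have unit DC gain (drive = 1 - decay), so their
    relative influence on sustained versus transient rewards is explicit:

    * unit 0: fast reward trace   s0' = tanh(0.5*s0 + 0.5*(r - 0.5)),
      kept in the tanh linear regime so the chosen-arm update stays close
      to an incremental delta rule,
    * unit 1: slow reward trace   s1' = tanh(0.99*s1 + 0.01*(r - 0.5)),
      a ~100-trial baseline of how reward-rich the task is overall,
    * unit 2: saturating gain unit s2' = tanh(3.0*s1 + 0.5*(r - 0.5)) —
      when the slow trace is high the unit saturates and loses reward
      sensitivity, so the value written for the chosen arm depends on the
      long-run reward baseline in a way no choice-variable summary carries,
    * unit 3: medium reward trace s3' = tanh(0.9*s3 + 0.1*(r - 0.5)),
      a ~10-trial global baseline close to the value-decay timescale, so
      the mean of the value vector is an informative proxy for it —
      information available to context-conditioned models but not to
      models that only see the chosen action's value.

    Chosen-arm value logit:
    Q = scale*(0.5 + 1.2*s0 - 0.25*s1 + 0.4*s2 - 0.45*s3),
    a relative-reward code: values reflect how much better a reward is
    than the recent and long-run norms, with sensitivity controlled by
    the slow-trace gain unit.
    (``scale`` plays the role of an inverse temperature, absorbed into the
    readout as in any trained network); unchosen arms decay toward
    Q_init = scale*0.5 at rate f ~ 0.12.

    Action module: four steep-threshold units turn the scalar action code
    into a one-hot bump; the output adds ``kappa`` to the previously
    chosen action's logit (plain perseveration).

    Returns (MemoryANN instance, parameter dict).
    """
    from .hybrid_models import MemoryANN, ACTION_CODES

    H = 8
    model = MemoryANN(hidden_size=H)
    rng = np.random.default_rng(0)
    params = model.init_params(rng)
    for k in ("W1r", "b1r", "W2r", "W1a", "b1a", "W2a"):
        params[k] = np.zeros_like(params[k])
    params["b2r"] = np.zeros(1)
    params["b2a"] = np.zeros(N_ARMS)

    W1r, b1r = params["W1r"], params["b1r"]   # (1+H, H), (H,)
    # rows: 0 = reward input, 1+j = recurrent from unit j
    W1r[0, 0], W1r[1 + 0, 0], b1r[0] = 0.5, 0.50, -0.5 * 0.5
    W1r[0, 1], W1r[1 + 1, 1], b1r[1] = 0.01, 0.99, -0.01 * 0.5
    W1r[0, 2], W1r[1 + 1, 2], b1r[2] = 0.5, 3.0, -0.5 * 0.5
    W1r[0, 3], W1r[1 + 3, 3], b1r[3] = 0.10, 0.90, -0.10 * 0.5
    params["W2r"] = np.zeros((H, 1))
    params["W2r"][[0, 1, 2, 3], 0] = np.array([1.2, -0.25, 0.4, -0.45]) * scale
    params["b2r"][0] = 0.5 * scale

    # action side: steep steps between the scalar action codes
    steep = 30.0
    thresholds = np.concatenate([[ACTION_CODES[0] - 0.125],
                                 0.5 * (ACTION_CODES[1:] + ACTION_CODES[:-1])])
    W1a, b1a = params["W1a"], params["b1a"]   # (1+H, H)
    for j, th in enumerate(thresholds):
        W1a[0, j] = steep
        b1a[j] = -steep * th
    W2a = np.zeros((H, N_ARMS))
    for j in range(N_ARMS):
        W2a[j, j] = 0.5 * kappa
        if j + 1 < N_ARMS:
            W2a[j + 1, j] = -0.5 * kappa
    params["W2a"] = W2a
    params["b2a"][N_ARMS - 1] = 0.5 * kappa

    params["f_raw"] = np.array(-2.0)     # sigmoid -> f ~ 0.12
    params["q_init"] = np.array(0.5 * scale)
    return model, params
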