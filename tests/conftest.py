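import numpy as np
import pytest

from banditlab.bandit_task import SessionBlock, generate_schedule
from banditlab.cohort import CohortSpec, build_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """Tiny Best-RL cohort shared by I/O, fitting and latent tests."""
    return build_dataset(CohortSpec(n_participants=10, blocks_per_participant=2,
                                    n_trials=40, miss_rate=0.05, seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_block(actions, rewards=None, valid=None, pid="p0", bid="b0"):
    """Construct a SessionBlock from plain sequences (rewards default 50)."""
    actions = np.asarray(actions, dtype=int)
    if rewards is None:
        rewards = np.full(len(actions), 50, dtype=int)
    if valid is None:
        valid = np.ones(len(actions), dtype=bool)
    return SessionBlock(participant_id=pid, block_id=bid, actions=actions,
                        rewards=np.asarray(rewards, dtype=int),
                        valid=np.asarray(valid, dtype=bool))
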