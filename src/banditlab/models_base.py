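"""Shared step interface for all choice models (tabular and neural).

Every model exposes the same contract, which the fitting, simulation and
interpretability code relies on:

* ``init_params(rng)`` -> dict of named numpy parameter arrays (leaves).
* ``init_state(params, batch)`` -> dict of named state tensors for a batch
  of blocks (values ``Q``, perseveration ``c``, hidden states where the
  architecture has them).
* ``update(params, state, oh, r, m)`` -> next state, where ``oh`` is the
  previous trial's action as a one-hot ``(B, 4)`` row (all zeros when there
  is no previous action), ``r`` is the previous scaled reward ``(B, 1)``
  (0.5 mid-scale placeholder when there is none) and ``m`` is a ``(B, 1)``
  mask that is 0 when the previous trial was missed, in which case the
  latent update is skipped and state is carried forward unchanged.
* ``logits(params, state)`` -> ``(B, 4)`` pre-softmax action preferences
  for the upcoming choice.

The first trial of a block is included in the likelihood: its logits are
read from the state produced by one update with the placeholder inputs.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

N_ARMS = 4
MID_REWARD = 0.5  # placeholder scaled reward when no previous trial exists

__all__ = ["PolicyModel", "N_ARMS", "MID_REWARD"]


class PolicyModel:
    """Abstract base: a trial-by-trial policy over four arms."""

    name: str = "policy_model"

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def decay_param_names(self) -> set[str]:
        """Parameter names subject to L2 weight decay (network weights)."""
        return set()

    def prepare(self, params: dict[str, Tensor]) -> dict:
        """Per-unroll precomputation (e.g. parameter transforms).

        The returned context is what ``init_state``/``update``/``logits``
        receive as their first argument, so transforms are evaluated once
        per block batch rather than once per trial.
        """
        return params

    def init_state(self, params: dict[str, Tensor], batch: int) -> dict[str, Tensor]:
        raise NotImplementedError

    def update(self, params: dict[str, Tensor], state: dict[str, Tensor],
               oh: Tensor, r: Tensor, m: Tensor) -> dict[str, Tensor]:
        raise NotImplementedError

    def logits(self, params: dict[str, Tensor], state: dict[str, Tensor]) -> Tensor:
        raise NotImplementedError
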