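"""Adam optimizer with decoupled L2 weight decay, on plain numpy arrays."""

from __future__ import annotations

import numpy as np

__all__ = ["Adam"]


class Adam:
    """First-order adaptive stochastic gradient descent (Adam).

    Parameters
    ----------
    params
        Mapping name -> ndarray; arrays are updated in place.
    step_size
        Optimizer step size (often called the optimizer learning rate).
    weight_decay
        Decoupled L2 decay applied each step to parameters whose name is in
        ``decay_names`` (typically network weights, not cognitive parameters).
    """

    def __init__(self, params: dict[str, np.ndarray], step_size: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_names: set[str] | None = None):
        self.params = params
        self.step_size = step_size
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.decay_names = decay_names if decay_names is not None else set(params)
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, p in self.params.items():
            g = grads.get(name)
            if g is None:
                continue
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            p -= self.step_size * m_hat / (np.sqrt(v_hat) + self.eps)
            if self.weight_decay and name in self.decay_names:
                p -= self.step_size * self.weight_decay * p
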