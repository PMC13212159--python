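"""Tabular Q-learning model family: update rules, transforms, variant grid.

The family is built from a small set of mechanisms layered on a delta-rule
value update:

* value update with optional additive bias ``b``:
  Q(a) <- Q(a) + alpha * (r - Q(a)) + b
* perseveration: a choice-kernel vector ``c`` whose entry for the
  previously chosen action is set to ``kappa`` (positive = repeat,
  negative = switch) and 0 elsewhere
* forgetting: exponential decay of action values back to the initial value
  Q_init, Q <- (1 - f) * Q + f * Q_init, applied to the unchosen arms by
  default (optionally to all arms)
* Pearce-Hall variable learning rate: alpha_{t+1} = w*|delta| + (1-w)*alpha_t

Action probabilities are softmax(beta * (Q + c)).  Rewards enter on the
points/100 scale, so |delta| <= 1 and the variable-learning-rate update
stays inside [0, 1].

``enumerate_variants`` spans a 48-model grid; ``SIMPLE_RL`` (alpha, beta
only) and ``BEST_RL`` (alpha, beta, f, kappa, b, Q_init) are its named
anchor points.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .models_base import N_ARMS, PolicyModel

__all__ = [
    "RLParams", "VariantSpec", "TabularModel",
    "q_update", "apply_forgetting", "perseveration_update",
    "variable_lr_step", "policy", "transform_params", "inverse_transform_params",
    "enumerate_variants", "SIMPLE_RL", "BEST_RL", "variant_by_name",
]

DEFAULT_Q_INIT = 0.5  # mid-scale initialization when Q_init is not free


# ---------------------------------------------------------------------------
# parameters and variants

@dataclass(frozen=True)
class RLParams:
    """Constrained Q-learning parameters (after transform)."""

    alpha: float = 0.3          # learning rate, (0, 1)
    beta: float = 5.0           # inverse temperature, (0, inf)
    b: float = 0.0              # additive update bias, (-1, 1)
    kappa: float = 0.0          # perseveration strength, (-1, 1)
    f: float = 0.0              # forgetting rate, (0, 1)
    q_init: float = DEFAULT_Q_INIT  # initial value / decay target
    alpha_init: float = 0.3     # initial learning rate (variable-LR variants)
    w: float = 0.0              # learning-rate weighting, (0, 1)


@dataclass(frozen=True)
class VariantSpec:
    """Which mechanisms a Q-learning variant activates."""

    name: str
    bias: bool = False
    perseveration: bool = False
    forgetting: str = "off"      # "off" | "unchosen" | "all"
    free_q_init: bool = False
    variable_lr: bool = False

    def __post_init__(self):
        if self.forgetting not in ("off", "unchosen", "all"):
            raise ValueError(f"unknown forgetting scope {self.forgetting!r}")

    @property
    def free_params(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.variable_lr:
            names += ["alpha_init", "w"]
        else:
            names += ["alpha"]
        names += ["beta"]
        if self.bias:
            names += ["b"]
        if self.perseveration:
            names += ["kappa"]
        if self.forgetting != "off":
            names += ["f"]
        if self.free_q_init:
            names += ["q_init"]
        return tuple(names)

    @property
    def n_free(self) -> int:
        return len(self.free_params)


SIMPLE_RL = VariantSpec(name="simple_rl")
BEST_RL = VariantSpec(name="best_rl", bias=True, perseveration=True,
                      forgetting="unchosen", free_q_init=True)


def enumerate_variants() -> list[VariantSpec]:
    """The default 48-variant grid of Q-learning mechanisms.

    Full factorial over bias x perseveration x free-Q_init x variable
    learning rate (2^4) crossed with the forgetting scope
    {off, unchosen arms, all arms} (x3), i.e. 48 variants.  The scope axis
    makes the two published readings of the decay rule (decay of unchosen
    values vs. decay of all values) explicit alternatives in the grid.
    """
    variants = []
    for bias in (False, True):
        for pers in (False, True):
            for fq in (False, True):
                for vlr in (False, True):
                    for scope in ("off", "unchosen", "all"):
                        spec = VariantSpec(name="", bias=bias, perseveration=pers,
                                           forgetting=scope, free_q_init=fq,
                                           variable_lr=vlr)
                        if spec == replace(SIMPLE_RL, name=""):
                            name = "simple_rl"
                        elif spec == replace(BEST_RL, name=""):
                            name = "best_rl"
                        else:
                            bits = [
                                "b" if bias else "",
                                "k" if pers else "",
                                {"off": "", "unchosen": "fu", "all": "fa"}[scope],
                                "q" if fq else "",
                                "w" if vlr else "",
                            ]
                            name = "rl_" + ("".join(bits) or "plain")
                        variants.append(replace(spec, name=name))
    return variants


def variant_by_name(name: str) -> VariantSpec:
    for v in enumerate_variants():
        if v.name == name:
            return v
    raise KeyError(f"unknown variant {name!r}")


# ---------------------------------------------------------------------------
# elementary update rules (numpy; these also serve as the reference path
# against which the batched training graph is checked)

def q_update(q_a: float, r: float, alpha: float, b: float = 0.0) -> float:
    """Biased delta-rule update of the chosen action's value."""
    return q_a + alpha * (r - q_a) + b


def apply_forgetting(q: np.ndarray, chosen_arm: int | None, f: float,
                     q_init: float, decay_scope: str = "unchosen") -> np.ndarray:
    """Exponential decay of action values back to ``q_init``.

    ``decay_scope`` "unchosen" spares the arm about to be updated;
    "all" decays every arm; "off" is the identity.
    """
    if not (0.0 <= f <= 1.0):
        raise ValueError("f must be in [0, 1]")
    q = np.array(q, dtype=float)
    if decay_scope == "off":
        return q
    scope = np.ones_like(q, dtype=bool)
    if decay_scope == "unchosen" and chosen_arm is not None:
        scope[chosen_arm] = False
    q[scope] = (1.0 - f) * q[scope] + f * q_init
    return q


def perseveration_update(chosen_arm: int, kappa: float, n_arms: int = N_ARMS) -> np.ndarray:
    """Choice-kernel vector: ``kappa`` at the chosen arm, 0 elsewhere."""
    c = np.zeros(n_arms)
    c[chosen_arm] = kappa
    return c


def variable_lr_step(q_a: float, r: float, alpha_t: float, w: float) -> tuple[float, float, float]:
    """Pearce-Hall step: returns (updated q_a, next alpha, delta)."""
    delta = r - q_a
    q_new = q_a + alpha_t * delta
    alpha_next = w * abs(delta) + (1.0 - w) * alpha_t
    return q_new, alpha_next, delta


def policy(q: np.ndarray, c: np.ndarray | None, beta: float) -> np.ndarray:
    """softmax(beta * (q + c)); invariant to common logit shifts."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    h = np.asarray(q, dtype=float)
    if c is not None:
        h = h + np.asarray(c, dtype=float)
    z = beta * h
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


# ---------------------------------------------------------------------------
# parameter transforms

def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _softplus(x):
    return np.logaddexp(0.0, x)


def _inv_softplus(y):
    # log(e^y - 1), stable for small and large y
    return y + np.log(-np.expm1(-y))


_TRANSFORMS = {
    "alpha": (_sigmoid, lambda y: np.log(y / (1 - y))),
    "alpha_init": (_sigmoid, lambda y: np.log(y / (1 - y))),
    "f": (_sigmoid, lambda y: np.log(y / (1 - y))),
    "w": (_sigmoid, lambda y: np.log(y / (1 - y))),
    "b": (np.tanh, np.arctanh),
    "kappa": (np.tanh, np.arctanh),
    "beta": (_softplus, _inv_softplus),
    "q_init": (lambda x: x, lambda y: y),
}


def transform_params(raw: np.ndarray, variant: VariantSpec) -> RLParams:
    """Map an unconstrained raw vector to constrained parameters.

    Sigmoid for rates in (0, 1), tanh for signed strengths in (-1, 1),
    softplus for beta in (0, inf); Q_init passes through unrestricted.
    """
    raw = np.asarray(raw, dtype=float)
    names = variant.free_params
    if raw.shape != (len(names),):
        raise ValueError(f"raw vector length {raw.shape} does not match "
                         f"{len(names)} free parameters of {variant.name}")
    values = {n: float(_TRANSFORMS[n][0](x)) for n, x in zip(names, raw)}
    if variant.variable_lr:
        values.setdefault("alpha", values["alpha_init"])
    return RLParams(**values)


def inverse_transform_params(params: RLParams, variant: VariantSpec) -> np.ndarray:
    """Inverse of :func:`transform_params` (exact round-trip)."""
    return np.array([_TRANSFORMS[n][1](getattr(params, n))
                     for n in variant.free_params])


# ---------------------------------------------------------------------------
# the trainable model

class TabularModel(PolicyModel):
    """A Q-learning variant behind the unified step interface.

    Free parameters live as unconstrained scalars and are pushed through
    the same transforms during the forward pass, so the model can be
    fitted by the same gradient machinery as the networks.
    """

    def __init__(self, variant: VariantSpec):
        self.variant = variant
        self.name = variant.name

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        raws = {}
        for n in self.variant.free_params:
            if n == "q_init":
                raws[n] = np.array(DEFAULT_Q_INIT + 0.1 * rng.standard_normal())
            else:
                raws[n] = np.array(0.5 * rng.standard_normal())
        return raws

    def params_from_values(self, params: RLParams) -> dict[str, np.ndarray]:
        raw = inverse_transform_params(params, self.variant)
        return {n: np.array(x) for n, x in zip(self.variant.free_params, raw)}

    def constrained(self, params: dict[str, np.ndarray | Tensor]) -> RLParams:
        vals = {}
        for n in self.variant.free_params:
            x = params[n]
            x = x.data if isinstance(x, Tensor) else x
            vals[n] = float(_TRANSFORMS[n][0](float(x)))
        if self.variant.variable_lr:
            vals.setdefault("alpha", vals["alpha_init"])
        return RLParams(**vals)

    # -- graph-side transforms ------------------------------------------

    def _constrained_tensors(self, params: dict[str, Tensor]) -> dict[str, Tensor]:
        v = self.variant
        out: dict[str, Tensor] = {}
        out["beta"] = params["beta"].softplus()
        if v.variable_lr:
            out["alpha_init"] = params["alpha_init"].sigmoid()
            out["w"] = params["w"].sigmoid()
        else:
            out["alpha"] = params["alpha"].sigmoid()
        out["b"] = params["b"].tanh() if v.bias else Tensor(0.0)
        out["kappa"] = params["kappa"].tanh() if v.perseveration else Tensor(0.0)
        out["f"] = params["f"].sigmoid() if v.forgetting != "off" else Tensor(0.0)
        out["q_init"] = params["q_init"] if v.free_q_init else Tensor(DEFAULT_Q_INIT)
        return out

    # -- unified step interface ------------------------------------------

    def prepare(self, params: dict[str, Tensor]) -> dict:
        return self._constrained_tensors(params)

    def init_state(self, cp: dict, batch: int) -> dict[str, Tensor]:
        state = {"q": cp["q_init"] * Tensor(np.ones((batch, N_ARMS)))}
        if self.variant.perseveration:
            state["c"] = Tensor(np.zeros((batch, N_ARMS)))
        if self.variant.variable_lr:
            state["alpha"] = cp["alpha_init"] * Tensor(np.ones((batch, 1)))
        return state

    def update(self, cp, state, oh, r, m):
        v = self.variant
        q = state["q"]
        ch = oh.sum(axis=1, keepdims=True)  # 1 iff a previous action exists

        # (1) decay toward q_init on the configured scope
        if v.forgetting == "unchosen":
            scope = 1.0 - oh.data  # constant w.r.t. parameters
            q_dec = q + Tensor(scope) * (cp["f"] * (cp["q_init"] - q))
        elif v.forgetting == "all":
            q_dec = q + cp["f"] * (cp["q_init"] - q)
        else:
            q_dec = q

        # (2) delta-rule update of the chosen arm from its post-decay value
        q_a = (q_dec * oh).sum(axis=1, keepdims=True)
        delta = r - q_a
        alpha_t = state["alpha"] if v.variable_lr else cp["alpha"]
        upd = alpha_t * delta                      # q_new(a) - q_dec(a) ...
        if v.bias:
            upd = upd + cp["b"]                    # ... plus the bias offset
        q_next = q_dec + oh * upd

        # gate: no previous valid action -> state carried forward unchanged
        # (with forgetting off, oh == 0 already leaves q untouched)
        if v.forgetting == "off":
            new_state = {"q": q_next}
        else:
            new_state = {"q": ch * q_next + (1.0 - ch) * q}

        # (3) perseveration overwrite of the choice kernel
        if v.perseveration:
            new_state["c"] = ch * (cp["kappa"] * oh) + (1.0 - ch) * state["c"]
        if v.variable_lr:
            alpha_next = cp["w"] * delta.abs() + (1.0 - cp["w"]) * alpha_t
            new_state["alpha"] = ch * alpha_next + (1.0 - ch) * alpha_t
        return new_state

    def logits(self, cp, state):
        if self.variant.perseveration:
            return cp["beta"] * (state["q"] + state["c"])
        return cp["beta"] * state["q"]
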