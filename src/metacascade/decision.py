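"""Sigmoid/softmax readout of the attractor decision network.

The winner-take-all competition between action-selective populations is
summarized by its known sigmoid approximation: the probability of choosing
an action is a logistic function of the difference in total synaptic
strength between the candidate populations, with a single temperature
parameter ``T`` absorbing the network noise (input rates are rescaled so
``nu * N = 1``).  For more than two actions the softmax of strengths at the
same temperature is used, which reduces exactly to the sigmoid for two.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cascade import CascadeState

__all__ = ["DecisionParams", "synaptic_strength", "choice_probability", "sample_choice"]


@dataclass(frozen=True)
class DecisionParams:
    """Noise temperature of the decision network (T > 0)."""

    T: float = 0.1

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("temperature T must be > 0")


def synaptic_strength(state: CascadeState, action: int | None = None) -> np.ndarray:
    """Normalized total synaptic strength ``<w>_a``: the potentiated mass.

    With ``action=None`` returns strengths for all actions, shape
    ``(..., n_actions)``.
    """
    w = state.f_plus.sum(axis=-1)
    if action is not None:
        w = w[..., action]
    return w if np.ndim(w) else float(w)


def choice_probability(state: CascadeState, params: DecisionParams) -> np.ndarray:
    """Choice probability vector, shape ``(..., n_actions)``.

    Softmax of synaptic strengths at temperature ``T``; for two actions this
    is the sigmoid of the strength difference.
    """
    w = state.f_plus.sum(axis=-1) / params.T
    w -= w.max(axis=-1, keepdims=True)
    e = np.exp(w)
    return e / e.sum(axis=-1, keepdims=True)


def sample_choice(prob, rng: np.random.Generator) -> np.ndarray:
    """Categorical draw per run from probability vectors ``(..., n_actions)``."""
    p = np.asarray(prob, dtype=float)
    c = p.cumsum(axis=-1)
    c /= c[..., -1:]
    u = rng.random(p.shape[:-1] + (1,))
    out = (c < u).sum(axis=-1)
    return out if out.ndim else int(out)
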