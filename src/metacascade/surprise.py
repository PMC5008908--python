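"""Surprise detection from multi-timescale reward monitors.

A bank of simple (non-metaplastic) bounded binary synapse populations tracks
the incoming reward rate on several fixed timescales: population ``i`` has a
fixed plasticity rate ``alpha_i`` taken from the cascade ladder, and its
potentiated fraction ``v_i`` is a leaky average of rewards with time constant
``1/alpha_i`` trials, updated independently of which action was chosen.

For every monitored pair (fast ``f``, slow ``s``) the bank maintains the
*expected uncertainty* ``u_{f,s}`` — a leaky average (at the slower rate) of
the absolute fast-slow discrepancy ``|v_f - v_s|`` — and compares it each
trial with the current discrepancy (the *unexpected* uncertainty).  When the
fast estimate has dropped below the slow one by significantly more than
expected — the one-sided Gaussian tail of ``(v_s - v_f)`` at scale ``u`` falls
below the threshold ``h`` — a surprise is asserted and the cascade synapses
at levels up to the pair's slow timescale have their plasticity boosted.
Increases in reward rate never trigger a surprise.

A pair's test is *armed* only after its expected uncertainty has had two full
timescales (``2/min(alpha)`` trials) of learning, i.e. once the leaky average
defining the baseline is within ~15% of its asymptote: before that the
baseline is still dominated by the ignorant initial conditions (monitors
start at 0.5, ``u`` at 0) and a comparison against it is meaningless.  Deep
pairs therefore come online progressively, at the same pace at which the
system becomes able to consolidate memory on their timescales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import erfc

from .cascade import CascadeParams

__all__ = [
    "SurpriseParams",
    "MonitorBank",
    "monitor_update",
    "uncertainty_update",
    "detect_surprise",
    "step_surprise_system",
]


@dataclass(frozen=True)
class SurpriseParams:
    """Threshold and conventions of the surprise test.

    ``h`` is the one-sided tail-probability threshold, in ``(0, 0.5)`` so
    that reward-rate increases can never fire.  ``epsilon`` floors the
    expected uncertainty in the test, defining behavior at t=0.
    ``boost_rule`` selects which cascade levels a firing pair boosts:
    ``"slow"`` boosts every level up to the pair's slow timescale (deepest
    slow level over simultaneously firing pairs), ``"fast"`` only up to the
    fast timescale (shallowest fast level over firing pairs).
    """

    h: float = 0.05
    epsilon: float = 1e-6
    boost_rule: str = "slow"

    def __post_init__(self):
        if not 0 < self.h < 0.5:
            raise ValueError("h must be in (0, 0.5)")
        if self.boost_rule not in ("slow", "fast"):
            raise ValueError("boost_rule must be 'slow' or 'fast'")


@dataclass
class MonitorBank:
    """State of the reward-rate monitors and pairwise expected uncertainties.

    ``levels`` are the 1-based cascade depth levels the monitors correspond
    to; ``alphas_r`` / ``alphas_nr`` their plasticity rates after reward /
    no-reward.  ``g_plus[..., i]`` is the potentiated fraction (readout
    ``v_i``) of monitor ``i``; ``u[..., q]`` the expected uncertainty of pair
    ``q = (pairs_fast[q], pairs_slow[q])``; ``active[..., q]`` whether that
    pair's surprise condition currently holds.
    """

    levels: np.ndarray
    alphas_r: np.ndarray
    alphas_nr: np.ndarray
    pairs_fast: np.ndarray
    pairs_slow: np.ndarray
    g_plus: np.ndarray
    u: np.ndarray
    active: np.ndarray
    trials_seen: int = 0

    @classmethod
    def from_cascade(cls, params: CascadeParams, levels=None, pair_set=None,
                     pair_window: int = 2, n_runs: int = 1) -> "MonitorBank":
        """Build monitors matching cascade ladder levels.

        ``levels`` defaults to all ``m`` cascade levels (one monitor per
        ladder rate).  ``pair_set`` defaults to all (fast, slow) pairs within
        ``pair_window`` levels of each other: an anomaly on a given timescale
        is detected by comparing that timescale's monitor with its nearest
        neighbors, which also bounds the reach of a false alarm to the depth
        at which it was (mis)detected.  ``pair_window=None`` compares all
        pairs.
        """
        if levels is None:
            levels = tuple(range(1, params.m + 1))
        levels = np.asarray(levels, dtype=int)
        if np.any(levels < 1) or np.any(levels > params.m):
            raise ValueError("monitor levels must lie within the cascade depth")
        if np.any(np.diff(levels) <= 0):
            raise ValueError("monitor levels must be strictly increasing")
        k = levels.size
        if pair_set is None:
            stop = (lambda i: k) if pair_window is None else (
                lambda i: min(i + pair_window + 1, k))
            pair_set = [(i, j) for i in range(k) for j in range(i + 1, stop(i))]
        pf = np.array([p[0] for p in pair_set], dtype=int)
        ps = np.array([p[1] for p in pair_set], dtype=int)
        if np.any(pf >= ps):
            raise ValueError("pairs must be (fast, slow) with fast index < slow index")
        return cls(
            levels=levels,
            alphas_r=params.alpha_r[levels - 1],
            alphas_nr=params.alpha_nr[levels - 1],
            pairs_fast=pf,
            pairs_slow=ps,
            g_plus=np.full((n_runs, k), 0.5),
            u=np.zeros((n_runs, pf.size)),
            active=np.zeros((n_runs, pf.size), dtype=bool),
        )

    @property
    def v(self) -> np.ndarray:
        """Monitor readouts (normalized synaptic strengths)."""
        return self.g_plus

    @property
    def pair_timescales(self) -> np.ndarray:
        """Learning timescale (trials) of each pair's expected uncertainty."""
        return 1.0 / np.minimum(self.alphas_r[self.pairs_fast],
                                self.alphas_r[self.pairs_slow])

    # expected uncertainty counts as calibrated after this many timescales
    calibration_timescales: float = 2.0

    @property
    def armed(self) -> np.ndarray:
        """Pairs whose expected uncertainty is calibrated (has had
        ``calibration_timescales`` full timescales of learning) and whose
        surprise test is therefore in force."""
        return self.trials_seen >= self.calibration_timescales * self.pair_timescales

    def copy(self) -> "MonitorBank":
        return MonitorBank(self.levels, self.alphas_r, self.alphas_nr,
                           self.pairs_fast, self.pairs_slow,
                           self.g_plus.copy(), self.u.copy(),
                           self.active.copy(), self.trials_seen,
                           self.calibration_timescales)


def monitor_update(bank: MonitorBank, rewarded) -> MonitorBank:
    """Reward-based update of every monitor, independent of the chosen action.

    Reward: depressed mass flips up, ``G+ += alpha_r (1 - G+)``; no reward:
    potentiated mass flips down, ``G+ -= alpha_nr G+``.  ``rewarded`` may be
    a bool or a bool array over runs.
    """
    out = bank.copy()
    rew = np.asarray(rewarded, dtype=bool)
    if rew.ndim:
        rew = rew[..., None]
    g = out.g_plus
    out.g_plus = np.where(rew,
                          g + bank.alphas_r * (1.0 - g),
                          g - bank.alphas_nr * g)
    return out


def uncertainty_update(bank: MonitorBank) -> MonitorBank:
    """Leaky update of each pair's expected uncertainty toward the current
    unexpected uncertainty ``|v_f - v_s|``, at the slower rate of the pair."""
    out = bank.copy()
    dv = np.abs(bank.g_plus[..., bank.pairs_fast] - bank.g_plus[..., bank.pairs_slow])
    rate = np.minimum(bank.alphas_r[bank.pairs_fast], bank.alphas_r[bank.pairs_slow])
    out.u = bank.u + rate * (dv - bank.u)
    return out


def detect_surprise(bank: MonitorBank, params: SurpriseParams):
    """One-sided test of unexpected against expected uncertainty.

    A pair fires iff the Gaussian upper-tail probability of its fast-slow
    deficit ``v_slow - v_fast`` at standard deviation ``max(u, epsilon)``
    falls below ``h``; only reward-rate *decreases* (positive deficit) can
    fire, and only pairs whose expected uncertainty is calibrated (see
    ``MonitorBank.armed``) take part.
    Returns ``(surprise, boost_level, fired)`` where ``surprise`` is a
    bool array over runs, ``boost_level`` the 1-based cascade level the
    directive extends to (0 where no pair fired) and ``fired`` the per-pair
    firing mask.
    """
    deficit = bank.g_plus[..., bank.pairs_slow] - bank.g_plus[..., bank.pairs_fast]
    sd = np.maximum(bank.u, params.epsilon)
    tail = 0.5 * erfc(deficit / (np.sqrt(2.0) * sd))
    fired = (tail < params.h) & bank.armed
    surprise = fired.any(axis=-1)
    if params.boost_rule == "slow":
        lv = bank.levels[bank.pairs_slow]
        boost_level = np.where(fired, lv, 0).max(axis=-1)
    else:
        lv = bank.levels[bank.pairs_fast]
        big = bank.levels[-1] + 1
        boost_level = np.where(fired, lv, big).min(axis=-1)
        boost_level = np.where(surprise, boost_level, 0)
    return surprise, boost_level, fired


def step_surprise_system(bank: MonitorBank, rewarded, params: SurpriseParams):
    """One trial: monitor update, uncertainty update, surprise test.

    Returns ``(bank, boost_level)``; ``boost_level`` is the per-run boost
    directive for the cascade (0 = clear).  Monitors and uncertainties keep
    updating during active surprise periods, which is what lets the expected
    uncertainty catch up and terminate the surprise.
    """
    bank = monitor_update(bank, rewarded)
    bank = uncertainty_update(bank)
    bank.trials_seen += 1
    surprise, boost_level, fired = detect_surprise(bank, params)
    bank.active = fired
    return bank, boost_level
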