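"""Mean-field dynamics of cascade-model metaplastic synapses.

Each action-selective synaptic population is described by its occupancy
distribution over ``2*m`` states: a binary strength (depressed ``-`` or
potentiated ``+``) crossed with ``m`` metaplastic depth levels.  Level 1 is
the most plastic; deeper levels flip their strength with geometrically
smaller probabilities ``alpha_i`` and are entered with geometrically smaller
metaplastic probabilities ``p_i``.  The production dynamics are deterministic
flow equations on the occupancy fractions; stochasticity enters only through
choice sampling and reward generation.  :func:`simulate_finite_synapses`
provides the microscopic stochastic counterpart used as a test oracle.

All state arrays carry a leading batch axis so that many independent
simulation runs can be propagated at once.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CascadeParams",
    "CascadeState",
    "init_cascade",
    "cascade_update",
    "forgetting_step",
    "apply_isi",
    "set_boost",
    "clear_boost",
    "effective_learning_rate",
    "simulate_finite_synapses",
    "mean_field_trajectory",
]

logger = logging.getLogger(__name__)

# per-population occupancy must stay normalized to this tolerance
_MASS_TOL = 1e-9


@dataclass(frozen=True)
class CascadeParams:
    """Transition-rate ladders of the cascade synapse model.

    Parameters
    ----------
    alpha_r, alpha_nr
        Strength-transition probabilities per depth level after a reward /
        no-reward, each of length ``m``, strictly decreasing, in ``(0, 1]``.
        ``1/alpha_i`` is the timescale (in trials) that level ``i``
        integrates.
    p_r, p_nr
        Metaplastic (deepening) transition probabilities from level ``i`` to
        ``i+1``, length ``m - 1``, strictly decreasing.
    gamma
        Scale in ``[0, 1]`` of the opposite-direction update applied to the
        population of the unchosen action (0: unchosen synapses untouched).
    """

    alpha_r: np.ndarray
    alpha_nr: np.ndarray
    p_r: np.ndarray
    p_nr: np.ndarray
    gamma: float = 0.0

    def __post_init__(self):
        for name in ("alpha_r", "alpha_nr", "p_r", "p_nr"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        m = self.alpha_r.size
        if self.alpha_nr.size != m or self.p_r.size != m - 1 or self.p_nr.size != m - 1:
            raise ValueError("ladder lengths inconsistent: need m, m, m-1, m-1")
        for name in ("alpha_r", "alpha_nr", "p_r", "p_nr"):
            arr = getattr(self, name)
            if arr.size and (np.any(arr <= 0) or np.any(arr > 1)):
                raise ValueError(f"{name} must lie in (0, 1]")
            if arr.size > 1 and np.any(np.diff(arr) >= 0):
                raise ValueError(f"{name} must be strictly decreasing with depth")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")

    @property
    def m(self) -> int:
        """Number of metaplastic depth levels per strength."""
        return self.alpha_r.size

    @classmethod
    def geometric(cls, base: float, m: int, gamma: float = 0.0,
                  nr_shift: int = 0) -> "CascadeParams":
        """Logarithmically separated ladders ``alpha_i = base**i``.

        ``nr_shift=1`` builds the asymmetric variant with
        ``alpha_nr_i = base**(i+1)`` (and likewise for ``p_nr``).
        """
        if not 0 < base < 1:
            raise ValueError("base must be in (0, 1)")
        i = np.arange(1, m + 1, dtype=float)
        return cls(
            alpha_r=base ** i,
            alpha_nr=base ** (i + nr_shift),
            p_r=base ** i[:-1],
            p_nr=base ** (i[:-1] + nr_shift),
            gamma=gamma,
        )

    @classmethod
    def single(cls, alpha: float, gamma: float = 0.0) -> "CascadeParams":
        """Non-metaplastic (m=1) population with a single fixed rate."""
        a = np.array([alpha], dtype=float)
        e = np.empty(0, dtype=float)
        return cls(alpha_r=a, alpha_nr=a.copy(), p_r=e, p_nr=e.copy(), gamma=gamma)


@dataclass
class CascadeState:
    """Occupancy fractions over the cascade state space.

    ``f_plus[..., a, i]`` / ``f_minus[..., a, i]`` are the fractions of the
    synaptic population targeting action ``a`` that sit in the potentiated /
    depressed state at depth level ``i`` (0-based here; level 1 of the model
    is index 0).  For every run and action the total mass is 1.
    ``boost[..., a, i]`` marks levels whose strength-transition rate is
    currently elevated to the level-1 rate by a surprise signal; it never
    affects the metaplastic ``p`` rates.
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    boost: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.f_plus = np.asarray(self.f_plus, dtype=float)
        self.f_minus = np.asarray(self.f_minus, dtype=float)
        if self.boost is None:
            self.boost = np.zeros(self.f_plus.shape, dtype=bool)

    @property
    def n_actions(self) -> int:
        return self.f_plus.shape[-2]

    @property
    def m(self) -> int:
        return self.f_plus.shape[-1]

    def copy(self) -> "CascadeState":
        return CascadeState(self.f_plus.copy(), self.f_minus.copy(), self.boost.copy())

    def total_mass(self) -> np.ndarray:
        """Per-population total occupancy, shape ``(..., n_actions)``."""
        return self.f_plus.sum(axis=-1) + self.f_minus.sum(axis=-1)

    def to_frame(self):
        """Snapshot of run 0 as a tidy table (action, strength, level, fraction)."""
        import pandas as pd

        fp = self.f_plus.reshape(-1, self.n_actions, self.m)[0]
        fm = self.f_minus.reshape(-1, self.n_actions, self.m)[0]
        rows = []
        for a in range(self.n_actions):
            for i in range(self.m):
                rows.append((a, "+", i + 1, fp[a, i]))
                rows.append((a, "-", i + 1, fm[a, i]))
        return pd.DataFrame(rows, columns=["action", "strength", "level", "fraction"])


def init_cascade(params: CascadeParams, n_actions: int, mode: str = "top-states",
                 n_runs: int = 1) -> CascadeState:
    """Initial occupancy distribution.

    ``top-states`` puts half the mass in each strength at the most plastic
    level (the naive, fully plastic configuration); ``uniform`` spreads mass
    evenly over all ``2*m`` states.
    """
    if n_actions < 2:
        raise ValueError("need at least 2 actions")
    m = params.m
    fp = np.zeros((n_runs, n_actions, m))
    fm = np.zeros((n_runs, n_actions, m))
    if mode == "top-states":
        fp[..., 0] = 0.5
        fm[..., 0] = 0.5
    elif mode == "uniform":
        fp[...] = 1.0 / (2 * m)
        fm[...] = 1.0 / (2 * m)
    else:
        raise ValueError(f"unknown init mode: {mode!r}")
    return CascadeState(fp, fm)


def _effective_alpha(alpha: np.ndarray, boost: np.ndarray) -> np.ndarray:
    """Ladder with boosted levels elevated to the level-1 rate."""
    return np.where(boost, alpha[..., :1], alpha)


def _directional_flows(f_src: np.ndarray, f_dst: np.ndarray, a_eff: np.ndarray,
                       p: np.ndarray, scale: np.ndarray):
    """One-sided cascade flow: ``src`` strength flips to the top ``dst``
    state at rate ``a_eff`` per level, while ``dst`` mass deepens at rate
    ``p``.  Returns the updated (src, dst) pair; all flows evaluated on the
    pre-update state so the operator is a simultaneous update.
    """
    flip = scale * a_eff * f_src                      # (..., a, m)
    new_src = f_src - flip
    deep = scale * p * f_dst[..., :-1] if p.size else np.zeros_like(f_dst[..., :0])
    new_dst = f_dst.copy()
    if p.size:
        new_dst[..., :-1] -= deep
        new_dst[..., 1:] += deep
    new_dst[..., 0] += flip.sum(axis=-1)
    return new_src, new_dst


def cascade_update(state: CascadeState, chosen, rewarded, params: CascadeParams,
                   renormalize: bool = True) -> CascadeState:
    """One trial of reward-based learning.

    The population of the chosen action follows the congruent rule: after a
    reward, depressed mass at every level flips to the top potentiated state
    at its (possibly boosted) ``alpha_r`` rate and potentiated mass deepens
    at ``p_r``; after no reward the mirror image runs on the ``alpha_nr`` /
    ``p_nr`` ladders.  Unchosen populations receive the opposite-direction
    update scaled by ``gamma``.

    ``chosen`` may be an int or an int array over the batch axis; likewise
    ``rewarded`` a bool or bool array.
    """
    fp, fm, boost = state.f_plus, state.f_minus, state.boost
    batch_shape = fp.shape[:-2]
    n_actions, m = fp.shape[-2], fp.shape[-1]

    chosen = np.broadcast_to(np.asarray(chosen, dtype=int), batch_shape)
    rewarded = np.broadcast_to(np.asarray(rewarded, dtype=bool), batch_shape)

    rew = rewarded[..., None, None]                          # (..., 1, 1)
    alpha = np.where(rew, params.alpha_r, params.alpha_nr)   # (..., 1, m)
    p = (np.where(rew, params.p_r, params.p_nr)
         if params.p_r.size else np.zeros(batch_shape + (1, 0)))
    a_eff = _effective_alpha(alpha, boost)

    is_chosen = (np.arange(n_actions) == chosen[..., None])[..., None]  # (...,a,1)
    scale = np.where(is_chosen, 1.0, params.gamma)

    # Potentiation-direction update: depressed -> top potentiated, potentiated
    # deepens.  Runs on (chosen & rewarded) and (unchosen & unrewarded)
    # populations; the mirror (depression) runs on the other two cases.
    pot_fm, pot_fp = _directional_flows(fm, fp, a_eff, p, scale)
    dep_fp, dep_fm = _directional_flows(fp, fm, a_eff, p, scale)

    pot_mask = is_chosen == rew                              # (..., a, 1)
    new_fp = np.where(pot_mask, pot_fp, dep_fp)
    new_fm = np.where(pot_mask, pot_fm, dep_fm)

    out = CascadeState(new_fp, new_fm, boost.copy())
    if renormalize:
        _check_mass(out)
    return out


def forgetting_step(state: CascadeState, params: CascadeParams) -> CascadeState:
    """One strength-randomizing transition of an inter-session interval.

    Potentiated mass at level ``i`` decays to the top depressed state at
    rate ``alpha_i`` and vice versa; no metaplastic (deepening) transitions
    occur.  Applied to all action populations; the reward ladder ``alpha_r``
    is used (the two ladders coincide in all forgetting experiments).
    """
    fp, fm = state.f_plus, state.f_minus
    alpha = params.alpha_r
    loss_p = alpha * fp
    loss_m = alpha * fm
    new_fp = fp - loss_p
    new_fm = fm - loss_m
    new_fp[..., 0] += loss_m.sum(axis=-1)
    new_fm[..., 0] += loss_p.sum(axis=-1)
    return CascadeState(new_fp, new_fm, state.boost.copy())


def apply_isi(state: CascadeState, params: CascadeParams, n_units: int,
              reps_per_unit: int = 100) -> CascadeState:
    """Forgetting over ``n_units`` inter-session-interval units.

    One ISI unit is ``reps_per_unit`` repetitions of the forgetting
    transition.
    """
    for _ in range(int(n_units) * int(reps_per_unit)):
        state = forgetting_step(state, params)
    return state


def set_boost(state: CascadeState, level_j) -> CascadeState:
    """Elevate strength-transition rates of levels ``k <= level_j`` to the
    level-1 rate (for all actions, both reward directions).  ``level_j`` is
    1-based and may be an int array over the batch axis; 0 clears the boost
    for that run.  Metaplastic rates are never altered.
    """
    level = np.asarray(level_j, dtype=int)
    if np.any(level > state.m):
        raise ValueError("boost level exceeds cascade depth")
    mask = np.arange(1, state.m + 1) <= level[..., None]     # (..., m)
    boost = np.broadcast_to(mask[..., None, :], state.f_plus.shape).copy()
    return CascadeState(state.f_plus.copy(), state.f_minus.copy(), boost)


def clear_boost(state: CascadeState) -> CascadeState:
    return CascadeState(state.f_plus.copy(), state.f_minus.copy(),
                        np.zeros_like(state.boost))


def effective_learning_rate(state: CascadeState, params: CascadeParams) -> np.ndarray:
    """Occupancy-weighted mean strength-transition rate.

    Pools both strengths and all action populations; level ``i`` contributes
    its (boost-elevated) rate weighted by the total mass occupying it.  When
    the reward and no-reward ladders differ, the per-level mean of the two
    is used as the level's rate.  Returns a scalar for a single run, else an
    array over the batch axis.
    """
    if np.array_equal(params.alpha_r, params.alpha_nr):
        ladder = params.alpha_r
    else:
        ladder = 0.5 * (params.alpha_r + params.alpha_nr)
    rate = _effective_alpha(ladder, state.boost)             # (..., a, m)
    weight = state.f_plus + state.f_minus
    out = (rate * weight).sum(axis=(-1, -2)) / weight.sum(axis=(-1, -2))
    return out if out.ndim else float(out)


def _check_mass(state: CascadeState) -> None:
    mass = state.total_mass()
    drift = np.abs(mass - 1.0)
    # hand-built partial states (single populated action) are left alone
    fix = (drift > _MASS_TOL) & (mass > 0.5)
    if np.any(fix):
        logger.warning("occupancy mass drift up to %.3e; renormalizing",
                       drift[fix].max())
        norm = np.where(fix, mass, 1.0)[..., None]
        state.f_plus /= norm
        state.f_minus /= norm


# ---------------------------------------------------------------------------
# Finite-population stochastic oracle
# ---------------------------------------------------------------------------

_EVENTS = ("chosen_reward", "chosen_noreward",
           "unchosen_reward", "unchosen_noreward", "forget")


def simulate_finite_synapses(params: CascadeParams, n_syn: int, outcome_sequence,
                             seed: int, mode: str = "top-states") -> np.ndarray:
    """Microscopic simulation of one synaptic population.

    Every one of ``n_syn`` synapses occupies a discrete (strength, level)
    state and makes the literal stochastic transitions of the cascade
    learning rule.  ``outcome_sequence`` is an iterable of event names from
    ``{'chosen_reward', 'chosen_noreward', 'unchosen_reward',
    'unchosen_noreward', 'forget'}`` describing what happened to the action
    this population targets on each trial.

    Returns the empirical occupancy trajectory, shape
    ``(len(sequence) + 1, 2, m)`` with axis 1 = (potentiated, depressed),
    whose expectation is the mean-field dynamics.
    """
    rng = np.random.default_rng(seed)
    m = params.m
    level = np.zeros(n_syn, dtype=np.int64)
    if mode == "top-states":
        potentiated = rng.random(n_syn) < 0.5
    elif mode == "uniform":
        idx = rng.integers(0, 2 * m, size=n_syn)
        potentiated = idx < m
        level = np.where(potentiated, idx, idx - m)
    else:
        raise ValueError(f"unknown init mode: {mode!r}")

    events = list(outcome_sequence)
    traj = np.zeros((len(events) + 1, 2, m))

    def record(t):
        traj[t, 0] = np.bincount(level[potentiated], minlength=m) / n_syn
        traj[t, 1] = np.bincount(level[~potentiated], minlength=m) / n_syn

    record(0)
    for t, ev in enumerate(events):
        if ev not in _EVENTS:
            raise ValueError(f"unknown event: {ev!r}")
        u = rng.random(n_syn)
        if ev == "forget":
            flip = u < params.alpha_r[level]
            np.logical_not(potentiated, out=potentiated, where=flip)
            level[flip] = 0
        else:
            chosen = ev.startswith("chosen")
            rewarded = ev.endswith("_reward") and not ev.endswith("noreward")
            scale = 1.0 if chosen else params.gamma
            alpha = params.alpha_r if rewarded else params.alpha_nr
            p = params.p_r if rewarded else params.p_nr
            # direction: potentiate on (chosen == rewarded), else depress
            pot_dir = chosen == rewarded
            src = ~potentiated if pot_dir else potentiated
            flip = src & (u < scale * alpha[level])
            deep = np.zeros(n_syn, dtype=bool)
            if m > 1:
                congruent = potentiated if pot_dir else ~potentiated
                shallow = congruent & (level < m - 1)
                deep = shallow & (u < scale * np.where(level < m - 1,
                                                       np.append(p, 0.0)[level], 0.0))
            potentiated[flip] = pot_dir
            level[flip] = 0
            level[deep] += 1
        record(t + 1)
    return traj


def mean_field_trajectory(params: CascadeParams, outcome_sequence,
                          mode: str = "top-states") -> np.ndarray:
    """Mean-field counterpart of :func:`simulate_finite_synapses`.

    Propagates a single action population through the same event sequence and
    returns occupancies with the same shape convention.
    """
    state = init_cascade(params, n_actions=2, mode=mode)
    events = list(outcome_sequence)
    traj = np.zeros((len(events) + 1, 2, params.m))
    traj[0, 0] = state.f_plus[0, 0]
    traj[0, 1] = state.f_minus[0, 0]
    for t, ev in enumerate(events):
        if ev == "forget":
            state = forgetting_step(state, params)
        else:
            chosen = 0 if ev.startswith("chosen") else 1
            rewarded = ev.endswith("_reward") and not ev.endswith("noreward")
            state = cascade_update(state, chosen, rewarded, params)
        traj[t + 1, 0] = state.f_plus[0, 0]
        traj[t + 1, 1] = state.f_minus[0, 0]
    return traj
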