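"""Generative task environments.

Two discrete-trial reward schedules are provided: the concurrent
variable-interval (VI) schedule, in which each arm is independently *baited*
with a fixed per-trial probability and a bait persists until the arm is
chosen (so reward probability grows with time since the last visit, and the
matching law is near-optimal), and the variable-ratio (VR) schedule — a
multi-armed bandit with fixed per-choice reward probabilities.  Block
schedules chain segments of either type with optional contingency reversals
and inter-session-interval (ISI) markers.

Environments carry a leading batch axis so many independent runs share one
schedule object.  Within a trial, baiting happens before the choice is
evaluated, so a reward on trial 1 is possible; at most one bait is held per
arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VISchedule",
    "VRSchedule",
    "Segment",
    "BlockSchedule",
    "vi_step",
    "vr_step",
    "matching_target",
    "iterate_schedule",
]


@dataclass
class VISchedule:
    """Concurrent VI (baited) schedule state.

    ``rates[a]`` is arm ``a``'s per-trial baiting probability; ``baited`` the
    persistent bait flags, shape ``(n_runs, n_actions)``.
    """

    rates: np.ndarray
    baited: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_runs: int = 1

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("baiting rates must lie in [0, 1]")
        if self.baited is None:
            self.baited = np.zeros((self.n_runs, self.rates.size), dtype=bool)

    @classmethod
    def from_ratio(cls, total_rate: float, ratio, n_runs: int = 1) -> "VISchedule":
        """Split a total baiting rate by a contingency ratio, e.g. 0.4 at 9:1."""
        ratio = np.asarray(ratio, dtype=float)
        return cls(rates=total_rate * ratio / ratio.sum(), n_runs=n_runs)

    @property
    def n_actions(self) -> int:
        return self.rates.size


@dataclass
class VRSchedule:
    """Variable-ratio (bandit) schedule: fixed per-choice reward probabilities."""

    reward_probs: np.ndarray
    n_runs: int = 1

    def __post_init__(self):
        self.reward_probs = np.asarray(self.reward_probs, dtype=float)
        if np.any(self.reward_probs < 0) or np.any(self.reward_probs > 1):
            raise ValueError("reward probabilities must lie in [0, 1]")

    @property
    def n_actions(self) -> int:
        return self.reward_probs.size


def vi_step(sched: VISchedule, choice, rng: np.random.Generator):
    """One VI trial: bait, then collect.

    Each unbaited arm becomes baited with its rate; the chosen arm yields
    reward 1 iff it holds a bait, which is then cleared.  Unchosen baits
    persist.  ``choice`` is an int or int array over runs.  The schedule is
    updated in place and returned with the per-run rewards.  Exactly
    ``n_runs * n_actions`` uniforms are consumed per call regardless of the
    choices, so paired models see identical bait streams.
    """
    draws = rng.random(sched.baited.shape)
    sched.baited |= draws < sched.rates
    choice = np.broadcast_to(np.asarray(choice, dtype=int), (sched.baited.shape[0],))
    runs = np.arange(sched.baited.shape[0])
    reward = sched.baited[runs, choice].astype(int)
    sched.baited[runs, choice] = False
    return reward, sched


def vr_step(sched: VRSchedule, choice, rng: np.random.Generator):
    """One VR trial: Bernoulli reward at the chosen arm's fixed probability.

    Consumes ``n_runs * n_actions`` uniforms (the full bandit outcome table)
    per call so paired models see identical reward contingencies.
    """
    draws = rng.random((sched.n_runs, sched.n_actions))
    choice = np.broadcast_to(np.asarray(choice, dtype=int), (sched.n_runs,))
    runs = np.arange(sched.n_runs)
    return (draws[runs, choice] < sched.reward_probs[choice]).astype(int)


def matching_target(sched: VISchedule) -> np.ndarray:
    """Ideal matching-law choice probabilities: each arm's baiting-rate share."""
    return sched.rates / sched.rates.sum()


@dataclass(frozen=True)
class Segment:
    """One block of trials under fixed contingencies.

    ``kind`` is ``"VI"`` or ``"VR"``; ``values`` the per-arm baiting rates or
    reward probabilities; ``length`` the number of trials; ``isi_units``
    inter-session-interval units to apply *before* the segment starts.
    """

    kind: str
    values: tuple
    length: int
    isi_units: int = 0

    def __post_init__(self):
        if self.kind not in ("VI", "VR"):
            raise ValueError("segment kind must be 'VI' or 'VR'")
        if self.length < 1:
            raise ValueError("segment length must be >= 1")


@dataclass(frozen=True)
class BlockSchedule:
    """A sequence of segments with change points and ISI markers."""

    segments: tuple

    @classmethod
    def reversal_vi(cls, total_rate: float, ratio, block_length: int,
                    n_blocks: int, isi_units: int = 0) -> "BlockSchedule":
        """Alternating VI contingency, swapping the rich arm each block."""
        ratio = np.asarray(ratio, dtype=float)
        rates = total_rate * ratio / ratio.sum()
        segs = []
        for b in range(n_blocks):
            vals = tuple(rates if b % 2 == 0 else rates[::-1])
            segs.append(Segment("VI", vals, block_length,
                                isi_units if b > 0 else 0))
        return cls(tuple(segs))

    @classmethod
    def rotating_vr(cls, best_prob: float, other_prob: float, n_actions: int,
                    block_lengths, rng: np.random.Generator | None = None,
                    start: int = 0) -> "BlockSchedule":
        """VR blocks in which the identity of the best arm moves each block.

        The best arm advances cyclically (or is drawn by ``rng`` among the
        other arms) at every block boundary.
        """
        segs = []
        best = start
        for length in block_lengths:
            vals = np.full(n_actions, other_prob)
            vals[best] = best_prob
            segs.append(Segment("VR", tuple(vals), int(length)))
            if rng is None:
                best = (best + 1) % n_actions
            else:
                best = (best + int(rng.integers(1, n_actions))) % n_actions
        return cls(tuple(segs))

    @property
    def n_trials(self) -> int:
        return sum(s.length for s in self.segments)

    @property
    def n_actions(self) -> int:
        return len(self.segments[0].values) if self.segments else 0


def iterate_schedule(blocks: BlockSchedule):
    """Deterministic expansion of a block schedule.

    Returns ``(segment_of_trial, change_points, isi_units_at)`` where
    ``segment_of_trial`` maps each trial to its segment index,
    ``change_points`` lists the first trial index of every segment after the
    first, and ``isi_units_at`` maps those trial indices to the ISI units to
    apply before them (0 if none).
    """
    seg_of_trial = np.concatenate(
        [np.full(s.length, i, dtype=int) for i, s in enumerate(blocks.segments)]
    ) if blocks.segments else np.empty(0, dtype=int)
    change_points = []
    isi_units_at = {}
    t = 0
    for i, s in enumerate(blocks.segments):
        if i > 0:
            change_points.append(t)
            if s.isi_units:
                isi_units_at[t] = s.isi_units
        t += s.length
    return seg_of_trial, change_points, isi_units_at
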