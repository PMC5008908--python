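"""Experiment configurations, the coupled trial loop, and figure runners.

The trial loop couples the pieces in a fixed order each trial: the decision
network turns synaptic strengths into choice probabilities, a choice is
sampled, the environment delivers a reward, the surprise system (when
enabled) consumes the outcome and emits a plasticity-boost directive, and the
cascade synapses are updated with the directive in force.  All state arrays
carry a run axis, so a whole population of independent simulations advances
in lock step; with a fixed seed the output is byte-for-byte reproducible.

Model variants:

- ``fixed``: single-timescale bounded synapses (cascade depth m=1).
- ``cascade``: metaplastic cascade synapses, no surprise system.
- ``cascade+surprise``: the full model.
- ``bayes``: the grid Bayesian volatility learner with a matching policy.

Paired comparisons use a dedicated environment random stream derived only
from the seed, so different models see identical bait/reward tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayes as bayes_mod
from .cascade import (CascadeParams, apply_isi, cascade_update,
                      effective_learning_rate, init_cascade, set_boost)
from .decision import DecisionParams, choice_probability, sample_choice
from .metrics import adaptation_times, prob_fluctuation
from .surprise import MonitorBank, SurpriseParams, step_surprise_system
from .tasks import (BlockSchedule, Segment, VISchedule, VRSchedule,
                    iterate_schedule, vi_step, vr_step)

__all__ = ["ExperimentConfig", "SimulationResult", "run_trial_loop",
           "reproduce_figure", "FIGURES"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Full specification of one simulated experiment."""

    schedule: BlockSchedule
    model: str = "cascade+surprise"          # fixed|cascade|cascade+surprise|bayes
    cascade: CascadeParams | None = None
    decision: DecisionParams = field(default_factory=DecisionParams)
    surprise: SurpriseParams = field(default_factory=SurpriseParams)
    monitor_levels: tuple | None = None      # default: all m cascade levels
    bayes: bayes_mod.BayesConfig = field(default_factory=bayes_mod.BayesConfig)
    init_mode: str = "top-states"
    n_runs: int = 1
    seed: int = 0
    record_monitors: bool = False

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimulationResult:
    """Per-trial arrays over all runs, plus schedule annotations."""

    config: ExperimentConfig
    p: np.ndarray                 # (runs, T, A) pre-choice probabilities
    choices: np.ndarray           # (runs, T)
    rewards: np.ndarray           # (runs, T)
    eff_rate: np.ndarray          # (runs, T); NaN for the Bayes model
    surprise: np.ndarray          # (runs, T) bool
    boost_level: np.ndarray       # (runs, T) int, 0 = no boost
    seg_of_trial: np.ndarray      # (T,)
    change_points: list
    isi_units_at: dict
    monitors: np.ndarray | None = None   # (runs, T, k) readouts v_i
    uncertainty: np.ndarray | None = None  # (runs, T, n_pairs)

    @property
    def n_trials(self) -> int:
        return self.choices.shape[1]

    def delta_p(self, action: int = 0) -> np.ndarray:
        """Across-run fluctuation of the choice probability of ``action``."""
        return prob_fluctuation(self.p[:, :, action])

    def adaptation_times(self, change_point: int, threshold: float,
                         favored: int, window: int | None = None) -> np.ndarray:
        return adaptation_times(self.p[:, :, favored], change_point,
                                threshold, window)

    def to_dataframe(self, runs=None) -> pd.DataFrame:
        """Tidy per-trial record table (one row per trial per run)."""
        runs = range(self.choices.shape[0]) if runs is None else runs
        frames = []
        for r in runs:
            df = pd.DataFrame({
                "run": r,
                "trial": np.arange(self.n_trials),
                "block": self.seg_of_trial,
                "choice": self.choices[r],
                "reward": self.rewards[r],
                "effective_learning_rate": self.eff_rate[r],
                "surprise": self.surprise[r].astype(int),
                "boost_level": self.boost_level[r],
            })
            for a in range(self.p.shape[2]):
                df[f"P_{a}"] = self.p[r, :, a]
            if self.monitors is not None:
                for i in range(self.monitors.shape[2]):
                    df[f"v_{i + 1}"] = self.monitors[r, :, i]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def save_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


def _make_env(seg: Segment, n_runs: int):
    if seg.kind == "VI":
        return VISchedule(np.asarray(seg.values, dtype=float), n_runs=n_runs)
    return VRSchedule(np.asarray(seg.values, dtype=float), n_runs=n_runs)


def _set_env(env, seg: Segment):
    """Swap contingencies at a block boundary; VI bait states persist."""
    vals = np.asarray(seg.values, dtype=float)
    if isinstance(env, VISchedule):
        env.rates = vals
    else:
        env.reward_probs = vals
    return env


class _NeuralAgent:
    """Cascade (or fixed-rate) decision network, optionally surprise-guided."""

    def __init__(self, config: ExperimentConfig, n_actions: int):
        if config.cascade is None:
            raise ValueError("neural models need cascade parameters")
        self.params = config.cascade
        self.decision = config.decision
        self.state = init_cascade(self.params, n_actions, config.init_mode,
                                  n_runs=config.n_runs)
        self.bank = None
        self.surprise_params = config.surprise
        if config.model == "cascade+surprise":
            self.bank = MonitorBank.from_cascade(
                self.params, levels=config.monitor_levels, n_runs=config.n_runs)
        self.last_surprise = np.zeros(config.n_runs, dtype=bool)
        self.last_boost = np.zeros(config.n_runs, dtype=int)

    def choice_probs(self) -> np.ndarray:
        return choice_probability(self.state, self.decision)

    def observe(self, choice, reward) -> None:
        if self.bank is not None:
            self.bank, level = step_surprise_system(
                self.bank, reward.astype(bool), self.surprise_params)
            self.state = set_boost(self.state, level)
            self.last_boost = level
            self.last_surprise = level > 0
        self.state = cascade_update(self.state, choice, reward.astype(bool),
                                    self.params)

    def isi(self, n_units: int) -> None:
        self.state = apply_isi(self.state, self.params, n_units)

    def effective_rate(self) -> np.ndarray:
        return np.atleast_1d(effective_learning_rate(self.state, self.params))


class _BayesAgent:
    """Grid Bayesian learner with matching-law policy."""

    def __init__(self, config: ExperimentConfig, n_actions: int):
        self.grid = bayes_mod.init_grid(config.bayes, n_targets=n_actions,
                                        n_runs=config.n_runs)
        self.last_surprise = np.zeros(config.n_runs, dtype=bool)
        self.last_boost = np.zeros(config.n_runs, dtype=int)

    def choice_probs(self) -> np.ndarray:
        return bayes_mod.bayes_policy(self.grid)

    def observe(self, choice, reward) -> None:
        self.grid = bayes_mod.bayes_update(self.grid, choice, reward)

    def isi(self, n_units: int) -> None:
        pass  # inference carries no forgetting process

    def effective_rate(self) -> np.ndarray:
        return np.full(self.grid.posterior.shape[0], np.nan)


def run_trial_loop(config: ExperimentConfig) -> SimulationResult:
    """Run the full coupled loop over the configured block schedule.

    Per trial: choice probabilities -> sampled choice -> environment step ->
    surprise system step -> boost directive -> cascade update.  The
    environment consumes its own random stream (derived from the seed alone)
    so that different models under the same seed face identical reward
    contingencies.
    """
    seg_of_trial, change_points, isi_units_at = iterate_schedule(config.schedule)
    T = seg_of_trial.size
    R = config.n_runs
    if T == 0:
        z = np.zeros((R, 0))
        return SimulationResult(config, z.reshape(R, 0, 1), z.astype(np.int16),
                                z.astype(np.int8), z, z.astype(bool),
                                z.astype(np.int16), seg_of_trial, [], {})
    n_actions = config.schedule.n_actions
    rng_env = np.random.default_rng([config.seed, 0])
    rng_choice = np.random.default_rng([config.seed, 1])

    if config.model in ("fixed", "cascade", "cascade+surprise"):
        agent = _NeuralAgent(config, n_actions)
    elif config.model == "bayes":
        agent = _BayesAgent(config, n_actions)
    else:
        raise ValueError(f"unknown model variant: {config.model!r}")


    p = np.zeros((R, T, n_actions))
    choices = np.zeros((R, T), dtype=np.int16)
    rewards = np.zeros((R, T), dtype=np.int8)
    eff = np.full((R, T), np.nan)
    surprise = np.zeros((R, T), dtype=bool)
    boost = np.zeros((R, T), dtype=np.int16)
    mon = unc = None
    if config.record_monitors and getattr(agent, "bank", None) is not None:
        mon = np.zeros((R, T, agent.bank.g_plus.shape[1]))
        unc = np.zeros((R, T, agent.bank.u.shape[1]))

    env = _make_env(config.schedule.segments[0], R)
    seg_idx = 0
    for t in range(T):
        if seg_of_trial[t] != seg_idx:
            seg_idx = int(seg_of_trial[t])
            env = _set_env(env, config.schedule.segments[seg_idx])
            if t in isi_units_at:
                agent.isi(isi_units_at[t])
        prob = agent.choice_probs()
        choice = sample_choice(prob, rng_choice)
        if isinstance(env, VISchedule):
            reward, env = vi_step(env, choice, rng_env)
        else:
            reward = vr_step(env, choice, rng_env)
        agent.observe(choice, reward)
        p[:, t] = prob
        choices[:, t] = choice
        rewards[:, t] = reward
        eff[:, t] = agent.effective_rate()
        surprise[:, t] = agent.last_surprise
        boost[:, t] = agent.last_boost
        if mon is not None:
            mon[:, t] = agent.bank.g_plus
            unc[:, t] = agent.bank.u
    return SimulationResult(config, p, choices, rewards, eff, surprise, boost,
                            seg_of_trial, change_points, isi_units_at, mon, unc)


# ---------------------------------------------------------------------------
# Figure runners
# ---------------------------------------------------------------------------

def _vi_reversal_config(base: float, m: int, h: float, pre: int, post: int,
                        seed: int, n_runs: int, model: str = "cascade+surprise",
                        gamma: float = 0.0, T: float = 0.1, ratio=(9, 1),
                        total_rate: float = 0.4, **kw) -> ExperimentConfig:
    sched = BlockSchedule((
        Segment("VI", tuple(VISchedule.from_ratio(total_rate, ratio).rates), pre),
        Segment("VI", tuple(VISchedule.from_ratio(total_rate, ratio[::-1]).rates), post),
    ))
    return ExperimentConfig(
        schedule=sched, model=model,
        cascade=CascadeParams.geometric(base, m, gamma=gamma),
        decision=DecisionParams(T=T), surprise=SurpriseParams(h=h),
        n_runs=n_runs, seed=seed, **kw)


def fig1bc(seed: int = 0, n_runs: int = 200, block: int = 300,
           alphas=(0.2, 0.002)) -> dict:
    """Speed-accuracy tradeoff of fixed-rate plasticity on a VI reversal.

    Returns per-alpha mean choice-probability traces, per-trial fluctuation
    and adaptation times (threshold 0.7) after the mid-run reversal.
    """
    out = {"traces": {}, "delta_p": {}, "adaptation": {}, "change_point": block}
    for alpha in alphas:
        sched = BlockSchedule((
            Segment("VI", tuple(VISchedule.from_ratio(0.4, (9, 1)).rates), block),
            Segment("VI", tuple(VISchedule.from_ratio(0.4, (1, 9)).rates), block),
        ))
        cfg = ExperimentConfig(
            schedule=sched, model="fixed",
            cascade=CascadeParams.single(alpha, gamma=0.0),
            decision=DecisionParams(T=0.1), n_runs=n_runs, seed=seed)
        res = run_trial_loop(cfg)
        out["traces"][alpha] = res.p[:, :, 0].mean(axis=0)
        out["delta_p"][alpha] = res.delta_p(action=0)
        from .metrics import adaptation_time
        mean_fav = res.p[:, :, 1].mean(axis=0)
        out["adaptation"][alpha] = adaptation_time(mean_fav, block, 0.7)
    return out


def fig2bcd(seed: int = 0, n_runs: int = 200, stable_blocks=(250, 2000),
            post: int = 600, delta_p_trials: int = 1000,
            threshold: float = 0.7) -> dict:
    """Consolidation and adaptation of the cascade model, with and without
    the surprise system (ladder (1/5)^i, m=10, h=0.05, VI 0.4 at 9:1).

    Returns the cascade-only fluctuation trace over a stable period and the
    mean adaptation time after each stable-block length for both variants.
    """
    out = {"delta_p": None, "adaptation": {"cascade": {}, "cascade+surprise": {}}}
    sched = BlockSchedule((
        Segment("VI", tuple(VISchedule.from_ratio(0.4, (9, 1)).rates),
                delta_p_trials),))
    cfg = ExperimentConfig(
        schedule=sched, model="cascade",
        cascade=CascadeParams.geometric(0.2, 10, gamma=0.0),
        decision=DecisionParams(T=0.1), n_runs=n_runs, seed=seed)
    out["delta_p"] = run_trial_loop(cfg).delta_p(action=0)

    for model in ("cascade", "cascade+surprise"):
        for pre in stable_blocks:
            cfg = _vi_reversal_config(0.2, 10, 0.05, pre, post, seed, n_runs,
                                      model=model)
            res = run_trial_loop(cfg)
            mean_fav = res.p[:, :, 1].mean(axis=0)
            from .metrics import adaptation_time
            out["adaptation"][model][pre] = adaptation_time(mean_fav, pre,
                                                            threshold)
    return out


def _mixed_vr_schedule(n_actions: int, best: float, other: float,
                       long_len: int, short_len: int, n_short: int,
                       n_long: int = 2) -> BlockSchedule:
    """Alternating long/short VR blocks, best arm rotating each block."""
    lengths = []
    for _ in range(n_long):
        lengths.append(long_len)
        lengths.extend([short_len] * (n_short // n_long))
    return BlockSchedule.rotating_vr(best, other, n_actions, lengths)


def fig3a(seed: int = 0, n_runs: int = 50, long_len: int = 1000,
          short_len: int = 10, n_short: int = 40) -> dict:
    """Self-tuned effective learning rate on a four-armed bandit with mixed
    block lengths (ladders 0.5^i / 0.5^(i+1), m=12, gamma=1, h=0.05)."""
    sched = _mixed_vr_schedule(4, 0.8, 0.2, long_len, short_len, n_short)
    cfg = ExperimentConfig(
        schedule=sched, model="cascade+surprise",
        cascade=CascadeParams.geometric(0.5, 12, gamma=1.0, nr_shift=1),
        decision=DecisionParams(T=0.1), surprise=SurpriseParams(h=0.05),
        n_runs=n_runs, seed=seed)
    res = run_trial_loop(cfg)
    from .metrics import effective_rate_summary
    lengths = np.array([s.length for s in sched.segments])
    summary = effective_rate_summary(res.eff_rate, res.seg_of_trial)
    summary["block_length"] = lengths[summary["block"].to_numpy()]
    return {"result": res, "summary": summary, "block_lengths": lengths}


_BASELINE_ALPHAS = tuple(0.5 ** np.arange(1, 9))


def fig3bc(seed: int = 0, n_runs: int = 100, short_len: int = 10,
           long_len: int = 1000, n_short_blocks: int = 100,
           n_long_blocks: int = 2, short_to_long: int = 100) -> dict:
    """Harvest efficiency of the full model against the fixed-rate family on
    four-armed VR tasks (0.8 vs 0.2).

    Single-timescale tasks (one block length throughout) use the deep-ladder
    self-tuning configuration (0.5^i, m=20, h=0.05, gamma=1); the mixed task
    interleaving ``short_to_long`` short blocks per long block uses the
    shallow high-specificity configuration (m=4, h=0.0005).  Returns per-run
    reward totals per task for the full model and each fixed-alpha baseline,
    under paired environment streams.
    """
    tasks = {
        "short": (BlockSchedule.rotating_vr(0.8, 0.2, 4,
                                            [short_len] * n_short_blocks),
                  CascadeParams.geometric(0.5, 20, gamma=1.0), 0.05),
        "long": (BlockSchedule.rotating_vr(0.8, 0.2, 4,
                                           [long_len] * n_long_blocks),
                 CascadeParams.geometric(0.5, 20, gamma=1.0), 0.05),
    }
    mixed_lengths = []
    for _ in range(n_long_blocks):
        mixed_lengths.append(long_len)
        mixed_lengths.extend([short_len] * short_to_long)
    tasks["mixed"] = (BlockSchedule.rotating_vr(0.8, 0.2, 4, mixed_lengths),
                      CascadeParams.geometric(0.5, 4, gamma=1.0), 0.0005)

    totals = {}
    for name, (sched, cascade, h) in tasks.items():
        totals[name] = {}
        cfg = ExperimentConfig(
            schedule=sched, model="cascade+surprise", cascade=cascade,
            decision=DecisionParams(T=0.1), surprise=SurpriseParams(h=h),
            n_runs=n_runs, seed=seed)
        totals[name]["full"] = run_trial_loop(cfg).rewards.sum(axis=1)
        for alpha in _BASELINE_ALPHAS:
            cfg_b = cfg.replace(model="fixed",
                                cascade=CascadeParams.single(alpha, gamma=1.0))
            totals[name][float(alpha)] = run_trial_loop(cfg_b).rewards.sum(axis=1)
    return {"totals": totals, "baseline_alphas": _BASELINE_ALPHAS}


def fig4ab(seed: int = 0, n_runs: int = 50, stable: int = 800,
           pre: int = 400, post: int = 400, threshold: float = 0.6) -> dict:
    """Full model against the grid Bayesian learner on paired VI streams
    (2-target VI, total rate 0.4 at 9:1; ladder 0.2^i, m=10, h=0.01)."""
    out = {"delta_p": {}, "adaptation": {}}
    stable_sched = BlockSchedule((
        Segment("VI", tuple(VISchedule.from_ratio(0.4, (9, 1)).rates), stable),))
    for model in ("cascade+surprise", "bayes"):
        cfg = ExperimentConfig(
            schedule=stable_sched, model=model,
            cascade=CascadeParams.geometric(0.2, 10, gamma=0.0),
            decision=DecisionParams(T=0.1), surprise=SurpriseParams(h=0.01),
            n_runs=n_runs, seed=seed)
        out["delta_p"][model] = run_trial_loop(cfg).delta_p(action=0)
        cfg_rev = _vi_reversal_config(0.2, 10, 0.01, pre, post, seed, n_runs,
                                      model=model)
        res = run_trial_loop(cfg_rev)
        mean_fav = res.p[:, :, 1].mean(axis=0)
        from .metrics import adaptation_time
        out["adaptation"][model] = adaptation_time(mean_fav, pre, threshold)
    return out


def fig5ab(seed: int = 0, n_runs: int = 100, session1: int = 3000,
           session_len: int = 200, isi_conditions=(1, 5)) -> dict:
    """Spontaneous recovery of preference across sessions separated by ISIs
    (session 1 balanced, sessions 2-4 at 9:1; ladder 0.2^i, m=10, h=0.001)."""
    out = {}
    for isi in isi_conditions:
        segs = [Segment("VI", (0.2, 0.2), session1)]
        rates = tuple(VISchedule.from_ratio(0.4, (9, 1)).rates)
        for _ in range(3):
            segs.append(Segment("VI", rates, session_len, isi_units=isi))
        cfg = ExperimentConfig(
            schedule=BlockSchedule(tuple(segs)), model="cascade+surprise",
            cascade=CascadeParams.geometric(0.2, 10, gamma=0.0),
            decision=DecisionParams(T=0.1), surprise=SurpriseParams(h=0.001),
            n_runs=n_runs, seed=seed)
        out[isi] = run_trial_loop(cfg)
    return out


def fig8(seed: int = 0, n_runs: int = 100, block: int = 100,
         n_blocks: int = 20, h: float = 0.01) -> dict:
    """The whole model trial by trial: VI 0.4 reversing between 1:4 and 4:1
    every 100 trials (ladder (1/5)^i, m=10).  Returns the simulation with
    monitor traces plus surprise-timing statistics."""
    sched = BlockSchedule.reversal_vi(0.4, (4, 1), block, n_blocks)
    cfg = ExperimentConfig(
        schedule=sched, model="cascade+surprise",
        cascade=CascadeParams.geometric(0.2, 10, gamma=0.0),
        decision=DecisionParams(T=0.1), surprise=SurpriseParams(h=h),
        n_runs=n_runs, seed=seed, record_monitors=True)
    res = run_trial_loop(cfg)

    detect_window = 30
    stable_tail = 50
    hits = []
    for cp in res.change_points:
        hits.append(res.surprise[:, cp:cp + detect_window].any(axis=1))
    detected = np.mean(np.stack(hits, axis=1)) if hits else np.nan
    tail_rates = []
    for cp in res.change_points + [res.n_trials]:
        tail = res.surprise[:, max(cp - stable_tail, 0):cp]
        tail_rates.append(tail.mean())
    return {"result": res, "reversal_detection_rate": float(detected),
            "stable_surprise_rate": float(np.mean(tail_rates))}


FIGURES = {
    "fig1bc": fig1bc,
    "fig2bcd": fig2bcd,
    "fig3a": fig3a,
    "fig3bc": fig3bc,
    "fig4ab": fig4ab,
    "fig5ab": fig5ab,
    "fig8": fig8,
}


def reproduce_figure(name: str, out_dir=None, **overrides):
    """Run a named figure configuration (desk-scale defaults) and optionally
    write its tables and a plot under ``out_dir``."""
    if name not in FIGURES:
        raise ValueError(f"unknown figure {name!r}; choose from {sorted(FIGURES)}")
    result = FIGURES[name](**overrides)
    if out_dir is not None:
        from . import plotting
        plotting.write_figure_outputs(name, result, out_dir)
    return result
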