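"""Behavioral metrics over simulated trial records.

Covers the quantities used to characterize adaptive learning: the across-run
fluctuation of choice probability, the adaptation time after a contingency
change, harvest efficiency against a fixed-learning-rate baseline family,
and block-wise summaries of the effective learning rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["prob_fluctuation", "adaptation_time", "adaptation_times",
           "harvest_efficiency", "effective_rate_summary"]


def prob_fluctuation(p_traces: np.ndarray) -> np.ndarray:
    """Per-trial population standard deviation of choice probability across
    independent runs.  ``p_traces`` has shape ``(n_runs, n_trials)``."""
    p = np.asarray(p_traces, dtype=float)
    if p.ndim != 2:
        raise ValueError("expected (n_runs, n_trials) array")
    return p.std(axis=0, ddof=0)


def adaptation_time(trace: np.ndarray, change_point: int, threshold: float,
                    window: int | None = None):
    """Trials needed after ``change_point`` for ``trace`` (the choice
    probability of the post-change-favored action) to reach ``threshold``.

    The first evaluated trial counts as 1, so a trace already above threshold
    at the change point returns 1.  Returns ``None`` (censored) if the
    threshold is not reached within ``window`` trials (or the end of the
    trace).
    """
    seg = np.asarray(trace, dtype=float)[change_point:]
    if window is not None:
        seg = seg[:window]
    hits = np.nonzero(seg >= threshold)[0]
    return int(hits[0]) + 1 if hits.size else None


def adaptation_times(traces: np.ndarray, change_point: int, threshold: float,
                     window: int | None = None) -> np.ndarray:
    """Vectorized :func:`adaptation_time` over runs; censored entries are NaN."""
    seg = np.asarray(traces, dtype=float)[:, change_point:]
    if window is not None:
        seg = seg[:, :window]
    crossed = seg >= threshold
    first = crossed.argmax(axis=1).astype(float) + 1
    first[~crossed.any(axis=1)] = np.nan
    return first


def harvest_efficiency(model_rewards, baseline_rewards_by_alpha) -> float:
    """Total rewards normalized by the best fixed-learning-rate baseline.

    ``baseline_rewards_by_alpha`` maps each baseline (e.g. its alpha) to the
    total rewards it collected on the same task and seeds; the best baseline
    has efficiency exactly 1.
    """
    if isinstance(baseline_rewards_by_alpha, dict):
        baselines = np.array(list(baseline_rewards_by_alpha.values()), dtype=float)
    else:
        baselines = np.asarray(baseline_rewards_by_alpha, dtype=float)
    best = baselines.max()
    if best <= 0:
        raise ValueError("baseline family collected no rewards")
    return float(model_rewards) / float(best)


def effective_rate_summary(rates: np.ndarray, seg_of_trial: np.ndarray) -> pd.DataFrame:
    """Median and (25th, 70th) percentiles of the effective learning rate per
    block, pooled over runs.

    ``rates`` is ``(n_runs, n_trials)`` or ``(n_trials,)``; ``seg_of_trial``
    assigns each trial to a block and must cover every trial exactly once.
    """
    rates = np.atleast_2d(np.asarray(rates, dtype=float))
    seg = np.asarray(seg_of_trial, dtype=int)
    if seg.size != rates.shape[1]:
        raise ValueError("seg_of_trial must label every trial")
    rows = []
    for b in np.unique(seg):
        vals = rates[:, seg == b].ravel()
        rows.append({
            "block": int(b),
            "n_trials": int((seg == b).sum()),
            "q25": float(np.percentile(vals, 25)),
            "median": float(np.median(vals)),
            "q70": float(np.percentile(vals, 70)),
        })
    return pd.DataFrame(rows)
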