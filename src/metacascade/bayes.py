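"""Grid-based Bayesian volatility learner (Behrens-style benchmark).

Each target's reward probability is modeled through a latent logit ``r``
(``R = 1/(1+e^-r)``) performing a Gaussian random walk whose per-trial
variance ``V = e^v`` is itself latent: the log-volatility ``v`` performs a
random walk with variance ``K = e^k``, and the meta-volatility parameter
``k`` is static.  The joint posterior over ``(r, v, k)`` is propagated on a
fixed grid by discrete convolution (transition kernels truncated at the grid
edges and renormalized) followed by a Bernoulli likelihood update, per
target independently.  The policy allocates choices proportionally to the
posterior-predictive reward probabilities (the matching law), optionally
greedily.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["BayesConfig", "BayesGrid", "init_grid", "bayes_update",
           "predictive_prob", "bayes_policy"]


@dataclass(frozen=True)
class BayesConfig:
    """Grid specification.

    Axis ranges follow the usual volatility-tracking choices: ``r`` spans
    reward probabilities ~0.007-0.993, ``v`` log-volatilities and ``k``
    log-meta-volatilities over broad negative ranges.  30 points per axis is
    enough that doubling the resolution moves predictive probabilities by
    less than 0.01 (checked by test).
    """

    n_r: int = 30
    n_v: int = 30
    n_k: int = 30
    r_range: tuple = (-5.0, 5.0)
    v_range: tuple = (-11.0, -2.0)
    k_range: tuple = (-8.0, -2.0)


def _gauss_kernel(grid: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Column-stochastic transition matrices ``T[..., new, old]`` for a
    Gaussian step of standard deviation ``sd`` on ``grid``.

    The Gaussian is integrated over destination grid cells (erf differences
    at the cell midpoints) rather than sampled at the nodes, so kernels
    narrower than the grid spacing still move the correct probability mass to
    neighboring cells and the discretization converges under refinement.
    Mass falling outside the grid is truncated and renormalized.
    """
    from scipy.special import erf

    edges = np.concatenate([[-np.inf], 0.5 * (grid[1:] + grid[:-1]), [np.inf]])
    sd = np.asarray(sd, dtype=float)[:, None, None]
    z = (edges[None, :, None] - grid[None, None, :]) / (np.sqrt(2.0) * sd)
    cdf = 0.5 * (1.0 + erf(z))                             # (sd, edge, old)
    k = np.diff(cdf, axis=1)                               # (sd, new, old)
    return k / k.sum(axis=1, keepdims=True)


@dataclass
class BayesGrid:
    """Discretized joint posterior per run and target.

    ``posterior`` has shape ``(n_runs, n_targets, n_r, n_v, n_k)`` and sums
    to 1 over the grid axes for every (run, target).
    """

    config: BayesConfig
    r: np.ndarray
    v: np.ndarray
    k: np.ndarray
    trans_v: np.ndarray      # (n_k, n_v_new, n_v_old)
    trans_r: np.ndarray      # (n_v, n_r_new, n_r_old)
    sigmoid_r: np.ndarray
    posterior: np.ndarray

    @property
    def n_targets(self) -> int:
        return self.posterior.shape[1]


def init_grid(config: BayesConfig = BayesConfig(), n_targets: int = 2,
              n_runs: int = 1) -> BayesGrid:
    """Uniform joint prior over the grid, one posterior per target."""
    r = np.linspace(*config.r_range, config.n_r)
    v = np.linspace(*config.v_range, config.n_v)
    k = np.linspace(*config.k_range, config.n_k)
    trans_v = _gauss_kernel(v, np.exp(k / 2.0))            # sd = sqrt(K)
    trans_r = _gauss_kernel(r, np.exp(v / 2.0))            # sd = sqrt(V)
    post = np.full((n_runs, n_targets, config.n_r, config.n_v, config.n_k),
                   1.0 / (config.n_r * config.n_v * config.n_k))
    return BayesGrid(config, r, v, k, trans_v, trans_r,
                     1.0 / (1.0 + np.exp(-r)), post)


def _diffuse(grid: BayesGrid, post: np.ndarray) -> np.ndarray:
    """Two-stage transition: v diffuses given k, then r diffuses given the
    new v.  ``post`` has shape ``(..., n_r, n_v, n_k)``."""
    lead = post.shape[:-3]
    n_r, n_v, n_k = post.shape[-3:]
    flat = post.reshape(-1, n_r, n_v, n_k)
    # v-step, one batched matmul over k: T_v[k] @ P(v, R*r) per k
    pv = np.ascontiguousarray(flat.transpose(3, 2, 0, 1)).reshape(n_k, n_v, -1)
    pv = grid.trans_v @ pv                                   # (k, w, R*r)
    # r-step, batched over the new v: T_r[w] @ P(r, R*k) per w
    pr = np.ascontiguousarray(
        pv.reshape(n_k, n_v, -1, n_r).transpose(1, 3, 2, 0)
    ).reshape(n_v, n_r, -1)
    pr = grid.trans_r @ pr                                   # (w, s, R*k)
    out = pr.reshape(n_v, n_r, -1, n_k).transpose(2, 1, 0, 3)
    return np.ascontiguousarray(out).reshape(lead + (n_r, n_v, n_k))


def bayes_update(grid: BayesGrid, target, outcome) -> BayesGrid:
    """One-trial posterior recursion.

    The transition (diffusion) applies to every target — time passes for all
    of them — while the Bernoulli likelihood applies only to the observed
    ``target`` with its ``outcome``.  ``target`` and ``outcome`` may be ints
    or per-run arrays; ``outcome=-1`` (or ``target=-1``) skips the likelihood
    for that run.  Renormalizes per (run, target).
    """
    post = _diffuse(grid, grid.posterior)
    n_runs, n_targets = post.shape[:2]
    target = np.broadcast_to(np.asarray(target, dtype=int), (n_runs,))
    outcome = np.broadcast_to(np.asarray(outcome, dtype=int), (n_runs,))
    lik = np.ones((n_runs, n_targets, grid.config.n_r))
    obs = (target >= 0) & (outcome >= 0)
    runs = np.nonzero(obs)[0]
    if runs.size:
        lr = np.where(outcome[runs, None] == 1, grid.sigmoid_r,
                      1.0 - grid.sigmoid_r)
        lik[runs, target[runs]] = lr
    post = post * lik[..., None, None]
    norm = post.sum(axis=(-1, -2, -3), keepdims=True)
    if np.any(norm <= 0):
        raise FloatingPointError("posterior mass underflow in Bayes update")
    grid.posterior = post / norm
    return grid


def predictive_prob(grid: BayesGrid, target=None) -> np.ndarray:
    """Posterior-predictive reward probability ``E[1/(1+e^-r)]`` per target.

    Shape ``(n_runs, n_targets)``, or ``(n_runs,)`` for a given ``target``.
    """
    marg_r = grid.posterior.sum(axis=(-1, -2))
    pred = marg_r @ grid.sigmoid_r
    return pred if target is None else pred[:, target]


def bayes_policy(grid: BayesGrid, greedy: bool = False) -> np.ndarray:
    """Choice probabilities from predictive reward probabilities.

    Matching-law allocation (proportional to predictive probabilities) by
    default; ``greedy`` puts all mass on the argmax.
    """
    pred = predictive_prob(grid)
    if greedy:
        out = np.zeros_like(pred)
        out[np.arange(pred.shape[0]), pred.argmax(axis=1)] = 1.0
        return out
    total = pred.sum(axis=1, keepdims=True)
    n = pred.shape[1]
    return np.where(total > 0, pred / np.maximum(total, 1e-300), 1.0 / n)
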