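# Methods

## Model overview

The simulator couples three systems on a per-trial cycle: (1) a decision
network reads the synaptic strengths of its action-selective populations and
emits a choice probability; (2) a choice is sampled and the environment
returns a binary reward; (3) a surprise-detection system consumes the reward,
updates its multi-timescale monitors, and may issue a plasticity-boost
directive; (4) the cascade synapses of the decision network are updated with
the directive in force. All model state carries a leading run axis so
hundreds of independent simulations are propagated in lock step; with a fixed
seed every output is bit-reproducible.

## Decision network

The winner-take-all attractor between action populations is summarized by its
sigmoid approximation: `P_A = 1/(1 + exp(−(⟨w⟩_A − ⟨w⟩_B)/T))` with
`⟨w⟩_a` the potentiated occupancy of population *a*. Input firing rates are
rescaled into the temperature, leaving `T` (default 0.1) as the only noise
parameter. For more than two actions we use the softmax of strengths at the
same temperature, which reduces exactly to the sigmoid for two; how the
original four-armed network combines pairwise competitions is not determined
by the attractor picture, and softmax is the standard choice.

## Cascade synapse dynamics

Each action population's synapses occupy `2·m` states: binary strength
(depressed/potentiated) × metaplastic depth 1..m. Strength transitions out of
depth *i* occur with probability `α_i` (after reward, toward the top
potentiated state, for the chosen action) and metaplastic deepening with
probability `p_i`; omissions run the mirror image on the `α_nr/p_nr`
ladders, and unchosen populations receive the opposite-direction update
scaled by `γ ∈ [0, 1]`. Ladders are geometric (`α_i = p_i = x^i`, typically
x = 1/2 or 1/5), so depth *i* integrates over `1/α_i` trials.

The production dynamics are deterministic flow equations on occupancy
fractions, evaluated simultaneously from the pre-trial state. The per-level
bookkeeping requires care — naive formulations leave the deepest level's
inflow and the source-pool depletion inconsistent with the normalization
constraint — so we use the unique mass-conserving form: every level's source
pool is depleted by exactly the flow it emits, and level *m* absorbs its
inflow. Mass conservation to 1e-12
per population after arbitrary update sequences is enforced by test; a
renormalization guard (tolerance 1e-9, logged) exists but is never triggered
in normal operation.

`simulate_finite_synapses` implements the same rule as literal per-synapse
stochastic transitions; tests verify the mean-field flow lies within four
binomial standard errors of a 10^5-synapse population over mixed 200-trial
event sequences. Production runs are mean-field only: synapse-count noise is
excluded by design, and choice sampling plus reward generation are the only
stochastic elements.

**Forgetting / inter-session intervals.** During an ISI, potentiated mass at
level *i* flips to the top depressed state at rate `α_i` and vice versa — no
metaplastic moves. One ISI unit is 100 such transitions. Repeated
application contracts any state toward the symmetric fixed point (all mass at
depth 1, strengths 0.5/0.5), erasing shallow memory first; deep consolidated
bias survives short ISIs, which is what produces spontaneous recovery. The
reward ladder `α_r` is used when the two ladders differ (they coincide in
every forgetting experiment here).

**Effective learning rate.** The occupancy-weighted mean of the (possibly
boosted) strength-transition rates, pooled over both strengths and all
populations; when the reward and no-reward ladders differ the per-level mean
of the two serves as the level's rate. This is a readout only — it drives no
dynamics.

## Surprise detection

One monitor population per cascade level integrates the reward stream
(action-independently) with fixed rate `α_i`: `G⁺ ← G⁺ + α_i(1−G⁺)` on
reward, `G⁺ ← G⁺ − α_i G⁺` on omission, so the readout `v_i` is a leaky
reward-rate average with time constant `1/α_i`. For each compared pair
(fast *f*, slow *s*) the expected uncertainty is the leaky average of the
unexpected uncertainty, `u ← u + min(α_f, α_s)(|v_f − v_s| − u)`.

**Threshold test.** A pair fires when the one-sided Gaussian upper tail of
the deficit `v_s − v_f` at standard deviation `max(u, ε)` falls below `h`
(`ε = 1e-6` defines behavior at u = 0). Only decreases in reward rate can
fire; improvements never do. The test's normalization constant is a pure
convention absorbed into `h`, whose effect is robust over a wide range
precisely because the statistic `deficit/u` is scale-free. A corollary worth knowing: the
stable-state false-alarm rate is set by `h` alone (roughly the tail of the
deficit beyond `√2·erfc⁻¹(2h)` times its own mean absolute value), about 3%
per calibrated pair per trial at h = 0.01 and 9% at h = 0.05.

**Pair set.** Pairs within two levels of each other, `(i, i+1)` and
`(i, i+2)`, over all m levels. Comparing every pair makes the system
false-alarm rate the union of up to m(m−1)/2 tail tests and lets a single
noise event boost arbitrarily deep levels, abolishing consolidation; the
nearest-neighbor window localizes both detection and the damage of a false
alarm to the timescale at which it occurred.

**Calibration gate.** A pair participates in detection only after
`2/min(α_f, α_s)` trials, i.e. once its expected uncertainty — initialized
at 0, with monitors initialized at 0.5 — has had two full timescales of
learning and is within ~15% of its asymptote. Without the gate, any task
whose overall reward rate differs from 0.5 presents a standing fast–slow
deficit that fires slow pairs chronically for ~0.4/α_slow trials; with it,
deep pairs come online progressively, at the same pace at which the system
becomes able to consolidate (and hence needs to reset) memory on their
timescales.

**Boost.** When pairs fire, the strength-transition rates of all levels
`k ≤ j` are elevated to `α_1`, where *j* is the deepest slow level among the
firing pairs; metaplastic `p` rates are never altered, and the boost is
re-evaluated every trial, so it persists exactly while the unexpected
uncertainty exceeds the expected one and releases once `u` catches up.

## Tasks

Concurrent VI: each arm is baited with fixed per-trial probability
(`total_rate` split by a contingency ratio, e.g. 0.4 at 4:1); a bait (at most
one per arm) persists until the arm is chosen; baiting happens before the
choice within a trial. Under this schedule the matching law —
choice fractions proportional to baiting rates — is the near-optimal
probabilistic policy and serves as the reference line. VR: fixed per-choice
reward probabilities. Block schedules chain segments with reversals,
best-arm rotations, and ISI markers; environments consume a fixed number of
random draws per trial from a stream derived only from the seed, so different
models under one seed face identical contingency tables ("paired streams").

## Bayesian volatility learner

Per target, the reward probability is `R = 1/(1+e^{−r})` where *r* performs
a Gaussian random walk with variance `V = e^v`; *v* itself random-walks with
variance `K = e^k`; *k* is static and inferred jointly. The joint posterior
over `(r, v, k)` lives on a fixed grid — defaults 30 points per axis over
r ∈ [−5, 5], v ∈ [−11, −2], k ∈ [−8, −2] — and is propagated by two
batched-matmul convolutions per trial followed by a Bernoulli likelihood on
the observed target and renormalization. Transition kernels integrate the
Gaussian over destination cells (erf differences) rather than sampling the
density, so kernels narrower than the grid spacing still diffuse correctly
and predictions converge under refinement (mean predictive shift < 0.01 on
doubling all axes; the pointwise maximum occurs during fast post-change
transients where a fraction-of-a-trial timing offset dominates). Time passes
for all targets (all diffuse each trial); only the chosen target receives a
likelihood. Renormalizing every trial keeps linear-space densities well away
from underflow. The policy allocates choices proportionally to posterior
predictive reward probabilities (matching), with an optional greedy mode.

## Experiment conditions and desk-scale sizes

Figure runners encode the reference parameter sets: fixed-rate tradeoff
(α ∈ {0.2, 0.002}, VI 0.4 at 9:1, reversal mid-run); consolidation/adaptation
(ladder 0.2^i, m = 10, h = 0.05, γ = 0, stable blocks of 250 and 2000
trials); four-armed self-tuning (ladders 0.5^i / 0.5^{i+1}, m = 12, γ = 1,
h = 0.05, mixed 10/1000-trial blocks); harvest efficiency (single-timescale
tasks with 0.5^i, m = 20, h = 0.05; mixed task with m = 4, h = 0.0005;
baseline family α ∈ {0.5^1..0.5^8} with γ = 1, T = 0.1); Bayes comparison
(0.2^i, m = 10, h = 0.01, threshold P = 0.6); spontaneous recovery (sessions
3000/200/200/200, 0.2^i, m = 10, h = 0.001, ISIs of 1 vs 5 units); whole-model
trace (VI 4:1 reversing every 100 trials, 0.2^i, m = 10, h = 0.01).

Desk-scale choices: 10,000-trial blocks are reduced to 1000-trial blocks and
the short:long block-count ratio to 100:1; run counts are 30–200 per
experiment; the Bayes comparison uses 50 paired runs over 800-trial
horizons. Adaptation times are computed per run as the first post-change
trial at which the newly favored action's probability reaches threshold
(counting from 1; censored runs enter medians as +∞) and summarized by the
median, which is robust to censoring and to the early first-passage bias of
noisy single-run traces. Choice-probability fluctuation δP is the per-trial
population SD across runs.

## What the synthetic environments do and do not cover

The generative tasks reproduce the statistical structure the model was built
for: Bernoulli rewards, persistent baits, abrupt contingency reversals at
fixed block boundaries, and idealized inter-session forgetting. They omit
features of real behavioral data — reaction times, satiety and motivational
drift, changeover behavior, gradual (non-step) drifts, and any stimulus
identity beyond the action label — so passing tests demonstrate internal
consistency of the mechanism and reproduction of its characteristic
simulation phenomenology, not fit to animal data.

## Known limitations

- The surprise statistic compares single-trial deficits against a learned
  scale; its detection/specificity ceiling is set by the monitors' own
  sampling noise. At the whole-model demonstration's contrast (VI 4:1,
  blocks of 100, h = 0.01) reversal detection within 30 trials plateaus
  around 20–40% of runs, although surprises remain ~10× enriched after
  reversals relative to stable stretches.
- After very long stable blocks, mass consolidates to depths whose monitor
  pairs are not yet calibrated; adaptation then runs at the deepest armed
  boost and is slower than the Bayesian learner's (about 2.4× after a
  400-trial block at threshold 0.6, consistent with the model's known
  tendency to be marginally slower for longer stable blocks).
- On a task composed purely of 10-trial blocks the self-tuned effective
  learning rate equilibrates about one ladder rung below the best fixed
  rate, costing ~12% harvest relative to the best baseline.
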