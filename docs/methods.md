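# Methods

## Model

The random-dots direction discrimination task is treated as a partially
observable Markov decision process.  The hidden state is the pair
(coherence c, direction d), held fixed within a trial.  Two opposing MT
populations fire as Poisson processes with rates linear in coherence,

    f_pref = r0 (1 + k_p c),     f_null = r0 (1 − k_n c),

and the observation available to the decision maker in a step of N spikes is
the number z of spikes from the rightward-preferring pool.  Conditioning on
the total count makes z ~ Binomial(N, p) with p = f_R/(f_R + f_L), so p is a
one-dimensional sufficient reparameterization of the hidden state: p > ½
means rightward motion, |p − ½| grows with coherence, and a direction flip
maps p ↦ 1 − p.

Inference is conjugate: a Beta(α₀, β₀) prior over p turns the posterior
after t steps into Beta(α₀ + n_R, β₀ + n_L).  Beliefs therefore live on the
exact integer lattice {(t, n_R) : 0 ≤ n_R ≤ Nt} — there is no belief-space
discretization anywhere in the package, and all "analytic" quantities are
exact up to floating point.  The posterior probability of rightward motion is
1 − I_{1/2}(α, β) with I the regularized incomplete beta function.

Actions are sample (cost c_s per spike, i.e. N·c_s per step), go-right and
go-left (expected reward R⁺·P(correct) + R⁻·P(incorrect), then absorption
into a zero-reward terminal state).  Bellman's equation on the lattice is
solved by backward induction; the sampling branch uses the beta-binomial
posterior predictive, which is stationary (belief-dependent, not
time-dependent).  The resulting policy is a partition of each time slice
into left / sample / right regions whose edges, expressed as count ratios
n_R/(Nt), are the decision boundaries θ_L(t) < θ_R(t).  They collapse toward
½: with more evidence the point estimate is trusted at smaller deviations
from chance, and terminating ambiguous trials frees time for rewarding ones.

Behavioral predictions come from exact forward propagation of the occupancy
distribution over the sampling region under the true p: the per-step masses
entering the right/left regions are the reaction-time distributions, their
sums the choice probabilities, and their normalized first moments the mean
RTs.  Accuracy is reported conditioned on a decision being reached (the
horizon leak is below 1e−6 for any certified policy, so this normalization
is cosmetic; at c = 0 it makes "accuracy" the rightward fraction, exactly ½
by symmetry).

The LIP read-out is rate(t) = max(floor, B + κ(p̂(t) − θ_R(t))).  Because
θ_R(t) is the smallest count ratio preferring go-right, the rate reaches B
exactly when the policy emits go-right — the collapsing belief boundary and
the fixed firing-rate bound are the same object in different coordinates
(verified bit-exactly in the tests).  The zero-coherence expected response,
B + κ(½ − θ_R(t)), is the urgency signal; the left-preferring population is
the mirror image and needs no separate code.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `base_rate` r0 | 40 | spikes/s | MT population rate at zero coherence; conventional order of magnitude for task-driven MT activity |
| `drive_pref` k_p | 1.0 | — | preferred-direction coherence gain |
| `drive_null` k_n | 0.5 | — | null-direction suppression; must stay < 1 so rates remain positive; 0.5 keeps p(c=1, right) = 0.8 < 1 |
| `spikes_per_step` N | 1 | spikes | a decision opportunity at every spike (the finest granularity); N > 1 supported |
| `alpha0`, `beta0` | 1, 1 | — | uniform symmetric prior over p; no direction bias |
| `sample_cost` c_s | −1 | reward/spike | fixes the reward unit (the policy depends only on reward ratios) |
| `reward_correct` R⁺ | 450 | reward | with c_s = −1 gives accuracy 0.50→0.99 and mean correct RT 45→18 steps across the conventional coherence grid — the characteristic psychophysical operating range (≈0.5 s zero-coherence decision time at ~12 ms/step) |
| `reward_error` R⁻ | 0 | reward | errors unrewarded rather than punished; only (R⁺ − R⁻)/\|c_s\| matters |
| `horizon` T | 400 | steps | truncation point; the stationarity certificate (below) and the < 1e−6 zero-coherence survival by t ≈ 360 show it is effectively infinite |
| `coherences` | 0, .032, .064, .128, .256, .512 | — | the conventional doubling ladder of task difficulty |
| LIP `bound_rate` B | 60 | spikes/s | order of magnitude of pre-saccadic LIP peak rates |
| LIP `gain` κ | 50 | spikes/s per unit p̂ − θ | kept ≤ B so the rate floor never engages and the read-out stays affine |
| LIP `buildup_window` | 20 | steps | early-epoch window (~250 ms at ~12 ms/step) for the buildup-rate line fit |

MT constants and the reward magnitudes are study conditions chosen once, not
fitted quantities; users comparing against a specific dataset should override
them in the run configuration and use `calibrate_time` for the
steps-to-milliseconds map (ordinary least squares of observed mean RT on
predicted mean decision steps; the intercept is the non-decision residual).

## Numerical choices

- **Horizon truncation and certification.**  Sampling is disallowed on the
  final slice.  `solve` re-solves at a 1.25× horizon and sets `converged`
  only if the action tables agree *exactly* (integer lattice, no epsilon)
  for all t ≤ 0.8·T.  First-passage analysis and simulation refuse
  uncertified policies.  Probability reaching the final slice is reported as
  `leak` and never renormalized.
- **Tail-safe split probabilities.**  P(p < ½) and P(p > ½) are both
  evaluated directly as regularized incomplete beta functions with swapped
  arguments, never as one-minus-the-other; this keeps tiny tails accurate
  and makes mirrored lattice cells bit-exact mirrors under a symmetric
  prior.
- **Exact mirror symmetry.**  For symmetric priors the sampling Q-values
  are re-symmetrized each slice ((q + reversed q)/2, a ≤ 1 ulp adjustment)
  so the value table, policy, and the p = ½ first-passage masses are
  bit-for-bit mirror symmetric; zero-coherence "accuracy" is then exactly ½
  rather than ½ ± 1e−16.
- **Tie-breaking.**  At exact value ties sampling is preferred over
  terminating (except on the final slice) and go-right over go-left.  Ties
  occur only on the lattice's symmetry line; one center cell may therefore
  join the rightward region where the boundary has fully collapsed.
- **Boundary staircase.**  θ_R(t) = n_min(t)/(Nt) on an integer lattice is
  a staircase: when n_min increments, the ratio can tick *up* by less than
  one cell width (e.g. 4/5 → 5/6) even though the underlying threshold is
  collapsing.  Monotonicity statements are therefore made at one-cell
  resolution (the running minimum is never exceeded by a full cell and
  n_min never decreases), which is the discrete form of a collapsing bound.
- **Hyperbolic fits.**  The boundary is summarized by least squares against
  θ(t) = ½ + aτ/(t + τ) (τ = half-time of the excess over ½), the urgency
  signal against B − Aτ/(t + τ) with the asymptote pinned at B; amplitudes
  are unconstrained because the first defined boundary point lies at t ≥ ~5
  and the fitted t → 0 intercept is an extrapolation.  Flat inputs are
  flagged degenerate rather than fitted.
- **Calibration.**  Centered-moment OLS (slope = S_xy/S_xx), which
  reproduces collinear inputs exactly in floating point.
- **Seeding.**  Every simulated trial draws its uniform stream from
  `SeedSequence([base_seed, coherence_key, trial_index])`, so a global seed
  plus trial index determines each trial regardless of batch size;
  observations are generated by inverse-CDF so N = 1 and N > 1 share one
  code path.

## The simulator as synthetic data

`simulate` is the stand-in for behavioral experiments: seeded Monte-Carlo
trials drawn from the same observation model the solver assumes, decided by
the solved policy.  It emulates trial-by-trial choice and reaction-time
variability at the task's coherence ladder and serves as the stochastic
oracle for the exact first-passage code (they agree within Monte-Carlo error
by construction of the model — the tests check 3-standard-error agreement at
10⁵ trials).  It does **not** emulate features of real data outside the
model class: non-Poisson spiking statistics, temporally correlated or
adapting MT responses, tuning-curve heterogeneity, lapses, sequential
effects across trials, or non-decision-time variability.  Passing tests
therefore demonstrate internal correctness of the solution and its
read-outs, not that the generative assumptions hold in any particular
dataset.

## Findings the implementation makes precise

- **Observation granularity.**  One N-spike belief transition is exactly
  the N-fold composition of single-spike transitions (verified to 1e−12),
  and with the sampling cost charged per spike the value of any
  pure-sampling plan is granularity-independent.  The *optimal policies*
  are nonetheless not identical: a decision opportunity at every spike
  strictly enlarges the sampling region at a small set of boundary-adjacent
  cells (64 of 16 281 shared cells at the defaults, value differences
  < 0.6%).  Boundaries at matching spike counts agree to within one lattice
  cell; exact policy identity across N holds only for the transition
  structure, not for optimal stopping.
- **Buildup-rate scaling.**  With survivor-conditioned trial averages the
  early LIP slope is positive at every coherence (the urgency component),
  but its regression against coherence is slightly *negative* at the
  defaults: the count-ratio point estimate has time-constant expectation,
  so the early ramp is driven by the collapsing bound, and conditioning on
  undecided trials removes the fastest (highest-p̂) trials preferentially
  at high coherence.  The package reports the scaling as an output rather
  than asserting its sign.

## Limitations

- Stationary hidden state only: no within-trial changes in coherence or
  direction, no temporally correlated observations.
- Behavioral comparisons to published monkey/human datasets require those
  datasets; the package ships none and fits none.  The time calibration
  consumes a user-supplied table of mean RTs per coherence.
- The reward parameters are subjective quantities; only their ratios are
  identifiable, and the defaults are an operating point, not an estimate.
- The LIP read-out is a firing-rate abstraction (no spiking LIP model, no
  PSTH fitting), and its additive constant/floor handling is a documented
  convention.
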