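"""Reward-optimal decision policy via dynamic programming on the belief lattice.

Because the beta family is conjugate to the binomial observations, the set of
reachable beliefs after t steps is the exact integer lattice
{(t, n_R) : 0 <= n_R <= N*t}: no discretization of belief space is involved.
The POMDP therefore reduces to a finite Markov decision process over lattice
points plus one absorbing terminal state, and Bellman's equation

    V(b) = max_a [ R(b, a) + sum_b' P(b' | b, a) V(b') ]

is solved exactly by backward induction.  Actions are ``sample`` (pay the
observation cost, move to one of N+1 successor beliefs with beta-binomial
predictive probabilities), ``go_right`` and ``go_left`` (collect the expected
terminal reward and stop).

The optimal policy partitions each time slice into a left-choice region, a
sampling region and a right-choice region; the region edges expressed as
count ratios n_R / (N t) are the decision boundaries theta_L(t) < theta_R(t).
As t grows the posterior sharpens and the boundaries collapse toward 1/2 —
the collapsing bound arises from reward maximization alone, with no deadline
or other ad-hoc assumption.

A finite horizon T_max truncates the recursion (sampling is disallowed at
t = T_max).  Stationarity is certified by re-solving at a 25% longer horizon
and requiring the policy over the first 80% of T_max to be unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, special, stats

from .belief import BeliefState, PriorParams

__all__ = [
    "SAMPLE",
    "GO_RIGHT",
    "GO_LEFT",
    "ABSORBING",
    "RewardParams",
    "PolicySolution",
    "HyperbolicFit",
    "NotConvergedError",
    "predictive_obs_prob",
    "expected_reward",
    "belief_transition",
    "solve",
    "extract_boundaries",
    "fit_hyperbolic_boundary",
]

# action codes used throughout the package (int8 in tables)
SAMPLE = 0
GO_RIGHT = 1
GO_LEFT = 2

ACTION_NAMES = {SAMPLE: "sample", GO_RIGHT: "go_right", GO_LEFT: "go_left"}

#: sentinel for the absorbing post-decision state in belief_transition
ABSORBING = "absorbing"


class NotConvergedError(RuntimeError):
    """Raised when an operation requires a stationarity-certified policy."""


@dataclass(frozen=True)
class RewardParams:
    """The three behavioral free parameters of the model.

    ``sample_cost`` is charged per MT spike observed (so a step of N spikes
    costs N * sample_cost), making the solution independent of the
    observation granularity N.  The policy depends on the rewards only
    through ratios; ``sample_cost = -1`` fixes the reward unit.
    """

    sample_cost: float = -1.0
    reward_correct: float = 450.0
    reward_error: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_cost >= 0:
            raise ValueError(f"sample_cost must be negative, got {self.sample_cost}")
        if self.reward_correct <= 0:
            raise ValueError(
                f"reward_correct must be positive, got {self.reward_correct}"
            )
        if self.reward_error > 0:
            raise ValueError(
                f"reward_error must be nonpositive, got {self.reward_error}"
            )

    @property
    def ratio(self) -> float:
        """Reward span per unit sampling cost, (R+ - R-)/|c_s| — the single
        scale-free knob controlling the speed-accuracy tradeoff."""
        return (self.reward_correct - self.reward_error) / abs(self.sample_cost)

    def scaled(self, lam: float) -> "RewardParams":
        return RewardParams(
            sample_cost=self.sample_cost * lam,
            reward_correct=self.reward_correct * lam,
            reward_error=self.reward_error * lam,
        )


def predictive_obs_prob(b: BeliefState, z, n: int):
    """Posterior-predictive probability of observing z right spikes out of n.

    This is the beta-binomial distribution: the binomial likelihood averaged
    over the current beta posterior.  It is stationary — it depends on the
    belief, not on elapsed time.  Vectorized over ``z``.
    """
    z_arr = np.asarray(z)
    if np.any(z_arr < 0) or np.any(z_arr > n):
        raise ValueError(f"observation z must lie in [0, {n}]")
    out = stats.betabinom.pmf(z_arr, n, b.alpha, b.beta)
    return out if out.shape else float(out)


def _split_probs(alpha, beta):
    """(P(p < 1/2), P(p > 1/2)) for Beta(alpha, beta) posteriors.

    Both sides are evaluated directly with the regularized incomplete beta
    function (never as one-minus-the-other), which keeps tiny tail
    probabilities accurate and makes mirrored lattice cells bit-exact mirrors
    of each other under a symmetric prior.
    """
    p_below = special.betainc(alpha, beta, 0.5)
    p_above = special.betainc(beta, alpha, 0.5)
    return p_below, p_above


def expected_reward(b: BeliefState, action: int, r: RewardParams, n: int) -> float:
    """Immediate expected reward R(b, a).

    sample: n * sample_cost regardless of belief; go_right:
    R+ P(p > 1/2 | b) + R- P(p < 1/2 | b); go_left mirrored.
    """
    if action == SAMPLE:
        return n * r.sample_cost
    p_below, p_above = _split_probs(b.alpha, b.beta)
    if action == GO_RIGHT:
        return r.reward_correct * p_above + r.reward_error * p_below
    if action == GO_LEFT:
        return r.reward_correct * p_below + r.reward_error * p_above
    raise ValueError(f"unknown action code {action!r}")


def belief_transition(b: BeliefState, action: int, n: int):
    """Distribution over successor beliefs for one action.

    Returns a dict mapping successors to probabilities.  Terminal actions
    move to the absorbing state (key :data:`ABSORBING`) with probability 1;
    sampling branches over the N+1 possible observations with
    beta-binomial predictive weights.
    """
    if action in (GO_RIGHT, GO_LEFT):
        return {ABSORBING: 1.0}
    if action != SAMPLE:
        raise ValueError(f"unknown action code {action!r}")
    probs = predictive_obs_prob(b, np.arange(n + 1), n)
    out = {}
    for z in range(n + 1):
        succ = BeliefState(alpha=b.alpha + z, beta=b.beta + (n - z), prior=b.prior)
        out[succ] = float(probs[z])
    return out


@dataclass
class PolicySolution:
    """Solved value function, action table and decision boundaries.

    ``value[t]`` and ``action[t]`` are arrays over n_R = 0..N*t.
    ``theta_right[t]`` / ``theta_left[t]`` are the boundary count ratios
    (NaN where the time slice contains no cell preferring that action).
    """

    horizon: int
    spikes_per_step: int
    rewards: RewardParams
    prior: PriorParams
    value: list = field(repr=False)
    action: list = field(repr=False)
    theta_right: np.ndarray = field(repr=False)
    theta_left: np.ndarray = field(repr=False)
    converged: bool = False

    @property
    def root_value(self) -> float:
        return float(self.value[0][0])

    @property
    def symmetric(self) -> bool:
        return self.prior.symmetric

    def action_at(self, t: int, n_right: int) -> int:
        return int(self.action[t][n_right])

    def sampling_mask(self, t: int) -> np.ndarray:
        return self.action[t] == SAMPLE

    def first_decision_step(self) -> int:
        """Earliest t at which some lattice cell prefers a terminal action."""
        for t in range(self.horizon + 1):
            if np.any(self.action[t] != SAMPLE):
                return t
        return self.horizon  # pragma: no cover - horizon slice is terminal

    def dense_action_table(self) -> np.ndarray:
        """(T+1, N*T+1) int8 matrix of action codes, -1 outside the lattice."""
        n = self.spikes_per_step
        out = np.full((self.horizon + 1, n * self.horizon + 1), -1, dtype=np.int8)
        for t in range(self.horizon + 1):
            out[t, : n * t + 1] = self.action[t]
        return out

    def to_dict(self, include_tables: bool = True) -> dict:
        d = {
            "horizon": self.horizon,
            "spikes_per_step": self.spikes_per_step,
            "rewards": {
                "sample_cost": self.rewards.sample_cost,
                "reward_correct": self.rewards.reward_correct,
                "reward_error": self.rewards.reward_error,
            },
            "prior": {"alpha0": self.prior.alpha0, "beta0": self.prior.beta0},
            "theta_right": [None if np.isnan(x) else x for x in self.theta_right],
            "theta_left": [None if np.isnan(x) else x for x in self.theta_left],
            "converged": bool(self.converged),
            "root_value": self.root_value,
        }
        if include_tables:
            d["value"] = [v.tolist() for v in self.value]
            d["action"] = [a.tolist() for a in self.action]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PolicySolution":
        if "action" not in d:
            raise ValueError("policy dictionary lacks the action table")
        theta_r = np.array(
            [np.nan if x is None else x for x in d["theta_right"]], dtype=float
        )
        theta_l = np.array(
            [np.nan if x is None else x for x in d["theta_left"]], dtype=float
        )
        return cls(
            horizon=int(d["horizon"]),
            spikes_per_step=int(d["spikes_per_step"]),
            rewards=RewardParams(**d["rewards"]),
            prior=PriorParams(**d["prior"]),
            value=[np.asarray(v, dtype=float) for v in d["value"]],
            action=[np.asarray(a, dtype=np.int8) for a in d["action"]],
            theta_right=theta_r,
            theta_left=theta_l,
            converged=bool(d["converged"]),
        )


def _predictive_matrix(alpha: np.ndarray, beta: np.ndarray, n: int) -> np.ndarray:
    """(N+1, len(alpha)) matrix of beta-binomial predictive masses."""
    if n == 1:
        tot = alpha + beta
        return np.vstack([beta / tot, alpha / tot])
    z = np.arange(n + 1)[:, None]
    return stats.betabinom.pmf(z, n, alpha[None, :], beta[None, :])


def _backward_induction(
    r: RewardParams, prior: PriorParams, n: int, horizon: int
) -> tuple[list, list]:
    """Exact finite-horizon solve; returns ragged (value, action) tables.

    For a symmetric prior the recursion is mirror symmetric by construction;
    the sampling Q-values are explicitly re-symmetrized each slice
    ((q + reversed q)/2) to suppress last-bit rounding asymmetry from
    summation order, so the mirror identities hold bit-exactly in the output.
    """
    symmetric = prior.symmetric
    value: list = [None] * (horizon + 1)
    action: list = [None] * (horizon + 1)
    v_next: np.ndarray | None = None
    for t in range(horizon, -1, -1):
        n_arr = np.arange(n * t + 1, dtype=float)
        alpha = prior.alpha0 + n_arr
        beta = prior.beta0 + (n * t - n_arr)
        p_below, p_above = _split_probs(alpha, beta)
        q_right = r.reward_correct * p_above + r.reward_error * p_below
        q_left = r.reward_correct * p_below + r.reward_error * p_above
        q_term = np.maximum(q_right, q_left)
        a_term = np.where(q_right >= q_left, GO_RIGHT, GO_LEFT).astype(np.int8)
        if t == horizon:
            value[t] = q_term
            action[t] = a_term
        else:
            pred = _predictive_matrix(alpha, beta, n)
            q_sample = np.full(n * t + 1, float(n) * r.sample_cost)
            for z in range(n + 1):
                q_sample += pred[z] * v_next[z : z + n * t + 1]
            if symmetric:
                q_sample = 0.5 * (q_sample + q_sample[::-1])
            sample_wins = q_sample >= q_term  # ties prefer sampling
            value[t] = np.where(sample_wins, q_sample, q_term)
            action[t] = np.where(sample_wins, SAMPLE, a_term).astype(np.int8)
        v_next = value[t]
    return value, action


def extract_boundaries(
    action: Sequence[np.ndarray], n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-step decision boundaries in count-ratio coordinates.

    theta_R(t) is the smallest ratio n_R/(N t) whose cell prefers go_right
    (NaN if no cell does); theta_L(t) the largest preferring go_left.  The
    terminal regions are verified to be contiguous edge intervals of each
    time slice (right region upward-closed in n_R, left region
    downward-closed), which the reward monotonicity in n_R guarantees.
    """
    horizon = len(action) - 1
    theta_r = np.full(horizon + 1, np.nan)
    theta_l = np.full(horizon + 1, np.nan)
    for t in range(horizon + 1):
        acts = action[t]
        right = np.flatnonzero(acts == GO_RIGHT)
        left = np.flatnonzero(acts == GO_LEFT)
        if right.size:
            if not np.all(acts[right[0] :] == GO_RIGHT):
                raise ValueError(
                    f"go_right region is not upward-closed at t={t}; "
                    "boundary extraction is ill-defined"
                )
            theta_r[t] = right[0] / (n * t) if t > 0 else 0.5
        if left.size:
            if not np.all(acts[: left[-1] + 1] == GO_LEFT):
                raise ValueError(
                    f"go_left region is not downward-closed at t={t}; "
                    "boundary extraction is ill-defined"
                )
            theta_l[t] = left[-1] / (n * t) if t > 0 else 0.5
    return theta_r, theta_l


def solve(
    r: RewardParams | None = None,
    prior: PriorParams | None = None,
    n: int = 1,
    horizon: int = 400,
    check_stationarity: bool = True,
    stationarity_fraction: float = 0.8,
    horizon_growth: float = 1.25,
) -> PolicySolution:
    """Solve the belief MDP by backward induction and certify stationarity.

    The infinite-horizon stationary solution is approximated by truncating at
    ``horizon`` (sampling disallowed on the last slice).  When
    ``check_stationarity`` is set, the problem is re-solved at a
    ``horizon_growth``-times longer horizon and ``converged`` records whether
    the action tables agree exactly (integer lattice, no epsilon) for all
    t <= stationarity_fraction * horizon.  An unconverged solution is
    returned, not raised; downstream first-passage analysis refuses it.
    """
    r = r if r is not None else RewardParams()
    prior = prior if prior is not None else PriorParams()
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    value, action = _backward_induction(r, prior, n, horizon)
    theta_r, theta_l = extract_boundaries(action, n)
    converged = False
    if check_stationarity:
        horizon2 = int(np.ceil(horizon * horizon_growth))
        _, action2 = _backward_induction(r, prior, n, horizon2)
        t_check = int(np.floor(stationarity_fraction * horizon))
        converged = all(
            np.array_equal(action[t], action2[t]) for t in range(t_check + 1)
        )
    if not all(np.all(np.isfinite(v)) for v in value):
        raise FloatingPointError("non-finite values in the solved table")
    return PolicySolution(
        horizon=horizon,
        spikes_per_step=n,
        rewards=r,
        prior=prior,
        value=value,
        action=action,
        theta_right=theta_r,
        theta_left=theta_l,
        converged=converged,
    )


@dataclass(frozen=True)
class HyperbolicFit:
    """Least-squares fit of a collapsing boundary to
    theta(t) = 1/2 + a * tau / (t + tau).

    ``half_time`` is tau: the time at which the boundary's excess over 1/2
    has fallen to half its t=0 value.  ``ok`` is False for degenerate
    (flat) input, in which case the parameters are NaN.
    """

    amplitude: float
    half_time: float
    rms_residual: float
    ok: bool


def fit_hyperbolic_boundary(
    t: np.ndarray, theta: np.ndarray, min_points: int = 5
) -> HyperbolicFit:
    """Fit theta(t) = 1/2 + a*tau/(t+tau) to defined boundary points."""
    t = np.asarray(t, dtype=float)
    theta = np.asarray(theta, dtype=float)
    keep = np.isfinite(theta) & np.isfinite(t)
    t, theta = t[keep], theta[keep]
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} defined boundary points")
    excess = theta - 0.5
    if np.ptp(excess) < 1e-12 or np.max(np.abs(excess)) < 1e-12:
        return HyperbolicFit(np.nan, np.nan, np.nan, ok=False)

    def model(tt, a, tau):
        return 0.5 + a * tau / (tt + tau)

    a0 = float(np.max(excess))
    # initial tau: time at which the excess is closest to half its maximum
    tau0 = float(t[np.argmin(np.abs(excess - a0 / 2))])
    tau0 = max(tau0, 1.0)
    popt, _ = optimize.curve_fit(
        model,
        t,
        theta,
        p0=[a0, tau0],
        bounds=([1e-9, 1e-9], [np.inf, 1e9]),
        maxfev=20000,
    )
    resid = theta - model(t, *popt)
    return HyperbolicFit(
        amplitude=float(popt[0]),
        half_time=float(popt[1]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        ok=True,
    )
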