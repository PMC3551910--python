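"""Exact behavioral predictions by first-passage analysis of the policy.

Under a fixed true stimulus (success probability ``p_true``) the lattice
coordinate n_R performs a binomial random walk.  Propagating its occupancy
distribution forward, restricted to the sampling region of the solved
policy, yields the exact per-step probabilities of crossing into the
right- or left-choice regions — the reaction-time distributions — without
any Monte Carlo error.  Summaries over a coherence grid give the
psychometric (accuracy vs. coherence) and chronometric (mean RT vs.
coherence) functions; a linear regression maps model steps to milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .observation import MTParams, success_prob
from .policy import (
    GO_LEFT,
    GO_RIGHT,
    SAMPLE,
    NotConvergedError,
    PolicySolution,
    RewardParams,
    fit_hyperbolic_boundary,
    solve,
)

__all__ = [
    "BehaviorPrediction",
    "TimeCalibration",
    "first_passage",
    "choice_and_rt",
    "psychometric_chronometric",
    "speed_accuracy_tradeoff",
    "calibrate_time",
]


@dataclass
class BehaviorPrediction:
    """Exact first-passage summary for one true stimulus.

    ``survival[t]`` is the probability of still sampling after the action at
    step t; ``cross_right[t]`` / ``cross_left[t]`` the probability of first
    crossing into the respective choice region exactly at step t.  Mass still
    undecided when the horizon slice is reached is reported as ``leak`` and
    never renormalized; a converged policy keeps it at numerical zero.
    """

    p_true: float
    survival: np.ndarray
    cross_right: np.ndarray
    cross_left: np.ndarray

    @property
    def p_right(self) -> float:
        return float(self.cross_right.sum())

    @property
    def p_left(self) -> float:
        return float(self.cross_left.sum())

    @property
    def leak(self) -> float:
        return float(self.survival[-1])

    @property
    def conservation_residual(self) -> float:
        return abs(self.p_right + self.p_left + self.leak - 1.0)

    def mean_rt(self, side: str) -> float:
        """Mean crossing step conditioned on the choice; NaN (flagged) when
        that choice has zero probability."""
        h = self.cross_right if side == "right" else self.cross_left
        total = h.sum()
        if total <= 0.0:
            return float("nan")
        t = np.arange(h.size, dtype=float)
        return float((t * h).sum() / total)


def first_passage(sol: PolicySolution, p_true: float) -> BehaviorPrediction:
    """Propagate the occupancy distribution through the sampling region.

    Crossing masses are recorded for steps t < horizon; occupancy that
    reaches the truncated horizon slice (where sampling is disallowed) is
    classified as leak.  For a mirror-symmetric policy the left-crossing
    mass at each step is accumulated by reflecting the occupancy vector and
    summing over the *same* index set as the right mass, so that at
    p_true = 1/2 the two reaction-time distributions are bit-for-bit equal.
    """
    if not sol.converged:
        raise NotConvergedError(
            "policy is not stationarity-certified (converged=False); "
            "re-solve with a longer horizon before first-passage analysis"
        )
    if not 0.0 <= p_true <= 1.0:
        raise ValueError(f"p_true must lie in [0, 1], got {p_true}")
    n = sol.spikes_per_step
    horizon = sol.horizon
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_true)

    survival = np.zeros(horizon + 1)
    h_right = np.zeros(horizon + 1)
    h_left = np.zeros(horizon + 1)

    occ = np.array([1.0])  # occupancy over n_R at t=0
    acts = sol.action[0]
    if acts[0] == GO_RIGHT:
        h_right[0] = 1.0
        occ = np.array([0.0])
    elif acts[0] == GO_LEFT:
        h_left[0] = 1.0
        occ = np.array([0.0])
    survival[0] = occ.sum()

    for t in range(horizon):
        if not occ.any():
            break
        width = occ.size + n
        occ_next = np.zeros(width)
        for z in range(n + 1):
            if pmf[z] != 0.0:
                occ_next[z : z + occ.size] += pmf[z] * occ
        t1 = t + 1
        if t1 == horizon:
            survival[t1] = occ_next.sum()
            occ = np.zeros_like(occ_next)
            break
        acts = sol.action[t1]
        right_mask = acts == GO_RIGHT
        left_mask = acts == GO_LEFT
        if sol.symmetric and np.array_equal(right_mask[::-1], left_mask):
            # mirror-symmetric regions: accumulate the left mass by
            # reflecting the occupancy and summing over the same index set,
            # so both sums share a summation order (bit-exact at p = 1/2)
            if p_true == 0.5:
                occ_next = 0.5 * (occ_next + occ_next[::-1])
            h_right[t1] = occ_next[right_mask].sum()
            h_left[t1] = occ_next[::-1][right_mask].sum()
        else:
            h_right[t1] = occ_next[right_mask].sum()
            h_left[t1] = occ_next[left_mask].sum()
        occ = np.where(acts == SAMPLE, occ_next, 0.0)
        survival[t1] = occ.sum()

    return BehaviorPrediction(
        p_true=p_true, survival=survival, cross_right=h_right, cross_left=h_left
    )


def choice_and_rt(pred: BehaviorPrediction) -> tuple[float, float, float, float]:
    """(P_right, P_left, mean_rt_right, mean_rt_left); RTs in steps, NaN
    for a zero-probability choice."""
    return pred.p_right, pred.p_left, pred.mean_rt("right"), pred.mean_rt("left")


def psychometric_chronometric(
    sol: PolicySolution,
    mt: MTParams,
    coherences,
    direction: str = "right",
) -> pd.DataFrame:
    """Accuracy and mean reaction time (in steps) across a coherence grid.

    Accuracy is the probability of choosing the true direction conditioned
    on a decision being reached (the horizon leak, at most the converged
    contract's 1e-6, is excluded from the normalization); at zero coherence,
    where no direction is correct, it is the rightward-choice fraction,
    exactly 1/2 for a symmetric policy.  ``mean_rt_steps`` conditions on
    correct (true-direction) choices, ``mean_rt_error_steps`` on errors.
    """
    rows = []
    for c in np.asarray(coherences, dtype=float):
        p = success_prob(c, direction, mt)
        pred = first_passage(sol, p)
        decided = pred.p_right + pred.p_left
        p_corr = pred.p_right if direction == "right" else pred.p_left
        correct_side = direction
        error_side = "left" if direction == "right" else "right"
        rows.append(
            {
                "coherence": c,
                "p_true": p,
                "p_right": pred.p_right,
                "p_left": pred.p_left,
                "accuracy": p_corr / decided,
                "mean_rt_steps": pred.mean_rt(correct_side),
                "mean_rt_error_steps": pred.mean_rt(error_side),
                "leak": pred.leak,
            }
        )
    return pd.DataFrame(rows)


def speed_accuracy_tradeoff(
    reward_corrects,
    mt: MTParams,
    coherences,
    base_rewards: RewardParams | None = None,
    prior=None,
    n: int = 1,
    horizon: int = 400,
) -> pd.DataFrame:
    """Re-solve the policy across a grid of reward magnitudes and tabulate
    accuracy, mean RT and the fitted boundary half-time at each coherence.

    Raising the correct-choice reward relative to the (fixed) sampling cost
    makes observations more affordable: the boundary widens and collapses
    later, trading longer reaction times for higher accuracy.
    """
    base = base_rewards if base_rewards is not None else RewardParams()
    frames = []
    for rc in reward_corrects:
        r = RewardParams(
            sample_cost=base.sample_cost,
            reward_correct=float(rc),
            reward_error=base.reward_error,
        )
        sol = solve(r, prior=prior, n=n, horizon=horizon)
        t = np.arange(sol.horizon + 1)
        fit = fit_hyperbolic_boundary(t, sol.theta_right)
        tab = psychometric_chronometric(sol, mt, coherences)
        tab.insert(0, "reward_correct", rc)
        tab.insert(1, "reward_ratio", r.ratio)
        tab["boundary_half_time"] = fit.half_time if fit.ok else np.nan
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class TimeCalibration:
    """Linear map from model steps to milliseconds:
    RT_ms = ms_per_step * steps + residual_ms.

    ``residual_ms`` is the non-decision residual time (sensory and motor
    delays outside the evidence-accumulation process); ``rms_error_ms`` is
    the root-mean-square regression residual (zero for collinear input).
    """

    ms_per_step: float
    residual_ms: float
    rms_error_ms: float

    def steps_to_ms(self, steps) -> np.ndarray:
        return self.ms_per_step * np.asarray(steps, dtype=float) + self.residual_ms


def calibrate_time(expected_steps, observed_rt_ms) -> TimeCalibration:
    """Ordinary least squares of observed mean RT (ms) on predicted mean
    decision steps, one point per coherence condition."""
    x = np.asarray(expected_steps, dtype=float)
    y = np.asarray(observed_rt_ms, dtype=float)
    if x.size != y.size:
        raise ValueError("expected_steps and observed_rt_ms must align")
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError(
            "calibration needs at least two distinct step predictions"
        )
    xbar, ybar = x.mean(), y.mean()
    dx = x - xbar
    slope = float((dx * (y - ybar)).sum() / (dx * dx).sum())
    intercept = float(ybar - slope * xbar)
    resid = y - (slope * x + intercept)
    return TimeCalibration(
        ms_per_step=slope,
        residual_ms=intercept,
        rms_error_ms=float(np.sqrt(np.mean(resid**2))),
    )
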