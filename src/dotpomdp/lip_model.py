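"""LIP firing-rate read-out of the belief relative to the collapsing bound.

The policy only needs the two one-dimensional decision boundaries, which
suggests a neural implementation in which area-LIP neurons encode the gap
between the running point estimate p-hat and the rightward boundary:

    rate(t) = max(floor, B + kappa * (p_hat(t) - theta_R(t)))

A rightward saccade is triggered exactly when the rate reaches the fixed
bound B — the collapsing boundary in belief coordinates becomes a fixed
firing-rate bound, as observed physiologically.  Two signatures follow:
the zero-coherence response climbs along the image of the collapsing
boundary (the "urgency" signal), and the early slope of the
trial-averaged response (the buildup rate) is summarized per coherence
together with a linear fit of its scaling across coherence.
The left-preferring population is the mirror image (p_hat -> 1 - p_hat,
theta_R -> 1 - theta_L) and needs no separate code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .observation import MTParams, success_prob
from .policy import SAMPLE, PolicySolution

__all__ = [
    "LIPParams",
    "UrgencyFit",
    "lip_rate",
    "urgency_signal",
    "mean_lip_trajectory",
    "buildup_rates",
]


@dataclass(frozen=True)
class LIPParams:
    """Read-out parameters of the LIP rate model.

    bound_rate
        B, spikes/s: firing rate at which the decision is triggered.
    gain
        kappa, spikes/s per unit of (p_hat - theta_R); keeping gain <= B
        (as in the default) means the floor is never engaged, so the
        read-out stays affine in the point estimate.
    floor
        Lower clamp on the firing rate, spikes/s.
    buildup_window
        Number of early decision steps used for the buildup-rate line fit.
    """

    bound_rate: float = 60.0
    gain: float = 50.0
    floor: float = 0.0
    buildup_window: int = 20

    def __post_init__(self) -> None:
        if self.bound_rate <= 0 or self.gain < 0 or self.floor < 0:
            raise ValueError("LIP parameters out of range")
        if self.buildup_window < 2:
            raise ValueError("buildup_window must span at least 2 steps")


def lip_rate(p_hat: float, theta_r_t: float, lip: LIPParams) -> float:
    """Instantaneous LIP rate for point estimate p_hat against the boundary
    value theta_R(t).  Errors on an undefined (NaN) boundary."""
    if not np.isfinite(theta_r_t):
        raise ValueError("theta_R is undefined at this step")
    return max(lip.floor, lip.bound_rate + lip.gain * (p_hat - theta_r_t))


@dataclass(frozen=True)
class UrgencyFit:
    """Hyperbolic fit u(t) = B - A * tau / (t + tau) of the urgency signal;
    tau is the half-time of the remaining climb to the bound."""

    amplitude: float
    half_time: float
    rms_residual: float
    ok: bool


def fit_urgency_hyperbolic(
    t: np.ndarray, rate: np.ndarray, bound_rate: float
) -> UrgencyFit:
    """Least-squares fit of a saturating hyperbola with fixed asymptote B."""
    t = np.asarray(t, dtype=float)
    rate = np.asarray(rate, dtype=float)
    keep = np.isfinite(rate)
    t, rate = t[keep], rate[keep]
    if t.size < 5:
        raise ValueError("need at least 5 defined urgency points")
    deficit = bound_rate - rate
    if np.max(np.abs(deficit)) < 1e-9 or np.ptp(deficit) < 1e-9:
        return UrgencyFit(np.nan, np.nan, np.nan, ok=False)

    def model(tt, a, tau):
        return bound_rate - a * tau / (tt + tau)

    a0 = float(np.max(deficit))
    tau0 = max(float(t[np.argmin(np.abs(deficit - a0 / 2))]), 1.0)
    popt, _ = optimize.curve_fit(
        model, t, rate, p0=[a0, tau0], bounds=([1e-9, 1e-9], [np.inf, 1e9]),
        maxfev=20000,
    )
    resid = rate - model(t, *popt)
    return UrgencyFit(
        amplitude=float(popt[0]),
        half_time=float(popt[1]),
        rms_residual=float(np.sqrt(np.mean(resid**2))),
        ok=True,
    )


def urgency_signal(
    sol: PolicySolution, lip: LIPParams
) -> tuple[pd.DataFrame, UrgencyFit]:
    """Expected LIP rate for fully random motion, plus its hyperbolic fit.

    At zero coherence the expected point estimate is 1/2, so the signal is
    the direct image of the collapsing boundary:
    u(t) = B + kappa * (1/2 - theta_R(t)), rising toward B as the bound
    collapses.  Only steps with a defined boundary are included.
    """
    t = np.arange(sol.horizon + 1)
    theta = sol.theta_right
    defined = np.isfinite(theta)
    rate = np.where(
        defined,
        np.maximum(lip.floor, lip.bound_rate + lip.gain * (0.5 - theta)),
        np.nan,
    )
    table = pd.DataFrame({"t": t[defined], "urgency_rate": rate[defined]})
    fit = fit_urgency_hyperbolic(t[defined], rate[defined], lip.bound_rate)
    return table, fit


def mean_lip_trajectory(
    sol: PolicySolution, p_true: float, lip: LIPParams
) -> pd.DataFrame:
    """Survivor-conditioned expected LIP rate trajectory, computed exactly.

    At each step t the expectation runs over lattice cells still inside the
    sampling region (trials that have not yet decided — the same
    conditioning used for experimental trial averages), weighting the
    clamped per-cell rate by the exact occupancy from the first-passage
    recursion.  Steps with undefined boundary or negligible (< 1e-300)
    surviving mass are omitted.
    """
    if not 0.0 <= p_true <= 1.0:
        raise ValueError(f"p_true must lie in [0, 1], got {p_true}")
    from scipy import stats  # local: only binom pmf needed

    n = sol.spikes_per_step
    pmf = stats.binom.pmf(np.arange(n + 1), n, p_true)
    occ = np.array([1.0])
    rows = []
    for t in range(1, sol.horizon):
        width = occ.size + n
        occ_next = np.zeros(width)
        for z in range(n + 1):
            if pmf[z] != 0.0:
                occ_next[z : z + occ.size] += pmf[z] * occ
        if sol.symmetric and p_true == 0.5:
            occ_next = 0.5 * (occ_next + occ_next[::-1])
        acts = sol.action[t]
        occ = np.where(acts == SAMPLE, occ_next, 0.0)
        mass = occ.sum()
        theta = sol.theta_right[t]
        if np.isfinite(theta) and mass > 1e-300:
            p_hat = np.arange(occ.size) / (n * t)
            rates = np.maximum(
                lip.floor, lip.bound_rate + lip.gain * (p_hat - theta)
            )
            rows.append(
                {"t": t, "mean_rate": float((occ * rates).sum() / mass),
                 "survival": float(mass)}
            )
        if mass == 0.0:
            break
    return pd.DataFrame(rows)


def _line_slope(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    dx = x - x.mean()
    denom = (dx * dx).sum()
    if denom == 0.0:
        return float("nan")  # undefined slope on a degenerate abscissa
    return float((dx * (y - y.mean())).sum() / denom)


def buildup_rates(
    sol: PolicySolution,
    mt: MTParams,
    lip: LIPParams,
    coherences,
    n_trials: int | None = None,
    seed: int = 0,
    direction: str = "right",
) -> tuple[pd.DataFrame, float]:
    """Early slope of the LIP response per coherence, and its linear scaling.

    For each coherence the survivor-conditioned mean rate trajectory is fit
    with a line over the first ``lip.buildup_window`` steps with a defined
    boundary (truncated with a warning when fewer are available).
    With ``n_trials`` unset the exact occupancy-weighted
    trajectory is used; otherwise trajectories are averaged over seeded
    simulated trials.  Returns the per-coherence table and the slope of the
    least-squares line of buildup rate against coherence (per unit
    coherence; divide by 100 for per-percent).
    """
    rows = []
    for c in np.asarray(coherences, dtype=float):
        p = success_prob(c, direction, mt)
        if n_trials is None:
            traj = mean_lip_trajectory(sol, p, lip)
            t_arr = traj["t"].to_numpy()
            r_arr = traj["mean_rate"].to_numpy()
        else:
            t_arr, r_arr = _simulated_mean_trajectory(
                sol, p, lip, n_trials, seed, c
            )
        window = min(lip.buildup_window, t_arr.size)
        if window < 2:
            raise ValueError(
                "fewer than 2 trajectory points available for the "
                "buildup-rate fit; shrink buildup_window or the horizon gap"
            )
        if window < lip.buildup_window:
            warnings.warn(
                f"buildup window truncated to {window} steps at coherence "
                f"{c:g} (trajectory shorter than requested window)",
                stacklevel=2,
            )
        slope = _line_slope(t_arr[:window], r_arr[:window])
        rows.append({"coherence": c, "buildup_rate": slope})
    table = pd.DataFrame(rows)
    scaling = _line_slope(
        table["coherence"].to_numpy(), table["buildup_rate"].to_numpy()
    )
    return table, scaling


def _simulated_mean_trajectory(
    sol: PolicySolution,
    p_true: float,
    lip: LIPParams,
    n_trials: int,
    seed: int,
    coherence_key: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Monte-Carlo survivor-conditioned mean LIP trajectory."""
    from .simulate import _observation_matrix  # avoids a module cycle

    n = sol.spikes_per_step
    z = _observation_matrix(n_trials, sol.horizon, n, p_true, seed, coherence_key)
    cum = np.cumsum(z, axis=1)
    dense = sol.dense_action_table()
    theta = sol.theta_right
    ts, means = [], []
    alive = np.ones(n_trials, dtype=bool)
    for t in range(1, sol.horizon):
        n_t = cum[:, t - 1]
        alive = alive & (dense[t, n_t] == SAMPLE)
        if not np.isfinite(theta[t]):
            continue
        count = int(alive.sum())
        if count == 0:
            break
        p_hat = n_t[alive] / (n * t)
        rates = np.maximum(
            lip.floor, lip.bound_rate + lip.gain * (p_hat - theta[t])
        )
        ts.append(t)
        means.append(float(rates.mean()))
    return np.asarray(ts), np.asarray(means)
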