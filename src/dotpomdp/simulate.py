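"""Seeded Monte-Carlo trial generation — the synthetic stand-in for the
behavioral experiments, and the stochastic oracle for the exact
first-passage predictions.

Reproducibility contract: every trial's observation stream is generated by
its own counter-based seed ``SeedSequence([base_seed, stream_key,
trial_index])`` (stream_key derives from the coherence condition), so a
global seed plus the trial index fully determines each trial regardless of
batch size or execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .observation import MTParams, success_prob
from .policy import ACTION_NAMES, GO_RIGHT, SAMPLE, NotConvergedError, PolicySolution

__all__ = ["TrialRecord", "simulate_trial", "simulate_experiment"]

_CHUNK = 4096


def _stream_key(coherence_key: float) -> int:
    """Stable nonnegative integer key for a coherence condition."""
    return int(round(coherence_key * 10**6)) & 0x7FFFFFFF


def _observation_matrix(
    n_trials: int,
    horizon: int,
    n: int,
    p_true: float,
    base_seed: int,
    coherence_key: float,
    start_index: int = 0,
) -> np.ndarray:
    """(n_trials, horizon) int16 matrix of per-step right-spike counts.

    Observations are drawn by inverse-CDF from per-trial uniform streams,
    so trial rows are reproducible in isolation.
    """
    key = _stream_key(coherence_key)
    out = np.empty((n_trials, horizon), dtype=np.int16)
    for lo in range(0, n_trials, _CHUNK):
        hi = min(lo + _CHUNK, n_trials)
        u = np.stack(
            [
                np.random.default_rng(
                    np.random.SeedSequence([base_seed, key, start_index + i])
                ).random(horizon)
                for i in range(lo, hi)
            ]
        )
        if n == 1:
            # inverse CDF of Bernoulli(p): z = 1 iff u > 1 - p
            out[lo:hi] = (u > 1.0 - p_true).astype(np.int16)
        else:
            out[lo:hi] = stats.binom.ppf(u, n, p_true).astype(np.int16)
    return out


@dataclass
class TrialRecord:
    """One simulated trial: the stimulus, the observation stream up to the
    decision, and the resulting choice."""

    coherence: float
    direction: str
    base_seed: int
    trial_index: int
    observations: np.ndarray
    n_right_traj: np.ndarray  # cumulative right-spike count after each step
    decision_step: int
    choice: str


def _require_converged(sol: PolicySolution) -> None:
    if not sol.converged:
        raise NotConvergedError(
            "refusing to simulate with a policy that failed the "
            "stationarity check; increase the horizon"
        )


def _decide_paths(
    sol: PolicySolution, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized policy walk: (decision_step, choice_code, n_at_decision)."""
    n_trials, horizon = z.shape
    cum = np.cumsum(z, axis=1)
    states = np.zeros((n_trials, horizon + 1), dtype=np.int64)
    states[:, 1:] = cum
    dense = sol.dense_action_table()
    acts_path = dense[np.arange(horizon + 1)[None, :], states]
    stopped = acts_path != SAMPLE
    decision_step = np.argmax(stopped, axis=1)
    rows = np.arange(n_trials)
    choice_code = acts_path[rows, decision_step]
    n_at_decision = states[rows, decision_step]
    return decision_step, choice_code, n_at_decision


def simulate_trial(
    c: float,
    d: str,
    sol: PolicySolution,
    mt: MTParams,
    base_seed: int,
    trial_index: int = 0,
) -> TrialRecord:
    """Simulate one trial: draw observations under the true stimulus,
    update the belief lattice coordinate, act per the solved policy until a
    terminal action, and record the full trajectory up to the decision."""
    _require_converged(sol)
    p = success_prob(c, d, mt)
    z = _observation_matrix(
        1, sol.horizon, sol.spikes_per_step, p, base_seed, c, start_index=trial_index
    )
    step, code, _ = _decide_paths(sol, z)
    t_dec = int(step[0])
    return TrialRecord(
        coherence=c,
        direction=d,
        base_seed=base_seed,
        trial_index=trial_index,
        observations=z[0, :t_dec].copy(),
        n_right_traj=np.cumsum(z[0, :t_dec]),
        decision_step=t_dec,
        choice=ACTION_NAMES[int(code[0])].removeprefix("go_"),
    )


def simulate_experiment(
    coherences,
    n_trials: int,
    sol: PolicySolution,
    mt: MTParams,
    base_seed: int,
    direction: str = "right",
    return_trials: bool = False,
):
    """Run ``n_trials`` seeded trials at each coherence and summarize.

    Returns a per-coherence DataFrame with choice fractions, accuracy
    (fraction choosing the true direction; rightward fraction at c = 0),
    mean correct-choice RT in steps, and their standard errors.  With
    ``return_trials`` also returns the raw one-row-per-trial table.
    """
    _require_converged(sol)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    summaries = []
    raw_frames = []
    for c in np.asarray(coherences, dtype=float):
        p = success_prob(c, direction, mt)
        z = _observation_matrix(
            n_trials, sol.horizon, sol.spikes_per_step, p, base_seed, c
        )
        step, code, _ = _decide_paths(sol, z)
        chose_right = code == GO_RIGHT
        correct = chose_right if direction == "right" else ~chose_right
        acc = float(correct.mean())
        rt_corr = step[correct]
        rt_err = step[~correct]
        summaries.append(
            {
                "coherence": c,
                "p_true": p,
                "n_trials": n_trials,
                "p_right": float(chose_right.mean()),
                "accuracy": acc,
                "accuracy_sem": float(np.sqrt(acc * (1.0 - acc) / n_trials)),
                "mean_rt_steps": float(rt_corr.mean()) if rt_corr.size else np.nan,
                "rt_sem_steps": (
                    float(rt_corr.std(ddof=1) / np.sqrt(rt_corr.size))
                    if rt_corr.size > 1
                    else np.nan
                ),
                "mean_rt_error_steps": (
                    float(rt_err.mean()) if rt_err.size else np.nan
                ),
            }
        )
        if return_trials:
            raw_frames.append(
                pd.DataFrame(
                    {
                        "coherence": c,
                        "direction": direction,
                        "base_seed": base_seed,
                        "trial_index": np.arange(n_trials),
                        "decision_step": step,
                        "choice": np.where(chose_right, "right", "left"),
                    }
                )
            )
    summary = pd.DataFrame(summaries)
    if return_trials:
        return summary, pd.concat(raw_frames, ignore_index=True)
    return summary
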