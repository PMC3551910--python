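"""Stimulus encoding by motion-sensitive (MT) neurons.

The stimulus in the random-dots task is a pair ``(c, d)``: motion coherence
``c`` (fraction of dots moving coherently, in [0, 1]) and direction ``d``
(left or right).  Two opposing MT populations fire as Poisson processes whose
rates are linear in coherence: the population preferring the true direction
is driven up, the opposing one is driven down.  Conditioning on the total
spike count, the number of right-preferring spikes in a step of ``N`` spikes
is Binomial(N, p) with

    p = f_R / (f_R + f_L),

so a single number ``p`` jointly encodes direction (p > 1/2 means rightward)
and coherence (|p - 1/2| grows with c).  ``p`` is the hidden parameter the
decision maker must infer from spike counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

Direction = Literal["left", "right"]

__all__ = [
    "MTParams",
    "TaskState",
    "Observation",
    "firing_rates",
    "success_prob",
    "observation_pmf",
    "sample_step",
]


@dataclass(frozen=True)
class MTParams:
    """Linear rate model for the two MT populations.

    Parameters
    ----------
    base_rate
        Population firing rate in spikes/s at zero coherence (both
        populations fire at this rate for random motion).
    drive_pref
        Dimensionless gain of coherence in the preferred direction;
        rate = base_rate * (1 + drive_pref * c).
    drive_null
        Dimensionless suppression gain in the null direction;
        rate = base_rate * (1 - drive_null * c).  Must satisfy
        drive_null < 1 so the null rate stays positive at c = 1.
    spikes_per_step
        Observation granularity N: the belief is updated (and an action
        chosen) every N MT spikes.  N = 1 is the finest granularity —
        a decision opportunity at every spike.
    """

    base_rate: float = 40.0
    drive_pref: float = 1.0
    drive_null: float = 0.5
    spikes_per_step: int = 1

    def __post_init__(self) -> None:
        if self.base_rate <= 0:
            raise ValueError(f"base_rate must be positive, got {self.base_rate}")
        if self.drive_pref < 0 or self.drive_null < 0:
            raise ValueError("drive gains must be nonnegative")
        if self.drive_null >= 1:
            raise ValueError(
                f"drive_null must be < 1 so the null-direction rate stays "
                f"positive for all coherences, got {self.drive_null}"
            )
        if self.spikes_per_step < 1:
            raise ValueError("spikes_per_step must be a positive integer")


@dataclass(frozen=True)
class TaskState:
    """Hidden state of one trial: coherence, direction and the induced p."""

    coherence: float
    direction: Direction
    p: float


@dataclass(frozen=True)
class Observation:
    """One step's observation: count of right-preferring spikes out of N."""

    z: int
    n_right_raw: int | None = None
    n_left_raw: int | None = None
    duration_s: float | None = None


def _validate_coherence(c: float) -> None:
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"coherence must lie in [0, 1], got {c}")


def firing_rates(c: float, d: Direction, mt: MTParams) -> tuple[float, float]:
    """Mean rates (f_R, f_L) in spikes/s of the right- and left-preferring
    MT populations for a stimulus of coherence ``c`` moving in direction ``d``.
    """
    _validate_coherence(c)
    if mt.drive_null * c >= 1.0:
        raise ValueError("drive_null * c >= 1 gives a nonpositive null rate")
    up = mt.base_rate * (1.0 + mt.drive_pref * c)
    down = mt.base_rate * (1.0 - mt.drive_null * c)
    if d == "right":
        return up, down
    if d == "left":
        return down, up
    raise ValueError(f"direction must be 'left' or 'right', got {d!r}")


def success_prob(c: float, d: Direction, mt: MTParams) -> float:
    """Probability p that a given MT spike comes from the right-preferring
    population: p = f_R / (f_R + f_L)."""
    f_r, f_l = firing_rates(c, d, mt)
    return f_r / (f_r + f_l)


def task_state(c: float, d: Direction, mt: MTParams) -> TaskState:
    """Bundle the stimulus with its induced success probability."""
    return TaskState(coherence=c, direction=d, p=success_prob(c, d, mt))


def observation_pmf(z, n: int, p: float):
    """Binomial(N, p) mass of observing ``z`` right-preferring spikes out
    of ``n`` total.  Vectorized over ``z``."""
    z_arr = np.asarray(z)
    if np.any(z_arr < 0) or np.any(z_arr > n):
        raise ValueError(f"spike count z must lie in [0, {n}]")
    out = stats.binom.pmf(z_arr, n, p)
    return out if out.shape else float(out)


def sample_step(
    c: float,
    d: Direction,
    mt: MTParams,
    rng: np.random.Generator | int,
) -> Observation:
    """Draw one observation step from the Poisson race.

    Both populations emit Poisson spike trains; the step ends when the
    ``N``-th spike (from either population) arrives, so the step duration
    is the N-th arrival time of a rate-(f_R + f_L) Poisson process (Erlang
    distributed; exponential for N = 1).  Conditioned on the total count,
    each spike is right-preferring with probability p, so z | N is
    Binomial(N, p).  The raw per-population counts are reported alongside.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    f_r, f_l = firing_rates(c, d, mt)
    n = mt.spikes_per_step
    p = f_r / (f_r + f_l)
    z = int(rng.binomial(n, p))
    duration = float(rng.gamma(shape=n, scale=1.0 / (f_r + f_l)))
    return Observation(z=z, n_right_raw=z, n_left_raw=n - z, duration_s=duration)
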