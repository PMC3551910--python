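"""Conjugate beta belief over the spike-success probability p.

With Binomial(N, p) observations and a Beta(alpha0, beta0) prior, the
posterior after t steps is Beta(alpha0 + n_R, beta0 + n_L), where n_R and
n_L count right- and left-preferring spikes so far.  The whole belief state
is therefore the integer pair (n_R, n_L) — equivalently a point on the
(t, n_R) lattice — which is what makes the decision problem exactly
solvable by dynamic programming.

The posterior probability that the motion is rightward is
P(p > 1/2 | belief) = 1 - I_{1/2}(alpha, beta), with I the regularized
incomplete beta function (the beta CDF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "PriorParams",
    "BeliefState",
    "update_belief",
    "point_estimate",
    "posterior_mean",
    "prob_direction_right",
    "posterior_density",
]


@dataclass(frozen=True)
class PriorParams:
    """Beta prior over p.  alpha0 = beta0 gives the symmetric prior used
    throughout (no a-priori bias toward either direction); the uniform
    prior is alpha0 = beta0 = 1."""

    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("prior parameters must be positive")

    @property
    def symmetric(self) -> bool:
        return self.alpha0 == self.beta0


@dataclass(frozen=True)
class BeliefState:
    """Beta(alpha, beta) posterior over p, tagged with its prior so the
    observation counts can be recovered."""

    alpha: float
    beta: float
    prior: PriorParams = PriorParams()

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("belief parameters must be positive")

    @property
    def n_right(self) -> float:
        """Right-preferring spikes observed so far."""
        return self.alpha - self.prior.alpha0

    @property
    def n_total(self) -> float:
        """Total spikes observed so far."""
        return (self.alpha - self.prior.alpha0) + (self.beta - self.prior.beta0)

    @classmethod
    def from_counts(
        cls, n_right: int, n_total: int, prior: PriorParams = PriorParams()
    ) -> "BeliefState":
        if not 0 <= n_right <= n_total:
            raise ValueError("need 0 <= n_right <= n_total")
        return cls(
            alpha=prior.alpha0 + n_right,
            beta=prior.beta0 + (n_total - n_right),
            prior=prior,
        )


def update_belief(b: BeliefState, z: int, n: int) -> BeliefState:
    """Conjugate update after observing z right-preferring spikes out of n:
    (alpha, beta) -> (alpha + z, beta + n - z)."""
    if not 0 <= z <= n:
        raise ValueError(f"observation z must lie in [0, {n}], got {z}")
    return BeliefState(alpha=b.alpha + z, beta=b.beta + (n - z), prior=b.prior)


def point_estimate(b: BeliefState) -> float:
    """Count-ratio estimator n_R / (n_R + n_L) of p.

    This is the quantity the decision boundaries are drawn against.  Before
    the first observation it is defined as 1/2, the symmetry point of the
    prior.  The posterior mean alpha / (alpha + beta) is available
    separately via :func:`posterior_mean`.
    """
    if b.n_total <= 0:
        return 0.5
    return b.n_right / b.n_total


def posterior_mean(b: BeliefState) -> float:
    """Posterior mean of p, alpha / (alpha + beta) (diagnostic)."""
    return b.alpha / (b.alpha + b.beta)


def prob_direction_right(b: BeliefState) -> float:
    """P(motion is rightward | belief) = P(p > 1/2) = 1 - I_{1/2}(a, b).

    Computed as I_{1/2}(beta, alpha) via the reflection identity of the
    regularized incomplete beta function, avoiding the cancellation in
    ``1 - I`` when the posterior is nearly one-sided.
    """
    return float(special.betainc(b.beta, b.alpha, 0.5))


def posterior_density(b: BeliefState, p_grid: np.ndarray) -> np.ndarray:
    """Beta posterior density evaluated on a grid in (0, 1)."""
    p_grid = np.asarray(p_grid, dtype=float)
    if np.any(p_grid <= 0) or np.any(p_grid >= 1):
        raise ValueError("p_grid must lie strictly inside (0, 1)")
    return stats.beta.pdf(p_grid, b.alpha, b.beta)
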