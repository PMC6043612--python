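"""Memory-less differentiation (decision) process.

A cell that has not yet committed to a lineage decides with hazard rate
λ(t) = max(0, a0 + a1·t), a clipped linear function of absolute
experiment time (hours since movie start).  The clipping keeps the event
density valid when a1 < 0 (a decreasing hazard, as fitted to real
genealogies); past the zero-crossing the hazard stays 0 and the total
decision probability saturates below 1, interpreted as "the cell never
differentiates".

Quantities follow standard survival analysis:

* cumulative hazard  Λ(t) = ∫₀ᵗ λ(τ) dτ                 (analytic, piecewise quadratic)
* event density      ϕ(t) = λ(t)·exp(−Λ(t))
* decision CDF       Φ(t) = 1 − exp(−Λ(t))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DecisionParams",
    "hazard",
    "cumulative_hazard",
    "decision_density",
    "decision_cdf",
    "total_decision_probability",
    "sample_decision_time",
    "NEVER",
]

#: sentinel decision time of a cell that never differentiates
NEVER = np.inf


@dataclass(frozen=True)
class DecisionParams:
    """Linear-hazard parameters θ = (a0, a1).

    a0: rate per hour at t=0, must be >= 0.
    a1: slope of the hazard per hour^2, any sign.
    """

    a0: float
    a1: float = 0.0

    def __post_init__(self):
        if self.a0 < 0:
            raise ValueError("a0 must be nonnegative")


def _check_t(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be nonnegative")
    return t


def hazard(t, theta: DecisionParams):
    """λ(t) = max(0, a0 + a1·t)."""
    t = _check_t(t)
    return np.maximum(0.0, theta.a0 + theta.a1 * t)


def cumulative_hazard(t, theta: DecisionParams):
    """Λ(t) = ∫₀ᵗ max(0, a0 + a1·τ) dτ, closed form.

    For a1 >= 0 the hazard never clips on t >= 0.  For a1 < 0 it reaches
    zero at t_c = a0/|a1| and Λ is constant beyond.
    """
    t = _check_t(t)
    a0, a1 = theta.a0, theta.a1
    if a1 >= 0:
        return a0 * t + 0.5 * a1 * t * t
    tc = a0 / (-a1)
    tt = np.minimum(t, tc)
    return a0 * tt + 0.5 * a1 * tt * tt


def decision_density(t, theta: DecisionParams):
    """ϕ(t) = λ(t)·exp(−Λ(t)); a (sub-)density when the hazard clips."""
    return hazard(t, theta) * np.exp(-cumulative_hazard(t, theta))


def decision_cdf(t, theta: DecisionParams):
    """Φ(t) = 1 − exp(−Λ(t)); Φ(0) = 0, nondecreasing."""
    return -np.expm1(-cumulative_hazard(t, theta))


def total_decision_probability(theta: DecisionParams) -> float:
    """Φ(∞).  Equals 1 − exp(−a0²/(2|a1|)) for a1 < 0, else 1 (or 0 if λ≡0)."""
    if theta.a1 < 0:
        return float(-np.expm1(-theta.a0 ** 2 / (2.0 * -theta.a1)))
    if theta.a0 == 0 and theta.a1 == 0:
        return 0.0
    return 1.0


def sample_decision_time(theta: DecisionParams, rng, size=None):
    """Inverse-CDF samples of decision times; ``inf`` means "never".

    Solves Λ(t) = E with E ~ Exp(1).  When the hazard clips (a1 < 0)
    draws with E > Λ(∞) never differentiate.
    """
    rng = np.random.default_rng(rng)
    e = rng.exponential(size=size)
    a0, a1 = theta.a0, theta.a1
    scalar = np.isscalar(e)
    e = np.atleast_1d(np.asarray(e, dtype=float))
    out = np.full(e.shape, NEVER)
    if a1 == 0:
        if a0 > 0:
            out = e / a0
    elif a1 > 0:
        # a1/2 t^2 + a0 t - e = 0
        out = (-a0 + np.sqrt(a0 * a0 + 2.0 * a1 * e)) / a1
    else:
        lam_max = a0 ** 2 / (2.0 * -a1)
        ok = e < lam_max
        disc = a0 * a0 + 2.0 * a1 * e[ok]
        out[ok] = (-a0 + np.sqrt(np.maximum(disc, 0.0))) / a1
    return float(out[0]) if scalar and size is None else out
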