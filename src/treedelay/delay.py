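"""Stochastic marker-expression delay: birth-death process with an
absorbing detection threshold.

After the (unobserved) decision, marker expression is modelled as a
birth-death process on protein copy number x: production at constant
rate α (zeroth order) and removal at rate γ·x (first order).  The
marker becomes observable when x first crosses the detection threshold
x*; the dynamics beyond x* are irrelevant, so the master equation is
solved on the transient states {0, ..., x*−1} with an absorbing
boundary at x*.

Two quantities drive the tree likelihood:

* the propagator P_{x→x'}(t): probability to be (still sub-threshold)
  in state x' after time t having started in x;
* the first-passage density ψ_{x0}(t) = α · P_{x0→x*−1}(t), the
  probability flux across the threshold.

Both are obtained from the transient sub-generator A via matrix
exponentials, which keeps the absolute error at solver precision
(likelihoods multiply many such terms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DelayParams",
    "DelaySolution",
    "transient_generator",
    "propagator_matrix",
    "propagator",
    "solve_master_equation",
    "first_passage_density",
    "first_passage_moments",
    "sample_first_passage",
    "simulate_birth_death_interval",
]


@dataclass(frozen=True)
class DelayParams:
    """Delay-process parameters η = (α, γ, x*).

    alpha: protein production rate per hour (> 0 for a live marker).
    gamma: per-molecule degradation rate per hour (>= 0).
    x_star: integer detection threshold (>= 1).
    """

    alpha: float
    gamma: float
    x_star: int

    def __post_init__(self):
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("rates must be nonnegative")
        if int(self.x_star) != self.x_star or self.x_star < 1:
            raise ValueError("x_star must be an integer >= 1")
        object.__setattr__(self, "x_star", int(self.x_star))


@dataclass
class DelaySolution:
    """Master-equation solution from one start state on a time grid."""

    time_grid: np.ndarray
    sub_threshold_prob: np.ndarray  # (n_times, x_star) over states 0..x*-1
    absorbed_mass: np.ndarray  # cumulative crossing probability per time
    start_state: int


def transient_generator(eta: DelayParams) -> np.ndarray:
    """Sub-generator A on transient states {0..x*−1}.

    Row sums are 0 except for the boundary row x*−1, which leaks
    probability into the absorbing (detected) state at rate α.
    """
    n = eta.x_star
    a = np.zeros((n, n))
    states = np.arange(n)
    a[states, states] = -(eta.alpha + eta.gamma * states)
    if n > 1:
        a[states[:-1], states[:-1] + 1] = eta.alpha
        a[states[1:], states[1:] - 1] = eta.gamma * states[1:]
    return a


def propagator_matrix(eta: DelayParams, t: float) -> np.ndarray:
    """P(t) = exp(A t) restricted to sub-threshold states."""
    if t < 0:
        raise ValueError("time must be nonnegative")
    return expm(transient_generator(eta) * t)


def propagator(eta: DelayParams, x_from: int, x_to: int, t: float) -> float:
    """P_{x→x'}(t); both states must lie in 0..x*−1."""
    n = eta.x_star
    if not (0 <= x_from < n and 0 <= x_to < n):
        raise ValueError(f"states must lie in 0..{n - 1}")
    return float(propagator_matrix(eta, t)[x_from, x_to])


def solve_master_equation(eta: DelayParams, x0: int, t_grid) -> DelaySolution:
    """Master-equation solution for start state x0 on a strictly
    increasing time grid starting at 0.

    ``x0 == x_star`` means already detected: all mass absorbed at t=0.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid[0] != 0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing from 0")
    n = eta.x_star
    if not (0 <= x0 <= n):
        raise ValueError(f"x0 must lie in 0..{n}")
    if x0 == n:
        probs = np.zeros((len(t_grid), n))
        return DelaySolution(t_grid, probs, np.ones(len(t_grid)), x0)
    a = transient_generator(eta)
    probs = np.empty((len(t_grid), n))
    p = np.zeros(n)
    p[x0] = 1.0
    probs[0] = p
    # step with exact matrix exponentials between grid points
    dts = np.diff(t_grid)
    cache: dict[float, np.ndarray] = {}
    for i, dt in enumerate(dts):
        key = round(float(dt), 12)
        step = cache.get(key)
        if step is None:
            step = expm(a * dt)
            cache[key] = step
        p = p @ step
        probs[i + 1] = p
    absorbed = 1.0 - probs.sum(axis=1)
    return DelaySolution(t_grid, probs, np.clip(absorbed, 0.0, 1.0), x0)


def first_passage_density(eta: DelayParams, x0: int, t) -> np.ndarray | float:
    """ψ_{x0}(t) = α·P_{x0→x*−1}(t), the threshold-crossing flux.

    Requires x0 < x* (for x0 = x* the distribution is an atom at t=0,
    represented by :func:`solve_master_equation`).
    """
    n = eta.x_star
    if not (0 <= x0 < n):
        raise ValueError(f"x0 must lie in 0..{n - 1}")
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("time must be nonnegative")
    a = transient_generator(eta)
    e0 = np.zeros(n)
    e0[x0] = 1.0
    out = np.empty(len(t_arr))
    for i, ti in enumerate(t_arr):
        out[i] = eta.alpha * (e0 @ expm(a * ti))[n - 1]
    return float(out[0]) if scalar else out


def first_passage_moments(eta: DelayParams, x0: int) -> tuple[float, float]:
    """(mean, variance) of the first-passage time from x0 (< x*).

    Uses m = (−A)⁻¹·1 and E[T²] = 2(−A)⁻²·1; absorption is certain
    whenever α > 0.
    """
    n = eta.x_star
    if not (0 <= x0 < n):
        raise ValueError(f"x0 must lie in 0..{n - 1}")
    if eta.alpha <= 0:
        return np.inf, np.inf
    neg_a = -transient_generator(eta)
    ones = np.ones(n)
    m1 = np.linalg.solve(neg_a, ones)
    m2 = 2.0 * np.linalg.solve(neg_a, m1)
    mean = m1[x0]
    return float(mean), float(m2[x0] - mean**2)


# -- stochastic simulation (exact SSA) ------------------------------------

def sample_first_passage(
    eta: DelayParams, x0: int, rng, size: int, t_max: float = np.inf
) -> np.ndarray:
    """Gillespie samples of the threshold-crossing time (vectorised in
    lock-step across samples); times > t_max are returned as inf."""
    rng = np.random.default_rng(rng)
    n = eta.x_star
    x = np.full(size, x0, dtype=np.int64)
    t = np.zeros(size)
    result = np.full(size, np.inf)
    alive = np.arange(size)
    while alive.size:
        birth = np.full(alive.size, eta.alpha)
        death = eta.gamma * x[alive]
        total = birth + death
        t[alive] += rng.exponential(1.0 / total)
        up = rng.random(alive.size) * total < birth
        x[alive] += np.where(up, 1, -1)
        crossed = x[alive] >= n
        done_time = t[alive] > t_max
        hit = crossed & ~done_time
        result[alive[hit]] = t[alive[hit]]
        alive = alive[~(crossed | done_time)]
    return result


def simulate_birth_death_interval(
    eta: DelayParams, x0: int, duration: float, rng
) -> tuple[int, float | None]:
    """Propagate one cell's marker state over ``duration`` hours.

    Returns ``(x_end, crossing_time)`` where ``crossing_time`` is the
    time offset of the first threshold crossing within the interval, or
    None if the state stays sub-threshold.
    """
    n = eta.x_star
    x = x0
    t = 0.0
    alpha, gamma = eta.alpha, eta.gamma
    expo = rng.exponential
    uni = rng.random
    while True:
        total = alpha + gamma * x
        if total <= 0:
            return x, None
        t += expo(1.0 / total)
        if t > duration:
            return x, None
        if uni() * total < alpha:
            x += 1
            if x >= n:
                return x, t
        else:
            x -= 1
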