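"""Branching-process model of colony-assay frequencies.

A colony grows from a single founding cell for N generations.  In
generation i the (still undecided) cell differentiates with probability
λ(i), picking the GM lineage with probability p_GM and the MegE lineage
otherwise; an undecided cell divides into two cells that found
independent sub-colonies.  The probability of observing a *pure* GM
colony satisfies the recursion

    f_GM(N, i) = λ(i)·p_GM + (1 − λ(i))·f_GM(N−1, i+1)²,   f_GM(0, ·) = 0

with F_GM(N) = f_GM(N, 1); F_MegE analogously with p_MegE = 1 − p_GM,
and the mixed/undifferentiated complement F_GMMegE = 1 − F_GM − F_MegE.
(Colonies whose founder never decides within N generations are not
pure, so they fall into the GMMegE complement by definition.)

The per-generation decision probabilities λ(i) are obtained from the
continuous hazard λ(t) by averaging the within-generation decision
probability over the birth time s_i and cycle length c_i of a
generation-i cell:  λ(i) = E[1 − exp(−∫_{s_i}^{s_i+c_i} λ(τ)dτ)].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import DecisionParams, cumulative_hazard
from .simulate import CellCycleSpec

__all__ = [
    "ColonyModel",
    "discretize_hazard",
    "colony_frequencies",
    "sweep_pgm",
    "simulate_colonies",
]


@dataclass(frozen=True)
class ColonyModel:
    """Generation-indexed decision probabilities plus the lineage bias."""

    lambda_gen: tuple[float, ...]  # λ(i) for i = 1..len; last value reused beyond
    p_gm: float
    n_generations: int = 10

    def __post_init__(self):
        if not self.lambda_gen:
            raise ValueError("lambda_gen must not be empty")
        if any(not 0.0 <= v <= 1.0 for v in self.lambda_gen):
            raise ValueError("all lambda(i) must lie in [0, 1]")
        if not 0.0 <= self.p_gm <= 1.0:
            raise ValueError("p_gm must lie in [0, 1]")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")

    def lam(self, i: int) -> float:
        """λ(i), 1-based generation index."""
        return self.lambda_gen[min(i, len(self.lambda_gen)) - 1]


def discretize_hazard(
    theta: DecisionParams,
    cellcycle: CellCycleSpec,
    n_generations: int,
    rng,
    n_samples: int = 100_000,
) -> np.ndarray:
    """Monte-Carlo discretisation λ(i) = E[1 − e^(−ΔΛ over generation i)].

    Lineages are sampled jointly: cycle lengths c_1..c_N are drawn per
    generation (allowing prolonged early generations) and birth times
    accumulate along the lineage (s_1 = 0, s_{i+1} = s_i + c_i), so the
    (s_i, c_i) expectation respects within-lineage correlations.
    """
    rng = np.random.default_rng(rng)
    c = np.empty((n_samples, n_generations))
    for g in range(n_generations):
        mean = (
            cellcycle.generation_means[g]
            if g < len(cellcycle.generation_means)
            else cellcycle.mean
        )
        if cellcycle.family == "fixed" or cellcycle.sd == 0:
            c[:, g] = mean
        else:
            shape = (mean / cellcycle.sd) ** 2
            scale = cellcycle.sd**2 / mean
            c[:, g] = rng.gamma(shape, scale, size=n_samples)
    s = np.concatenate([np.zeros((n_samples, 1)), np.cumsum(c, axis=1)[:, :-1]], axis=1)
    dlam = cumulative_hazard(s + c, theta) - cumulative_hazard(s, theta)
    return np.asarray(-np.expm1(-dlam)).mean(axis=0)


def _pure_colony_probability(model: ColonyModel, p_lineage: float) -> float:
    """f(N, 1) for a pure colony of one lineage (probability p_lineage)."""
    f_next = np.zeros(model.n_generations + 2)  # f(0, i) = 0
    # iterate n = 1..N; f(n, i) needs f(n-1, i+1)
    f_prev = f_next.copy()
    for n in range(1, model.n_generations + 1):
        f_cur = np.zeros_like(f_prev)
        for i in range(1, model.n_generations + 2 - n):
            lam = model.lam(i)
            f_cur[i] = lam * p_lineage + (1.0 - lam) * f_prev[i + 1] ** 2
        f_prev = f_cur
    return float(f_prev[1])


def colony_frequencies(model: ColonyModel) -> tuple[float, float, float]:
    """(F_GM, F_MegE, F_GMMegE); sums to 1 exactly by construction."""
    f_gm = _pure_colony_probability(model, model.p_gm)
    f_mege = _pure_colony_probability(model, 1.0 - model.p_gm)
    return f_gm, f_mege, 1.0 - f_gm - f_mege


def sweep_pgm(lambda_gen, n_generations: int, grid) -> np.ndarray:
    """Frequency triples along a grid of p_GM values — the one-parameter
    curve traced by the model in (F_GM, F_MegE, F_GMMegE) space."""
    grid = np.asarray(grid, dtype=float)
    if np.any((grid < 0) | (grid > 1)):
        raise ValueError("p_gm grid must lie in [0, 1]")
    out = np.empty((grid.size, 3))
    for j, p in enumerate(grid):
        out[j] = colony_frequencies(
            ColonyModel(tuple(lambda_gen), float(p), n_generations)
        )
    return out


def simulate_colonies(model: ColonyModel, n_colonies: int, rng) -> np.ndarray:
    """Direct Monte-Carlo of the branching process; returns observed
    (F_GM, F_MegE, F_GMMegE) frequencies.

    Each colony is expanded generation by generation (vectorised across
    colonies); a colony is pure GM iff every terminal lineage decided GM.
    Used as the independent cross-check of the recursion.
    """
    rng = np.random.default_rng(rng)

    GM, MEGE, UNDEC = 1, 2, 4

    def grow(n: int, i: int, count: int) -> np.ndarray:
        """Bit-masks of lineage outcomes for `count` cells at generation
        i with n division rounds remaining."""
        if count == 0:
            return np.zeros(0, dtype=np.int8)
        if n == 0:
            return np.full(count, UNDEC, dtype=np.int8)
        lam = model.lam(i)
        decides = rng.random(count) < lam
        n_dec = int(decides.sum())
        out = np.empty(count, dtype=np.int8)
        out[decides] = np.where(rng.random(n_dec) < model.p_gm, GM, MEGE)
        n_undec = count - n_dec
        kids = grow(n - 1, i + 1, n_undec) | grow(n - 1, i + 1, n_undec)
        out[~decides] = kids
        return out

    masks = grow(model.n_generations, 1, n_colonies)
    f_gm = float(np.mean(masks == GM))
    f_mege = float(np.mean(masks == MEGE))
    return np.array([f_gm, f_mege, 1.0 - f_gm - f_mege])
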