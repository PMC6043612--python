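"""Generative simulator of genealogies under the decision + delay model.

Each tree starts from a single undecided cell at t = 0 (movie start).
Cells divide after sampled cell-cycle lengths until the movie ends.
While a lineage is undecided, every cell independently commits with the
time-dependent hazard λ(t); after the decision, marker expression runs
as the birth-death delay process from x0 = 0, its state is inherited at
division (copied to both daughters by default), and the branch's onset
is recorded when the copy number first crosses the detection threshold.
By default tracking of a branch stops at marker detection (as in the
real assay, where the fate of the branch is then known), so onset cells
are leaves censored at their onset time.

The simulator returns the observable genealogies together with the
hidden ground truth (which cells decided, and when) for recovery
experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .decision import DecisionParams, cumulative_hazard
from .delay import DelayParams, simulate_birth_death_interval
from .genealogy import Cell, EndReason, FateLabel, Genealogy

__all__ = [
    "CellCycleSpec",
    "SimConfig",
    "SimResult",
    "simulate_trees",
    "sister_onset_correlation",
]


@dataclass(frozen=True)
class CellCycleSpec:
    """Cell-cycle length distribution.

    family: "gamma" (default) or "fixed".
    mean/sd in hours; ``generation_means`` optionally overrides the mean
    for the first generations (index 0 = founding cell), emulating the
    prolonged cycles of freshly activated stem cells.
    """

    family: str = "gamma"
    mean: float = 12.0
    sd: float = 5.0
    generation_means: tuple[float, ...] = ()

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean cell cycle must be positive")
        if self.family not in ("gamma", "fixed"):
            raise ValueError(f"unknown cell-cycle family {self.family!r}")

    def sample(self, generation: int, rng) -> float:
        mean = (
            self.generation_means[generation]
            if generation < len(self.generation_means)
            else self.mean
        )
        if self.family == "fixed" or self.sd == 0:
            return mean
        shape = (mean / self.sd) ** 2
        scale = self.sd**2 / mean
        return float(rng.gamma(shape, scale))


@dataclass(frozen=True)
class SimConfig:
    theta: DecisionParams = DecisionParams(a0=0.15, a1=-0.002)
    eta: DelayParams = DelayParams(alpha=0.5, gamma=0.01, x_star=25)
    cellcycle: CellCycleSpec = CellCycleSpec()
    movie_end: float = 120.0
    n_trees: int = 100
    inheritance_mode: str = "copy"  # or "binomial"
    loss_rate: float = 0.0  # per-hour tracking-loss hazard
    prune_after_onset: bool = True
    fate_label: FateLabel = FateLabel.NONE

    def __post_init__(self):
        if self.movie_end <= 0:
            raise ValueError("movie_end must be positive")
        if self.inheritance_mode not in ("copy", "binomial"):
            raise ValueError(f"unknown inheritance_mode {self.inheritance_mode!r}")


@dataclass
class SimResult:
    trees: list[Genealogy]
    #: tree_id -> {cell_id: decision_time} for cells in which a decision fell
    decisions: dict[str, dict[str, float]] = field(default_factory=dict)

    def decision_generations(self) -> list[int]:
        gens = []
        by_id = {t.tree_id: t for t in self.trees}
        for tid, dec in self.decisions.items():
            tree = by_id[tid]
            gens.extend(tree.cells[cid].generation for cid in dec)
        return gens


def _sample_decision_after(theta: DecisionParams, t0: float, rng) -> float:
    """First decision time conditional on no decision before t0 (inf = never)."""
    a0, a1 = theta.a0, theta.a1
    target = float(cumulative_hazard(t0, theta)) + rng.exponential()
    # solve Lambda(t) = target
    if a1 == 0:
        return target / a0 if a0 > 0 else math.inf
    if a1 > 0:
        return (-a0 + math.sqrt(a0 * a0 + 2.0 * a1 * target)) / a1
    lam_max = a0 * a0 / (2.0 * -a1)
    if target >= lam_max:
        return math.inf
    return (-a0 + math.sqrt(a0 * a0 + 2.0 * a1 * target)) / a1


def simulate_trees(config: SimConfig, rng) -> SimResult:
    """Simulate ``config.n_trees`` genealogies; see module docstring."""
    rng = np.random.default_rng(rng)
    trees: list[Genealogy] = []
    all_decisions: dict[str, dict[str, float]] = {}
    for i in range(config.n_trees):
        tree_id = f"sim{i:04d}"
        tree, decisions = _simulate_one(config, tree_id, rng)
        trees.append(tree)
        all_decisions[tree_id] = decisions
    return SimResult(trees=trees, decisions=all_decisions)


def _simulate_one(config, tree_id, rng) -> tuple[Genealogy, dict[str, float]]:
    theta, eta = config.theta, config.eta
    cells: dict[str, Cell] = {}
    decisions: dict[str, float] = {}
    # stack entries: (cell_id, birth, generation, lineage_state)
    # lineage_state: None if undecided, else (decision_time, x_at_birth, post_onset)
    stack = [("1", 0.0, 0, None)]
    while stack:
        cid, birth, gen, state = stack.pop()
        cycle = config.cellcycle.sample(gen, rng)
        end = birth + cycle
        reason = EndReason.DIVISION
        if end >= config.movie_end:
            end = config.movie_end
            reason = EndReason.MOVIE_END
        if config.loss_rate > 0:
            t_lost = birth + rng.exponential(1.0 / config.loss_rate)
            if t_lost < end:
                end, reason = t_lost, EndReason.LOST

        if state is None:
            t_dec = _sample_decision_after(theta, birth, rng)
            if t_dec <= end:
                decisions[cid] = t_dec
                state = (t_dec, 0, False)

        onset = None
        if state is not None:
            t_dec, x_birth, post_onset = state
            if not post_onset:
                start = max(birth, t_dec)
                x_end, t_cross = simulate_birth_death_interval(
                    eta, x_birth, end - start, rng
                )
                if t_cross is not None:
                    onset = start + t_cross
                    if config.prune_after_onset:
                        end, reason = onset, EndReason.LOST
                    else:
                        state = (t_dec, x_end, True)
                else:
                    state = (t_dec, x_end, False)

        cells[cid] = Cell(
            cell_id=cid,
            parent_id=cid[:-1] if len(cid) > 1 else None,
            birth_time=birth,
            end_time=end,
            end_reason=reason,
            onset_time=onset,
        )
        if reason == EndReason.DIVISION:
            if state is not None and not state[2]:
                t_dec, x_end, _ = state
                if config.inheritance_mode == "binomial":
                    x_left = int(rng.binomial(x_end, 0.5))
                    child_states = [(t_dec, x_left, False), (t_dec, x_end - x_left, False)]
                else:  # copy: both daughters resume at the mother's level
                    child_states = [(t_dec, x_end, False)] * 2
            else:
                child_states = [state, state]
            for suffix, cs in zip("01", child_states):
                stack.append((cid + suffix, end, gen + 1, cs))

    tree = Genealogy(
        tree_id=tree_id,
        cells=cells,
        fate_label=config.fate_label,
        movie_end=config.movie_end,
    )
    return tree, decisions


def sister_onset_correlation(trees, min_pairs: int = 20) -> tuple[float, int]:
    """Pearson correlation of sister cells' onset times.

    Onsets are taken relative to the pair's shared birth time; pooling
    absolute times across pairs born at different moments would show
    correlation even for completely independent sisters.

    Returns (r, n_pairs); raises ValueError when fewer than ``min_pairs``
    sister pairs with onsets are available (correlation undefined).
    """
    a, b = [], []
    for tree in trees:
        for cell in tree.cells.values():
            kids = tree.children(cell.cell_id)
            if len(kids) == 2 and all(k.has_onset for k in kids):
                a.append(kids[0].onset_time - kids[0].birth_time)
                b.append(kids[1].onset_time - kids[1].birth_time)
    n = len(a)
    if n < min_pairs:
        raise ValueError(
            f"only {n} sister onset pairs (< {min_pairs}); correlation undefined"
        )
    # symmetrise: sister order is arbitrary
    x = np.array(a + b)
    y = np.array(b + a)
    return float(np.corrcoef(x, y)[0, 1]), n
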