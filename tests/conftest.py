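import numpy as np
import pytest

from treedelay.decision import DecisionParams
from treedelay.delay import DelayParams
from treedelay.genealogy import Cell, EndReason, FateLabel, Genealogy
from treedelay.simulate import CellCycleSpec, SimConfig, simulate_trees


def make_tree(spec, tree_id="t0", fate=FateLabel.NONE, movie_end=None):
    """Build a genealogy from a compact spec.

    ``spec`` maps cell_id -> (parent_id, birth, end, end_reason, onset);
    cell ids follow the heap convention ("1" root, children append 0/1).
    """
    cells = {}
    for cid, (pid, b, e, reason, onset) in spec.items():
        cells[cid] = Cell(
            cell_id=cid,
            parent_id=pid,
            birth_time=b,
            end_time=e,
            end_reason=EndReason(reason),
            onset_time=onset,
        )
    if movie_end is None:
        movie_end = max(c.end_time for c in cells.values())
    tree = Genealogy(tree_id=tree_id, cells=cells, fate_label=fate, movie_end=movie_end)
    tree.validate()
    return tree


@pytest.fixture
def single_onset_tree():
    """One root cell, censored at 20 h, onset at 12 h."""
    return make_tree({"1": (None, 0.0, 20.0, "lost", 12.0)})


@pytest.fixture
def cherry_onset_tree():
    """Mother divides at 10 h; both daughters have onsets."""
    return make_tree(
        {
            "1": (None, 0.0, 10.0, "division", None),
            "10": ("1", 10.0, 22.0, "lost", 18.0),
            "11": ("1", 10.0, 24.0, "lost", 20.0),
        }
    )


@pytest.fixture(scope="session")
def small_sim_trees():
    """~25 small genealogies for oracle comparisons (short movie)."""
    cfg = SimConfig(
        theta=DecisionParams(0.05, 0.0),
        eta=DelayParams(alpha=1.0, gamma=0.05, x_star=8),
        cellcycle=CellCycleSpec(mean=10, sd=3),
        movie_end=40.0,
        n_trees=25,
    )
    return simulate_trees(cfg, np.random.default_rng(0)).trees


@pytest.fixture(scope="session")
def default_sim():
    """A moderate dataset at the documented study conditions."""
    return simulate_trees(
        SimConfig(n_trees=60), np.random.default_rng(123)
    )
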