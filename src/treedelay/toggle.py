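"""Gillespie simulation of a tristable genetic toggle switch on
dividing lineages.

Two transcription factors A (PU.1-like) and B (GATA1-like) mutually
repress each other and weakly self-activate:

    production_A = (basal + amp · A^n / (K_self^n + A^n)) · K_rep^m / (K_rep^m + B^m)
    degradation_A = deg · A                     (B symmetric)

With the default parameters the stochastic system has three metastable
states: a central progenitor state (A ≈ B) and two committed states
with one factor high and the other repressed.  Commitment is a
noise-driven escape from the central well and is effectively
irreversible on culture timescales, so the quasi-potential −log P is
estimated from the pooled occupancy of an ensemble of trajectories
started in the progenitor state (a single run would only ever sample
one committed well).  Wells are found as local minima of the smoothed
potential and basin boundaries by watershed segmentation; a cell is
called lineage-marker positive when its trajectory first enters a
committed basin.

Simulated genealogies export as ordinary :class:`~treedelay.genealogy.
Genealogy` objects (basin entry = marker onset, branch tracking pruned
at onset) plus per-cell (A, B) signal tracks, so the full inference
stack can be validated end to end on data where the ground-truth
decision mechanism is a toggle switch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genealogy import Cell, EndReason, FateLabel, Genealogy, SignalTrack
from .simulate import CellCycleSpec

__all__ = [
    "ToggleParams",
    "BasinCall",
    "QuasiPotential",
    "SSATrajectory",
    "ssa_trajectory",
    "quasi_potential",
    "ToggleSimResult",
    "simulate_toggle_genealogy",
    "simulate_toggle_genealogies",
    "divergence_alignment",
]


@dataclass(frozen=True)
class ToggleParams:
    """Symmetric mutual-repression toggle with self-activation.

    Defaults were tuned (at package build time) so that the
    quasi-potential has exactly three wells and the mean residence time
    in the progenitor well is on the order of one to two cell cycles.
    Rates are per hour; copy numbers are literal molecule counts, so at
    division molecules are binomially partitioned by default.
    """

    basal: float = 5.0
    amp: float = 10.0
    k_self: float = 30.0
    n_self: int = 4
    k_rep: float = 25.0
    n_rep: int = 2
    deg: float = 0.25
    division: str = "binomial_partition"  # or "copy"
    species: tuple[str, str] = ("A", "B")

    def __post_init__(self):
        if min(self.basal, self.amp, self.k_self, self.k_rep, self.deg) < 0:
            raise ValueError("rates and thresholds must be nonnegative")
        if self.n_self < 1 or self.n_rep < 1:
            raise ValueError("Hill coefficients must be >= 1")
        if self.division not in ("binomial_partition", "copy"):
            raise ValueError(f"unknown division mode {self.division!r}")

    def production(self, a: float, b: float) -> tuple[float, float]:
        sa = a**self.n_self / (self.k_self**self.n_self + a**self.n_self) if a else 0.0
        sb = b**self.n_self / (self.k_self**self.n_self + b**self.n_self) if b else 0.0
        ra = (self.basal + self.amp * sa) * self.k_rep**self.n_rep / (
            self.k_rep**self.n_rep + b**self.n_rep
        )
        rb = (self.basal + self.amp * sb) * self.k_rep**self.n_rep / (
            self.k_rep**self.n_rep + a**self.n_rep
        )
        return ra, rb

    def progenitor_state(self) -> tuple[int, int]:
        """Deterministic symmetric fixed point (the central well)."""
        x = self.basal / self.deg
        for _ in range(200):
            ra, _ = self.production(x, x)
            x = ra / self.deg
        return int(round(x)), int(round(x))


@dataclass
class BasinCall:
    """First-entry basin classification of one cell's trajectory."""

    state: str  # progenitor | A_committed | B_committed
    entry_time: float | None = None


@dataclass
class SSATrajectory:
    times: np.ndarray
    a: np.ndarray
    b: np.ndarray
    final_state: tuple[int, int]
    event_times: np.ndarray | None = None
    event_states: np.ndarray | None = None


def _ssa(params: ToggleParams, a: int, b: int, duration: float, rng,
         sample_dt: float, record_events: bool = False) -> SSATrajectory:
    t = 0.0
    next_s = 0.0
    ts, as_, bs = [], [], []
    ev_t, ev_s = [], []
    expo = rng.exponential
    uni = rng.random
    deg = params.deg
    prod = params.production
    while True:
        ra, rb = prod(a, b)
        da, db = deg * a, deg * b
        tot = ra + rb + da + db
        t_next = t + (expo(1.0 / tot) if tot > 0 else math.inf)
        while next_s <= min(t_next, duration) + 1e-12:
            ts.append(next_s)
            as_.append(a)
            bs.append(b)
            next_s += sample_dt
        if t_next > duration:
            break
        t = t_next
        u = uni() * tot
        if u < ra:
            a += 1
        elif u < ra + rb:
            b += 1
        elif u < ra + rb + da:
            a -= 1
        else:
            b -= 1
        if record_events:
            ev_t.append(t)
            ev_s.append((a, b))
    return SSATrajectory(
        np.array(ts), np.array(as_, dtype=float), np.array(bs, dtype=float),
        (a, b),
        np.array(ev_t) if record_events else None,
        np.array(ev_s) if record_events else None,
    )


def ssa_trajectory(
    params: ToggleParams,
    initial: tuple[int, int],
    duration: float,
    rng,
    sample_dt: float = 0.5,
    record_events: bool = False,
) -> SSATrajectory:
    """Exact stochastic simulation of the toggle switch (no divisions)."""
    rng = np.random.default_rng(rng)
    return _ssa(params, int(initial[0]), int(initial[1]), float(duration), rng,
                sample_dt, record_events)


# ---------------------------------------------------------------------------
# quasi-potential and basins
# ---------------------------------------------------------------------------

@dataclass
class QuasiPotential:
    """−log P over the (A, B) plane with well/basin annotations."""

    potential: np.ndarray  # (na, nb), np.inf where unvisited
    occupancy: np.ndarray  # normalised histogram (sums to 1)
    labels: np.ndarray  # watershed basin label per bin (1-based)
    minima: list[tuple[int, int]]  # (A, B) bin coordinates of the wells
    roles: dict  # label -> "progenitor" | "A_committed" | "B_committed"

    @property
    def n_wells(self) -> int:
        return len(self.minima)

    def label_at(self, a, b) -> np.ndarray:
        na, nb = self.labels.shape
        ai = np.clip(np.asarray(a, dtype=int), 0, na - 1)
        bi = np.clip(np.asarray(b, dtype=int), 0, nb - 1)
        return self.labels[ai, bi]

    def state_at(self, a, b):
        lab = np.atleast_1d(self.label_at(a, b))
        return np.array([self.roles[int(v)] for v in lab])


def quasi_potential(
    params: ToggleParams,
    rng,
    n_chains: int = 100,
    t_chain: float = 150.0,
    burn_in: float = 5.0,
    sample_dt: float = 0.25,
    smooth_sigma: float = 1.5,
) -> QuasiPotential:
    """Ensemble estimate of the quasi-potential −log P.

    ``n_chains`` trajectories are started in the progenitor state and
    their sampled occupancies pooled; see the module docstring for why
    an ensemble replaces a single stationary run.  Raises ValueError if
    the landscape does not show exactly three wells (the parameterisation
    contract).
    """
    from scipy.ndimage import gaussian_filter, label as cc_label, minimum_filter
    from skimage.segmentation import watershed

    rng = np.random.default_rng(rng)
    start = params.progenitor_state()
    all_a, all_b = [], []
    for _ in range(n_chains):
        tr = _ssa(params, start[0], start[1], t_chain, rng, sample_dt)
        keep = tr.times >= burn_in
        all_a.append(tr.a[keep])
        all_b.append(tr.b[keep])
    a = np.concatenate(all_a)
    b = np.concatenate(all_b)
    amax = int(max(a.max(), b.max())) + 2
    hist, _, _ = np.histogram2d(a, b, bins=[np.arange(amax + 1)] * 2)
    occ = hist / hist.sum()

    with np.errstate(divide="ignore"):
        pot = -np.log(occ)
    filled = np.where(np.isfinite(pot), pot, np.nanmax(pot[np.isfinite(pot)]) + 1.0)
    smooth = gaussian_filter(filled, smooth_sigma)

    visited = hist > 0
    is_min = (smooth == minimum_filter(smooth, size=9)) & visited
    markers0, n_min = cc_label(is_min)
    # merge marker plateaus, then fuse minima closer than 8 bins
    # (sampling jitter can split a shallow well into nearby pits)
    raw = []
    for lab in range(1, n_min + 1):
        ys, xs = np.nonzero(markers0 == lab)
        raw.append((int(round(ys.mean())), int(round(xs.mean()))))
    minima: list[tuple[int, int]] = []
    for m in sorted(raw, key=lambda m: smooth[m[0], m[1]]):
        if all(max(abs(m[0] - o[0]), abs(m[1] - o[1])) > 8 for o in minima):
            minima.append(m)
    markers = np.zeros_like(markers0)
    for i, m in enumerate(minima, start=1):
        markers[m[0], m[1]] = i
    labels = watershed(smooth, markers)

    if len(minima) != 3:
        raise ValueError(
            f"quasi-potential shows {len(minima)} wells, expected 3 "
            "(progenitor + two committed); adjust the parameterisation"
        )
    diffs = [m[0] - m[1] for m in minima]
    order = np.argsort(diffs)  # most B-biased, central, most A-biased
    roles_by_min = {order[0]: "B_committed", order[1]: "progenitor", order[2]: "A_committed"}
    if not (diffs[order[0]] < 0 < diffs[order[2]]):
        raise ValueError("committed wells are not on opposite sides of the diagonal")
    roles = {}
    for i, m in enumerate(minima):
        roles[int(labels[m[0], m[1]])] = roles_by_min[i]
    pot_masked = np.where(visited, pot, np.inf)
    return QuasiPotential(pot_masked, occ, labels, minima, roles)


# ---------------------------------------------------------------------------
# genealogies driven by the toggle switch
# ---------------------------------------------------------------------------

@dataclass
class ToggleSimResult:
    trees: list[Genealogy]
    tracks: dict  # tree_id -> list[SignalTrack] (intensity = A copies, area = 1)
    tracks_b: dict  # tree_id -> list[SignalTrack] for species B
    basin_calls: dict  # (tree_id, cell_id) -> BasinCall
    onset_sides: dict  # (tree_id, cell_id) -> "A" | "B" for onset cells
    escape_times: dict = field(default_factory=dict)
    # (tree_id, onset_cell_id) -> last time on the branch in the progenitor basin


def simulate_toggle_genealogy(
    params: ToggleParams,
    qp: QuasiPotential,
    cellcycle: CellCycleSpec,
    movie_end: float,
    rng,
    tree_id: str = "toggle0000",
    sample_dt: float = 0.5,
    initial_state: tuple[int, int] | None = None,
) -> ToggleSimResult:
    """One genealogy with intracellular toggle dynamics.

    Marker onset of a branch = first entry of its trajectory into a
    committed basin (first-entry semantics); tracking of the branch
    stops there.  At division molecule counts are binomially
    partitioned between the daughters (or copied, per ``params``).
    """
    rng = np.random.default_rng(rng)
    cells: dict[str, Cell] = {}
    tracks: list[SignalTrack] = []
    tracks_b: list[SignalTrack] = []
    calls: dict = {}
    sides: dict = {}

    start = initial_state if initial_state is not None else params.progenitor_state()
    stack = [("1", 0.0, 0, start)]
    while stack:
        cid, birth, gen, state = stack.pop()
        cycle = cellcycle.sample(gen, rng)
        end = birth + cycle
        reason = EndReason.DIVISION
        if end >= movie_end:
            end, reason = movie_end, EndReason.MOVIE_END
        tr = _ssa(params, state[0], state[1], end - birth, rng, sample_dt)
        labels = qp.state_at(tr.a, tr.b)
        committed = np.flatnonzero(labels != "progenitor")
        onset = None
        if committed.size:
            j = committed[0]
            onset = birth + tr.times[j]
            side = "A" if labels[j] == "A_committed" else "B"
            if onset <= birth:  # snap degenerate first-sample entries
                onset = min(birth + sample_dt, end)
            end, reason = onset, EndReason.LOST
            keep = tr.times <= (onset - birth) + 1e-9
            tr = SSATrajectory(tr.times[keep], tr.a[keep], tr.b[keep], tr.final_state)
            calls[(tree_id, cid)] = BasinCall(f"{side}_committed", onset)
            sides[(tree_id, cid)] = side
        else:
            calls[(tree_id, cid)] = BasinCall("progenitor")

        cells[cid] = Cell(
            cell_id=cid,
            parent_id=cid[:-1] if len(cid) > 1 else None,
            birth_time=birth,
            end_time=end,
            end_reason=reason,
            onset_time=onset,
        )
        tracks.append(SignalTrack(cid, list(birth + tr.times), list(tr.a), [1.0] * len(tr.times)))
        tracks_b.append(SignalTrack(cid, list(birth + tr.times), list(tr.b), [1.0] * len(tr.times)))
        if reason == EndReason.DIVISION:
            a_end, b_end = tr.final_state
            if params.division == "binomial_partition":
                a0 = int(rng.binomial(a_end, 0.5))
                b0 = int(rng.binomial(b_end, 0.5))
                child_states = [(a0, b0), (a_end - a0, b_end - b0)]
            else:
                child_states = [(a_end, b_end)] * 2
            for suffix, cs in zip("01", child_states):
                stack.append((cid + suffix, end, gen + 1, cs))

    side_set = set(sides.values())
    fate = (
        FateLabel.MIXED if side_set == {"A", "B"}
        else FateLabel.GM if side_set == {"A"}
        else FateLabel.MEGE if side_set == {"B"}
        else FateLabel.NONE
    )
    tree = Genealogy(tree_id=tree_id, cells=cells, fate_label=fate, movie_end=movie_end)

    # ground-truth divergence: last visit of the branch to the progenitor
    # basin before its onset, scanning the lineage path backwards
    track_by_id = {t.cell_id: (np.array(t.times), np.array(t.intensities)) for t in tracks}
    track_b_by_id = {t.cell_id: np.array(t.intensities) for t in tracks_b}
    escapes = {}
    for cid, call in list(calls.items()):
        if call.entry_time is None:
            continue
        ccid = cid[1]
        esc = None
        cur = ccid
        while cur is not None and esc is None:
            tt, aa = track_by_id[cur]
            bb = track_b_by_id[cur]
            lab = qp.state_at(aa, bb)
            prog = np.flatnonzero(lab == "progenitor")
            if prog.size:
                esc = float(tt[prog[-1]])
            cur = cells[cur].parent_id
        escapes[(tree_id, ccid)] = esc if esc is not None else 0.0

    return ToggleSimResult(
        trees=[tree],
        tracks={tree_id: tracks},
        tracks_b={tree_id: tracks_b},
        basin_calls=calls,
        onset_sides=sides,
        escape_times=escapes,
    )


def simulate_toggle_genealogies(
    params: ToggleParams,
    qp: QuasiPotential,
    cellcycle: CellCycleSpec,
    movie_end: float,
    n_trees: int,
    rng,
    sample_dt: float = 0.5,
) -> ToggleSimResult:
    rng = np.random.default_rng(rng)
    out = ToggleSimResult([], {}, {}, {}, {}, {})
    for i in range(n_trees):
        one = simulate_toggle_genealogy(
            params, qp, cellcycle, movie_end, rng,
            tree_id=f"toggle{i:04d}", sample_dt=sample_dt,
        )
        out.trees.extend(one.trees)
        out.tracks.update(one.tracks)
        out.tracks_b.update(one.tracks_b)
        out.basin_calls.update(one.basin_calls)
        out.onset_sides.update(one.onset_sides)
        out.escape_times.update(one.escape_times)
    return out


def divergence_alignment(
    result: ToggleSimResult,
    decision_times: dict,
) -> list[dict]:
    """Single-branch (A, B) trajectories re-indexed to the predicted
    decision time.

    ``decision_times`` maps (tree_id, decision_cell_id) -> t̂ (hours).
    For every onset branch whose lineage passes through a predicted
    decision cell, the concatenated root-to-onset trajectory is returned
    with times shifted so the predicted decision sits at 0.
    """
    by_tree = {t.tree_id: t for t in result.trees}
    aligned = []
    for (tree_id, onset_cid) in list(result.onset_sides):
        tree = by_tree[tree_id]
        # lineage path root -> onset cell
        path = []
        cur = onset_cid
        while cur is not None:
            path.append(cur)
            cur = tree.cells[cur].parent_id
        path.reverse()
        that = None
        dec_cell = None
        for cid in path:
            if (tree_id, cid) in decision_times:
                that = decision_times[(tree_id, cid)]
                dec_cell = cid
        if that is None:
            continue
        tr_a = {t.cell_id: t for t in result.tracks[tree_id]}
        tr_b = {t.cell_id: t for t in result.tracks_b[tree_id]}
        times, avals, bvals = [], [], []
        for cid in path:
            times.extend(tr_a[cid].times)
            avals.extend(tr_a[cid].intensities)
            bvals.extend(tr_b[cid].intensities)
        aligned.append(
            {
                "tree_id": tree_id,
                "onset_cell": onset_cid,
                "decision_cell": dec_cell,
                "times": np.asarray(times) - that,
                "a": np.asarray(avals),
                "b": np.asarray(bvals),
                "side": result.onset_sides[(tree_id, onset_cid)],
            }
        )
    return aligned
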