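"""Hidden-tree likelihood: scoring differentiation scenarios on genealogies.

An observed genealogy T with marker onsets can be explained by many
"hidden trees": assignments of the unobserved decision event to an
antichain of cells (no decision cell is an ancestor of another) such
that every onset cell descends from (or is) a decision cell.  Cells
unrelated to any onset may or may not carry an invisible decision whose
marker expression was censored; both alternatives are scored.

The likelihood of one hidden tree factorises into

* a product over the undecided cells U of the probability of not
  deciding during each cell's lifetime, exp(−ΔΛ)  (the decision process
  is memory-less and runs on absolute time), and
* a term per decision-rooted subtree D_i: the decision time t' is
  integrated over the decision cell's lifetime with density
  λ(t')·exp(−(Λ(t')−Λ(birth))) (conditioned on lineage survival to the
  cell's birth — ancestors contribute the survival up to that point),
  convolved with the delay process propagated down the subtree.
  Within a cell the birth-death propagator applies; at division both
  daughters copy the mother's expression state and are conditionally
  independent *given* that state; an onset leaf contributes the
  first-passage flux at the observed time; a censored leaf contributes
  the remaining sub-threshold mass.

The total likelihood is the sum over all hidden trees, evaluated by a
post-order dynamic program: each cell carries the summed likelihood of
its induced subtree given "lineage undecided at my birth",

    A(c) = L_D(c) + S_c · Π_children A(child)          (no onset in c)
    A(c) = L_D(c)                                      (onset in c)

where S_c = exp(−ΔΛ_c) is the no-decision factor.  Replacing the sum by
a max (with backtracking) yields the most likely scenario; keeping
sorted k-lists yields the k-best scenarios.

Numerics: event times are snapped to a uniform time grid (default
0.25 h) shared by the trapezoidal decision-time quadrature and the
delay propagators, which are exact matrix exponentials on grid steps.
Both the dynamic program and the explicit-enumeration reference use the
same snapped representation, so they agree to floating-point accuracy
on small trees; grid refinement controls the quantisation error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import expm
from scipy.special import logsumexp

from .decision import DecisionParams, cumulative_hazard, hazard
from .delay import DelayParams, transient_generator
from .genealogy import Genealogy

__all__ = [
    "HiddenTree",
    "TreeLikelihood",
    "TreeLikelihoodEngine",
    "enumerate_hidden_trees",
    "likelihood_undiff",
    "likelihood_subtree",
    "likelihood_tree",
    "likelihood_tree_enumerated",
    "map_hidden_tree",
    "predicted_decision_generation",
    "snap_tree",
]

DEFAULT_GRID_H = 0.25  # hours


@dataclass(frozen=True)
class HiddenTree:
    """One differentiation scenario: an antichain of decision cells."""

    tree_ref: str
    decision_cells: frozenset

    def undiff_cells(self, tree: Genealogy) -> frozenset:
        """Cells in U: not equal to nor descended from a decision cell."""
        out = []
        stack = [tree.root.cell_id]
        while stack:
            cid = stack.pop()
            if cid in self.decision_cells:
                continue
            out.append(cid)
            if not tree.cells[cid].has_onset:
                stack.extend(c.cell_id for c in tree.children(cid))
        return frozenset(out)


@dataclass
class TreeLikelihood:
    """Log-likelihood of an observed genealogy (Σ over hidden trees)."""

    tree_ref: str
    log_likelihood: float


def snap_tree(tree: Genealogy, h: float) -> Genealogy:
    """Copy of ``tree`` with all event times quantised to multiples of h."""

    def q(t):
        return None if t is None else round(t / h) * h

    cells = {}
    for c in tree.cells.values():
        cells[c.cell_id] = replace(
            c, birth_time=q(c.birth_time), end_time=q(c.end_time), onset_time=q(c.onset_time)
        )
    return Genealogy(
        tree_id=tree.tree_id,
        cells=cells,
        fate_label=tree.fate_label,
        movie_end=round(tree.movie_end / h) * h if math.isfinite(tree.movie_end) else tree.movie_end,
    )


# ---------------------------------------------------------------------------
# explicit enumeration (reference path; exponential in tree size)
# ---------------------------------------------------------------------------

def _pruned_ids(tree: Genealogy) -> list[str]:
    """Cell ids with descendants of onset cells removed (they carry no
    information: the marker has already been detected on the branch)."""
    out = []
    stack = [tree.root.cell_id]
    while stack:
        cid = stack.pop()
        out.append(cid)
        if not tree.cells[cid].has_onset:
            stack.extend(c.cell_id for c in tree.children(cid))
    return out


def enumerate_hidden_trees(tree: Genealogy, max_cells: int = 31) -> list[HiddenTree]:
    """All valid decision antichains of ``tree``.

    Intended as a reference for small trees: the count grows doubly
    exponentially, so trees with more than ``max_cells`` informative
    cells are rejected.
    """
    n_informative = len(_pruned_ids(tree))
    if n_informative > max_cells:
        raise ValueError(
            f"tree has {n_informative} informative cells > guard {max_cells}; "
            "enumeration is exponential — use the dynamic program instead"
        )

    def rec(cid: str) -> list[frozenset]:
        cell = tree.cells[cid]
        if cell.has_onset:
            return [frozenset([cid])]
        kids = tree.children(cid)
        options = [frozenset([cid])]
        if not kids:
            options.append(frozenset())
        else:
            l, r = kids
            for sl in rec(l.cell_id):
                for sr in rec(r.cell_id):
                    options.append(sl | sr)
        return options

    return [HiddenTree(tree.tree_id, s) for s in rec(tree.root.cell_id)]


def likelihood_undiff(tree: Genealogy, cells, theta: DecisionParams) -> float:
    """Log-probability that every cell in ``cells`` stays undecided
    throughout its lifetime: −Σ (Λ(end)−Λ(birth)).  Analytic."""
    total = 0.0
    for cid in cells:
        c = tree.cells[cid]
        total -= float(
            cumulative_hazard(c.end_time, theta) - cumulative_hazard(c.birth_time, theta)
        )
    return total


class _DelayGrid:
    """Exact propagators of the delay process on a uniform time grid.

    P[k] = exp(A·k·h) on the transient states; u[k] = P[k][0, :] is the
    state profile started from x0 = 0 (expression starts at zero copies
    after the decision).
    """

    def __init__(self, eta: DelayParams, h: float, n_steps: int):
        self.eta, self.h = eta, h
        n = eta.x_star
        a = transient_generator(eta)
        step = expm(a * h)
        self.P = np.empty((n_steps + 1, n, n))
        self.P[0] = np.eye(n)
        for k in range(1, n_steps + 1):
            self.P[k] = self.P[k - 1] @ step
        self.u = self.P[:, 0, :]


def likelihood_subtree(
    tree: Genealogy,
    root_id: str,
    theta: DecisionParams,
    eta: DelayParams,
    h: float = DEFAULT_GRID_H,
    grid: _DelayGrid | None = None,
) -> float:
    """Log-likelihood of the decision-rooted subtree D at ``root_id``.

    Recursive message passing over the marker state, then trapezoidal
    integration of the latent decision time over the root cell's
    lifetime (truncated at its own onset, if any).  Times are snapped to
    the grid; see module docstring.
    """
    n = eta.x_star
    root = tree.cells[root_id]

    def k_of(t):
        return round(t / h)

    if grid is None:
        # conservative: longest span below the root
        max_end = max(c.end_time for c in tree.cells.values())
        grid = _DelayGrid(eta, h, k_of(max_end) - k_of(root.birth_time) + 1)

    def msg(cid: str) -> np.ndarray:
        """P(observations in subtree | marker state at this cell's birth)."""
        c = tree.cells[cid]
        kb = k_of(c.birth_time)
        if c.has_onset:
            return eta.alpha * grid.P[k_of(c.onset_time) - kb][:, n - 1]
        kids = tree.children(cid)
        dur = k_of(c.end_time) - kb
        if not kids:
            return grid.P[dur].sum(axis=1)
        w = msg(kids[0].cell_id) * msg(kids[1].cell_id)
        return grid.P[dur] @ w

    # weight vector over the state at the root's *effective end*
    # (onset time if it has one, else its division/censoring end)
    if root.has_onset:
        w = np.zeros(n)
        w[n - 1] = eta.alpha
        k_end = k_of(root.onset_time)
    else:
        kids = tree.children(root_id)
        if kids:
            w = msg(kids[0].cell_id) * msg(kids[1].cell_id)
        else:
            w = np.ones(n)
        k_end = k_of(root.end_time)

    kb = k_of(root.birth_time)
    if k_end <= kb:
        return -np.inf  # no room for a decision before the onset
    ks = np.arange(kb, k_end + 1)
    t_nodes = ks * h
    lam = hazard(t_nodes, theta)
    dlam = cumulative_hazard(t_nodes, theta) - float(cumulative_hazard(kb * h, theta))
    g = grid.u[k_end - ks] @ w  # (n_nodes,)
    integrand = lam * np.exp(-dlam) * g
    val = float(np.trapezoid(integrand, dx=h))
    return math.log(val) if val > 0 else -np.inf


def likelihood_tree_enumerated(
    tree: Genealogy,
    theta: DecisionParams,
    eta: DelayParams,
    h: float = DEFAULT_GRID_H,
    max_cells: int = 31,
    return_scenarios: bool = False,
):
    """Σ over explicitly enumerated hidden trees (reference path)."""
    snapped = snap_tree(tree, h)
    scen = enumerate_hidden_trees(snapped, max_cells=max_cells)
    max_end = max(c.end_time for c in snapped.cells.values())
    grid = _DelayGrid(eta, h, round(max_end / h) + 1)
    subtree_ll: dict[str, float] = {}
    undiff_ll = {
        cid: likelihood_undiff(snapped, [cid], theta) for cid in snapped.cells
    }
    logls = []
    for s in scen:
        ll = sum(undiff_ll[cid] for cid in s.undiff_cells(snapped))
        for d in s.decision_cells:
            if d not in subtree_ll:
                subtree_ll[d] = likelihood_subtree(snapped, d, theta, eta, h, grid=grid)
            ll += subtree_ll[d]
        logls.append(ll)
    total = float(logsumexp(logls)) if logls else -np.inf
    if return_scenarios:
        return total, list(zip(scen, logls))
    return total


# ---------------------------------------------------------------------------
# dynamic-programming engine (vectorised across all cells of all trees)
# ---------------------------------------------------------------------------

class TreeLikelihoodEngine:
    """Vectorised likelihood over a set of genealogies.

    The per-dataset structure (grid indices, windows, topology) is built
    once; per delay-parameter work (propagators, messages) is cached so
    the decision parameters can be re-scored cheaply — the layout the
    profile-likelihood optimiser exploits.
    """

    def __init__(self, trees, h: float = DEFAULT_GRID_H, quad_stride: int = 1):
        self.trees = list(trees)
        self.h = float(h)
        self.quad_stride = int(quad_stride)
        if self.quad_stride < 1:
            raise ValueError("quad_stride must be >= 1")
        self._eta = None
        self._build()

    # -- structure ---------------------------------------------------------
    def _build(self) -> None:
        h = self.h
        ids: list[tuple[int, str]] = []
        kb, ke, keff, onset, depth, left, right = [], [], [], [], [], [], []
        roots = []

        for ti, tree in enumerate(self.trees):
            def visit(cid: str, d: int) -> int:
                c = tree.cells[cid]
                i = len(kb)
                ids.append((ti, cid))
                b = round(c.birth_time / h)
                e = round(c.end_time / h)
                kb.append(b)
                ke.append(e)
                onset.append(c.has_onset)
                keff.append(round(c.onset_time / h) if c.has_onset else e)
                depth.append(d)
                left.append(-1)
                right.append(-1)
                kids = [] if c.has_onset else tree.children(cid)
                if kids:
                    left[i] = visit(kids[0].cell_id, d + 1)
                    right[i] = visit(kids[1].cell_id, d + 1)
                return i

            roots.append(visit(tree.root.cell_id, 0))

        self.ids = ids
        self.kb = np.asarray(kb, dtype=np.int64)
        self.ke = np.asarray(ke, dtype=np.int64)
        self.keff = np.asarray(keff, dtype=np.int64)
        self.onset = np.asarray(onset, dtype=bool)
        self.depth = np.asarray(depth, dtype=np.int64)
        self.left = np.asarray(left, dtype=np.int64)
        self.right = np.asarray(right, dtype=np.int64)
        self.roots = np.asarray(roots, dtype=np.int64)
        nc = len(ids)

        self.wl = self.keff - self.kb  # decision-window lengths (grid steps)
        self.life = self.ke - self.kb
        self.maxdur = int(max(self.wl.max(initial=0), self.life.max(initial=0)))
        self.kt = int(max(self.keff.max(initial=0), self.ke.max(initial=0)))
        lmax = int(self.wl.max(initial=0))

        # decision-time quadrature nodes: every quad_stride-th grid point
        # of each cell's window plus its end point (trapezoid weights on
        # the possibly-shorter last interval); quad_stride=1 is the plain
        # composite trapezoid on the grid.
        q = self.quad_stride
        m = lmax // q + 1
        j = np.arange(m + 1)
        nodes = np.minimum(j[None, :] * q, self.wl[:, None])  # (nc, m+1)
        gaps = np.diff(nodes, axis=1)
        trap = np.zeros((nc, m + 1))
        trap[:, :-1] += 0.5 * gaps
        trap[:, 1:] += 0.5 * gaps
        self.trap = trap * h
        self.tidx = np.minimum(self.kb[:, None] + nodes, self.kt)
        self.sidx = self.wl[:, None] - nodes
        self._col = np.arange(nc)

        # depth levels, deepest first, split by role
        self.levels = []
        for d in range(int(self.depth.max(initial=0)), -1, -1):
            idx = np.flatnonzero(self.depth == d)
            self.levels.append(idx)

    @property
    def n_cells(self) -> int:
        return len(self.ids)

    # -- delay-parameter stage --------------------------------------------
    def set_eta(self, eta: DelayParams) -> None:
        """(Re)compute messages and state-profile windows for η."""
        if self._eta == eta:
            return
        grid = _DelayGrid(eta, self.h, self.maxdur)
        n = eta.x_star
        nc = self.n_cells
        psi_col = np.ascontiguousarray(grid.P[:, :, n - 1])  # flux weight rows
        surv = grid.P.sum(axis=2)  # remaining sub-threshold mass
        msg = np.zeros((nc, n))
        msc = np.zeros(nc)  # log-scales of the normalised messages
        w = np.zeros((nc, n))
        wsc = np.zeros(nc)

        for idx in self.levels:
            if idx.size == 0:
                continue
            o = idx[self.onset[idx]]
            if o.size:
                w[o, n - 1] = eta.alpha
                msg[o] = eta.alpha * psi_col[self.wl[o]]
            rest = idx[~self.onset[idx]]
            if rest.size == 0:
                continue
            leaf = rest[self.left[rest] < 0]
            if leaf.size:
                w[leaf] = 1.0
                msg[leaf] = surv[self.life[leaf]]
            internal = rest[self.left[rest] >= 0]
            if internal.size:
                li, ri = self.left[internal], self.right[internal]
                prod = msg[li] * msg[ri]
                sc = msc[li] + msc[ri]
                w[internal] = prod
                wsc[internal] = sc
                # propagate over the cell's own lifetime, batched by
                # (shared) duration so each group is one BLAS product
                m = np.empty_like(prod)
                lifes = self.life[internal]
                for d in np.unique(lifes):
                    sel = lifes == d
                    m[sel] = prod[sel] @ grid.P[d].T
                nm = m.max(axis=1)
                safe = nm > 0
                scale = np.where(safe, nm, 1.0)
                msg[internal] = m / scale[:, None]
                with np.errstate(divide="ignore"):
                    msc[internal] = sc + np.where(safe, np.log(scale), -np.inf)

        g = w @ grid.u.T  # (nc, maxdur+1): profile from x0=0 dotted with weights
        gwin = np.take_along_axis(g, self.sidx, axis=1) * self.trap
        self._gwin = gwin
        self._wsc = wsc
        self._eta = eta

    # -- decision-parameter stage -----------------------------------------
    def _components(self, theta: DecisionParams):
        """Per-cell (log L_D, log S) for the current η and given θ."""
        if self._eta is None:
            raise RuntimeError("call set_eta() first")
        h = self.h
        tgrid = np.arange(self.kt + 1) * h
        lam = hazard(tgrid, theta)
        cum = cumulative_hazard(tgrid, theta)
        if cum[-1] < 600.0:
            # fast path: one gather of λ(t)·e^(−Λ(t)), rescaled per cell
            v = lam * np.exp(-cum)
            ld_lin = np.einsum("cr,cr->c", v[self.tidx], self._gwin)
            ld_lin *= np.exp(cum[self.kb])
        else:  # extreme hazards: exponentiate the differences directly
            dlam = cum[self.tidx] - cum[self.kb][:, None]
            coeff = lam[self.tidx] * np.exp(-dlam)
            ld_lin = np.einsum("cr,cr->c", coeff, self._gwin)
        with np.errstate(divide="ignore"):
            log_ld = np.where(ld_lin > 0, np.log(np.maximum(ld_lin, 1e-300)), -np.inf)
        log_ld = log_ld + self._wsc
        log_s = -(cum[self.ke] - cum[self.kb])
        return log_ld, log_s

    def loglik(self, theta: DecisionParams) -> float:
        """Total log-likelihood Σ_trees log Σ_{hidden trees} L(H|θ,η)."""
        log_ld, log_s = self._components(theta)
        log_a = np.empty(self.n_cells)
        for idx in self.levels:
            if idx.size == 0:
                continue
            o = idx[self.onset[idx]]
            log_a[o] = log_ld[o]
            rest = idx[~self.onset[idx]]
            leaf = rest[self.left[rest] < 0]
            if leaf.size:
                log_a[leaf] = np.logaddexp(log_ld[leaf], log_s[leaf])
            internal = rest[self.left[rest] >= 0]
            if internal.size:
                below = log_s[internal] + log_a[self.left[internal]] + log_a[self.right[internal]]
                log_a[internal] = np.logaddexp(log_ld[internal], below)
        self._log_a = log_a
        return float(log_a[self.roots].sum())

    def per_tree_loglik(self, theta: DecisionParams) -> list[TreeLikelihood]:
        self.loglik(theta)
        return [
            TreeLikelihood(t.tree_id, float(self._log_a[r]))
            for t, r in zip(self.trees, self.roots)
        ]

    # -- most likely scenarios --------------------------------------------
    def map_scenarios(
        self, theta: DecisionParams, k: int = 1
    ) -> list[list[tuple[HiddenTree, float]]]:
        """Per tree, the k best hidden trees (max-sum DP with k-lists).

        Ties within 1e−12 in log-likelihood are broken in favour of
        fewer decision cells (the earlier decision), then lexicographic
        cell ids, deterministically.
        """
        log_ld, log_s = self._components(theta)

        def topk(cands: list[tuple[float, frozenset]]) -> list[tuple[float, frozenset]]:
            cands.sort(key=lambda c: -c[0])
            # within 1e-12 of each other, prefer fewer decision cells
            # (the earlier decision), then lexicographic ids
            out: list[tuple[float, frozenset]] = []
            i = 0
            while i < len(cands) and len(out) < k:
                j = i
                while j < len(cands) and (
                    cands[i][0] == cands[j][0] or cands[i][0] - cands[j][0] <= 1e-12
                ):
                    j += 1
                group = sorted(cands[i:j], key=lambda c: (len(c[1]), sorted(c[1])))
                out.extend(group[: k - len(out)])
                i = j
            return out

        results = []
        for ti, (tree, root) in enumerate(zip(self.trees, self.roots)):
            def best(i: int) -> list[tuple[float, frozenset]]:
                cid = self.ids[i][1]
                cands = [(log_ld[i], frozenset([cid]))]
                if not self.onset[i]:
                    if self.left[i] < 0:
                        cands.append((log_s[i], frozenset()))
                    else:
                        for sl, cl in best(self.left[i]):
                            for sr, cr in best(self.right[i]):
                                cands.append((log_s[i] + sl + sr, cl | cr))
                return topk(cands)

            results.append(
                [
                    (HiddenTree(tree.tree_id, cells), float(score))
                    for score, cells in best(int(root))
                ]
            )
        return results

    def decision_time_modes(self, theta: DecisionParams) -> dict[tuple[str, str], float]:
        """Per cell, the mode of the latent decision-time integrand
        λ(t)·e^(−ΔΛ)·g(t) — a point estimate of *when* the decision fell
        if this cell is the decision cell.  Keyed by (tree_id, cell_id)."""
        if self._eta is None:
            raise RuntimeError("call set_eta() first")
        h = self.h
        tgrid = np.arange(self.kt + 1) * h
        lam = hazard(tgrid, theta)
        cum = cumulative_hazard(tgrid, theta)
        dlam = cum[self.tidx] - cum[self.kb][:, None]
        coeff = lam[self.tidx] * np.exp(-dlam)
        integ = coeff * self._gwin
        rhat = integ.argmax(axis=1)
        that = self.tidx[self._col, rhat] * h
        out = {}
        for (ti, cid), t in zip(self.ids, that):
            out[(self.trees[ti].tree_id, cid)] = float(t)
        return out


# ---------------------------------------------------------------------------
# convenience wrappers
# ---------------------------------------------------------------------------

def likelihood_tree(
    tree: Genealogy, theta: DecisionParams, eta: DelayParams, h: float = DEFAULT_GRID_H
) -> TreeLikelihood:
    """Log of the hidden-tree sum for one genealogy (dynamic program)."""
    eng = TreeLikelihoodEngine([tree], h=h)
    eng.set_eta(eta)
    return eng.per_tree_loglik(theta)[0]


def map_hidden_tree(
    tree: Genealogy,
    theta: DecisionParams,
    eta: DelayParams,
    k: int = 1,
    h: float = DEFAULT_GRID_H,
) -> list[tuple[HiddenTree, float]]:
    """The k most likely hidden trees of one genealogy with their
    log-likelihoods, best first."""
    if k < 1:
        raise ValueError("k must be >= 1")
    eng = TreeLikelihoodEngine([tree], h=h)
    eng.set_eta(eta)
    return eng.map_scenarios(theta, k=k)[0]


def predicted_decision_generation(hidden: HiddenTree, tree: Genealogy) -> dict:
    """Generation index of each predicted decision cell."""
    return {cid: tree.cells[cid].generation for cid in hidden.decision_cells}
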