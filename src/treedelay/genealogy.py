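"""Data model and I/O for annotated single-cell genealogies.

A genealogy is a rooted binary tree of tracked cells obtained from
time-lapse microscopy: every cell carries its birth and end time (hours
from movie start), the reason tracking of the cell ended (division,
movie end, or tracking loss), and optionally the time at which a lineage
marker was first detected on that cell ("onset").  Onsets are terminal
per branch: once the marker is detected, the branch below carries no
further annotation.

The on-disk representation is a tab-separated cell table with one header
line::

    tree_id  cell_id  parent_id  birth_time_h  end_time_h  end_reason  onset_time_h  fate_label

``parent_id`` is ``NA`` for roots and ``onset_time_h`` is ``NA`` when no
onset was observed.  Signal tracks (per-cell fluorescence time series)
use a second table: ``tree_id  cell_id  time_h  intensity  area``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "EndReason",
    "FateLabel",
    "Cell",
    "Genealogy",
    "SignalTrack",
    "GenealogyFormatError",
    "GenealogyValidationError",
    "read_genealogies",
    "write_genealogies",
    "read_signal_tracks",
    "write_signal_tracks",
    "subtree",
    "to_newick",
]

CELL_TABLE_COLUMNS = [
    "tree_id",
    "cell_id",
    "parent_id",
    "birth_time_h",
    "end_time_h",
    "end_reason",
    "onset_time_h",
    "fate_label",
]

TRACK_TABLE_COLUMNS = ["tree_id", "cell_id", "time_h", "intensity", "area"]


class EndReason(str, Enum):
    """Why tracking of a cell ended."""

    DIVISION = "division"
    MOVIE_END = "movie_end"
    LOST = "lost"


class FateLabel(str, Enum):
    GM = "GM"
    MEGE = "MegE"
    MIXED = "mixed"
    NONE = "none"


class GenealogyFormatError(ValueError):
    """Malformed cell-table input (names the offending line)."""


class GenealogyValidationError(ValueError):
    """A structural invariant of a genealogy is violated."""

    def __init__(self, cell_id, rule: str):
        self.cell_id = cell_id
        self.rule = rule
        super().__init__(f"cell {cell_id!r}: {rule}")


@dataclass
class Cell:
    """One tracked cell.

    Times are continuous hours with 0 = movie start.  ``generation`` is
    derived (root = 0) and filled in by :class:`Genealogy`.
    """

    cell_id: str
    parent_id: str | None
    birth_time: float
    end_time: float
    end_reason: EndReason
    onset_time: float | None = None
    generation: int = 0

    @property
    def lifetime(self) -> float:
        return self.end_time - self.birth_time

    @property
    def has_onset(self) -> bool:
        return self.onset_time is not None


@dataclass
class SignalTrack:
    """Fluorescence samples (time, intensity, area) of one cell."""

    cell_id: str
    times: list[float]
    intensities: list[float]
    areas: list[float]


@dataclass
class Genealogy:
    """A rooted binary genealogy of :class:`Cell` records."""

    tree_id: str
    cells: dict[str, Cell]
    fate_label: FateLabel = FateLabel.NONE
    movie_end: float = math.inf
    _children: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._rebuild()

    # -- structure ---------------------------------------------------------
    def _rebuild(self) -> None:
        self._children = {cid: [] for cid in self.cells}
        roots = []
        for c in self.cells.values():
            if c.parent_id is None:
                roots.append(c.cell_id)
            else:
                if c.parent_id not in self.cells:
                    raise GenealogyValidationError(
                        c.cell_id, f"parent {c.parent_id!r} not in tree"
                    )
                self._children[c.parent_id].append(c.cell_id)
        if len(roots) != 1:
            raise GenealogyValidationError(
                self.tree_id, f"expected exactly one root, found {len(roots)}"
            )
        self._root_id = roots[0]
        # derive generations, detect cycles
        seen = set()
        stack = [(self._root_id, 0)]
        while stack:
            cid, gen = stack.pop()
            if cid in seen:
                raise GenealogyValidationError(cid, "cycle in parent links")
            seen.add(cid)
            self.cells[cid].generation = gen
            for k in self._children[cid]:
                stack.append((k, gen + 1))
        if len(seen) != len(self.cells):
            raise GenealogyValidationError(
                self.tree_id, "tree is not connected (unreachable cells)"
            )

    @property
    def root(self) -> Cell:
        return self.cells[self._root_id]

    def children(self, cell_id: str) -> list[Cell]:
        return [self.cells[k] for k in self._children[cell_id]]

    def iter_preorder(self) -> Iterator[Cell]:
        stack = [self._root_id]
        while stack:
            cid = stack.pop()
            yield self.cells[cid]
            stack.extend(reversed(self._children[cid]))

    def n_cells(self) -> int:
        return len(self.cells)

    def onset_cells(self) -> list[Cell]:
        return [c for c in self.cells.values() if c.has_onset]

    def _has_onset_above(self, cell: Cell) -> bool:
        p = cell.parent_id
        while p is not None:
            if self.cells[p].has_onset:
                return True
            p = self.cells[p].parent_id
        return False

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`GenealogyValidationError` on the first violated rule."""
        for c in self.cells.values():
            if c.birth_time < 0:
                raise GenealogyValidationError(c.cell_id, "birth_time < 0")
            if not c.end_time > c.birth_time:
                raise GenealogyValidationError(
                    c.cell_id, "end_time must exceed birth_time strictly"
                )
            if c.end_time > self.movie_end + 1e-9:
                raise GenealogyValidationError(c.cell_id, "end_time > movie_end")
            if c.has_onset and not (
                c.birth_time - 1e-9 <= c.onset_time <= c.end_time + 1e-9
            ):
                raise GenealogyValidationError(
                    c.cell_id, "onset_time outside [birth_time, end_time]"
                )
            kids = self.children(c.cell_id)
            if c.end_reason == EndReason.DIVISION:
                if len(kids) != 2:
                    raise GenealogyValidationError(
                        c.cell_id,
                        f"division cell must have 2 children, has {len(kids)}",
                    )
            elif kids:
                raise GenealogyValidationError(
                    c.cell_id, f"non-dividing cell has {len(kids)} children"
                )
            for k in kids:
                if abs(k.birth_time - c.end_time) > 1e-9:
                    raise GenealogyValidationError(
                        k.cell_id, "child birth_time != parent end_time"
                    )
            if c.has_onset and self._has_onset_above(c):
                raise GenealogyValidationError(
                    c.cell_id, "onset annotation below another onset (onset is terminal)"
                )


def subtree(tree: Genealogy, cell_id: str) -> Genealogy:
    """Induced subtree rooted at ``cell_id``, preserving absolute times."""
    if cell_id not in tree.cells:
        raise KeyError(f"unknown cell_id {cell_id!r} in tree {tree.tree_id!r}")
    keep: dict[str, Cell] = {}
    stack = [cell_id]
    while stack:
        cid = stack.pop()
        c = replace(tree.cells[cid])
        if cid == cell_id:
            c.parent_id = None
        keep[cid] = c
        stack.extend(tree._children[cid])
    return Genealogy(
        tree_id=f"{tree.tree_id}:{cell_id}",
        cells=keep,
        fate_label=tree.fate_label,
        movie_end=tree.movie_end,
    )


# -- I/O -------------------------------------------------------------------

def _fmt_time(t: float | None) -> str:
    return "NA" if t is None else format(t, ".12g")


def write_genealogies(trees: Iterable[Genealogy], path) -> None:
    rows = []
    for tr in trees:
        for c in sorted(tr.cells.values(), key=lambda c: (c.generation, c.cell_id)):
            rows.append(
                (
                    tr.tree_id,
                    c.cell_id,
                    "NA" if c.parent_id is None else c.parent_id,
                    _fmt_time(c.birth_time),
                    _fmt_time(c.end_time),
                    c.end_reason.value,
                    _fmt_time(c.onset_time),
                    tr.fate_label.value,
                )
            )
    df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_genealogies(path, movie_end: float | None = None) -> list[Genealogy]:
    """Read a cell table; returns validated genealogies with derived fields.

    ``movie_end`` defaults, per tree, to the maximum end time in the tree
    (the table does not store it explicitly).
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, na_values=[]
        )
    except Exception as e:  # pragma: no cover - delegated parse failure
        raise GenealogyFormatError(f"cannot parse {path}: {e}") from e
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenealogyFormatError(f"{path}: missing columns {missing}")

    trees: list[Genealogy] = []
    for tree_id, grp in df.groupby("tree_id", sort=False):
        cells: dict[str, Cell] = {}
        fate = FateLabel.NONE
        for idx, row in grp.iterrows():
            line_no = idx + 2  # header is line 1
            try:
                birth = float(row["birth_time_h"])
                end = float(row["end_time_h"])
            except ValueError as e:
                raise GenealogyFormatError(
                    f"line {line_no}: non-numeric time field ({e})"
                ) from None
            onset_raw = row["onset_time_h"]
            try:
                onset = None if onset_raw == "NA" else float(onset_raw)
            except ValueError:
                raise GenealogyFormatError(
                    f"line {line_no}: bad onset_time_h {onset_raw!r}"
                ) from None
            try:
                reason = EndReason(row["end_reason"])
            except ValueError:
                raise GenealogyFormatError(
                    f"line {line_no}: unknown end_reason {row['end_reason']!r}"
                ) from None
            try:
                fate = FateLabel(row["fate_label"])
            except ValueError:
                raise GenealogyFormatError(
                    f"line {line_no}: unknown fate_label {row['fate_label']!r}"
                ) from None
            cid = row["cell_id"]
            if cid in cells:
                raise GenealogyFormatError(f"line {line_no}: duplicate cell_id {cid!r}")
            cells[cid] = Cell(
                cell_id=cid,
                parent_id=None if row["parent_id"] == "NA" else row["parent_id"],
                birth_time=birth,
                end_time=end,
                end_reason=reason,
                onset_time=onset,
            )
        me = movie_end
        if me is None:
            me = max(c.end_time for c in cells.values())
        tree = Genealogy(tree_id=str(tree_id), cells=cells, fate_label=fate, movie_end=me)
        tree.validate()
        trees.append(tree)
    return trees


def write_signal_tracks(tracks: dict[str, list[SignalTrack]], path) -> None:
    """``tracks`` maps tree_id -> list of SignalTrack."""
    rows = []
    for tree_id, tlist in tracks.items():
        for tr in tlist:
            for t, y, a in zip(tr.times, tr.intensities, tr.areas):
                rows.append((tree_id, tr.cell_id, t, y, a))
    pd.DataFrame(rows, columns=TRACK_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_signal_tracks(path) -> dict[str, list[SignalTrack]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRACK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GenealogyFormatError(f"{path}: missing columns {missing}")
    out: dict[str, list[SignalTrack]] = {}
    for (tree_id, cell_id), grp in df.groupby(["tree_id", "cell_id"], sort=False):
        grp = grp.sort_values("time_h")
        out.setdefault(str(tree_id), []).append(
            SignalTrack(
                cell_id=str(cell_id),
                times=grp["time_h"].tolist(),
                intensities=grp["intensity"].tolist(),
                areas=grp["area"].tolist(),
            )
        )
    return out


def to_newick(tree: Genealogy) -> str:
    """Topology export with cell_id labels and branch length = lifetime.

    Lossy: onset annotations and end reasons are dropped.
    """

    def rec(cid: str) -> str:
        c = tree.cells[cid]
        kids = tree._children[cid]
        label = f"{cid}:{c.lifetime:.6g}"
        if not kids:
            return label
        return "(" + ",".join(rec(k) for k in kids) + ")" + label

    return rec(tree._root_id) + ";"
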