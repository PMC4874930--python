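"""Just-enough-interaction refinement: global threshold reset, local surface
anchoring with similarity-matched cost notches, and undo.

A *global* refinement point resets the threshold Th to the uptake at that
point and pins the surface to the node nearest the point (cost 1000 on every
other node of that column); the entire boundary is re-optimized. A *local*
refinement point pins its column the same way, then searches nearby columns
(graph geodesic ds <= 5) for similar uptake patterns around the anchored node
and lowers their costs with a triangular notch whose width grows with ds --
narrow certainty near the click, wider uncertainty further away. Every action
snapshots the session state so undo restores the previous solution
bit-exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cost_field import CostField, base_cost
from .errors import SeedError
from .mesh_graph import ColumnGraph, bfs_depths
from .osf_solver import SurfaceSolution, resolve_with_updates, solve
from .volume_io import ScalarVolume, sample_uptake

#: anchoring constant on user-pinned columns, far above any achievable objective
ANCHOR_COST = 1000.0
#: graph-geodesic search bound of the local similarity search
BFS_BOUND = 5
#: half-width of the uptake-pattern comparison window (node levels)
SMC_WINDOW = 3
#: relative similarity bound: smc < 0.05 * sum |up| over the window
SIM_FRACTION = 0.05
#: depth of the triangular cost notch on matched columns
NOTCH_DEPTH = 3.0


def notch(j, center_level: int, depth: float = NOTCH_DEPTH, width: float = 1.0):
    """Non-positive triangular well: -depth * max(0, 1 - |j - c|/(width + 1))."""
    j = np.asarray(j, dtype=np.float64)
    return -depth * np.maximum(0.0, 1.0 - np.abs(j - center_level) / (width + 1.0))


@dataclass
class RefinementAction:
    kind: str  # "global" | "local"
    point: np.ndarray  # mm
    anchor: tuple[int, int]  # (column, level) nearest to the point
    matched: dict = field(default_factory=dict)  # local: column -> matched level
    new_th: float | None = None  # global: threshold installed by this action


@dataclass
class _Snapshot:
    th: float
    global_extra: np.ndarray
    local_extra: np.ndarray
    global_anchor: int | None
    anchored: set
    solution: SurfaceSolution


@dataclass
class Session:
    """Interactive segmentation state: graph, costs, current solution, undo stack."""

    graph: ColumnGraph
    vol: ScalarVolume
    node_uptake: np.ndarray  # (n_column, n_node)
    env: object  # EnvelopeFunction
    reject: np.ndarray
    mode_extra: np.ndarray
    center_uptake: float
    th: float
    label: int = 1
    solution: SurfaceSolution | None = None
    global_extra: np.ndarray = None  # type: ignore[assignment]
    local_extra: np.ndarray = None  # type: ignore[assignment]
    global_anchor_col: int | None = None
    local_anchored: set = field(default_factory=set)
    actions: list = field(default_factory=list)
    _undo: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        shape = (self.graph.n_column, self.graph.n_node)
        if self.global_extra is None:
            self.global_extra = np.zeros(shape)
        if self.local_extra is None:
            self.local_extra = np.zeros(shape)
        self._positions = self.graph.node_positions()
        if self.solution is None:
            self.solution = solve(self.graph, self.cost_field())

    @property
    def anchored_columns(self) -> set:
        cols = set(self.local_anchored)
        if self.global_anchor_col is not None:
            cols.add(self.global_anchor_col)
        return cols

    def cost_field(self) -> CostField:
        base = base_cost(self.node_uptake, self.th, self.env, self.center_uptake)
        return CostField(base=base, reject=self.reject,
                         extra=self.mode_extra + self.global_extra + self.local_extra)

    def nearest_node(self, point) -> tuple[int, int]:
        point = np.asarray(point, dtype=np.float64)
        d2 = np.sum((self._positions - point) ** 2, axis=2)
        i, j = np.unravel_index(np.argmin(d2), d2.shape)
        return int(i), int(j)

    def _push(self) -> None:
        self._undo.append(_Snapshot(
            th=self.th,
            global_extra=self.global_extra.copy(),
            local_extra=self.local_extra.copy(),
            global_anchor=self.global_anchor_col,
            anchored=set(self.local_anchored),
            solution=self.solution,
        ))

    def _resolve(self) -> None:
        self.solution = resolve_with_updates(self.solution, self.graph,
                                             self.cost_field())


def _clamped_window(up_col: np.ndarray, j: int) -> np.ndarray:
    """Uptake in the +-SMC_WINDOW window around level j, indices clamped."""
    n = len(up_col)
    ks = np.clip(np.arange(j - SMC_WINDOW, j + SMC_WINDOW + 1), 0, n - 1)
    return up_col[ks]


def find_similar_columns(session: Session, anchor: tuple[int, int]):
    """Columns near the anchor with a similar uptake pattern.

    BFS over column adjacency bounded by graph geodesic ds <= 5. A candidate
    node (i, j) with |j - j_anchor| <= ds(i) is similar when the L1 pattern
    distance over a +-3 level window stays below 5% of the candidate pattern's
    own L1 norm; per column the lowest-distance node wins (ties: smallest j).
    Columns skipped for dissimilarity are re-included when at least two thirds
    of their mesh neighbors were selected, taking their lowest-distance node.
    Returns ``(matched, depths)`` with ``matched`` mapping column -> level.
    """
    i_a, j_a = anchor
    up = session.node_uptake
    n_node = session.graph.n_node
    ref = _clamped_window(up[i_a], j_a)
    depths = bfs_depths(session.graph, i_a, max_depth=BFS_BOUND)

    best_similar: dict[int, int] = {}
    best_any: dict[int, int] = {}
    for i, ds in depths.items():
        if i == i_a or ds == 0:
            continue
        j_lo, j_hi = max(0, j_a - ds), min(n_node - 1, j_a + ds)
        best_s = best_a = None
        smc_s = smc_a = np.inf
        for j in range(j_lo, j_hi + 1):
            win = _clamped_window(up[i], j)
            smc = float(np.abs(win - ref).sum())
            th_sim = SIM_FRACTION * float(np.abs(win).sum())
            if smc < smc_a:
                smc_a, best_a = smc, j
            if smc < th_sim and smc < smc_s:
                smc_s, best_s = smc, j
        if best_a is not None:
            best_any[i] = best_a
        if best_s is not None:
            best_similar[i] = best_s

    # Closing step: fill BFS holes whose neighborhoods were mostly selected.
    matched = dict(best_similar)
    for i, ds in depths.items():
        if i == i_a or i in matched or i not in best_any:
            continue
        nbrs = session.graph.adjacency[i]
        n_sel = sum(1 for v in nbrs if int(v) in best_similar)
        if n_sel >= (2.0 / 3.0) * len(nbrs):
            matched[i] = best_any[i]
    return matched, depths


def global_refine(session: Session, point) -> Session:
    """Reset Th to the uptake at ``point`` and pin the surface there."""
    point = np.asarray(point, dtype=np.float64)
    new_th = float(sample_uptake(session.vol, point))
    if new_th >= session.center_uptake:
        raise SeedError(
            f"refinement uptake {new_th:.4g} is not below the center uptake "
            f"{session.center_uptake:.4g}")
    i_th, j_th = session.nearest_node(point)
    session._push()
    # A repeated global refinement overrides the previous one entirely.
    session.th = new_th
    session.global_extra = np.zeros_like(session.global_extra)
    session.global_extra[i_th, :] = ANCHOR_COST
    session.global_extra[i_th, j_th] = 0.0
    session.global_anchor_col = i_th
    session.actions.append(RefinementAction("global", point, (i_th, j_th),
                                            new_th=new_th))
    session._resolve()
    return session


def local_refine(session: Session, point) -> Session:
    """Pin the nearest node and notch similar neighboring columns."""
    point = np.asarray(point, dtype=np.float64)
    i_lp, j_lp = session.nearest_node(point)
    matched, depths = find_similar_columns(session, (i_lp, j_lp))
    session._push()
    already = session.anchored_columns
    delta = np.zeros_like(session.local_extra)
    js = np.arange(session.graph.n_node)
    if i_lp not in already:
        delta[i_lp, :] = ANCHOR_COST
        delta[i_lp, j_lp] = 0.0
    applied = {}
    for i, j_m in matched.items():
        # Columns already pinned by a user point keep their costs.
        if i in already or i == i_lp:
            continue
        delta[i, :] += notch(js, j_m, NOTCH_DEPTH, depths[i])
        applied[i] = j_m
    session.local_extra = session.local_extra + delta
    session.local_anchored.add(i_lp)
    session.actions.append(RefinementAction("local", point, (i_lp, j_lp),
                                            matched=applied))
    session._resolve()
    return session


def undo(session: Session) -> Session:
    """Reverse the most recent refinement action (no-op on an empty stack)."""
    if not session._undo:
        warnings.warn("undo called on an empty action stack; session unchanged")
        return session
    snap = session._undo.pop()
    session.actions.pop()
    session.th = snap.th
    session.global_extra = snap.global_extra
    session.local_extra = snap.local_extra
    session.global_anchor_col = snap.global_anchor
    session.local_anchored = snap.anchored
    session.solution = snap.solution
    return session
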