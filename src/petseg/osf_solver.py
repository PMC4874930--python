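"""Globally optimal closed-surface extraction on the column graph.

The search selects exactly one node per column, minimizing

    sum_i c(n_(i, j_i))  +  sp * sum_{adjacent pairs (i,i')} |j_i - j_i'|

subject to the hard constraint |j_i - j_i'| <= sc on every adjacent column
pair. The problem is solved exactly via the standard closure/min-cut
transform of optimal surface finding: per-node weights are the along-column
cost differences, intracolumn and hard-constraint arcs get effectively
infinite capacity, soft-constraint arcs get capacity sp, and a minimum s-t cut
(igraph max-flow) yields the minimum-cost closed set. Because the weights are
cost *differences*, negative node costs (from refinement notches) need no
special treatment. Among co-optimal surfaces, the minimal closed set -- the
source side reachable in the residual network -- is returned; it is pointwise
(hence lexicographically) minimal in the levels, making results deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import breadth_first_order

from .cost_field import CostField
from .errors import GraphError
from .mesh_graph import ColumnGraph, TriangleMesh


@dataclass
class SurfaceSolution:
    """One selected node level per column plus the deformed boundary mesh."""

    levels: np.ndarray  # (n_column,) int
    objective: float
    boundary_mesh: TriangleMesh
    center: np.ndarray  # (3,) mm

    @property
    def boundary_radii(self):
        """(n_column,) distance of each boundary vertex from the center, mm."""
        return np.linalg.norm(self.boundary_mesh.vertices - self.center, axis=1)


def _as_cost_array(costs) -> np.ndarray:
    if isinstance(costs, CostField):
        return costs.total()
    return np.asarray(costs, dtype=np.float64)


def surface_objective(graph: ColumnGraph, costs, levels: np.ndarray) -> float:
    """Objective value of a feasible level assignment."""
    c = _as_cost_array(costs)
    levels = np.asarray(levels)
    node_cost = c[np.arange(graph.n_column), levels].sum()
    me = graph.mesh.edges
    smooth = np.abs(levels[me[:, 0]] - levels[me[:, 1]]).sum()
    return float(node_cost + graph.sp * smooth)


def solve(graph: ColumnGraph, costs) -> SurfaceSolution:
    """Find the globally optimal feasible surface for the given cost field."""
    c = _as_cost_array(costs)
    n_col, n_node = graph.n_column, graph.n_node
    if c.shape != (n_col, n_node):
        raise GraphError(f"cost shape {c.shape} != graph shape {(n_col, n_node)}")
    if not np.all(np.isfinite(c)):
        raise GraphError("costs must be finite")
    sc, sp = graph.sc, graph.sp
    me = graph.mesh.edges
    pairs = np.vstack([me, me[:, ::-1]]).astype(np.int64)  # both directions

    # Closure weights: w(i,0) forces the base of every column into the closed
    # set; w(i,j) for j>=1 is the incremental cost of raising the surface.
    w = np.empty_like(c)
    w[:, 1:] = c[:, 1:] - c[:, :-1]
    pos_sum = float(np.maximum(w[:, 1:], 0.0).sum())
    soft_sum = sp * len(pairs) * n_node if sp > 0 else 0.0
    large = pos_sum + soft_sum + float(np.abs(c[:, 0]).sum()) + 1.0
    w[:, 0] = c[:, 0] - large
    inf_cap = 2.0 * (n_col * large + float(np.abs(w).sum()) + 1.0)

    n_nodes_total = n_col * n_node
    source, sink = n_nodes_total, n_nodes_total + 1
    ids = np.arange(n_nodes_total).reshape(n_col, n_node)

    srcs, dsts, caps = [], [], []

    wf = w.ravel()
    pos = wf > 0
    neg = wf < 0
    srcs.append(ids.ravel()[pos]); dsts.append(np.full(pos.sum(), sink)); caps.append(wf[pos])
    srcs.append(np.full(neg.sum(), source)); dsts.append(ids.ravel()[neg]); caps.append(-wf[neg])

    # Intracolumn arcs (i,j) -> (i,j-1).
    srcs.append(ids[:, 1:].ravel()); dsts.append(ids[:, :-1].ravel())
    caps.append(np.full(n_col * (n_node - 1), inf_cap))

    # Hard smoothness arcs (i,j) -> (i', max(j-sc, 0)), both directions.
    j = np.arange(n_node)
    jlo = np.maximum(j - sc, 0)
    u = (pairs[:, 0, None] * n_node + j[None, :]).ravel()
    v = (pairs[:, 1, None] * n_node + jlo[None, :]).ravel()
    srcs.append(u); dsts.append(v); caps.append(np.full(u.size, inf_cap))

    # Soft smoothness arcs (i,j) -> (i',j) with capacity sp.
    if sp > 0:
        jj = np.arange(1, n_node)
        u = (pairs[:, 0, None] * n_node + jj[None, :]).ravel()
        v = (pairs[:, 1, None] * n_node + jj[None, :]).ravel()
        srcs.append(u); dsts.append(v); caps.append(np.full(u.size, sp))

    srcs = np.concatenate(srcs)
    dsts = np.concatenate(dsts)
    caps = np.concatenate(caps)

    g = ig.Graph(n_nodes_total + 2, np.column_stack([srcs, dsts]).tolist(),
                 directed=True)
    flow = np.asarray(g.maxflow(source, sink, capacity=caps.tolist()).flow)

    # Minimal closed set = nodes reachable from the source in the residual
    # network; per-edge relative slack tolerance guards float round-off.
    slack_tol = np.maximum(1e-12, 1e-9 * caps)
    fwd = (caps - flow) > slack_tol
    bwd = flow > slack_tol
    rows = np.concatenate([srcs[fwd], dsts[bwd]])
    cols = np.concatenate([dsts[fwd], srcs[bwd]])
    adj = csr_matrix((np.ones(rows.size, dtype=np.int8), (rows, cols)),
                     shape=(n_nodes_total + 2, n_nodes_total + 2))
    reached = breadth_first_order(adj, source, directed=True,
                                  return_predecessors=False)
    in_s = np.zeros(n_nodes_total + 2, dtype=bool)
    in_s[reached] = True
    assert not in_s[sink], "max-flow did not separate source from sink"

    sel = in_s[:n_nodes_total].reshape(n_col, n_node)
    assert sel[:, 0].all(), "closed set must contain every column base node"
    levels = sel.sum(axis=1) - 1
    # The closed set is a prefix along every column (intracolumn arcs).
    assert np.array_equal(sel, np.arange(n_node)[None, :] <= levels[:, None])
    dlev = np.abs(levels[me[:, 0]] - levels[me[:, 1]])
    assert np.all(dlev <= sc), "hard smoothness constraint violated"

    verts = graph.center + graph.radii[levels][:, None] * graph.directions
    mesh = TriangleMesh(verts, graph.mesh.triangles.copy())
    return SurfaceSolution(levels=levels.astype(np.int64),
                           objective=surface_objective(graph, c, levels),
                           boundary_mesh=mesh, center=graph.center.copy())


def resolve_with_updates(prev: SurfaceSolution, graph: ColumnGraph,
                         costs_updated) -> SurfaceSolution:
    """Re-solve after cost updates on the same graph.

    Semantically identical to :func:`solve` on the updated field; kept as a
    separate entry point so callers express intent and graph identity is
    checked.
    """
    if len(prev.levels) != graph.n_column or not np.allclose(prev.center, graph.center):
        raise GraphError("previous solution does not belong to this graph")
    return solve(graph, costs_updated)
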