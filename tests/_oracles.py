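"""Independent oracles used by the test suite.

These deliberately avoid the package's solver path: a true brute-force
enumerator for tiny graphs and an exact min-sum variable-elimination solver
(junction-tree style dynamic programming) for graphs too large to enumerate.
The elimination oracle is itself cross-checked against brute force.
"""
from __future__ import annotations

import itertools

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp


def pair_penalty(n_levels: int, sc: int, sp: float) -> np.ndarray:
    """(L, L) pairwise term: sp*|dj| within the hard constraint, inf outside."""
    dj = np.abs(np.arange(n_levels)[:, None] - np.arange(n_levels)[None, :])
    pen = sp * dj.astype(float)
    pen[dj > sc] = np.inf
    return pen


def brute_force_optimum(costs: np.ndarray, edges: np.ndarray, sc: int,
                        sp: float) -> tuple[float, np.ndarray]:
    """Exhaustive minimum over all feasible level assignments (tiny graphs only)."""
    n_col, n_lev = costs.shape
    best, best_lev = np.inf, None
    for lev in itertools.product(range(n_lev), repeat=n_col):
        lev = np.asarray(lev)
        dj = np.abs(lev[edges[:, 0]] - lev[edges[:, 1]])
        if np.any(dj > sc):
            continue
        obj = costs[np.arange(n_col), lev].sum() + sp * dj.sum()
        if obj < best - 1e-15:
            best, best_lev = obj, lev
    return float(best), best_lev


def _broadcast_to(scope, table, union):
    """Expand a factor table over sorted ``scope`` to the axes of sorted ``union``."""
    t = table
    for a, v in enumerate(union):
        if v not in scope:
            t = np.expand_dims(t, a)
    return t


def elimination_optimum(costs: np.ndarray, edges: np.ndarray, sc: int,
                        sp: float) -> float:
    """Exact optimum by min-sum variable elimination (min-degree order)."""
    n_col, n_lev = costs.shape
    factors = [((i,), costs[i].astype(float)) for i in range(n_col)]
    pen = pair_penalty(n_lev, sc, sp)
    for a, b in np.asarray(edges):
        a, b = int(a), int(b)
        if a < b:
            factors.append(((a, b), pen))
        else:
            factors.append(((b, a), pen.T))

    remaining = set(range(n_col))
    constant = 0.0
    while remaining:
        # min-degree heuristic: eliminate the variable with the smallest
        # union scope among its factors.
        def union_size(v):
            s = set()
            for scope, _ in factors:
                if v in scope:
                    s.update(scope)
            return len(s)

        v = min(remaining, key=union_size)
        touching = [f for f in factors if v in f[0]]
        factors = [f for f in factors if v not in f[0]]
        union = sorted(set().union(*[set(s) for s, _ in touching]))
        acc = np.zeros([n_lev] * len(union))
        for scope, table in touching:
            acc = acc + _broadcast_to(list(scope), table, union)
        axis = union.index(v)
        reduced = np.min(acc, axis=axis)
        new_scope = tuple(u for u in union if u != v)
        if new_scope:
            factors.append((new_scope, reduced))
        else:
            constant += float(reduced)
        remaining.discard(v)
    for scope, table in factors:  # pragma: no cover - all vars eliminated
        constant += float(np.min(table))
    return constant


def milp_optimum(costs: np.ndarray, edges: np.ndarray, sc: int,
                 sp: float) -> float:
    """Exact optimum via mixed-integer programming (HiGHS branch-and-bound).

    One-hot binaries select a level per column; the level difference of each
    adjacent pair is bounded by the hard constraint and its absolute value is
    linearized with a continuous auxiliary charged at ``sp``.
    """
    n, n_lev = costs.shape
    edges = np.asarray(edges)
    n_e = len(edges)
    nx = n * n_lev
    cvec = np.concatenate([costs.ravel(), np.full(n_e, sp)])

    one_hot = sparse.lil_matrix((n, nx + n_e))
    lev = sparse.lil_matrix((n, nx + n_e))
    for i in range(n):
        one_hot[i, i * n_lev:(i + 1) * n_lev] = 1.0
        lev[i, i * n_lev:(i + 1) * n_lev] = np.arange(n_lev)
    lev = lev.tocsr()
    diff = sparse.lil_matrix((n_e, nx + n_e))
    for e, (a, b) in enumerate(edges):
        diff[e] = lev[int(a)] - lev[int(b)]
    diff = diff.tocsr()
    taux = sparse.hstack([sparse.csr_matrix((n_e, nx)),
                          sparse.eye(n_e)]).tocsr()
    constraints = [
        LinearConstraint(one_hot.tocsr(), 1, 1),
        LinearConstraint(diff, -sc, sc),
        LinearConstraint(taux - diff, 0, np.inf),
        LinearConstraint(taux + diff, 0, np.inf),
    ]
    integrality = np.concatenate([np.ones(nx), np.zeros(n_e)])
    res = milp(cvec, constraints=constraints, integrality=integrality,
               bounds=Bounds(np.zeros(nx + n_e),
                             np.concatenate([np.ones(nx), np.full(n_e, n_lev)])))
    assert res.success, res.message
    return float(res.fun)


def lp_levelset_optimum(costs: np.ndarray, edges: np.ndarray, sc: int,
                        sp: float) -> float:
    """Exact optimum via the threshold (level-set) linear program.

    Indicator variables y[i,j] = [level_i >= j] make every constraint a
    difference of two variables, so the constraint matrix is a network matrix
    (totally unimodular) and the plain LP optimum equals the integer optimum.
    Solved with HiGHS simplex -- an algorithmic route fully separate from the
    package's max-flow solver.
    """
    n, n_lev = costs.shape
    edges = np.asarray(edges)
    n_e = len(edges)
    ny = n * (n_lev - 1)
    nu = n_e * (n_lev - 1) if sp > 0 else 0

    def yid(i: int, j: int) -> int:
        return i * (n_lev - 1) + (j - 1)

    cobj = np.zeros(ny + nu)
    for i in range(n):
        cobj[yid(i, 1):yid(i, n_lev - 1) + 1] = costs[i, 1:] - costs[i, :-1]
    if sp > 0:
        cobj[ny:] = sp

    rows, cols, vals, ub = [], [], [], []

    def add_le(terms, bound):
        r = len(ub)
        for c_, v in terms:
            rows.append(r), cols.append(c_), vals.append(v)
        ub.append(bound)

    for i in range(n):  # y monotone along each column
        for j in range(2, n_lev):
            add_le([(yid(i, j), 1.0), (yid(i, j - 1), -1.0)], 0.0)
    for a, b in edges:  # hard constraint: level_p <= level_q + sc
        for p, q in ((int(a), int(b)), (int(b), int(a))):
            for j in range(sc + 1, n_lev):
                add_le([(yid(p, j), 1.0), (yid(q, j - sc), -1.0)], 0.0)
    if sp > 0:  # u >= |y_a - y_b| per level, charged at sp
        for e, (a, b) in enumerate(edges):
            for j in range(1, n_lev):
                u = ny + e * (n_lev - 1) + (j - 1)
                add_le([(yid(int(a), j), 1.0), (yid(int(b), j), -1.0), (u, -1.0)], 0.0)
                add_le([(yid(int(b), j), 1.0), (yid(int(a), j), -1.0), (u, -1.0)], 0.0)

    a_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(len(ub), ny + nu))
    bounds = [(0.0, 1.0)] * ny + [(0.0, None)] * nu
    res = linprog(cobj, A_ub=a_ub, b_ub=np.asarray(ub), bounds=bounds,
                  method="highs")
    assert res.status == 0, res.message
    return float(res.fun + costs[:, 0].sum())
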