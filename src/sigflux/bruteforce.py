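"""Naive reference implementations used to validate the fast paths.

These deliberately share no code with :mod:`sigflux.lp` or the GPR
evaluator: GPR rules are checked by exhaustive truth tables and flux
ranges by enumerating candidate vertices of the flux polytope.  Both are
exponential in problem size and intended for networks of half a dozen
reactions and rules with a handful of genes.
"""

from __future__ import annotations

import itertools

import numpy as np

from .core import Model
from .gpr import GprLeaf, GprNode, GprTree, _GprEmpty

__all__ = ["truth_table_eval", "enumerate_vertices", "vertex_fva", "vertex_fba_max"]


def truth_table_eval(tree: GprTree, assignment: dict[str, bool]) -> bool:
    """Evaluate a GPR tree by structural recursion, independently of
    ``GprTree.evaluate`` (no default handling: assignment must be total)."""
    if isinstance(tree, _GprEmpty):
        return True
    if isinstance(tree, GprLeaf):
        return assignment[tree.gene]
    assert isinstance(tree, GprNode)
    vals = [truth_table_eval(c, assignment) for c in tree.children]
    return all(vals) if tree.op == "and" else any(vals)


def enumerate_vertices(model: Model, atol: float = 1e-8) -> np.ndarray:
    """Candidate vertices of {v : S v = 0, lb <= v <= ub}.

    Every vertex of the (bounded) polytope has at least n - rank(S)
    coordinates tight at a bound, with the free columns of S linearly
    independent.  Enumerating all {free, at-lb, at-ub} patterns over the
    n reactions and solving for the free coordinates therefore visits
    every vertex.  Exponential (3^n patterns): use only for n <= ~8.
    """
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(rids)
    points = []
    for pattern in itertools.product((0, 1, 2), repeat=n):
        free = [j for j, p in enumerate(pattern) if p == 0]
        v = np.where(np.array(pattern) == 1, lb, ub).astype(float)
        if free:
            A = S[:, free]
            fixed = [j for j in range(n) if j not in free]
            b = -S[:, fixed] @ v[fixed] if fixed else np.zeros(S.shape[0])
            sol, residual, rank, _ = np.linalg.lstsq(A, b, rcond=None)
            if rank < len(free):
                continue  # not a vertex pattern; covered by a tighter one
            v[free] = sol
        if np.max(np.abs(S @ v)) > atol:
            continue
        if np.any(v < lb - atol) or np.any(v > ub + atol):
            continue
        points.append(np.clip(v, lb, ub))
    if not points:
        return np.empty((0, n))
    return np.array(points)


def vertex_fva(model: Model) -> dict[str, tuple[float, float]]:
    """FVA by vertex enumeration: extremes of each coordinate over vertices."""
    _, _, rids = model.stoichiometric_matrix()
    pts = enumerate_vertices(model)
    if pts.size == 0:
        raise RuntimeError("no feasible vertex found (infeasible model?)")
    return {rid: (float(pts[:, j].min()), float(pts[:, j].max()))
            for j, rid in enumerate(rids)}


def vertex_fba_max(model: Model, objective_rxn: str) -> float:
    """Max feasible flux of one reaction, by vertex enumeration."""
    return vertex_fva(model)[objective_rxn][1]
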