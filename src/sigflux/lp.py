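"""Linear-programming core: FBA, L1 min-norm FBA, FVA, robustness scans.

All solves go through ``scipy.optimize.linprog`` (HiGHS).  The feasible
set is the steady-state flux polytope {v : S v = 0, lb <= v <= ub}; with
finite bounds it is a bounded polytope, so every LP here is either
optimal or infeasible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import Model

__all__ = [
    "FluxResult",
    "FVAResult",
    "SensitivityCurve",
    "FEASIBILITY_TOL",
    "fba",
    "fba_min_norm",
    "fva",
    "robustness_scan",
]

#: Flux tolerance for feasibility checks and blocked classification.
FEASIBILITY_TOL = 1e-6


@dataclass
class FluxResult:
    """Outcome of a single FBA solve."""

    objective_value: float | None
    fluxes: dict[str, float]
    status: str  # optimal | infeasible | unbounded

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FVAResult:
    """Per-reaction feasible flux ranges."""

    ranges: dict[str, tuple[float, float]]

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]

    def __iter__(self):
        return iter(self.ranges)

    def items(self):
        return self.ranges.items()

    def minimum(self, rid: str) -> float:
        return self.ranges[rid][0]

    def maximum(self, rid: str) -> float:
        return self.ranges[rid][1]

    def blocked(self, tol: float = FEASIBILITY_TOL) -> set[str]:
        return {rid for rid, (lo, hi) in self.ranges.items()
                if abs(lo) <= tol and abs(hi) <= tol}


@dataclass
class SensitivityCurve:
    """Max output flux as a function of an energy-exchange lower bound."""

    control_id: str
    output_id: str
    control_values: np.ndarray  # lower-bound grid, strictly monotone
    responses: np.ndarray      # max objective flux; NaN where infeasible

    def classify(self, tol: float = FEASIBILITY_TOL) -> str:
        """Label the output {dependent, independent} of the control."""
        finite = self.responses[np.isfinite(self.responses)]
        if finite.size == 0:
            return "independent"
        return "dependent" if (finite.max() - finite.min()) > tol else "independent"


_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs")
    return res


def fba(model: Model, objective_rxn: str, sense: str = "max") -> FluxResult:
    """Flux balance analysis: optimize one reaction flux at steady state."""
    S, _, rids = model.stoichiometric_matrix()
    if objective_rxn not in model.reactions:
        raise KeyError(f"unknown objective reaction {objective_rxn!r}")
    lb, ub = model.bounds_arrays()
    n = len(rids)
    c = np.zeros(n)
    j = rids.index(objective_rxn)
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve(c, S, np.zeros(S.shape[0]), list(zip(lb, ub)))
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxResult(None, {}, status)
    fluxes = dict(zip(rids, res.x))
    return FluxResult(float(res.x[j]), fluxes, "optimal")


def fba_min_norm(model: Model, objective_rxn: str, sense: str = "max") -> FluxResult:
    """FBA followed by L1 flux minimization at the fixed optimum.

    Among the objective-optimal flux vectors, returns one minimizing
    sum_i |v_i| (parsimonious FBA).  This suppresses arbitrary flux
    through internal loops, which otherwise pad the solution.  The L1
    norm is used (split-variable LP) rather than the Euclidean norm so
    the whole stack stays within linear programming.
    """
    first = fba(model, objective_rxn, sense)
    if not first.ok:
        return first
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    n = len(rids)
    j = rids.index(objective_rxn)
    opt = first.objective_value
    # Variables [v; t], minimize sum t s.t. S v = 0, v_j = opt, |v| <= t.
    c = np.concatenate([np.zeros(n), np.ones(n)])
    A_eq = np.zeros((S.shape[0] + 1, 2 * n))
    A_eq[:S.shape[0], :n] = S
    A_eq[S.shape[0], j] = 1.0
    b_eq = np.concatenate([np.zeros(S.shape[0]), [opt]])
    A_ub = np.zeros((2 * n, 2 * n))
    A_ub[:n, :n] = np.eye(n)
    A_ub[:n, n:] = -np.eye(n)      # v - t <= 0
    A_ub[n:, :n] = -np.eye(n)
    A_ub[n:, n:] = -np.eye(n)      # -v - t <= 0
    b_ub = np.zeros(2 * n)
    tmax = np.maximum(np.abs(lb), np.abs(ub))
    bounds = list(zip(lb, ub)) + [(0.0, t) for t in tmax]
    res = _solve(c, A_eq, b_eq, bounds, A_ub, b_ub)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        # The L1 stage can only fail numerically; report the plain answer.
        warnings.warn(f"min-norm stage returned {status}; plain FBA vertex kept")
        return first
    v = res.x[:n]
    return FluxResult(float(v[j]), dict(zip(rids, v)), "optimal")


def fva(model: Model, reactions: Iterable[str] | None = None) -> FVAResult:
    """Flux variability analysis: min and max flux per listed reaction.

    No objective is fixed: the ranges are taken over the whole feasible
    set defined by the current bounds (two LPs per reaction).  Raises if
    the model is infeasible.
    """
    S, _, rids = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    bounds = list(zip(lb, ub))
    targets = list(reactions) if reactions is not None else list(rids)
    for t in targets:
        if t not in model.reactions:
            raise KeyError(f"unknown reaction {t!r}")
    feas = _solve(np.zeros(len(rids)), S, np.zeros(S.shape[0]), bounds)
    if feas.status != 0:
        raise RuntimeError(
            f"model infeasible under current bounds ({_STATUS.get(feas.status)})")
    ranges: dict[str, tuple[float, float]] = {}
    for t in targets:
        j = rids.index(t)
        c = np.zeros(len(rids))
        c[j] = 1.0
        lo = _solve(c, S, np.zeros(S.shape[0]), bounds)
        hi = _solve(-c, S, np.zeros(S.shape[0]), bounds)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA solve failed for {t}")
        vmin = float(np.clip(lo.x[j], lb[j], ub[j])) + 0.0  # drop negative zero
        vmax = float(np.clip(hi.x[j], lb[j], ub[j])) + 0.0
        if vmin > vmax:  # solver jitter on degenerate problems
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[t] = (vmin, vmax)
    return FVAResult(ranges)


def robustness_scan(model: Model, control_rxn: str, objective_rxn: str,
                    n_points: int = 50,
                    lb_range: Sequence[float] = (-25.0, 0.0)) -> SensitivityCurve:
    """Max objective flux while sweeping an exchange lower bound.

    The control reaction's lower bound is stepped over ``n_points``
    values spanning ``lb_range`` (its upper bound held at 0, i.e. uptake
    only); at each grid point the objective is maximized.  Infeasible
    grid points are recorded as NaN.  The input model is not mutated.
    """
    if control_rxn not in model.reactions:
        raise KeyError(f"unknown control reaction {control_rxn!r}")
    grid = np.linspace(lb_range[0], lb_range[1], n_points)
    work = model.copy()
    ctrl = work.reactions[control_rxn]
    responses = np.full(n_points, np.nan)
    for i, g in enumerate(grid):
        ctrl.lb = float(g)
        ctrl.ub = 0.0
        sol = fba(work, objective_rxn, "max")
        if sol.ok:
            responses[i] = sol.objective_value + 0.0  # drop negative zero
    return SensitivityCurve(control_rxn, objective_rxn, grid, responses)
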