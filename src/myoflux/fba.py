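"""Steady-state flux-balance analysis.

Solves the linear program

    max (or min)  v[objective]
    subject to    S @ v = 0,   lb <= v <= ub

with scipy's HiGHS backend.  The optimal objective *value* is unique even
when the optimal flux vector is degenerate; flux maps from degenerate
solutions carry a warning flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model import StoichiometricModel, assemble_matrix

__all__ = [
    "FluxSolution",
    "solve_fba",
    "flux_difference",
    "brute_force_vertex_optimum",
    "FEASIBILITY_TOL",
]

#: Componentwise tolerance for |S v| and bound violations on reported optima.
FEASIBILITY_TOL: float = 1e-6
#: Tolerance requested from the LP solver itself.
SOLVER_TOL: float = 1e-9


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_value: float | None = None
    fluxes: dict[str, float] = field(default_factory=dict)
    degenerate_warning: bool = False

    def flux(self, rid: str) -> float:
        return self.fluxes[rid]


_STATUS = {0: "optimal", 1: "iteration-limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def solve_bounds_lp(
    S: np.ndarray,
    objective_index: int,
    bounds: list[tuple[float, float]],
    direction: str = "maximize",
) -> tuple[str, float | None, np.ndarray | None]:
    """Low-level solve on a pre-assembled matrix; used by the sweep hot loop."""
    n = S.shape[1]
    c = np.zeros(n)
    c[objective_index] = -1.0 if direction == "maximize" else 1.0
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": SOLVER_TOL, "dual_feasibility_tolerance": SOLVER_TOL},
    )
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return status, None, None
    value = res.x[objective_index]
    return "optimal", float(value), res.x


def solve_fba(model: StoichiometricModel, direction: str = "maximize") -> FluxSolution:
    """Maximise (or minimise) the objective reaction's flux at steady state.

    Returns status ``infeasible`` or ``unbounded`` with no fluxes when the
    polytope is empty or the objective unbounded; otherwise an ``optimal``
    solution whose residual ``|S v|`` is within :data:`FEASIBILITY_TOL`.
    """
    if direction not in ("maximize", "minimize"):
        raise ValueError(f"direction must be maximize or minimize, got {direction!r}")
    S = assemble_matrix(model)
    j = model.objective_index()
    bnds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    status, value, x = solve_bounds_lp(S, j, bnds, direction)
    if status != "optimal":
        return FluxSolution(status=status if status in ("infeasible", "unbounded") else "infeasible")
    fluxes = dict(zip(model.reaction_ids(), map(float, x)))
    # crude degeneracy flag: any non-objective flux sits strictly between its
    # bounds while its reduced direction is unconstrained — we approximate by
    # counting interior fluxes beyond the equality-system rank
    rank = int(np.linalg.matrix_rank(S))
    interior = sum(
        1
        for (lo, hi), v in zip(bnds, x)
        if lo + FEASIBILITY_TOL < v < hi - FEASIBILITY_TOL
    )
    return FluxSolution(
        status="optimal",
        objective_value=value,
        fluxes=fluxes,
        degenerate_warning=interior > rank,
    )


def flux_difference(sol: FluxSolution, control: FluxSolution) -> dict[str, float]:
    """Per-reaction flux change of ``sol`` relative to ``control``.

    Both solutions must be optimal and cover the same reaction set.
    """
    if sol.status != "optimal" or control.status != "optimal":
        raise ValueError("flux_difference requires two optimal solutions")
    if set(sol.fluxes) != set(control.fluxes):
        missing = set(sol.fluxes) ^ set(control.fluxes)
        raise ValueError(f"mismatched reaction sets; differ on {sorted(missing)[:5]}")
    return {rid: sol.fluxes[rid] - control.fluxes[rid] for rid in sol.fluxes}


def export_fluxes_tsv(fluxes: dict[str, float], path) -> None:
    """Two-column TSV export (reaction id, flux)."""
    with open(path, "w") as fh:
        fh.write("reaction\tflux\n")
        for rid, v in fluxes.items():
            fh.write(f"{rid}\t{v:.12g}\n")


def brute_force_vertex_optimum(
    model: StoichiometricModel, direction: str = "maximize", max_reactions: int = 10
) -> FluxSolution:
    """Exhaustive vertex-enumeration oracle for tiny models.

    Enumerates candidate basic feasible solutions of the polytope
    ``{v : S v = 0, lb <= v <= ub}``: every choice of ``n - rank(S)``
    variables pinned to a bound whose remaining square-ish system is
    uniquely solvable.  Intended purely as an independent correctness check
    for :func:`solve_fba`; refuses models with more than ``max_reactions``
    reactions.
    """
    n = len(model.reactions)
    if n > max_reactions:
        raise ValueError(f"vertex enumeration capped at {max_reactions} reactions, got {n}")
    S = assemble_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if not (np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))):
        raise ValueError("vertex enumeration requires finite bounds")
    j_obj = model.objective_index()
    rank = int(np.linalg.matrix_rank(S)) if S.size else 0
    k = n - rank  # number of variables pinned at bounds in a basis

    sign = 1.0 if direction == "maximize" else -1.0
    best: float | None = None
    best_x: np.ndarray | None = None
    tol = 1e-7
    for fixed in itertools.combinations(range(n), k):
        free = [i for i in range(n) if i not in fixed]
        A = S[:, free]
        if free and np.linalg.matrix_rank(A) < len(free):
            continue  # free block not uniquely solvable -> not a vertex basis
        for pattern in itertools.product(*[(lb[i], ub[i]) for i in fixed]):
            x = np.empty(n)
            for i, val in zip(fixed, pattern):
                x[i] = val
            if free:
                rhs = -S[:, fixed] @ np.array(pattern) if fixed else np.zeros(S.shape[0])
                sol, res, *_ = np.linalg.lstsq(A, rhs, rcond=None)
                if np.linalg.norm(S[:, fixed] @ np.array(pattern) + A @ sol, ord=np.inf) > tol:
                    continue  # inconsistent: no steady state with this pinning
                for i, v in zip(free, sol):
                    x[i] = v
            elif np.linalg.norm(S @ x, ord=np.inf) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            val = sign * x[j_obj]
            if best is None or val > best + 1e-12:
                best, best_x = val, x.copy()
    if best is None:
        return FluxSolution(status="infeasible")
    return FluxSolution(
        status="optimal",
        objective_value=float(sign * best),
        fluxes=dict(zip(model.reaction_ids(), map(float, best_x))),
    )
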