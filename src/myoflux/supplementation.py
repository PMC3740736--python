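"""Condition application, supplementation, and the combinatorial sweep.

Supplementing an amino acid means relaxing its uptake upper bound to an
effectively unlimited cap (99999 in model units).  The sweep enumerates
every subset of 1..k_max amino acids (k_max 7 by default; the search space
grows steeply beyond that), re-solves the FBA problem for each, and flags
subsets whose optimum exceeds the control optimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aminoacids import AMINO_ACIDS
from .conditions import Condition
from .fba import FluxSolution, solve_bounds_lp, solve_fba
from .model import UNBOUNDED_CAP, StoichiometricModel, assemble_matrix

__all__ = [
    "SupplementResult",
    "SweepOutcome",
    "ConditionMappingError",
    "uptake_reaction_id",
    "find_uptake_reaction",
    "apply_condition",
    "supplement",
    "sweep",
    "best_per_size",
]

IMPROVEMENT_TOL = 1e-9


class ConditionMappingError(KeyError):
    """A condition names a metabolite with no uptake exchange in the model."""


def uptake_reaction_id(metabolite_id: str) -> str:
    """Canonical id of the uptake exchange for a metabolite."""
    return f"EX_{metabolite_id}"


def find_uptake_reaction(model: StoichiometricModel, metabolite_id: str) -> str:
    """Resolve the uptake exchange reaction for a metabolite.

    Tries the canonical ``EX_<met>`` id first, then any exchange-subsystem
    reaction that only produces the metabolite.
    """
    rid = uptake_reaction_id(metabolite_id)
    if model.has_reaction(rid):
        return rid
    for r in model.reactions:
        if r.subsystem == "exchange" and not r.id.endswith("_out"):
            if set(r.stoichiometry) == {metabolite_id} and r.stoichiometry[metabolite_id] > 0:
                return r.id
    raise ConditionMappingError(
        f"no uptake exchange reaction for metabolite {metabolite_id!r}"
    )


def apply_condition(model: StoichiometricModel, condition: Condition) -> StoichiometricModel:
    """Return a copy with each listed uptake's upper bound set to the profile value.

    Unlisted exchanges are untouched; export reactions are not constrained
    here (secretion stays allowed up to the unbounded cap).
    """
    bounded = model.copy()
    for met, value in condition.uptake_bounds.items():
        rid = find_uptake_reaction(bounded, met)
        rxn = bounded.reaction(rid)
        rxn.upper_bound = float(value)
        rxn.lower_bound = min(rxn.lower_bound, float(value))
    return bounded


def supplement(
    model: StoichiometricModel,
    subset: set[str] | frozenset[str],
    cap: float = UNBOUNDED_CAP,
) -> StoichiometricModel:
    """Return a copy with the subset's amino-acid uptake bounds raised to ``cap``."""
    bad = set(subset) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"subset contains non-amino-acid ids: {sorted(bad)}")
    relaxed = model.copy()
    for aa in subset:
        rid = find_uptake_reaction(relaxed, aa)
        relaxed.reaction(rid).upper_bound = float(cap)
    return relaxed


@dataclass(frozen=True)
class SupplementResult:
    """Objective outcome for one supplemented amino-acid subset."""

    subset: frozenset[str]
    condition: str
    objective_value: float
    improved: bool


@dataclass
class SweepOutcome:
    """Control solution plus one result per enumerated subset."""

    condition: str
    control: FluxSolution
    results: list[SupplementResult]

    @property
    def control_objective(self) -> float:
        return self.control.objective_value


def sweep(
    model: StoichiometricModel,
    condition: Condition,
    k_max: int = 7,
    prune: bool = False,
    cap: float = UNBOUNDED_CAP,
    amino_acids: tuple[str, ...] | None = None,
) -> SweepOutcome:
    """Exhaustive supplementation sweep over subsets of size 1..k_max.

    The model's bounds are first set from ``condition``; the control optimum
    is solved, then every subset of the model's amino-acid uptakes up to
    ``k_max`` is relaxed to ``cap`` and re-solved.  With ``prune=True`` the
    optimum under relaxing *all* amino acids is used as a proven upper
    bound: when it shows no subset can improve on control, per-subset solves
    are skipped and each objective is reported at the control value (the
    bound pins it there); best-per-size output is unchanged.
    """
    bounded = apply_condition(model, condition)
    control = solve_fba(bounded)
    if control.status != "optimal":
        raise RuntimeError(
            f"control problem is {control.status} under condition {condition.name!r}; "
            "check exchange bounds and demand stoichiometry"
        )

    if amino_acids is None:
        aas = tuple(
            aa for aa in AMINO_ACIDS if _has_uptake(bounded, aa)
        )
    else:
        aas = tuple(sorted(amino_acids))
    # hot loop works on the assembled matrix with per-subset bound edits
    S = assemble_matrix(bounded)
    j_obj = bounded.objective_index()
    base_bounds = [(r.lower_bound, r.upper_bound) for r in bounded.reactions]
    uptake_index = {
        aa: bounded.reaction_ids().index(find_uptake_reaction(bounded, aa)) for aa in aas
    }

    ceiling = None
    if prune:
        all_bounds = list(base_bounds)
        for aa in aas:
            lo, _ = all_bounds[uptake_index[aa]]
            all_bounds[uptake_index[aa]] = (lo, cap)
        status, ceiling, _ = solve_bounds_lp(S, j_obj, all_bounds)
        if status != "optimal":
            ceiling = None

    results: list[SupplementResult] = []
    c0 = control.objective_value
    skip_all = prune and ceiling is not None and ceiling <= c0 + IMPROVEMENT_TOL
    for k in range(1, min(k_max, len(aas)) + 1):
        for combo in itertools.combinations(aas, k):
            if skip_all:
                results.append(
                    SupplementResult(frozenset(combo), condition.name, c0, False)
                )
                continue
            bnds = list(base_bounds)
            for aa in combo:
                lo, _ = bnds[uptake_index[aa]]
                bnds[uptake_index[aa]] = (lo, cap)
            status, value, _ = solve_bounds_lp(S, j_obj, bnds)
            if status != "optimal":
                raise RuntimeError(f"subset {combo}: solver returned {status}")
            results.append(
                SupplementResult(
                    frozenset(combo),
                    condition.name,
                    value,
                    value > c0 + IMPROVEMENT_TOL,
                )
            )
    return SweepOutcome(condition=condition.name, control=control, results=results)


def _has_uptake(model: StoichiometricModel, aa: str) -> bool:
    try:
        find_uptake_reaction(model, aa)
        return True
    except ConditionMappingError:
        return False


def best_per_size(outcome: SweepOutcome, tie_tol: float = 1e-9) -> pd.DataFrame:
    """Best subset (max objective) for each subset size.

    Ties within ``tie_tol`` are broken lexicographically on the sorted
    amino-acid names and flagged in the ``tie`` column.
    """
    if not outcome.results:
        raise ValueError("empty sweep results")
    rows = []
    by_size: dict[int, list[SupplementResult]] = {}
    for res in outcome.results:
        by_size.setdefault(len(res.subset), []).append(res)
    for k in sorted(by_size):
        group = by_size[k]
        top = max(r.objective_value for r in group)
        contenders = [r for r in group if r.objective_value >= top - tie_tol]
        contenders.sort(key=lambda r: tuple(sorted(r.subset)))
        winner = contenders[0]
        rows.append(
            {
                "size": k,
                "subset": tuple(sorted(winner.subset)),
                "objective": winner.objective_value,
                "improved": winner.improved,
                "tie": len(contenders) > 1,
            }
        )
    return pd.DataFrame(rows)


def export_sweep_tsv(outcome: SweepOutcome, path) -> None:
    """Sweep results as TSV: size, subset, objective, improved."""
    rows = [
        {
            "size": len(r.subset),
            "subset": "+".join(sorted(r.subset)),
            "objective": r.objective_value,
            "improved": r.improved,
        }
        for r in outcome.results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
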