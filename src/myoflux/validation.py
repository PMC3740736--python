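"""Self-validation checks on synthetic models with known answers.

Each function here exercises one end-to-end guarantee of the package on
generated fixtures and returns a measured number (an error bound, a
violation count, a recovery rate).  The test suite asserts on these; the
reproduction script reports them.  All randomness is seeded.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .effects import actual_effect, availability_counts, expected_effect
from .fba import brute_force_vertex_optimum, solve_bounds_lp, solve_fba
from .model import UNBOUNDED_CAP, assemble_matrix
from .supplementation import best_per_size, sweep
from .synthetic import (
    ToySpec,
    bottleneck_amino_acid,
    closed_form_optimum,
    make_assembly_model,
    make_muscle_like_model,
    random_assembly_spec,
    toy_condition,
)

__all__ = [
    "lp_vs_vertex_max_error",
    "closed_form_max_error",
    "monotonicity_violations",
    "bottleneck_recovery_rate",
    "expected_actual_top1_agreement",
    "catabolic_divergence_example",
]


def lp_vs_vertex_max_error(n_models: int = 20, seed0: int = 0) -> float:
    """Max |LP optimum - vertex-enumeration optimum| over small random fixtures.

    Fixtures are random assembly models with at most 10 reactions (3 or 4
    amino acids; uptakes + demand + sink), solved both by the HiGHS LP and
    by exhaustive basic-feasible-solution enumeration.
    """
    worst = 0.0
    for i in range(n_models):
        spec = random_assembly_spec(seed0 + i, n_amino_acids=3 + (i % 2))
        m = make_assembly_model(spec)
        lp = solve_fba(m)
        bf = brute_force_vertex_optimum(m)
        if lp.status != bf.status:
            return float("inf")
        if lp.status == "optimal":
            worst = max(worst, abs(lp.objective_value - bf.objective_value))
    return worst


def closed_form_max_error(n_specs: int = 100, seed0: int = 1000) -> float:
    """Max |LP optimum - min-ratio closed form| over random assembly specs."""
    worst = 0.0
    for i in range(n_specs):
        spec = random_assembly_spec(seed0 + i, n_amino_acids=3 + (i % 8))
        sol = solve_fba(make_assembly_model(spec))
        worst = max(worst, abs(sol.objective_value - closed_form_optimum(spec)))
    return worst


def monotonicity_violations(n_trials: int = 1000, seed: int = 7, tol: float = 1e-7) -> int:
    """Count objective decreases after enlarging one reaction's bound interval.

    Relaxation can never shrink the feasible polytope, so the maximal
    objective must be non-decreasing; any decrease beyond ``tol``
    (absolute + relative) counts as a violation.
    """
    rng = np.random.default_rng(seed)
    violations = 0
    trials_done = 0
    model_seed = 0
    while trials_done < n_trials:
        spec = random_assembly_spec(10_000 + model_seed, n_amino_acids=4 + model_seed % 5)
        if model_seed % 3 == 2:  # every third model exercises the energy economy
            spec = replace(
                spec,
                energy_pathway=True,
                energy_cost_per_bond=4.0,
                glucose_conc=float(rng.uniform(0.05, 5.0)),
                catabolizable={spec.amino_acids[0]: float(rng.uniform(5, 40))},
            )
            model = make_muscle_like_model(spec)
        else:
            model = make_assembly_model(spec)
        model_seed += 1
        S = assemble_matrix(model)
        j = model.objective_index()
        base = [(r.lower_bound, r.upper_bound) for r in model.reactions]
        _, obj0, _ = solve_bounds_lp(S, j, base)
        if obj0 is None:
            continue
        for _ in range(min(20, n_trials - trials_done)):
            k = int(rng.integers(len(base)))
            lo, hi = base[k]
            bnds = list(base)
            if rng.random() < 0.5:
                bnds[k] = (lo, min(hi * float(rng.uniform(1.1, 10.0)) + 0.1, UNBOUNDED_CAP))
            else:
                bnds[k] = (max(lo - float(rng.uniform(0.1, 5.0)), -UNBOUNDED_CAP), hi)
            _, obj1, _ = solve_bounds_lp(S, j, bnds)
            trials_done += 1
            if obj1 is None or obj1 < obj0 - (tol + tol * abs(obj0)):
                violations += 1
    return violations


def bottleneck_recovery_rate(n_models: int = 20, seed0: int = 500) -> float:
    """Fraction of seeded assembly models whose planted bottleneck is the
    unique single-supplement improver found by the sweep."""
    hits = 0
    for i in range(n_models):
        spec = random_assembly_spec(seed0 + i, n_amino_acids=4 + i % 4)
        model = make_assembly_model(spec)
        outcome = sweep(model, toy_condition(spec), k_max=1)
        improvers = sorted(
            next(iter(r.subset)) for r in outcome.results if r.improved
        )
        if improvers == [bottleneck_amino_acid(spec)]:
            hits += 1
    return hits / n_models


def expected_actual_top1_agreement(n_models: int = 20, seed0: int = 800) -> float:
    """On assembly-only toys the availability ranking and the sweep agree at
    the top: both identify the planted bottleneck.  Returns the agreement
    fraction."""
    hits = 0
    for i in range(n_models):
        spec = random_assembly_spec(seed0 + i, n_amino_acids=4 + i % 4)
        model = make_assembly_model(spec)
        cond = toy_condition(spec)
        outcome = sweep(model, cond, k_max=1)
        available = availability_counts(cond, outcome.control_objective)
        rows = expected_effect({aa: spec.composition[aa] for aa in spec.amino_acids}, available)
        expected_top = rows[0].amino_acid
        actual = actual_effect(outcome)
        actual_top = [aa for aa, r in actual.items() if r == 1]
        if actual_top == [expected_top]:
            hits += 1
    return hits / n_models


def catabolic_divergence_example() -> dict[str, str]:
    """A miniature of the fuel-amino-acid phenomenon.

    Builds an energy-limited muscle-like toy in which an abundant,
    catabolizable amino acid (leucine) is the most effective single
    supplement — it is burned for ATP — while the availability-minus-need
    ranking puts the scarce methionine first.  Returns the two top-ranked
    amino acids; they differ, showing that catabolic routes decouple the
    expected and actual effects.
    """
    spec = ToySpec(
        composition={"methionine": 1, "leucine": 1, "glycine": 1},
        concentrations={"methionine": 0.05, "leucine": 0.5, "glycine": 0.5},
        essential_set=frozenset({"methionine", "leucine"}),
        energy_pathway=True,
        energy_cost_per_bond=4.0,
        n_chains=1,
        glucose_conc=0.0,
        palmitate_conc=0.0,
        tetradecanoate_conc=0.0,
        catabolizable={"leucine": 0.5},
        seed=42,
    )
    model = make_muscle_like_model(spec)
    cond = toy_condition(spec)
    outcome = sweep(model, cond, k_max=1)
    available = availability_counts(cond, outcome.control_objective)
    rows = expected_effect(dict(spec.composition), available)
    actual = actual_effect(outcome)
    actual_top = [aa for aa, r in actual.items() if r == 1]
    return {
        "expected_top": rows[0].amino_acid,
        "actual_top": actual_top[0] if actual_top else "",
        "control_objective": outcome.control_objective,
        "best_single_objective": best_per_size(outcome).iloc[0]["objective"],
    }
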