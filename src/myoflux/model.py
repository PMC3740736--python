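"""Core stoichiometric-model representation.

A metabolic network is held as an ordered collection of metabolites and
reactions.  At steady state the flux vector ``v`` satisfies ``S @ v = 0``
where ``S`` is the metabolites-by-reactions stoichiometry matrix assembled
by :func:`assemble_matrix`; flux bounds on each reaction encode
thermodynamic direction and substrate availability.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "UNBOUNDED_CAP",
    "COMPARTMENTS",
    "Metabolite",
    "Reaction",
    "StoichiometricModel",
    "ModelStats",
    "Violation",
    "ModelIntegrityError",
    "assemble_matrix",
    "model_stats",
    "validate_model",
]

#: Numeric stand-in for an "unlimited" flux bound (mmol/L/time, time
#: deliberately left undefined by the plasma-concentration convention).
UNBOUNDED_CAP: float = 99999.0

COMPARTMENTS = ("extracellular", "cytosol", "mitochondrion")


class ModelIntegrityError(ValueError):
    """Raised when a model violates its structural invariants."""


@dataclass(frozen=True)
class Metabolite:
    """A chemical species in one of three compartments."""

    id: str
    name: str = ""
    compartment: str = "cytosol"

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelIntegrityError("metabolite id must be non-empty")
        if self.compartment not in COMPARTMENTS:
            raise ModelIntegrityError(
                f"metabolite {self.id!r}: compartment {self.compartment!r} "
                f"not in {COMPARTMENTS}"
            )


@dataclass
class Reaction:
    """A stoichiometric reaction with flux bounds.

    ``stoichiometry`` maps metabolite id to a signed coefficient
    (negative = consumed, positive = produced).  Bounds are fluxes in model
    units; ``lower_bound >= 0`` makes the reaction irreversible.
    """

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = UNBOUNDED_CAP
    name: str = ""
    subsystem: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelIntegrityError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction {self.id!r}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )


@dataclass
class StoichiometricModel:
    """An ordered metabolic network with a single objective reaction.

    Ordering of ``metabolites`` and ``reactions`` is significant: it fixes
    the row/column order of the assembled stoichiometry matrix so that
    repeated assemblies are reproducible.
    """

    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: str | None = None
    name: str = ""

    # -- indexing helpers -------------------------------------------------
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.name!r}")

    def has_reaction(self, rid: str) -> bool:
        return any(r.id == rid for r in self.reactions)

    def objective_index(self) -> int:
        if self.objective_id is None:
            raise ModelIntegrityError("model has no objective reaction set")
        for j, r in enumerate(self.reactions):
            if r.id == self.objective_id:
                return j
        raise ModelIntegrityError(
            f"objective id {self.objective_id!r} resolves to no reaction"
        )

    def copy(self) -> "StoichiometricModel":
        """Deep copy; bound mutations on the copy never touch the original."""
        return StoichiometricModel(
            metabolites=list(self.metabolites),
            reactions=[replace(r, stoichiometry=dict(r.stoichiometry)) for r in self.reactions],
            objective_id=self.objective_id,
            name=self.name,
        )

    def __deepcopy__(self, memo):  # dataclass default is fine but slower
        return _copy.copy(self).copy()


@dataclass(frozen=True)
class ModelStats:
    """Structural summary: counts, numerical rank and conserved pools.

    ``dof`` counts conserved metabolite pools (left-null-space dimension),
    defined as ``n_metabolites - rank``.
    """

    n_reactions: int
    n_metabolites: int
    rank: int
    dof: int


@dataclass(frozen=True)
class Violation:
    """One entry of a validation report."""

    kind: str  # duplicate-id | dangling-metabolite | bound-inversion |
    #            orphan-metabolite | empty-stoichiometry | id-collision |
    #            bad-objective
    subject: str
    message: str


def validate_model(model: StoichiometricModel) -> list[Violation]:
    """Report structural violations; an empty list means the model is valid."""
    report: list[Violation] = []
    met_ids = model.metabolite_ids()
    rxn_ids = model.reaction_ids()
    met_set = set(met_ids)

    seen: set[str] = set()
    for mid in met_ids:
        if mid in seen:
            report.append(Violation("duplicate-id", mid, "duplicate metabolite id"))
        seen.add(mid)
    seen = set()
    for rid in rxn_ids:
        if rid in seen:
            report.append(Violation("duplicate-id", rid, "duplicate reaction id"))
        seen.add(rid)
    for shared in sorted(met_set & set(rxn_ids)):
        report.append(
            Violation("id-collision", shared, "id used for both a metabolite and a reaction")
        )

    used: set[str] = set()
    for r in model.reactions:
        if not r.stoichiometry:
            report.append(Violation("empty-stoichiometry", r.id, "reaction has no participants"))
        if r.lower_bound > r.upper_bound:
            report.append(
                Violation(
                    "bound-inversion",
                    r.id,
                    f"lower_bound {r.lower_bound} > upper_bound {r.upper_bound}",
                )
            )
        for mid in r.stoichiometry:
            if mid not in met_set:
                report.append(
                    Violation(
                        "dangling-metabolite",
                        r.id,
                        f"references unknown metabolite {mid!r}",
                    )
                )
            used.add(mid)

    for mid in met_ids:
        if mid not in used:
            report.append(Violation("orphan-metabolite", mid, "appears in no reaction"))

    if model.objective_id is not None and model.objective_id not in rxn_ids:
        report.append(
            Violation("bad-objective", model.objective_id, "objective resolves to no reaction")
        )
    return report


def assemble_matrix(model: StoichiometricModel) -> np.ndarray:
    """Assemble the dense stoichiometry matrix S (metabolites x reactions).

    Entry ``(i, j)`` is the coefficient of metabolite ``i`` in reaction
    ``j``; zero where the metabolite does not participate.  Row/column order
    follows model order.
    """
    hard = [
        v
        for v in validate_model(model)
        if v.kind in ("dangling-metabolite", "duplicate-id", "empty-stoichiometry")
    ]
    if hard:
        raise ModelIntegrityError(
            "cannot assemble matrix: " + "; ".join(f"{v.kind}:{v.subject}" for v in hard)
        )
    index = {mid: i for i, mid in enumerate(model.metabolite_ids())}
    S = np.zeros((len(model.metabolites), len(model.reactions)))
    for j, r in enumerate(model.reactions):
        for mid, coeff in r.stoichiometry.items():
            S[index[mid], j] = coeff
    return S


def model_stats(model: StoichiometricModel, tol: float | None = None) -> ModelStats:
    """Counts, numerical rank and conserved-pool count of the network.

    Parameters
    ----------
    tol:
        Singular-value cutoff for the numerical rank.  Default is the
        standard ``max(m, n) * eps * sigma_max``.
    """
    S = assemble_matrix(model)
    rank = int(np.linalg.matrix_rank(S, tol=tol))
    return ModelStats(
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        rank=rank,
        dof=len(model.metabolites) - rank,
    )


def export_matrix_tsv(model: StoichiometricModel, path) -> None:
    """Write S as TSV with metabolite rows and reaction columns."""
    import pandas as pd

    S = assemble_matrix(model)
    pd.DataFrame(S, index=model.metabolite_ids(), columns=model.reaction_ids()).to_csv(
        path, sep="\t"
    )


def export_validation_tsv(report: list[Violation], path) -> None:
    """Write a validation report as a three-column TSV."""
    import pandas as pd

    pd.DataFrame(
        [(v.kind, v.subject, v.message) for v in report],
        columns=["kind", "subject", "message"],
    ).to_csv(path, sep="\t", index=False)
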