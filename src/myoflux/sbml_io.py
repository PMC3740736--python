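"""SBML import/export for stoichiometric models.

Reads SBML Level 2 or Level 3 files via libSBML.  Two bound dialects are
accepted: the fbc package (flux-bound parameters referenced from each
reaction) and the legacy kinetic-law convention (local parameters named
``LOWER_BOUND`` / ``UPPER_BOUND``).  A reversible flag without explicit
bounds maps to ``(-UNBOUNDED_CAP, +UNBOUNDED_CAP)``; irreversible to
``(0, +UNBOUNDED_CAP)``.  Files are written as Level 3 Version 1 with fbc
version 2, which round-trips bounds and the objective exactly.
"""

from __future__ import annotations

import warnings

import libsbml

from .model import (
    UNBOUNDED_CAP,
    Metabolite,
    ModelIntegrityError,
    Reaction,
    StoichiometricModel,
)

__all__ = ["read_sbml", "write_sbml", "SBMLParseError"]


class SBMLParseError(ValueError):
    """Raised on malformed or structurally unusable SBML input."""


_COMPARTMENT_ALIASES = {
    "e": "extracellular",
    "ext": "extracellular",
    "extracellular": "extracellular",
    "extra_cellular": "extracellular",
    "c": "cytosol",
    "cyt": "cytosol",
    "cytosol": "cytosol",
    "cytoplasm": "cytosol",
    "m": "mitochondrion",
    "mit": "mitochondrion",
    "mito": "mitochondrion",
    "mitochondrion": "mitochondrion",
    "mitochondria": "mitochondrion",
}


def _map_compartment(raw: str, species_id: str) -> str:
    if not raw:
        warnings.warn(
            f"species {species_id!r} has no compartment; assigned cytosol", stacklevel=3
        )
        return "cytosol"
    key = raw.strip().lower()
    if key in _COMPARTMENT_ALIASES:
        return _COMPARTMENT_ALIASES[key]
    warnings.warn(
        f"species {species_id!r}: unrecognised compartment {raw!r}; assigned cytosol",
        stacklevel=3,
    )
    return "cytosol"


def _reaction_bounds(sb_rxn, sb_model) -> tuple[float, float]:
    fbc_rxn = sb_rxn.getPlugin("fbc")
    if fbc_rxn is not None:
        lb_id = fbc_rxn.getLowerFluxBound()
        ub_id = fbc_rxn.getUpperFluxBound()
        if lb_id or ub_id:
            lb = ub = None
            for pid, target in ((lb_id, "lb"), (ub_id, "ub")):
                if not pid:
                    continue
                par = sb_model.getParameter(pid)
                if par is None:
                    raise SBMLParseError(
                        f"reaction {sb_rxn.getId()!r}: flux-bound parameter {pid!r} missing"
                    )
                if target == "lb":
                    lb = par.getValue()
                else:
                    ub = par.getValue()
            rev = sb_rxn.getReversible()
            if lb is None:
                lb = -UNBOUNDED_CAP if rev else 0.0
            if ub is None:
                ub = UNBOUNDED_CAP
            return float(lb), float(ub)
    kl = sb_rxn.getKineticLaw()
    if kl is not None:
        lb = ub = None
        for i in range(kl.getNumParameters()):
            par = kl.getParameter(i)
            if par.getId() in ("LOWER_BOUND", "lower_bound"):
                lb = par.getValue()
            elif par.getId() in ("UPPER_BOUND", "upper_bound"):
                ub = par.getValue()
        # older files put them as local parameters (L3)
        if hasattr(kl, "getNumLocalParameters"):
            for i in range(kl.getNumLocalParameters()):
                par = kl.getLocalParameter(i)
                if par.getId() in ("LOWER_BOUND", "lower_bound"):
                    lb = par.getValue()
                elif par.getId() in ("UPPER_BOUND", "upper_bound"):
                    ub = par.getValue()
        if lb is not None or ub is not None:
            rev = sb_rxn.getReversible()
            if lb is None:
                lb = -UNBOUNDED_CAP if rev else 0.0
            if ub is None:
                ub = UNBOUNDED_CAP
            return float(lb), float(ub)
    if sb_rxn.getReversible():
        return -UNBOUNDED_CAP, UNBOUNDED_CAP
    return 0.0, UNBOUNDED_CAP


def read_sbml(path, objective_id: str | None = None) -> StoichiometricModel:
    """Read an SBML file into a :class:`StoichiometricModel`.

    Parameters
    ----------
    objective_id:
        Reaction id to use as the objective.  Overrides any fbc objective in
        the file.  If neither is given, a reaction whose id or name contains
        ``demand`` is used when unique, otherwise the objective is left
        unset (set it before solving).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLParseError(f"SBML parse failed: {first.getMessage().strip()}")
    sb_model = doc.getModel()
    if sb_model is None:
        raise SBMLParseError("file contains no SBML model element")

    metabolites: list[Metabolite] = []
    boundary: set[str] = set()
    for i in range(sb_model.getNumSpecies()):
        sp = sb_model.getSpecies(i)
        if sp.getBoundaryCondition():
            # boundary species are outside the mass balance; drop them and
            # the corresponding matrix rows
            boundary.add(sp.getId())
            continue
        metabolites.append(
            Metabolite(
                id=sp.getId(),
                name=sp.getName() or "",
                compartment=_map_compartment(sp.getCompartment(), sp.getId()),
            )
        )

    reactions: list[Reaction] = []
    for i in range(sb_model.getNumReactions()):
        rx = sb_model.getReaction(i)
        stoich: dict[str, float] = {}
        for k in range(rx.getNumReactants()):
            ref = rx.getReactant(k)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - ref.getStoichiometry()
        for k in range(rx.getNumProducts()):
            ref = rx.getProduct(k)
            if ref.getSpecies() in boundary:
                continue
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + ref.getStoichiometry()
        if not stoich:
            # exchange written against boundary species only: keep the
            # reaction with its sole non-boundary participant if any side
            # survives; otherwise it is a pure source/sink with no internal
            # species and cannot appear in S — skip with a warning.
            warnings.warn(
                f"reaction {rx.getId()!r} involves only boundary species; skipped",
                stacklevel=2,
            )
            continue
        lb, ub = _reaction_bounds(rx, sb_model)
        reactions.append(
            Reaction(
                id=rx.getId(),
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                name=rx.getName() or "",
            )
        )

    obj = objective_id
    fbc_model = sb_model.getPlugin("fbc")
    if obj is None and fbc_model is not None and fbc_model.getNumObjectives() > 0:
        active = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if active is not None and active.getNumFluxObjectives() > 0:
            obj = active.getFluxObjective(0).getReaction()
    if obj is None:
        demand_like = [
            r.id for r in reactions if "demand" in r.id.lower() or "demand" in r.name.lower()
        ]
        if len(demand_like) == 1:
            obj = demand_like[0]
    if obj is not None and obj not in {r.id for r in reactions}:
        raise ModelIntegrityError(f"objective id {obj!r} not among reactions")
    return StoichiometricModel(
        metabolites=metabolites,
        reactions=reactions,
        objective_id=obj,
        name=sb_model.getId() or sb_model.getName() or "",
    )


def write_sbml(model: StoichiometricModel, path) -> None:
    """Write the model as SBML Level 3 Version 1 with fbc version 2."""
    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sb_model = doc.createModel()
    sb_model.setId(model.name or "model")
    fbc_model = sb_model.getPlugin("fbc")
    fbc_model.setStrict(True)

    for comp_id in ("extracellular", "cytosol", "mitochondrion"):
        comp = sb_model.createCompartment()
        comp.setId(comp_id)
        comp.setConstant(True)

    for m in model.metabolites:
        sp = sb_model.createSpecies()
        sp.setId(m.id)
        if m.name:
            sp.setName(m.name)
        sp.setCompartment(m.compartment)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
        sp.setConstant(False)

    bound_params: dict[float, str] = {}

    def bound_param(value: float) -> str:
        if value not in bound_params:
            pid = f"fb_{len(bound_params)}"
            par = sb_model.createParameter()
            par.setId(pid)
            par.setValue(float(value))
            par.setConstant(True)
            bound_params[value] = pid
        return bound_params[value]

    for r in model.reactions:
        rx = sb_model.createReaction()
        rx.setId(r.id)
        if r.name:
            rx.setName(r.name)
        rx.setFast(False)
        rx.setReversible(r.lower_bound < 0)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(float(coeff)))
            ref.setConstant(True)
        fbc_rxn = rx.getPlugin("fbc")
        fbc_rxn.setLowerFluxBound(bound_param(r.lower_bound))
        fbc_rxn.setUpperFluxBound(bound_param(r.upper_bound))

    if model.objective_id is not None:
        objective = fbc_model.createObjective()
        objective.setId("obj")
        objective.setType("maximize")
        flux_obj = objective.createFluxObjective()
        flux_obj.setReaction(model.objective_id)
        flux_obj.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path!r}")
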