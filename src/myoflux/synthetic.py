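"""Synthetic stoichiometric models with known optima.

Two generator families support testing of every pipeline stage:

* *assembly* models — only amino-acid uptakes feeding a single complex
  demand reaction.  Their FBA optimum has the closed form
  ``min over aa of concentration(aa) / residues(aa)``, so solver output can
  be checked exactly.
* *muscle-like* models — assembly plus a lumped energy economy (glucose and
  fatty-acid catabolism regenerating ATP, a nucleoside-diphosphate kinase
  supplying GTP), optional amino-acid catabolic routes that burn selected
  amino acids for ATP, and optional non-essential amino-acid
  interconversion through a glutamate hub.  These reproduce, in miniature,
  the structural features of the muscle network: peptide-bond energy
  coupling, amino acids usable as fuel, and availability shortcuts that
  decouple the sweep's outcome from the naive availability ranking.

All generation is deterministic given the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .aminoacids import AMINO_ACIDS, BCAA, ESSENTIAL
from .conditions import Condition, fasting_condition
from .model import UNBOUNDED_CAP, Metabolite, Reaction, StoichiometricModel
from .proteins import (
    DemandRecipe,
    ProteinComposition,
    build_demand_reaction,
    canonical_recipe,
    complex_metabolite_id,
    demand_metabolites,
    per_complex_need,
)

__all__ = [
    "ToySpec",
    "make_assembly_model",
    "make_muscle_like_model",
    "closed_form_optimum",
    "bottleneck_amino_acid",
    "random_assembly_spec",
    "reference_muscle_spec",
    "synthetic_composition_table",
    "MUSCLE_CATABOLIC_ATP_YIELD",
]

#: Lumped ATP-equivalents per unit of each fuel (glycolysis + oxidative
#: phosphorylation collapsed to one reaction; deliberate simplification).
GLUCOSE_ATP_YIELD = 30.0
PALMITATE_ATP_YIELD = 106.0
TETRADECANOATE_ATP_YIELD = 92.0

#: Amino acids muscle can burn for energy in the reference toy, with lumped
#: ATP yields per residue oxidised (BCAAs plus the other routes the muscle
#: network carries: serine via pyruvate, lysine via fatty-acid oxidation,
#: proline via FADH2, and the glucogenic ala/asp/asn/glu/gln/gly group).
MUSCLE_CATABOLIC_ATP_YIELD: dict[str, float] = {
    "isoleucine": 40.0,
    "leucine": 40.0,
    "valine": 32.0,
    "lysine": 35.0,
    "serine": 12.0,
    "proline": 25.0,
    "alanine": 13.0,
    "aspartate": 13.0,
    "asparagine": 13.0,
    "glutamate": 22.0,
    "glutamine": 22.0,
    "glycine": 7.0,
}


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one synthetic model; deterministic given ``seed``."""

    composition: dict[str, int] = field(hash=False)
    concentrations: dict[str, float] = field(hash=False)
    essential_set: frozenset[str] = frozenset()
    allow_interconversion: bool = False
    energy_pathway: bool = False
    energy_cost_per_bond: float = 0.0
    n_chains: int = 1
    glucose_conc: float = 5.0
    palmitate_conc: float = 0.125
    tetradecanoate_conc: float = 0.230
    catabolizable: dict[str, float] = field(default_factory=dict, hash=False)
    seed: int = 0

    def __post_init__(self) -> None:
        aas = set(self.composition)
        if set(self.concentrations) != aas:
            raise ValueError("composition and concentrations must key the same amino acids")
        if not aas <= set(AMINO_ACIDS):
            raise ValueError(f"unknown amino-acid ids: {sorted(aas - set(AMINO_ACIDS))}")
        if not 2 <= len(aas) <= 20:
            raise ValueError("need between 2 and 20 amino acids")
        if not self.essential_set <= aas:
            raise ValueError("essential_set must be a subset of the amino acids")
        if all(c <= 0 for c in self.composition.values()):
            raise ValueError("composition must have at least one positive count")
        if any(v < 0 for v in self.concentrations.values()):
            raise ValueError("concentrations must be non-negative")

    @property
    def amino_acids(self) -> tuple[str, ...]:
        return tuple(sorted(self.composition))

    @property
    def n_amino_acids(self) -> int:
        return len(self.composition)


def _aa_exchanges(spec: ToySpec, with_export: bool) -> tuple[list[Metabolite], list[Reaction]]:
    mets = [Metabolite(aa, compartment="cytosol") for aa in spec.amino_acids]
    rxns = []
    for aa in spec.amino_acids:
        rxns.append(
            Reaction(
                id=f"EX_{aa}",
                stoichiometry={aa: 1.0},
                lower_bound=0.0,
                upper_bound=float(spec.concentrations[aa]),
                subsystem="exchange",
            )
        )
        if with_export:
            rxns.append(
                Reaction(
                    id=f"EX_{aa}_out",
                    stoichiometry={aa: -1.0},
                    lower_bound=0.0,
                    upper_bound=UNBOUNDED_CAP,
                    subsystem="exchange",
                )
            )
    return mets, rxns


def _demand_block(spec: ToySpec, muscle_type: str) -> tuple[list[Metabolite], list[Reaction]]:
    demand = DemandRecipe(
        aa_demand={aa: spec.composition[aa] for aa in spec.amino_acids},
        n_chains=spec.n_chains,
        energy_cost_per_bond=spec.energy_cost_per_bond,
    )
    rxn = build_demand_reaction(demand, muscle_type)
    mets = demand_metabolites(demand, muscle_type)
    sink = Reaction(
        id=f"SK_{complex_metabolite_id(muscle_type)}",
        stoichiometry={complex_metabolite_id(muscle_type): -1.0},
        lower_bound=0.0,
        upper_bound=UNBOUNDED_CAP,
        subsystem="demand",
    )
    return mets, [rxn, sink]


def make_assembly_model(spec: ToySpec, muscle_type: str = "type2a") -> StoichiometricModel:
    """Build the minimal assembly network: uptakes + demand + complex sink.

    Requires a pure-assembly spec (no energy pathway, no interconversion,
    zero bond cost) so the optimum keeps its min-ratio closed form.
    """
    if spec.energy_pathway or spec.allow_interconversion or spec.energy_cost_per_bond != 0:
        raise ValueError("assembly models require energy_pathway=False, "
                         "allow_interconversion=False and zero bond cost")
    aa_mets, aa_rxns = _aa_exchanges(spec, with_export=False)
    dm_mets, dm_rxns = _demand_block(spec, muscle_type)
    return StoichiometricModel(
        metabolites=aa_mets + dm_mets,
        reactions=aa_rxns + dm_rxns,
        objective_id=dm_rxns[0].id,
        name=f"assembly_toy_seed{spec.seed}",
    )


def make_muscle_like_model(spec: ToySpec, muscle_type: str = "type2a") -> StoichiometricModel:
    """Assembly network plus lumped energy economy and optional aa routes.

    Adds glucose / palmitate / tetradecanoate uptakes feeding a one-step
    ATP-regeneration reaction each, an NDK reaction converting ATP+GDP to
    ADP+GTP, catabolic routes burning the spec's ``catabolizable`` amino
    acids for ATP, and (optionally) 1:1 interconversion of non-essential
    amino acids through a glutamate hub.
    """
    if not spec.energy_pathway:
        raise ValueError("muscle-like models require energy_pathway=True")
    if spec.energy_cost_per_bond > 0 and (
        spec.glucose_conc <= 0
        and spec.palmitate_conc <= 0
        and spec.tetradecanoate_conc <= 0
        and not any(spec.concentrations.get(aa, 0) > 0 for aa in spec.catabolizable)
    ):
        raise ValueError("energy demanded but no energy source has positive availability")

    aa_mets, aa_rxns = _aa_exchanges(spec, with_export=True)
    dm_mets, dm_rxns = _demand_block(spec, muscle_type)
    mets = aa_mets + dm_mets
    met_ids = {m.id for m in mets}
    for extra in ("atp", "adp", "gtp", "gdp", "pi"):
        if extra not in met_ids:
            mets.append(Metabolite(extra, compartment="cytosol"))
            met_ids.add(extra)

    rxns = aa_rxns + dm_rxns
    fuels = (
        ("glucose", spec.glucose_conc, GLUCOSE_ATP_YIELD),
        ("palmitate", spec.palmitate_conc, PALMITATE_ATP_YIELD),
        ("tetradecanoate", spec.tetradecanoate_conc, TETRADECANOATE_ATP_YIELD),
    )
    for fuel, conc, atp_yield in fuels:
        mets.append(Metabolite(fuel, compartment="cytosol"))
        rxns.append(
            Reaction(
                id=f"EX_{fuel}",
                stoichiometry={fuel: 1.0},
                upper_bound=float(conc),
                subsystem="exchange",
            )
        )
        rxns.append(
            Reaction(
                id=f"CAT_{fuel}",
                stoichiometry={fuel: -1.0, "adp": -atp_yield, "pi": -atp_yield, "atp": atp_yield},
                subsystem="energy",
            )
        )
    rxns.append(
        Reaction(
            id="NDK",
            stoichiometry={"atp": -1.0, "gdp": -1.0, "adp": 1.0, "gtp": 1.0},
            subsystem="energy",
            name="nucleoside-diphosphate kinase",
        )
    )
    for aa, atp_yield in sorted(spec.catabolizable.items()):
        if aa not in spec.composition:
            continue
        rxns.append(
            Reaction(
                id=f"CAT_{aa}",
                stoichiometry={aa: -1.0, "adp": -atp_yield, "pi": -atp_yield, "atp": atp_yield},
                subsystem="aa-catabolism",
            )
        )
    if spec.allow_interconversion:
        nonessential = [aa for aa in spec.amino_acids if aa not in spec.essential_set]
        hub = "glutamate" if "glutamate" in nonessential else (nonessential[0] if nonessential else None)
        if hub is not None:
            for aa in nonessential:
                if aa == hub:
                    continue
                rxns.append(
                    Reaction(
                        id=f"CONV_{hub}_{aa}",
                        stoichiometry={hub: -1.0, aa: 1.0},
                        subsystem="aa-interconversion",
                    )
                )
                rxns.append(
                    Reaction(
                        id=f"CONV_{aa}_{hub}",
                        stoichiometry={aa: -1.0, hub: 1.0},
                        subsystem="aa-interconversion",
                    )
                )
    return StoichiometricModel(
        metabolites=mets,
        reactions=rxns,
        objective_id=dm_rxns[0].id,
        name=f"muscle_toy_seed{spec.seed}",
    )


def closed_form_optimum(spec: ToySpec) -> float:
    """Analytic optimum of an assembly model: min concentration/residues."""
    if spec.energy_pathway or spec.allow_interconversion or spec.energy_cost_per_bond != 0:
        raise ValueError("closed form only holds for pure assembly specs")
    ratios = [
        spec.concentrations[aa] / spec.composition[aa]
        for aa in spec.amino_acids
        if spec.composition[aa] > 0
    ]
    return min(ratios)


def bottleneck_amino_acid(spec: ToySpec) -> str:
    """The amino acid attaining the min availability/need ratio (lexicographic ties)."""
    candidates = [aa for aa in spec.amino_acids if spec.composition[aa] > 0]
    return min(candidates, key=lambda aa: (spec.concentrations[aa] / spec.composition[aa], aa))


def toy_condition(spec: ToySpec) -> Condition:
    """Condition profile matching a toy spec's generator concentrations."""
    bounds = {aa: float(spec.concentrations[aa]) for aa in spec.amino_acids}
    if spec.energy_pathway:
        bounds["glucose"] = float(spec.glucose_conc)
        bounds["palmitate"] = float(spec.palmitate_conc)
        bounds["tetradecanoate"] = float(spec.tetradecanoate_conc)
    return Condition(name=f"toy_seed{spec.seed}", uptake_bounds=bounds)


def random_assembly_spec(
    seed: int, n_amino_acids: int = 6, unique_bottleneck: bool = True
) -> ToySpec:
    """Draw a random assembly spec over a subset of the canonical amino acids.

    Residue counts are uniform on 1..8 and concentrations log-uniform over
    roughly the physiological plasma range.  With ``unique_bottleneck`` the
    limiting amino acid's availability/need ratio is separated from the
    runner-up by at least 5%, so sweep-recovery tests are unambiguous.
    """
    rng = np.random.default_rng(seed)
    aas = sorted(rng.choice(AMINO_ACIDS, size=n_amino_acids, replace=False))
    counts = {aa: int(rng.integers(1, 9)) for aa in aas}
    conc = {aa: float(np.exp(rng.uniform(np.log(0.02), np.log(0.6)))) for aa in aas}
    spec = ToySpec(
        composition=counts,
        concentrations=conc,
        essential_set=frozenset(aa for aa in aas if aa in ESSENTIAL),
        seed=seed,
    )
    if unique_bottleneck:
        ratios = sorted(conc[aa] / counts[aa] for aa in aas)
        if len(ratios) > 1 and ratios[1] < ratios[0] * 1.05:
            bn = bottleneck_amino_acid(spec)
            conc = dict(conc)
            conc[bn] = ratios[1] * 0.9 * counts[bn]  # pull the winner clear
            spec = replace(spec, concentrations=conc)
    return spec


def reference_muscle_spec(
    condition: Condition | None = None,
    compositions: dict[str, ProteinComposition] | None = None,
    muscle_type: str = "type2a",
    allow_interconversion: bool = True,
    energy_cost_per_bond: float = 4.0,
) -> ToySpec:
    """The package's reference miniature muscle model spec.

    Amino-acid demand is one contractile complex of the requested fiber
    type (bundled synthetic compositions by default); uptake concentrations
    are the plasma profile of ``condition`` (fasting by default); the
    catabolizable set and yields are :data:`MUSCLE_CATABOLIC_ATP_YIELD`.
    """
    if condition is None:
        condition = fasting_condition()
    if compositions is None:
        from .proteins import load_reference_compositions

        compositions = load_reference_compositions()
    need = per_complex_need(muscle_type, compositions)
    recipe = canonical_recipe(muscle_type)
    conc = {aa: condition.uptake_bounds[aa] for aa in AMINO_ACIDS}
    return ToySpec(
        composition=need,
        concentrations=conc,
        essential_set=frozenset(ESSENTIAL),
        allow_interconversion=allow_interconversion,
        energy_pathway=True,
        energy_cost_per_bond=energy_cost_per_bond,
        n_chains=recipe.n_chains,
        glucose_conc=condition.uptake_bounds.get("glucose", 5.0),
        palmitate_conc=condition.uptake_bounds.get("palmitate", 0.125),
        tetradecanoate_conc=condition.uptake_bounds.get("tetradecanoate", 0.230),
        catabolizable=dict(MUSCLE_CATABOLIC_ATP_YIELD),
        seed=0,
    )


# ---------------------------------------------------------------------------
# synthetic composition table (stand-in for curated sequence records)

#: Average vertebrate proteome amino-acid frequencies (normalised at use).
_MEAN_AA_FREQ = {
    "alanine": 0.083, "arginine": 0.055, "asparagine": 0.040, "aspartate": 0.054,
    "cysteine": 0.014, "glutamate": 0.068, "glutamine": 0.039, "glycine": 0.071,
    "histidine": 0.023, "isoleucine": 0.060, "leucine": 0.097, "lysine": 0.058,
    "methionine": 0.024, "phenylalanine": 0.039, "proline": 0.047, "serine": 0.066,
    "threonine": 0.053, "tryptophan": 0.011, "tyrosine": 0.029, "valine": 0.069,
}

#: Chain lengths (residues) matching the real contractile proteins.
_CHAIN_LENGTHS = {
    "actin": 375,
    "myosin_heavy_chain_1_2x": 1939,
    "myosin_heavy_chain_2a": 1935,
    "myosin_heavy_chain_2b": 1937,
    "myosin_light_chain_kinase": 596,
    "myosin_light_chain_phosphorylatable": 169,
    "tropomyosin_1": 284,
    "tropomyosin_2": 284,
    "troponin_c_1": 161,
    "troponin_c_2": 160,
    "troponin_i_1": 187,
    "troponin_i_2": 182,
    "troponin_t_1": 262,
    "troponin_t_2": 288,
}


def synthetic_composition_table(seed: int = 20130805) -> dict[str, ProteinComposition]:
    """Generate the synthetic stand-in composition set deterministically.

    Residue counts are multinomial around average vertebrate frequencies
    (±10% per-protein jitter) at realistic chain lengths.  These are
    *synthetic* compositions: structurally faithful (chain identities,
    lengths, frequency profile) but not taken from sequence databases.
    """
    rng = np.random.default_rng(seed)
    freqs = np.array([_MEAN_AA_FREQ[aa] for aa in AMINO_ACIDS])
    out: dict[str, ProteinComposition] = {}
    for pid in sorted(_CHAIN_LENGTHS):
        length = _CHAIN_LENGTHS[pid]
        jitter = freqs * rng.uniform(0.9, 1.1, size=len(freqs))
        p = jitter / jitter.sum()
        draw = rng.multinomial(length, p)
        counts = {aa: int(c) for aa, c in zip(AMINO_ACIDS, draw)}
        out[pid] = ProteinComposition(protein_id=pid, counts=counts)
    return out
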