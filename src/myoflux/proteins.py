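"""Contractile-protein-complex demand construction.

The objective of the muscle model is synthesis of the sarcomeric
contractile complex: 7 actin : 7 myosin : 1 tropomyosin dimer : 1 troponin
complex.  Each myosin unit expands to a fiber-type-specific heavy chain
plus a light chain kinase and a phosphorylatable light chain; the
tropomyosin dimer is two chains of the type-appropriate isoform; the
troponin complex contributes its C, I and T subunits once each.  Given
per-protein residue counts, this module sums the amino-acid demand of one
complex and emits the irreversible demand reaction that consumes the
amino acids plus the ATP/GTP cost of peptide-bond formation and produces
one unit of the complex pseudo-metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .aminoacids import AMINO_ACIDS, ONE_LETTER
from .model import Metabolite, Reaction

__all__ = [
    "MUSCLE_TYPES",
    "ProteinComposition",
    "ComplexRecipe",
    "DemandRecipe",
    "canonical_recipe",
    "complex_aa_demand",
    "per_complex_need",
    "make_demand_recipe",
    "build_demand_reaction",
    "read_composition_tsv",
    "read_composition_fasta",
    "load_reference_compositions",
    "complex_metabolite_id",
]

MUSCLE_TYPES = ("type1", "type2a", "type2x", "type2b")

#: Default peptide-bond energy cost in ATP-equivalents: 2 ATP for amino-acid
#: activation plus 2 GTP for ribosomal elongation per bond.
DEFAULT_ENERGY_COST_PER_BOND = 4.0


@dataclass(frozen=True)
class ProteinComposition:
    """Residue counts of one protein over the 20 canonical amino acids."""

    protein_id: str
    counts: dict[str, int] = field(hash=False)

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.counts)
        extra = set(self.counts) - set(AMINO_ACIDS)
        if missing or extra:
            raise ValueError(
                f"composition {self.protein_id!r}: must key exactly the 20 canonical "
                f"amino acids (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if any(c < 0 or int(c) != c for c in self.counts.values()):
            raise ValueError(f"composition {self.protein_id!r}: counts must be non-negative integers")
        if sum(self.counts.values()) < 1:
            raise ValueError(f"composition {self.protein_id!r}: total residues must be >= 1")

    @property
    def length(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class ComplexRecipe:
    """Chain-level composition of one fiber type's contractile complex.

    ``components`` lists ``(protein_id, multiplicity)`` pairs; every entry is
    a single polypeptide chain, so the sum of multiplicities is the chain
    count used for the peptide-bond tally.
    """

    muscle_type: str
    components: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        if self.muscle_type not in MUSCLE_TYPES:
            raise ValueError(f"muscle_type must be one of {MUSCLE_TYPES}")
        if any(mult < 1 for _, mult in self.components):
            raise ValueError("multiplicities must be positive integers")

    @property
    def n_chains(self) -> int:
        return sum(mult for _, mult in self.components)


def _heavy_chain_id(muscle_type: str) -> str:
    # type 1 and type 2x share a heavy-chain isoform group; 2a and 2b differ
    return {
        "type1": "myosin_heavy_chain_1_2x",
        "type2x": "myosin_heavy_chain_1_2x",
        "type2a": "myosin_heavy_chain_2a",
        "type2b": "myosin_heavy_chain_2b",
    }[muscle_type]


def _isoform_group(muscle_type: str) -> str:
    return "1" if muscle_type == "type1" else "2"


def canonical_recipe(muscle_type: str) -> ComplexRecipe:
    """The 7:7:1:1 contractile complex recipe, expanded to chains."""
    if muscle_type not in MUSCLE_TYPES:
        raise ValueError(f"muscle_type must be one of {MUSCLE_TYPES}")
    grp = _isoform_group(muscle_type)
    return ComplexRecipe(
        muscle_type=muscle_type,
        components=(
            ("actin", 7),
            (_heavy_chain_id(muscle_type), 7),
            ("myosin_light_chain_kinase", 7),
            ("myosin_light_chain_phosphorylatable", 7),
            (f"tropomyosin_{grp}", 2),  # dimer = two chains of the isoform
            (f"troponin_c_{grp}", 1),
            (f"troponin_i_{grp}", 1),
            (f"troponin_t_{grp}", 1),
        ),
    )


def complex_aa_demand(
    recipe: ComplexRecipe, compositions: dict[str, ProteinComposition]
) -> dict[str, int]:
    """Total residues of each amino acid consumed by one complex.

    ``demand(aa) = sum over components of multiplicity * counts(aa)``.
    """
    demand = {aa: 0 for aa in AMINO_ACIDS}
    for pid, mult in recipe.components:
        if pid not in compositions:
            raise KeyError(f"no composition for protein {pid!r} required by recipe")
        for aa, cnt in compositions[pid].counts.items():
            demand[aa] += mult * cnt
    if sum(demand.values()) <= 0:
        raise ValueError("recipe yields zero total residue demand")
    return demand


def per_complex_need(
    muscle_type: str, compositions: dict[str, ProteinComposition]
) -> dict[str, int]:
    """Amino acids needed per complex for the canonical recipe (effect-analysis input)."""
    return complex_aa_demand(canonical_recipe(muscle_type), compositions)


@dataclass(frozen=True)
class DemandRecipe:
    """Aggregated demand of one complex plus its polymerisation energy cost."""

    aa_demand: dict[str, int] = field(hash=False)
    n_chains: int = 1
    energy_cost_per_bond: float = DEFAULT_ENERGY_COST_PER_BOND

    def __post_init__(self) -> None:
        if sum(self.aa_demand.values()) <= 0:
            raise ValueError("aa_demand must have positive total")
        if any(c < 0 for c in self.aa_demand.values()):
            raise ValueError("aa_demand entries must be non-negative")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.energy_cost_per_bond < 0:
            raise ValueError("energy_cost_per_bond must be >= 0")

    @property
    def total_residues(self) -> int:
        return int(sum(self.aa_demand.values()))

    @property
    def n_bonds(self) -> int:
        return self.total_residues - self.n_chains

    @property
    def total_energy(self) -> float:
        """ATP-equivalents consumed per complex."""
        return self.energy_cost_per_bond * self.n_bonds


def make_demand_recipe(
    muscle_type: str,
    compositions: dict[str, ProteinComposition],
    energy_cost_per_bond: float = DEFAULT_ENERGY_COST_PER_BOND,
) -> DemandRecipe:
    recipe = canonical_recipe(muscle_type)
    return DemandRecipe(
        aa_demand=complex_aa_demand(recipe, compositions),
        n_chains=recipe.n_chains,
        energy_cost_per_bond=energy_cost_per_bond,
    )


def complex_metabolite_id(muscle_type: str) -> str:
    return f"contractile_complex_{muscle_type}"


def build_demand_reaction(demand: DemandRecipe, muscle_type: str) -> Reaction:
    """Build the irreversible complex-synthesis demand reaction.

    Consumes ``aa_demand`` of each amino acid and, when the per-bond cost is
    positive, splits it half ATP -> ADP and half GTP -> GDP (releasing one Pi
    per hydrolysed nucleotide); produces one unit of the complex
    pseudo-metabolite.
    """
    if muscle_type not in MUSCLE_TYPES:
        raise ValueError(f"muscle_type must be one of {MUSCLE_TYPES}")
    stoich: dict[str, float] = {
        aa: -float(cnt) for aa, cnt in demand.aa_demand.items() if cnt > 0
    }
    if not stoich:
        raise ValueError("demand reaction would consume no amino acids")
    energy = demand.total_energy
    if energy > 0:
        half = energy / 2.0
        stoich["atp"] = stoich.get("atp", 0.0) - half
        stoich["adp"] = stoich.get("adp", 0.0) + half
        stoich["gtp"] = stoich.get("gtp", 0.0) - half
        stoich["gdp"] = stoich.get("gdp", 0.0) + half
        stoich["pi"] = stoich.get("pi", 0.0) + energy
    stoich[complex_metabolite_id(muscle_type)] = 1.0
    return Reaction(
        id=f"DM_{complex_metabolite_id(muscle_type)}",
        stoichiometry=stoich,
        lower_bound=0.0,
        name=f"{muscle_type} contractile complex synthesis",
        subsystem="demand",
    )


def demand_metabolites(demand: DemandRecipe, muscle_type: str) -> list[Metabolite]:
    """Metabolites the demand reaction introduces (complex + energy currency)."""
    mets = [Metabolite(complex_metabolite_id(muscle_type), compartment="cytosol")]
    if demand.total_energy > 0:
        mets += [Metabolite(m, compartment="cytosol") for m in ("atp", "adp", "gtp", "gdp", "pi")]
    return mets


# ---------------------------------------------------------------------------
# composition I/O


def read_composition_tsv(path) -> dict[str, ProteinComposition]:
    """Read a composition table: one row per protein, 20 amino-acid columns."""
    df = pd.read_csv(path, sep="\t")
    if "protein_id" not in df.columns:
        raise ValueError("composition TSV needs a protein_id column")
    out: dict[str, ProteinComposition] = {}
    for _, row in df.iterrows():
        counts = {aa: int(row[aa]) for aa in AMINO_ACIDS}
        pid = str(row["protein_id"])
        out[pid] = ProteinComposition(protein_id=pid, counts=counts)
    return out


def write_composition_tsv(compositions: dict[str, ProteinComposition], path) -> None:
    rows = [
        {"protein_id": pid, **{aa: comp.counts[aa] for aa in AMINO_ACIDS}}
        for pid, comp in compositions.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_composition_fasta(path) -> dict[str, ProteinComposition]:
    """Count residues from protein FASTA records (record id -> protein_id)."""
    from Bio import SeqIO

    out: dict[str, ProteinComposition] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        counts = {aa: 0 for aa in AMINO_ACIDS}
        for letter in str(rec.seq).upper():
            aa = ONE_LETTER.get(letter)
            if aa is None:
                if letter in "*-":
                    continue
                raise ValueError(f"record {rec.id!r}: unknown residue letter {letter!r}")
            counts[aa] += 1
        out[rec.id] = ProteinComposition(protein_id=rec.id, counts=counts)
    return out


def load_reference_compositions() -> dict[str, ProteinComposition]:
    """Load the bundled synthetic stand-in composition table.

    The bundled table is *synthetic*: chain lengths match the real
    contractile proteins but residue counts are drawn from average
    vertebrate amino-acid frequencies, not from curated sequence records.
    """
    ref = resources.files("myoflux.data") / "contractile_compositions_synthetic.tsv"
    with resources.as_file(ref) as path:
        return read_composition_tsv(path)
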