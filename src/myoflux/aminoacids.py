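"""Canonical amino-acid identifiers and essentiality classes.

Amino acids are identified throughout the package by their full lowercase
English names (matching the plasma-profile tables), not by three- or
one-letter codes; codes are mapped only at format boundaries (FASTA input).
"""

from __future__ import annotations

#: The 20 canonical proteinogenic amino acids, lexicographic order.
AMINO_ACIDS: tuple[str, ...] = (
    "alanine",
    "arginine",
    "asparagine",
    "aspartate",
    "cysteine",
    "glutamate",
    "glutamine",
    "glycine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "proline",
    "serine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
)

#: Nutritionally essential amino acids for adult humans.
ESSENTIAL: frozenset[str] = frozenset(
    {
        "histidine",
        "isoleucine",
        "leucine",
        "lysine",
        "methionine",
        "phenylalanine",
        "threonine",
        "tryptophan",
        "valine",
    }
)

#: Conditionally essential (synthesised, but limiting under stress/growth).
CONDITIONALLY_ESSENTIAL: frozenset[str] = frozenset(
    {"arginine", "cysteine", "glutamine", "glycine", "proline", "tyrosine"}
)

#: Branched-chain amino acids, catabolisable for energy in muscle.
BCAA: frozenset[str] = frozenset({"isoleucine", "leucine", "valine"})

ONE_LETTER: dict[str, str] = {
    "A": "alanine",
    "R": "arginine",
    "N": "asparagine",
    "D": "aspartate",
    "C": "cysteine",
    "E": "glutamate",
    "Q": "glutamine",
    "G": "glycine",
    "H": "histidine",
    "I": "isoleucine",
    "L": "leucine",
    "K": "lysine",
    "M": "methionine",
    "F": "phenylalanine",
    "P": "proline",
    "S": "serine",
    "T": "threonine",
    "W": "tryptophan",
    "Y": "tyrosine",
    "V": "valine",
}


def essentiality(aa: str) -> str:
    """Classify an amino acid as ``essential``, ``conditional`` or ``nonessential``."""
    if aa in ESSENTIAL:
        return "essential"
    if aa in CONDITIONALLY_ESSENTIAL:
        return "conditional"
    if aa in AMINO_ACIDS:
        return "nonessential"
    raise KeyError(f"unknown amino acid id: {aa!r}")
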