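"""Expected vs actual supplementation effect.

The *expected* effect ranks amino acids by availability minus need: how
many complexes' worth of each amino acid the plasma supplies (concentration
divided by the control synthesis flux) minus the residues one complex
needs.  The most negative difference is rank 1 — the amino acid expected
to be most limiting.  The *actual* effect ranks amino acids by when they
first enter a best-per-size subset of the supplementation sweep.  Networks
with catabolic or biosynthetic amino-acid routes can make the two rankings
diverge; in a pure-assembly network they provably coincide at the top.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .aminoacids import AMINO_ACIDS, essentiality
from .conditions import Condition
from .supplementation import SweepOutcome, best_per_size

__all__ = [
    "EffectRow",
    "availability_counts",
    "expected_effect",
    "actual_effect",
    "compare_expected_actual",
]


@dataclass(frozen=True)
class EffectRow:
    """One amino acid's availability-vs-need record."""

    amino_acid: str
    needed: int
    available: float
    difference: float  # available - needed; most negative = most limiting
    expected_rank: int
    tie: bool = False


def availability_counts(condition: Condition, control_flux: float) -> dict[str, float]:
    """Complexes' worth of each amino acid the plasma profile can supply.

    ``available(aa) = concentration(aa) / control_flux`` — dimensionless
    because concentration doubles as the uptake flux bound.
    """
    if control_flux <= 0:
        raise ValueError(f"control_flux must be positive, got {control_flux}")
    return {
        aa: condition.uptake_bounds[aa] / control_flux
        for aa in AMINO_ACIDS
        if aa in condition.uptake_bounds
    }


def expected_effect(needed: dict[str, int], available: dict[str, float]) -> list[EffectRow]:
    """Rank amino acids by (available - needed), ascending.

    Rank 1 is the strongest expected supplementation effect.  Exact-tie
    groups are ordered lexicographically and flagged.
    """
    if set(needed) != set(available):
        raise ValueError(
            f"key mismatch between needed and available: {sorted(set(needed) ^ set(available))}"
        )
    diffs = {aa: available[aa] - needed[aa] for aa in needed}
    ordered = sorted(diffs, key=lambda aa: (diffs[aa], aa))
    tied = {
        aa
        for aa in diffs
        if sum(1 for other in diffs if diffs[other] == diffs[aa]) > 1
    }
    return [
        EffectRow(
            amino_acid=aa,
            needed=int(needed[aa]),
            available=float(available[aa]),
            difference=float(diffs[aa]),
            expected_rank=rank,
            tie=aa in tied,
        )
        for rank, aa in enumerate(ordered, start=1)
    ]


def actual_effect(outcome: SweepOutcome) -> dict[str, int | None]:
    """Rank amino acids by first appearance in a best-per-size subset.

    An amino acid entering the best subset at a smaller size ranks ahead;
    ties (entering at the same size) are broken lexicographically.  Amino
    acids never appearing in any best subset are unranked (``None``).
    Only improving best subsets count: if no subset beats control the
    sweep identified no effective supplement.
    """
    if not outcome.results:
        raise ValueError("empty sweep results")
    table = best_per_size(outcome)
    first_size: dict[str, int] = {}
    for _, row in table.iterrows():
        if not row["improved"]:
            continue
        for aa in row["subset"]:
            first_size.setdefault(aa, int(row["size"]))
    ordered = sorted(first_size, key=lambda aa: (first_size[aa], aa))
    ranks: dict[str, int | None] = {aa: None for aa in AMINO_ACIDS}
    for rank, aa in enumerate(ordered, start=1):
        ranks[aa] = rank
    return ranks


def compare_expected_actual(
    expected: list[EffectRow], actual: dict[str, int | None]
) -> pd.DataFrame:
    """Concordance table of expected vs actual ranks.

    ``rank_shift = expected_rank - actual_rank`` (positive: the sweep found
    the amino acid more effective than availability alone predicts).  The
    frame's ``attrs['footrule']`` carries the Spearman-footrule distance
    ``sum |expected - actual|`` over the amino acids ranked by both, after
    restricting the expected ranking to those amino acids (so identical
    orderings give 0 and a reversed ordering of n items gives the maximal
    footrule).
    """
    rows = []
    for row in expected:
        act = actual.get(row.amino_acid)
        rows.append(
            {
                "amino_acid": row.amino_acid,
                "essentiality": essentiality(row.amino_acid),
                "needed": row.needed,
                "available": row.available,
                "difference": row.difference,
                "expected_rank": row.expected_rank,
                "actual_rank": act,
                "rank_shift": (row.expected_rank - act) if act is not None else None,
            }
        )
    df = pd.DataFrame(rows).sort_values("expected_rank").reset_index(drop=True)

    ranked = [r for r in rows if r["actual_rank"] is not None]
    # re-rank expected among the commonly ranked amino acids so both
    # rankings live on 1..n before taking the footrule
    ranked.sort(key=lambda r: r["expected_rank"])
    footrule = sum(
        abs((i + 1) - r["actual_rank"]) for i, r in enumerate(ranked)
    )
    df.attrs["footrule"] = int(footrule)
    df.attrs["n_common"] = len(ranked)
    return df


def export_effect_tsv(df: pd.DataFrame, path) -> None:
    """Effect table TSV (needed, available, difference, expected/actual rank).

    Header comments declare the ranking conventions so downstream readers
    need not guess.
    """
    with open(path, "w") as fh:
        fh.write("# expected rank: ascending (available - needed); rank 1 most limiting\n")
        fh.write("# actual rank: first appearance in an improving best-per-size subset\n")
        fh.write(f"# footrule distance over commonly ranked amino acids: {df.attrs.get('footrule')}\n")
        df.to_csv(fh, sep="\t", index=False)
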