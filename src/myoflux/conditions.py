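"""Plasma condition profiles used as uptake bounds.

Uptake of each nutrient is assumed proportional to its plasma
concentration, so a condition is a map from exchanged metabolite to a
non-negative concentration (mmol/L) applied directly as the uptake flux
upper bound.  Two canonical profiles ship with the package: overnight
fasting and post-absorptive (~2 h after a protein meal); standard
deviations are recorded in the data file but only the means are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .aminoacids import AMINO_ACIDS

__all__ = ["Condition", "fasting_condition", "post_absorptive_condition", "load_conditions_tsv"]

#: Non-amino-acid nutrients every canonical profile carries.
CARBON_SOURCES = ("glucose", "palmitate", "tetradecanoate")


@dataclass(frozen=True)
class Condition:
    """A named uptake-bound profile."""

    name: str
    uptake_bounds: dict[str, float] = field(hash=False)

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.uptake_bounds.values()):
            raise ValueError(f"condition {self.name!r}: uptake bounds must be non-negative")

    def require_canonical(self) -> None:
        """Check the profile covers the carbon sources and all 20 amino acids."""
        needed = set(CARBON_SOURCES) | set(AMINO_ACIDS)
        missing = needed - set(self.uptake_bounds)
        if missing:
            raise ValueError(f"condition {self.name!r} missing metabolites: {sorted(missing)}")

    def amino_acid_bounds(self) -> dict[str, float]:
        return {aa: self.uptake_bounds[aa] for aa in AMINO_ACIDS if aa in self.uptake_bounds}


def _profile_table() -> pd.DataFrame:
    ref = resources.files("myoflux.data") / "plasma_conditions.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", index_col="metabolite")


def load_conditions_tsv(path) -> dict[str, Condition]:
    """Load condition profiles from a TSV with one ``*_mean`` column per state."""
    df = pd.read_csv(path, sep="\t", index_col="metabolite")
    out = {}
    for col in df.columns:
        if not col.endswith("_mean"):
            continue
        name = col[: -len("_mean")]
        out[name] = Condition(name=name, uptake_bounds=df[col].astype(float).to_dict())
    return out


def fasting_condition() -> Condition:
    """Overnight-fast plasma profile (canonical control)."""
    df = _profile_table()
    cond = Condition(name="fasting", uptake_bounds=df["fasting_mean"].astype(float).to_dict())
    cond.require_canonical()
    return cond


def post_absorptive_condition() -> Condition:
    """Plasma profile ~2 h after a 200 g protein meal."""
    df = _profile_table()
    cond = Condition(
        name="post_absorptive", uptake_bounds=df["post_absorptive_mean"].astype(float).to_dict()
    )
    cond.require_canonical()
    return cond
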