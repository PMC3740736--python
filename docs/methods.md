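# Methods

## Model and optimisation

A model is an ordered list of metabolites (compartments: extracellular,
cytosol, mitochondrion) and reactions with signed stoichiometric
coefficients and flux bounds. The steady-state assumption `S·v = 0` plus
box bounds defines a polytope; the objective is the flux of a single
demand reaction (no weighted multi-reaction objectives). The LP is solved
with scipy's HiGHS backend at a solver tolerance of 1e-9; reported optima
are accepted when the residual `|S·v|∞` and bound violations are within
1e-6. Only the optimal objective *value* is contract-guaranteed: the flux
vector of a degenerate LP is solver-dependent, and solutions whose number
of strictly interior fluxes exceeds `rank(S)` carry a `degenerate_warning`
flag. `flux_difference` therefore compares objective-relevant summaries,
not bit-exact flux maps.

Degrees of freedom are defined as `n_metabolites − rank(S)` — the
dimension of the left null space, i.e. the number of conserved metabolite
pools. Numerical rank uses the standard cutoff
`max(m, n) · eps · σ_max`, overridable via `model_stats(tol=...)`.

## SBML exchange

Files are read at Level 2 or 3. Bounds are taken from fbc flux-bound
parameters when present, else from kinetic-law parameters named
`LOWER_BOUND`/`UPPER_BOUND`; a bare `reversible` flag maps to
`(−99999, +99999)` and irreversible to `(0, +99999)`. 99999 is the
package-wide stand-in for an unlimited flux; time units are deliberately
undefined (concentrations double as flux bounds, so all fluxes share one
arbitrary time unit). Species with missing or unrecognised compartments
are assigned to the cytosol with a warning. Output is Level 3 + fbc v2,
which round-trips bounds and the objective; round-trip identity on
`ModelStats` and on the stoichiometry matrix (up to row/column reorder) is
tested.

## Contractile-complex demand

The demand reaction for fiber type *t* consumes the summed residue counts
of 7 actin + 7 myosin (heavy chain specific to 1/2x, 2a or 2b, plus light
chain kinase and phosphorylatable light chain) + 1 tropomyosin dimer (two
chains of the type isoform) + 1 troponin complex (C, I, T once each) —
33 chains in total — and produces one unit of the complex
pseudo-metabolite. Peptide-bond energy defaults to 4 ATP-equivalents per
bond (2 ATP for amino-acid activation, 2 GTP for elongation), applied to
`total residues − number of chains` bonds and split half ATP→ADP, half
GTP→GDP, releasing one Pi per hydrolysed nucleotide. A general per-bond
cost `c` splits `c/2`/`c/2`. When a curated SBML network is loaded its own
demand stoichiometry is used as-is; the builder serves generated models
and user-supplied composition tables.

The bundled composition table
(`data/contractile_compositions_synthetic.tsv`) is a **synthetic
stand-in**: chain identities and lengths match the real contractile
proteins (actin 375 aa, heavy chains ~1.94 kaa, tropomyosin 284 aa, …) but
residue counts are multinomial draws around average vertebrate amino-acid
frequencies with ±10% per-protein jitter, generated deterministically by
`synthetic_composition_table(seed=20130805)`. It is not a curated sequence
digest, and conclusions about *which* amino acid limits synthesis in the
bundled reference model (isoleucine under fasting) reflect these synthetic
counts, not biology.

## Conditions and supplementation

A condition maps exchanged metabolites to non-negative plasma
concentrations (mmol/L) applied directly as uptake upper bounds — the
proportional-uptake assumption. Two canonical profiles ship with the
package (fasting; post-absorptive ≈2 h after a protein meal); standard
deviations are recorded in the data file but only means are applied.
Uptake exchanges are written extracellular→cytosol with uptake positive
and `lb = 0`; a paired `_out` export reaction allows secretion (muscle
exports glutamine, for example) up to the unlimited cap. Oxygen-, water-
and waste-like exchanges in generated models are implicit in the lumped
energy reactions.

`supplement` raises the chosen amino acids' uptake bounds to the cap on a
copy; it is idempotent and commutes over subsets (tested). The sweep
enumerates subsets of size 1..k_max (default 7; the subset count grows
steeply beyond that) over the amino acids that have uptake reactions,
re-solving a pre-assembled LP with per-subset bound edits. With
`prune=True` the optimum under relaxing *all* amino acids is a proven
upper bound; when it shows no improvement is possible the per-subset
solves are skipped and objectives are reported at the control value (the
bound pins them there), leaving best-per-size output identical to
exhaustive enumeration — pruning never changes results, only cost.
Best-per-size ties within 1e-9 are broken lexicographically on sorted
amino-acid names and flagged. `improved` means
`objective > control + 1e-9`.

## Expected vs actual effect

`available(aa) = concentration(aa) / control_flux` (dimensionless
complexes' worth); `difference = available − needed`; ascending rank, most
negative first, lexicographic tie-break with a tie flag. The *actual*
ranking orders amino acids by the smallest size at which they first appear
in an **improving** best-per-size subset (then lexicographically); amino
acids never appearing are unranked. This first-appearance rule is the
package's chosen formalisation of "effective from single to 7-way
combinations" and is declared in the exported table header. Concordance is
summarised by the Spearman footrule `Σ|expected − actual|` after
restricting the expected ranking to the commonly ranked amino acids. All
20 amino acids are ranked and tagged essential/conditional/non-essential
so an essential-only view can be extracted. Fasting is the default
condition for effect analysis.

## Synthetic models

*Assembly* models contain only amino-acid uptakes (ub = concentration), a
zero-energy demand reaction, and a complex sink; their optimum is exactly
`min_aa concentration(aa)/residues(aa)`, which anchors the solver tests.
*Muscle-like* models add: one-step fuel catabolism (glucose → 30 ATP,
palmitate → 106, tetradecanoate → 92, regenerating ATP from ADP+Pi),
a nucleoside-diphosphate kinase (ATP + GDP → ADP + GTP) supplying the
elongation GTP, per-amino-acid catabolic routes (aa + y·ADP + y·Pi →
y·ATP, with lumped yields such as 40 for leucine/isoleucine), and optional
1:1 interconversion of non-essential amino acids through a glutamate hub.
These reproduce, in miniature, the features the analysis depends on:
energy coupling of protein synthesis, amino acids as fuel, and
biosynthetic shortcuts. They do **not** emulate compartmentalised
transport, cofactor balancing beyond the adenylate/guanylate cycle,
carbon-correct catabolism (yields are lumped integers, and interconversion
is 1:1 regardless of carbon count), or regulation. Passing tests
therefore demonstrate correctness of the optimisation, sweep and ranking
machinery — not quantitative fidelity to muscle physiology.

The *reference muscle model* is `make_muscle_like_model(reference_muscle_spec())`:
type 2a complex demand from the bundled compositions (~31,800 residues,
33 chains, 4 ATP-equivalents/bond), uptake bounds from the bundled plasma
profiles, the muscle catabolizable set, interconversion on. It has 29
metabolites and 81 reactions — deliberately small enough that the full
k≤4 sweep (6,195 LPs per condition) runs in seconds.

## Numerical and design choices

- Solver tolerance 1e-9, acceptance tolerance 1e-6, improvement threshold
  1e-9, tie tolerance 1e-9.
- The vertex-enumeration oracle enumerates all candidate bases (pinning
  `n − rank(S)` variables at bounds) and refuses models with more than 10
  reactions; it exists purely as an independent check on the LP.
- Generated models sort amino-acid ids lexicographically; SBML readers
  preserve file order, so matrix layouts are reproducible in both paths.
- Random toy specs separate the bottleneck's availability/need ratio from
  the runner-up by ≥5% so recovery tests are unambiguous; all generators
  are deterministic given their seed.
- Degenerate inputs: empty stoichiometries, inverted bounds, dangling or
  orphan metabolites and id collisions are reported by `validate_model`;
  matrix assembly refuses models with structural (non-warning) defects.

## Problem sizes used in the shipped checks

Property suite: 20 vertex-oracle fixtures (≤10 reactions), 100 seeded
assembly specs for the closed form, 1,000 relaxation-monotonicity trials,
20 bottleneck-recovery sweeps, 20 concordance toys. Reference-model
analysis: sweep depth k≤3 in the test suite, k≤4 in the reproduction
script. These sizes were chosen so the entire suite solves a few thousand
small LPs — large enough to exercise every code path and tight statistical
property, small enough to run interactively.

## Known limitations

- The published 374-reaction muscle network is journal supplementary
  material and is not redistributed here; when available it can be dropped
  at `data/muscle_model.xml` and is then used directly by the acceptance
  tests. Without it, quantitative printed values (control optimum
  2.18×10⁻⁵, etc.) cannot be reproduced, only the method's structural and
  analytical properties.
- Flux *vectors* at degenerate optima are not reproducible across solvers;
  only objective values are comparable.
- The sweep is exhaustive; k beyond 7 is possible via `k_max` but the
  subset count (C(20, k)) grows quickly.
- Whether supplementation effects are equal across fiber types is left as
  a question the user can examine by switching `muscle_type`; the package
  does not assert it.
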