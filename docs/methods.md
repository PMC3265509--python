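# Methods

## The model

A metabolic network is a set of reactions `j` with stoichiometric
coefficients `S_ij` over metabolites `i`, flux bounds
`lb_j ≤ v_j ≤ ub_j` (mmol·gDW⁻¹·h⁻¹), and a distinguished biomass
pseudo-reaction that drains precursor metabolites in fixed proportions.
Flux balance analysis solves

```
max  v_biomass
s.t. S v = 0          (steady state over non-boundary metabolites)
     lb ≤ v ≤ ub
```

Boundary species (flagged in SBML, or carrying the `_b` suffix) are
excluded from the mass balance, so exchange reactions are single-ended:
their lower bound is the maximum uptake rate of the corresponding
external metabolite, their upper bound the secretion allowance.  A
medium is therefore nothing but a map from exchange reactions to bound
pairs; exchanges not listed default to secretion-only `(0, +∞)`.
"Unconstrained" is encoded as the large finite value `1e6`, the usual
convention of genome-scale reconstructions (configurable via
`UNBOUNDED_FLUX`).

Assumptions inherited from standard FBA: steady state (no metabolite
accumulation), a linear objective that equates fitness with biomass
yield, and no kinetic, thermodynamic or regulatory constraints.  Only
the optimal *objective value* is contractual: genome-scale LPs are
massively degenerate, so the returned flux vector is one optimum among
many, and every downstream statistic in this package is a function of
objective values only.  Flux reports label themselves accordingly.

## Gene–protein–reaction logic

GPR rules are boolean trees over gene identifiers: AND for the subunits
of an enzyme complex (all required), OR for isozymes (any one
suffices).  A reaction with no gene assignment carries the constant-true
rule — it can never be disabled by a gene deletion, though it remains a
removal candidate in reductive simulations.  Gene knockouts clamp to
zero the bounds of every reaction whose GPR evaluates false with the
knocked-out genes unavailable.  Two consequences worth noting:

* GPR evaluation is **not modular**: an isozyme pair disables its
  reaction only jointly, so double-knockout scans recompute the disabled
  reaction set per pair rather than uniting single-knockout sets.
* Isozyme counting normalises GPRs to disjunctive normal form with
  absorption, so `(g1 and g2) or g1` counts one enzyme, not two.

## Ancestral → extant derivation

Given a status table (`functional | pseudogene | deleted`), pseudogenes
and deleted genes are switched off permanently.  Reactions whose GPR
becomes unsatisfiable are removed from the network (not merely
constrained); surviving GPRs are partially evaluated so that their
leaves reference functional genes only.  Orphan pruning then drops genes
appearing in no GPR and metabolites used by no reaction — this is the
step that removes still-functional genes whose only role was as complex
partners of a pseudogenised subunit.  A status table that disables the
biomass reaction itself is rejected as degenerate input.

## Knockout robustness

Two essentiality criteria coexist in the robustness literature and both
are computed:

* **lethal**: knockout growth ≤ 1e-9 absolute — "growth rate of zero";
* **essential_99**: knockout growth < 1 % of wild type.

Lethal is a subset of essential_99 whenever the wild type grows.  The
1 % threshold follows the reading consistent with fraction-of-essential-
genes summaries: a gene is essential iff its knockout retains less than
1 % of *wild-type* biomass production.  Synthetic-lethal enumeration is
restricted to pairs of singly non-lethal genes (to avoid masking by
single-gene essentiality) and tests all n·(n−1)/2 unordered pairs,
caching LP solves by disabled-reaction set.

Robustness scans are run on the glucose + L-arginine aerobic medium.
For an extant network that can no longer synthesise a biomass component,
the corresponding biomass edit (e.g. removing the storage
polysaccharide) is applied first; the edit is exposed as a CLI flag so
both biomass variants are runnable.

## Reductive-evolution simulation

One run: draw a uniformly random permutation (Fisher–Yates, via
`numpy.random.Generator.permutation`) of the removable reactions, visit
each exactly once, tentatively clamp it to zero flux, and make the
removal permanent iff the reduced network's biomass rate stays strictly
above `cutoff × B₀ + 1e-9`, where `B₀` is the wild-type rate of the
*original* network — the baseline never moves during a run.  Genes are
retained iff they appear in at least one retained reaction's GPR, making
gene sets a pure function of reaction sets.

Minimality is guaranteed, not sampled: LP optima are monotone under
added constraints, so a reaction kept at its turn (its removal then
dropped growth to ≤ the cutoff) can only drop growth further if removed
from the smaller final network.  `audit_minimality` re-deletes every
retained internal reaction and verifies this; the test suite audits
every ensemble member it generates.

Removal candidates are internal reactions only (including
gene-associated transporters, excluding the biomass equation): the
environment is fixed per condition, and the biomass reaction is the
fitness proxy itself.  Cutoffs default to 0.1, 0.05 and 0.01 of `B₀`
with 500 replicates per cutoff in full-scale runs; the acceptance script
uses 50 replicates per cutoff, and the test suite 6–10, which are the
ensemble sizes this package adopts for its routine checks.  Pooled
statistics aggregate all cutoffs, mirroring the "total" column of
ensemble-statistics tables.

Randomness: the master seed plus the (cutoff index, replicate index)
pair form a `numpy.random.SeedSequence` spawn key, so ensembles are
bitwise reproducible per seed, replicates are independent, and results
do not depend on execution order.

Cross-condition classification compares two ensembles over the same
network: **always essential** = core (present in every minimal network)
under both media; **conditionally essential** = core under the
nutrient-limited medium only — the candidates for future loss in a rich
host environment; **disposable** = absent from every minimal network
under both.

## The synthetic study system

`make_toy_cell` builds a ~30-reaction cell with the structural features
the analysis depends on: an isozyme pair and a two-subunit complex (counts
configurable), a branch point where biosynthetic drains on oxaloacetate
must be replenished anaplerotically (PEP-carboxylase analogue, optional
glyoxylate-bypass analogue), a storage-polysaccharide biomass component,
and an arginine → polyamine → TCA-intermediate salvage route.  Its three
reference media (glucose-only, glucose + arginine, rich with four organic
nutrients) use uptake bounds of 6 mmol·gDW⁻¹·h⁻¹ for organics and
20 for oxygen, the conventional minimal-aerobic-medium bounds of
enterobacterial reconstructions; ammonium and CO₂ stand in for the full
inorganic set.  Stoichiometries are small integers and biomass
coefficients are 1 — the generator emulates network *topology*, not
elemental balancing, realistic yields, or the hundreds-fold size of a
genome-scale model.  Passing tests on it therefore demonstrate the
correctness of the algorithms and the qualitative mechanisms
(anaplerosis rescue, biomass-edit rescue, polyamine-mediated
non-rescue, rich-medium plasticity), not numeric agreement with any
particular organism's reconstruction.

`make_random_network` decorates a guaranteed-feasible linear scaffold
with random side reactions for property-test corpora; decoration is
mass-conservative (consumed ≥ produced, 1:1 when reversible) so no flux
loop can create substrate from nothing, keeping objectives finite and
the feasibility audit meaningful.

## Numerical choices

* LP solver: HiGHS (`scipy.optimize.linprog`); solutions satisfy
  `|S·v| ≤ 1e-6` and bounds within `1e-9` (asserted in tests).
* Infeasible LPs report status `infeasible` with growth 0 — the
  convention by which a network unable to produce biomass is a
  zero-yield phenotype rather than an error; solver failures other than
  in/unboundedness raise.
* Fluxes below `1e-9` are reported as exactly 0; `-0.0` objectives are
  normalised to `0.0`.
* Lethality tolerance `1e-9` absolute; essentiality fraction `0.01`;
  reduction survival margin `1e-9` above the cutoff ("strictly above").
* An exchange reaction clamped to `(0, 0)` by `delete_reactions` stays
  closed even though media otherwise override exchange bounds in the
  model file.
* Bounds are serialised to SBML as decimal `repr` strings and round-trip
  bit-exactly.
* GPR grammar: case-insensitive `and`/`or` with parentheses, AND binding
  tighter than OR — the COBRA-notes convention.  Duplicate metabolite
  entries within one reaction are summed at load time.

## Known limitations

* No parsimonious FBA, flux-variability analysis beyond the
  blocked-reaction test oracle, or MOMA/ROOM knockout models.
* SBML Level 3 / FBC is not parsed; only the Level 2 COBRA dialect.
* Compartments are limited to cytoplasm / extracellular / boundary.
* The conditionally-essential classification depends on ensemble size:
  core sets shrink as replicates grow, so cross-condition counts should
  be compared only at matched replicate numbers.
* Gene-level core nesting across media is reported but not asserted:
  unlike reactions, a gene can enter the rich-medium core through
  transporter dependence while staying out of the limited-medium core.
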