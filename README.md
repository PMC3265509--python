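# redevo

Constraint-based modelling of **reductive genome evolution** in bacteria.

When a free-living bacterium becomes an intracellular associate of a
eukaryotic host, relaxed selection and population bottlenecks let
inactivating mutations accumulate: genes decay into pseudogenes, and the
metabolic network contracts.  `redevo` provides the computational toolkit
for studying this process on genome-scale metabolic networks:

* **Flux balance analysis (FBA)** — maximise the flux `v_biomass` subject to
  steady-state mass balance `S·v = 0` and bounds `lb ≤ v ≤ ub`, where the
  external environment enters only through exchange-reaction bounds
  (a negative lower bound permits uptake, in mmol·gDW⁻¹·h⁻¹);
* **gene–protein–reaction (GPR) logic** — boolean rules in which AND joins
  the subunits of an enzyme complex and OR joins isozymes, so gene
  knockouts propagate correctly to reaction availability;
* **ancestral → extant derivation** — apply a gene-status table
  (`functional | pseudogene | deleted`) to an ancestral reconstruction:
  reactions whose GPR cannot be satisfied are removed, surviving GPRs are
  simplified to their functional leaves, and orphaned genes and
  metabolites are pruned (a pseudogenised complex subunit drags its intact
  partners out of the network);
* **knockout robustness scans** — single-gene essentiality under both the
  zero-growth and the >99 %-impairment criteria, and synthetic-lethal
  pair enumeration over singly non-lethal genes;
* **reductive-evolution simulation** — visit the internal reactions in a
  random permutation, permanently removing each one whose loss keeps
  biomass production above a cutoff fraction of the *original* wild-type
  rate.  Because LP optima are monotone under added constraints, a single
  pass yields a guaranteed-minimal network; ensembles over replicates and
  cutoffs are summarised by mean sizes, core sets (present in every
  minimal network) and absent sets (present in none), and compared across
  nutrient-limited and nutrient-rich media.

Models are read and written as COBRA-dialect SBML Level 2 (bounds in
kinetic-law parameters, `GENE_ASSOCIATION` notes), with plain TSV formats
for media and gene-status tables.  The LP is solved with HiGHS via
`scipy.optimize.linprog`.

## Worked example

The package ships a deterministic synthetic "toy cell" whose topology
mirrors the metabolic motifs that matter for genome reduction: a
phosphotransferase glucose uptake, a TCA-like cycle with an anaplerotic
PEP-carboxylase analogue, storage-polysaccharide synthesis, arginine
biosynthesis feeding polyamine synthesis, and an arginine-salvage route
that degrades putrescine to the cycle intermediate succinate.

```python
import redevo as rd

toy = rd.make_toy_cell()
print(rd.solve_fba(toy.network, toy.glucose_minimal).objective)
# 0.8571428571428568    -- biomass flux, glucose-only aerobic medium

ko = rd.delete_genes(toy.network, ["ppc"])   # lose anaplerosis
print(rd.solve_fba(ko, toy.glucose_minimal).growth)   # 0.0   (lethal)
print(rd.solve_fba(ko, toy.glc_arg).growth)           # 1.2   (arginine rescues)

# pseudogenise storage-polysaccharide synthesis, derive the extant network
status = rd.make_pseudogenization_scenario(toy.network, ["glycogen-synthesis"])
extant = rd.derive_extant(toy.network, status)
print(rd.solve_fba(extant, toy.glucose_minimal).growth)   # 0.0
edited = rd.apply_biomass_edit(extant, rd.BiomassEdit(["glyco"]))
print(rd.solve_fba(edited, toy.glucose_minimal).growth)   # 1.2000000000000002
```

The first knockout is lethal because the biomass drain on oxaloacetate
can no longer be replenished from phosphoenolpyruvate; external arginine
restores growth because putrescine degradation to succinate is an
alternative anaplerotic route.  The second scenario is lethal only
through the biomass equation: once the polysaccharide the cell can no
longer synthesise is removed from the biomass composition, growth
returns.

A command-line interface wraps the same operations:

```sh
redevo fixtures make-toy --out toy.sbml
redevo fba --model toy.sbml --medium toy_glucose_minimal.tsv
redevo ko single --model toy.sbml --medium toy_glc_arg.tsv --out single.tsv
redevo pipeline --model toy.sbml \
    --medium-limited toy_glc_arg.tsv --medium-rich toy_rich.tsv \
    --replicates 50 --seed 1 --out-dir results/
```

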