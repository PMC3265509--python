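"""Synthetic fixture networks for testing every analysis stage.

:func:`make_toy_cell` builds a small (~30 reaction) but mechanistically
faithful cell: a glucose phosphotransferase uptake chain, a lumped
glycolysis, a TCA-like cycle whose oxaloacetate pool is drained by
amino-acid biosynthesis and replenished by an anaplerotic
PEP-carboxylase analogue (with an optional glyoxylate-bypass analogue),
a storage-polysaccharide branch, arginine biosynthesis feeding polyamine
(putrescine/spermidine) synthesis, and an arginine salvage route that
degrades putrescine to the cycle intermediate succinate.  This topology
reproduces the three signature behaviours of reductive-evolution
analyses of an endosymbiont central metabolism:

* knocking out the anaplerotic reaction without the bypass is lethal on
  glucose alone but rescued by external arginine (salvage replenishes
  the cycle);
* losing the storage-polysaccharide pathway is lethal only until the
  polysaccharide is dropped from the biomass equation;
* losing arginine biosynthesis is *not* rescued by dropping arginine
  from the biomass equation, because the polyamines derived from it
  remain biomass components.

:func:`make_random_network` decorates a guaranteed-feasible linear
scaffold with random side reactions for property-test corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .fba_engine import (
    Medium,
    UNBOUNDED_FLUX,
    build_medium,
)
from .model_core import (
    Compartment,
    GeneProduct,
    GeneRef,
    GeneStatus,
    GprAnd,
    GprOr,
    Metabolite,
    MetabolicNetwork,
    ModelError,
    Reaction,
    ReactionKind,
)

E = Compartment.EXTRACELLULAR
C = Compartment.CYTOPLASM

#: Exchanges treated as freely exchangeable inorganics in toy media.
TOY_FREE_EXCHANGES = ("EX_nh4", "EX_co2")


@dataclass(frozen=True)
class ToyCellSpec:
    """Knobs of the toy cell generator.

    The defaults describe the ancestral-like cell: no glyoxylate bypass
    (the modelled endosymbiont lineage shows no trace of one), arginine
    salvage present, two isozyme pairs and two enzyme complexes.
    """

    include_glyoxylate_analogue: bool = False
    include_arginine_salvage: bool = True
    isozyme_pairs: int = 2
    complexes: int = 2
    biomass_components: tuple[str, ...] = (
        "asp", "glu", "arg", "ptrc", "spmd", "glyco", "accoa",
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isozyme_pairs < 0 or self.complexes < 0:
            raise ModelError("motif counts must be non-negative")


@dataclass(frozen=True)
class ToyCell:
    """A generated network plus its reference media."""

    network: MetabolicNetwork
    media: Mapping[str, Medium]

    @property
    def glucose_minimal(self) -> Medium:
        return self.media["glucose_minimal"]

    @property
    def glc_arg(self) -> Medium:
        return self.media["glc_arg"]

    @property
    def rich(self) -> Medium:
        return self.media["rich"]


def _ex(mid: str) -> Reaction:
    return Reaction(
        id=f"EX_{mid.removesuffix('_e')}",
        stoichiometry={mid: -1.0},
        lower_bound=0.0,
        upper_bound=UNBOUNDED_FLUX,
        kind=ReactionKind.EXCHANGE,
        pathway="exchange",
    )


def make_toy_cell(spec: ToyCellSpec = ToyCellSpec()) -> ToyCell:
    """Build the deterministic toy cell described in the module docstring."""
    mets = [
        Metabolite("glc_e", "glucose", E),
        Metabolite("arg_e", "L-arginine", E),
        Metabolite("asp_e", "L-aspartate", E),
        Metabolite("glu_e", "L-glutamate", E),
        Metabolite("o2_e", "oxygen", E),
        Metabolite("nh4_e", "ammonium", E),
        Metabolite("co2_e", "carbon dioxide", E),
        Metabolite("ac_e", "acetate", E),
        Metabolite("g6p", "glucose 6-phosphate", C),
        Metabolite("adpg", "ADP-glucose", C),
        Metabolite("glyco", "glycogen", C),
        Metabolite("t3p", "triose 3-phosphate", C),
        Metabolite("pep", "phosphoenolpyruvate", C),
        Metabolite("pyr", "pyruvate", C),
        Metabolite("accoa", "acetyl-CoA", C),
        Metabolite("oaa", "oxaloacetate", C),
        Metabolite("akg", "2-oxoglutarate", C),
        Metabolite("succ", "succinate", C),
        Metabolite("glu", "L-glutamate", C),
        Metabolite("orn", "L-ornithine", C),
        Metabolite("arg", "L-arginine", C),
        Metabolite("ptrc", "putrescine", C),
        Metabolite("spmd", "spermidine", C),
        Metabolite("asp", "L-aspartate", C),
        Metabolite("o2", "oxygen", C),
        Metabolite("nh4", "ammonium", C),
        Metabolite("co2", "carbon dioxide", C),
        Metabolite("ac", "acetate", C),
    ]

    def gene(g: str) -> GeneRef:
        return GeneRef(g)

    pair_gprs = [
        GprOr((gene("pfkA"), gene("pfkB"))),
        GprOr((gene("pykF"), gene("pykA"))),
    ]
    cplx_gprs = [
        GprAnd((gene("aceE"), gene("aceF"))),
        GprAnd((gene("artJ"), gene("artM"))),
    ]
    glyc1_gpr = pair_gprs[0] if spec.isozyme_pairs >= 1 else gene("pfkA")
    pyk_gpr = pair_gprs[1] if spec.isozyme_pairs >= 2 else gene("pykF")
    pdh_gpr = cplx_gprs[0] if spec.complexes >= 1 else gene("aceE")
    argt_gpr = cplx_gprs[1] if spec.complexes >= 2 else gene("artJ")

    rxns: list[Reaction] = [
        _ex("glc_e"), _ex("arg_e"), _ex("asp_e"), _ex("glu_e"),
        _ex("o2_e"), _ex("nh4_e"), _ex("co2_e"), _ex("ac_e"),
        # transport
        Reaction("GLCpts", {"glc_e": -1, "pep": -1, "g6p": 1, "pyr": 1},
                 0, UNBOUNDED_FLUX, gene("ptsG"), pathway="transport"),
        Reaction("O2t", {"o2_e": -1, "o2": 1}, 0, UNBOUNDED_FLUX,
                 None, pathway="transport"),
        Reaction("NH4t", {"nh4_e": -1, "nh4": 1}, 0, UNBOUNDED_FLUX,
                 gene("amtB"), pathway="transport"),
        Reaction("CO2t", {"co2": -1, "co2_e": 1}, -UNBOUNDED_FLUX,
                 UNBOUNDED_FLUX, None, pathway="transport"),
        Reaction("ACt", {"ac": -1, "ac_e": 1}, 0, UNBOUNDED_FLUX,
                 None, pathway="transport"),
        Reaction("ARGabc", {"arg_e": -1, "arg": 1}, 0, UNBOUNDED_FLUX,
                 argt_gpr, pathway="arginine-salvage"),
        Reaction("ASPt", {"asp_e": -1, "asp": 1}, 0, UNBOUNDED_FLUX,
                 gene("dctA"), pathway="transport"),
        Reaction("GLUt", {"glu_e": -1, "glu": 1}, 0, UNBOUNDED_FLUX,
                 gene("gltP"), pathway="transport"),
        # glycolysis
        Reaction("GLY1", {"g6p": -1, "t3p": 2}, 0, UNBOUNDED_FLUX,
                 glyc1_gpr, pathway="glycolysis"),
        Reaction("GLY2", {"t3p": -1, "pep": 1}, 0, UNBOUNDED_FLUX,
                 gene("gapA"), pathway="glycolysis"),
        Reaction("PYK", {"pep": -1, "pyr": 1}, 0, UNBOUNDED_FLUX,
                 pyk_gpr, pathway="glycolysis"),
        Reaction("ACS", {"pyr": -1, "ac": 1}, 0, UNBOUNDED_FLUX,
                 gene("poxB"), pathway="overflow"),
        # storage polysaccharide
        Reaction("GLGC", {"g6p": -1, "adpg": 1}, 0, UNBOUNDED_FLUX,
                 gene("glgC"), pathway="glycogen-synthesis"),
        Reaction("GLGA", {"adpg": -1, "glyco": 1}, 0, UNBOUNDED_FLUX,
                 gene("glgA"), pathway="glycogen-synthesis"),
        # TCA-like cycle and anaplerosis
        Reaction("PDH", {"pyr": -1, "accoa": 1, "co2": 1}, 0, UNBOUNDED_FLUX,
                 pdh_gpr, pathway="tca"),
        Reaction("CSICD", {"accoa": -1, "oaa": -1, "akg": 1, "co2": 2},
                 0, UNBOUNDED_FLUX, gene("gltA"), pathway="tca"),
        Reaction("AKGDH", {"akg": -1, "o2": -1, "succ": 1, "co2": 1},
                 0, UNBOUNDED_FLUX, gene("sucA"), pathway="tca"),
        Reaction("SDHMDH", {"succ": -1, "o2": -1, "oaa": 1},
                 0, UNBOUNDED_FLUX, gene("sdhA"), pathway="tca"),
        Reaction("PPC", {"pep": -1, "co2": -1, "oaa": 1}, 0, UNBOUNDED_FLUX,
                 gene("ppc"), pathway="anaplerosis"),
        # nitrogen assimilation and amino acids
        Reaction("GDH", {"akg": -1, "nh4": -1, "glu": 1}, 0, UNBOUNDED_FLUX,
                 gene("gdhA"), pathway="amino-acid-biosynthesis"),
        Reaction("ASPSYN", {"oaa": -1, "nh4": -1, "asp": 1},
                 0, UNBOUNDED_FLUX, gene("aspC"),
                 pathway="amino-acid-biosynthesis"),
        Reaction("ARGSYN1", {"glu": -1, "nh4": -1, "orn": 1},
                 0, UNBOUNDED_FLUX, gene("argA"),
                 pathway="arginine-biosynthesis"),
        Reaction("ARGSYN2", {"orn": -1, "nh4": -1, "co2": -1, "arg": 1},
                 0, UNBOUNDED_FLUX, gene("argG"),
                 pathway="arginine-biosynthesis"),
        # polyamines and arginine salvage
        Reaction("ARGDC", {"arg": -1, "ptrc": 1, "co2": 1}, 0, UNBOUNDED_FLUX,
                 gene("speA"), pathway="polyamine-biosynthesis"),
        Reaction("SPMDS", {"ptrc": -1, "spmd": 1}, 0, UNBOUNDED_FLUX,
                 gene("speE"), pathway="polyamine-biosynthesis"),
    ]
    if spec.include_arginine_salvage:
        rxns.append(
            Reaction("PTRCDEG", {"ptrc": -1, "o2": -1, "succ": 1, "nh4": 1},
                     0, UNBOUNDED_FLUX, GeneRef("puuA"),
                     pathway="arginine-salvage")
        )
    if spec.include_glyoxylate_analogue:
        rxns.append(
            Reaction("GLX", {"accoa": -2, "succ": 1}, 0, UNBOUNDED_FLUX,
                     GeneRef("aceA"), pathway="glyoxylate-bypass")
        )
    # decorative extra motifs beyond the two built-in pairs/complexes
    for k in range(2, spec.isozyme_pairs):
        rxns.append(
            Reaction(f"ALT_GLY2_{k}", {"t3p": -1, "pep": 1},
                     0, UNBOUNDED_FLUX,
                     GprOr((GeneRef(f"isoA{k}"), GeneRef(f"isoB{k}"))),
                     pathway="glycolysis")
        )
    for k in range(2, spec.complexes):
        rxns.append(
            Reaction(f"ALT_NH4t_{k}", {"nh4_e": -1, "nh4": 1},
                     0, UNBOUNDED_FLUX,
                     GprAnd((GeneRef(f"cplxA{k}"), GeneRef(f"cplxB{k}"))),
                     pathway="transport")
        )

    biomass_stoich = {m: -1.0 for m in spec.biomass_components}
    rxns.append(
        Reaction("BIOMASS", biomass_stoich, 0, UNBOUNDED_FLUX,
                 None, kind=ReactionKind.BIOMASS, pathway="biomass")
    )

    genes = sorted({g for r in rxns for g in r.genes})
    network = MetabolicNetwork(
        genes={g: GeneProduct(g) for g in genes},
        metabolites={m.id: m for m in mets},
        reactions=rxns,
        objective_id="BIOMASS",
        id="toycell",
    )
    network.validate()

    media = {
        "glucose_minimal": build_medium(
            {"EX_glc": 6.0}, "EX_o2", 20.0, TOY_FREE_EXCHANGES,
            name="glucose_minimal",
        ),
        "glc_arg": build_medium(
            {"EX_glc": 6.0, "EX_arg": 6.0}, "EX_o2", 20.0,
            TOY_FREE_EXCHANGES, name="glc_arg",
        ),
        "rich": build_medium(
            {"EX_glc": 6.0, "EX_arg": 6.0, "EX_asp": 6.0, "EX_glu": 6.0},
            "EX_o2", 20.0, TOY_FREE_EXCHANGES, name="rich",
        ),
    }
    return ToyCell(network=network, media=media)


# ---------------------------------------------------------------------------
# Pseudogenisation scenarios
# ---------------------------------------------------------------------------

def make_pseudogenization_scenario(
    network: MetabolicNetwork,
    target_pathways: Sequence[str],
    seed: int = 0,
) -> dict[str, GeneStatus]:
    """Mark every gene of the chosen pathways as a pseudogene.

    Pathways are the free-text labels attached to reactions; the gene set
    of a pathway is the union of its reactions' GPR genes.  Unknown
    labels raise :class:`ModelError`.  The seed is recorded for
    provenance only; the scenario is deterministic.
    """
    del seed
    known = {r.pathway for r in network.reactions if r.pathway}
    unknown = set(target_pathways) - known
    if unknown:
        raise ModelError(f"unknown pathway labels: {sorted(unknown)}")
    targeted: set[str] = set()
    for r in network.reactions:
        if r.pathway in set(target_pathways):
            targeted |= r.genes
    return {
        g: (GeneStatus.PSEUDOGENE if g in targeted else GeneStatus.FUNCTIONAL)
        for g in network.genes
    }


# ---------------------------------------------------------------------------
# Random property-test networks
# ---------------------------------------------------------------------------

def make_random_network(
    n_reactions: int,
    n_isozymes: int = 2,
    seed: int = 0,
) -> tuple[MetabolicNetwork, Medium]:
    """Random feasible network: a linear scaffold plus random decoration.

    The scaffold — substrate uptake, a conversion chain, and a biomass
    drain — guarantees a positive FBA optimum on the reference medium;
    decoration adds random side reactions (some reversible, some gated by
    OR isozyme pairs or AND complexes) that can only enlarge the feasible
    set.  Bitwise reproducible per seed.
    """
    if n_reactions < 5:
        raise ModelError("need at least 5 reactions for the scaffold")
    rng = np.random.default_rng(seed)
    chain_len = max(2, min(5, n_reactions - 3))
    mets = [Metabolite("s_e", "substrate", E)]
    mets += [Metabolite(f"m{i}", f"metabolite {i}", C) for i in range(chain_len)]
    rxns: list[Reaction] = [_ex("s_e")]
    genes: set[str] = set()

    def add_gene(g: str) -> GeneRef:
        genes.add(g)
        return GeneRef(g)

    rxns.append(
        Reaction("UPT", {"s_e": -1, "m0": 1}, 0, UNBOUNDED_FLUX,
                 add_gene("g_upt"), pathway="transport")
    )
    for i in range(chain_len - 1):
        rxns.append(
            Reaction(f"C{i}", {f"m{i}": -1, f"m{i+1}": 1}, 0, UNBOUNDED_FLUX,
                     add_gene(f"g_c{i}"), pathway="chain")
        )
    rxns.append(
        Reaction("BIOMASS", {f"m{chain_len-1}": -1.0}, 0, UNBOUNDED_FLUX,
                 None, kind=ReactionKind.BIOMASS, pathway="biomass")
    )

    n_extra = n_reactions - len(rxns)
    cyt_ids = [m.id for m in mets if m.compartment is C]
    for k in range(max(0, n_extra)):
        a, b = rng.choice(len(cyt_ids), size=2, replace=False)
        reversible = bool(rng.random() < 0.3)
        # mass-conservative decoration (consumed >= produced, and 1:1 when
        # reversible) so no flux loop can create substrate from nothing
        consumed = 1.0 if reversible else float(rng.integers(1, 3))
        coefs = {cyt_ids[a]: -consumed, cyt_ids[b]: 1.0}
        style = rng.random()
        if k < n_isozymes:
            gpr = GprOr((add_gene(f"g_i{k}a"), add_gene(f"g_i{k}b")))
        elif style < 0.3:
            gpr = GprAnd((add_gene(f"g_x{k}a"), add_gene(f"g_x{k}b")))
        elif style < 0.9:
            gpr = add_gene(f"g_x{k}")
        else:
            gpr = None
        rxns.append(
            Reaction(
                f"R{k}",
                coefs,
                -UNBOUNDED_FLUX if reversible else 0.0,
                UNBOUNDED_FLUX,
                gpr,
                pathway="decoration",
            )
        )

    network = MetabolicNetwork(
        genes={g: GeneProduct(g) for g in sorted(genes)},
        metabolites={m.id: m for m in mets},
        reactions=rxns,
        objective_id="BIOMASS",
        id=f"random_{seed}",
    )
    network.validate()
    medium = build_medium({"EX_s": 10.0}, name="reference")
    return network, medium
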