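"""In-memory model of genome-scale metabolic networks with gene status.

The central object is :class:`MetabolicNetwork`: compartmentalised
metabolites, reactions with stoichiometry, flux bounds and
gene-protein-reaction (GPR) boolean rules, and gene products annotated with
their evolutionary status (functional, pseudogene, or deleted from the
genome).  GPR rules use the standard semantics of constraint-based
modelling: AND joins subunits of an enzyme complex (all genes required),
OR joins isozymes (any one gene suffices).

Networks are treated as immutable values by the rest of the package;
operations such as :func:`apply_biomass_edit` and :func:`prune_orphans`
return modified copies.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Union


class GeneStatus(enum.Enum):
    """Evolutionary status of a gene in the reconstructed genome."""

    FUNCTIONAL = "functional"
    PSEUDOGENE = "pseudogene"
    DELETED = "deleted"


class ReactionKind(enum.Enum):
    INTERNAL = "internal"
    EXCHANGE = "exchange"
    BIOMASS = "biomass"


class Compartment(enum.Enum):
    CYTOPLASM = "cytoplasm"
    EXTRACELLULAR = "extracellular"


class ModelError(ValueError):
    """Structural problem in a network or an operation on it."""


@dataclass(frozen=True)
class GeneProduct:
    id: str
    status: GeneStatus = GeneStatus.FUNCTIONAL


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: Compartment = Compartment.CYTOPLASM
    is_boundary: bool = False


# ---------------------------------------------------------------------------
# GPR boolean expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneRef:
    """Leaf of a GPR tree: a single gene identifier."""

    gene: str

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class GprAnd:
    """Enzyme complex: every operand must be available."""

    children: tuple["Gpr", ...]

    def __str__(self) -> str:
        return "( " + " and ".join(str(c) for c in self.children) + " )"


@dataclass(frozen=True)
class GprOr:
    """Isozymes: any one operand suffices."""

    children: tuple["Gpr", ...]

    def __str__(self) -> str:
        return "( " + " or ".join(str(c) for c in self.children) + " )"


#: A GPR expression; ``None`` denotes a reaction with no gene assignment,
#: which always evaluates true (it cannot be disabled by gene deletion).
Gpr = Union[GeneRef, GprAnd, GprOr]


def gpr_genes(gpr: Optional[Gpr]) -> frozenset[str]:
    """All gene identifiers referenced by a GPR expression."""
    if gpr is None:
        return frozenset()
    if isinstance(gpr, GeneRef):
        return frozenset((gpr.gene,))
    out: set[str] = set()
    for child in gpr.children:
        out |= gpr_genes(child)
    return frozenset(out)


def evaluate_gpr(
    gpr: Optional[Gpr],
    inactive: Iterable[str],
    known_genes: Optional[Iterable[str]] = None,
) -> bool:
    """Evaluate a GPR rule with the given genes switched off.

    Leaves naming a gene in ``inactive`` evaluate false, all other leaves
    true.  The empty expression (``None``) evaluates true: reactions
    without a gene assignment are never disabled by gene deletions.

    Parameters
    ----------
    gpr
        Expression tree, or ``None`` for no gene association.
    inactive
        Gene ids treated as unavailable (knocked out, pseudogenised...).
    known_genes
        When given, every leaf must name a gene in this collection;
        a stray leaf raises :class:`ModelError`.
    """
    if known_genes is not None:
        known = set(known_genes)
        unknown = gpr_genes(gpr) - known
        if unknown:
            raise ModelError(f"GPR references unknown genes: {sorted(unknown)}")
    inactive_set = set(inactive)

    def _eval(node: Optional[Gpr]) -> bool:
        if node is None:
            return True
        if isinstance(node, GeneRef):
            return node.gene not in inactive_set
        if isinstance(node, GprAnd):
            return all(_eval(c) for c in node.children)
        if isinstance(node, GprOr):
            return any(_eval(c) for c in node.children)
        raise TypeError(f"not a GPR node: {node!r}")

    return _eval(gpr)


def simplify_gpr(
    gpr: Optional[Gpr], inactive: Iterable[str]
) -> tuple[bool, Optional[Gpr]]:
    """Partially evaluate a GPR with some genes permanently unavailable.

    Returns ``(satisfiable, simplified)``: leaves in ``inactive`` become
    constant false and the tree is folded — an AND dies with any false
    child, an OR drops false children and dies only when none survive.
    When satisfiable, the simplified tree references no inactive gene.
    A single-child node collapses to that child; ``None`` stays ``None``.
    """
    inactive_set = set(inactive)

    def _simp(node: Optional[Gpr]) -> tuple[bool, Optional[Gpr]]:
        if node is None:
            return True, None
        if isinstance(node, GeneRef):
            return node.gene not in inactive_set, node
        kept: list[Gpr] = []
        for child in node.children:
            ok, sub = _simp(child)
            if isinstance(node, GprAnd):
                if not ok:
                    return False, None
                kept.append(sub)
            else:
                if ok:
                    kept.append(sub)
        if isinstance(node, GprOr) and not kept:
            return False, None
        if len(kept) == 1:
            return True, kept[0]
        cls = GprAnd if isinstance(node, GprAnd) else GprOr
        return True, cls(tuple(kept))

    return _simp(gpr)


def gpr_to_dnf(gpr: Optional[Gpr]) -> frozenset[frozenset[str]]:
    """Normalise a GPR to disjunctive normal form.

    Returns a set of disjuncts, each a set of gene ids whose joint
    availability enables the reaction.  Absorbed disjuncts (supersets of
    another disjunct) and duplicates are removed, so the number of
    disjuncts counts genuinely alternative enzymes: a reaction is
    isozyme-catalysed iff the result has at least two disjuncts.
    ``None`` maps to a single empty disjunct (always available).
    """
    if gpr is None:
        return frozenset((frozenset(),))
    if isinstance(gpr, GeneRef):
        return frozenset((frozenset((gpr.gene,)),))
    if isinstance(gpr, GprOr):
        terms: set[frozenset[str]] = set()
        for child in gpr.children:
            terms |= gpr_to_dnf(child)
    elif isinstance(gpr, GprAnd):
        terms = {frozenset()}
        for child in gpr.children:
            terms = {
                a | b for a, b in itertools.product(terms, gpr_to_dnf(child))
            }
    else:
        raise TypeError(f"not a GPR node: {gpr!r}")
    # absorption: drop any disjunct containing another one
    minimal = {
        t for t in terms
        if not any(o < t for o in terms)
    }
    return frozenset(minimal)


# ---------------------------------------------------------------------------
# Reactions and networks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """A stoichiometric reaction.

    ``stoichiometry`` maps metabolite ids to signed coefficients
    (negative = consumed).  Bounds are fluxes in mmol gDW^-1 h^-1; the
    convention for exchange reactions is that a negative lower bound
    permits uptake.  ``pathway`` is a free-text functional label used by
    the fixture generators and reports; it carries no model semantics.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    gpr: Optional[Gpr] = None
    kind: ReactionKind = ReactionKind.INTERNAL
    name: str = ""
    pathway: Optional[str] = None

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)

    def reactants(self) -> frozenset[str]:
        return frozenset(m for m, c in self.stoichiometry.items() if c < 0)


@dataclass(frozen=True)
class BiomassEdit:
    """Removal of components from the biomass equation's reactant side."""

    removed_components: frozenset[str]

    def __init__(self, removed_components: Iterable[str]):
        object.__setattr__(
            self, "removed_components", frozenset(removed_components)
        )


@dataclass
class MetabolicNetwork:
    genes: dict[str, GeneProduct] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: list[Reaction] = field(default_factory=list)
    objective_id: Optional[str] = None
    id: str = "network"

    # -- construction helpers ------------------------------------------------

    @classmethod
    def build(
        cls,
        genes: Iterable[GeneProduct],
        metabolites: Iterable[Metabolite],
        reactions: Iterable[Reaction],
        objective_id: Optional[str] = None,
        id: str = "network",
        validate: bool = True,
    ) -> "MetabolicNetwork":
        net = cls(
            genes={g.id: g for g in genes},
            metabolites={m.id: m for m in metabolites},
            reactions=list(reactions),
            objective_id=objective_id,
            id=id,
        )
        if validate:
            net.validate()
        return net

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            genes=dict(self.genes),
            metabolites=dict(self.metabolites),
            reactions=list(self.reactions),
            objective_id=self.objective_id,
            id=self.id,
        )

    # -- lookups -------------------------------------------------------------

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def biomass_reaction(self) -> Reaction:
        if self.objective_id is None:
            raise ModelError("network has no biomass/objective reaction")
        return self.reaction(self.objective_id)

    def internal_reactions(self) -> list[Reaction]:
        """Non-exchange reactions (the biomass equation counts as internal)."""
        return [r for r in self.reactions if r.kind is not ReactionKind.EXCHANGE]

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind is ReactionKind.EXCHANGE]

    def balanced_metabolites(self) -> list[Metabolite]:
        """Metabolites subject to the steady-state mass balance."""
        return [m for m in self.metabolites.values() if not m.is_boundary]

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        seen_rids: set[str] = set()
        biomass_count = 0
        for r in self.reactions:
            if r.id in seen_rids:
                raise ModelError(f"duplicate reaction id {r.id}")
            seen_rids.add(r.id)
            for mid in r.stoichiometry:
                if mid not in self.metabolites:
                    raise ModelError(
                        f"reaction {r.id} references unknown metabolite {mid}"
                    )
            unknown = r.genes - self.genes.keys()
            if unknown:
                raise ModelError(
                    f"reaction {r.id} GPR references unknown genes "
                    f"{sorted(unknown)}"
                )
            if r.kind is ReactionKind.BIOMASS:
                biomass_count += 1
            if r.kind is ReactionKind.EXCHANGE:
                balanced = [
                    mid for mid in r.stoichiometry
                    if not self.metabolites[mid].is_boundary
                ]
                if len(balanced) != 1:
                    raise ModelError(
                        f"exchange reaction {r.id} must touch exactly one "
                        f"mass-balanced metabolite, found {balanced}"
                    )
                met = self.metabolites[balanced[0]]
                if met.compartment is not Compartment.EXTRACELLULAR:
                    raise ModelError(
                        f"exchange reaction {r.id} touches non-extracellular "
                        f"metabolite {met.id}"
                    )
        if biomass_count > 1:
            raise ModelError("more than one biomass reaction")
        if self.objective_id is not None and self.objective_id not in seen_rids:
            raise ModelError(f"objective reaction {self.objective_id} missing")

    # -- summary counts ------------------------------------------------------

    def summary(self) -> dict[str, int]:
        cyt = sum(
            1 for m in self.balanced_metabolites()
            if m.compartment is Compartment.CYTOPLASM
        )
        ext = sum(
            1 for m in self.balanced_metabolites()
            if m.compartment is Compartment.EXTRACELLULAR
        )
        return {
            "genes": len(self.genes),
            "metabolites": len(self.balanced_metabolites()),
            "cytoplasmic_metabolites": cyt,
            "extracellular_metabolites": ext,
            "reactions": len(self.reactions),
            "internal_reactions": len(self.internal_reactions()),
            "exchange_reactions": len(self.exchange_reactions()),
        }


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_biomass_edit(
    network: MetabolicNetwork, edit: BiomassEdit
) -> MetabolicNetwork:
    """Drop components from the biomass equation.

    Used to model the loss of a biomass constituent whose biosynthesis has
    been pseudogenised (e.g. a storage polysaccharide the organism can no
    longer make).  Every id in the edit must be a reactant of the biomass
    reaction; anything else raises :class:`ModelError`.
    """
    biomass = network.biomass_reaction
    bad = edit.removed_components - biomass.reactants()
    if bad:
        raise ModelError(
            f"not reactants of the biomass reaction: {sorted(bad)}"
        )
    new_stoich = {
        m: c for m, c in biomass.stoichiometry.items()
        if m not in edit.removed_components
    }
    out = network.copy()
    out.reactions = [
        replace(r, stoichiometry=new_stoich) if r.id == biomass.id else r
        for r in network.reactions
    ]
    return out


def prune_orphans(network: MetabolicNetwork) -> MetabolicNetwork:
    """Drop genes referenced by no GPR and metabolites used by no reaction.

    The reaction list is untouched.  Needed after reaction removal so that
    gene and metabolite counts reflect the functional network: removing a
    reaction can orphan a functional gene whose only role was as a subunit
    of that reaction's enzyme complex.  Idempotent.
    """
    used_genes: set[str] = set()
    used_mets: set[str] = set()
    for r in network.reactions:
        used_genes |= r.genes
        used_mets |= set(r.stoichiometry)
    out = network.copy()
    out.genes = {g: gp for g, gp in network.genes.items() if g in used_genes}
    out.metabolites = {
        m: met for m, met in network.metabolites.items() if m in used_mets
    }
    return out
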