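"""SBML Level 2 reading/writing in the classic COBRA dialect, plus the
tabular side formats (gene status, medium definitions).

The COBRA dialect of the genome-scale reconstruction era encodes flux
bounds as kinetic-law parameters (``LOWER_BOUND``/``UPPER_BOUND``), the
objective as ``OBJECTIVE_COEFFICIENT``, gene-protein-reaction rules as a
``GENE_ASSOCIATION:`` line inside reaction notes, and boundary
metabolites either by the SBML boundary-condition flag or an id suffix
(conventionally ``_b``).  All of these are configurable through
:class:`SbmlDialectOptions` so that files from different reconstructions
can be read through one code path.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import libsbml

from .model_core import (
    Compartment,
    GeneProduct,
    GeneRef,
    GeneStatus,
    Gpr,
    GprAnd,
    GprOr,
    Metabolite,
    MetabolicNetwork,
    ModelError,
    Reaction,
    ReactionKind,
    gpr_genes,
)


class SbmlIOError(ValueError):
    pass


@dataclass(frozen=True)
class SbmlDialectOptions:
    gene_association_key: str = "GENE_ASSOCIATION"
    lower_bound_name: str = "LOWER_BOUND"
    upper_bound_name: str = "UPPER_BOUND"
    objective_name: str = "OBJECTIVE_COEFFICIENT"
    boundary_suffix: str = "_b"
    extracellular_compartments: tuple[str, ...] = ("e", "extracellular", "Extra_organism")

    def __post_init__(self) -> None:
        for name in (
            self.gene_association_key,
            self.lower_bound_name,
            self.upper_bound_name,
            self.objective_name,
        ):
            if not name:
                raise SbmlIOError("dialect option names must be non-empty")


DEFAULT_DIALECT = SbmlDialectOptions()


# ---------------------------------------------------------------------------
# GPR grammar:  expr := term (OR term)* ; term := factor (AND factor)* ;
#               factor := gene | '(' expr ')'    -- AND binds tighter than OR
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(text: str) -> Optional[Gpr]:
    """Parse a COBRA-style gene association string into a GPR tree.

    ``and``/``or`` keywords are case-insensitive; parentheses group; AND
    binds tighter than OR.  An empty or whitespace-only string yields
    ``None`` (no gene association).
    """
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        return None
    pos = 0

    def peek() -> Optional[str]:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_expr() -> Gpr:
        terms = [parse_term()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_term())
        return terms[0] if len(terms) == 1 else GprOr(tuple(terms))

    def parse_term() -> Gpr:
        factors = [parse_factor()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_factor())
        return factors[0] if len(factors) == 1 else GprAnd(tuple(factors))

    def parse_factor() -> Gpr:
        tok = peek()
        if tok is None:
            raise SbmlIOError(f"unexpected end of GPR string: {text!r}")
        if tok == "(":
            take()
            node = parse_expr()
            if peek() != ")":
                raise SbmlIOError(f"unbalanced parentheses in GPR: {text!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise SbmlIOError(f"malformed GPR string: {text!r}")
        return GeneRef(take())

    tree = parse_expr()
    if pos != len(tokens):
        raise SbmlIOError(f"trailing tokens in GPR string: {text!r}")
    return tree


def gpr_to_string(gpr: Optional[Gpr]) -> str:
    """Serialise a GPR tree back to the parenthesised and/or notation."""
    if gpr is None:
        return ""
    if isinstance(gpr, GeneRef):
        return gpr.gene
    if isinstance(gpr, GprAnd):
        return "( " + " and ".join(gpr_to_string(c) for c in gpr.children) + " )"
    if isinstance(gpr, GprOr):
        return "( " + " or ".join(gpr_to_string(c) for c in gpr.children) + " )"
    raise TypeError(f"not a GPR node: {gpr!r}")


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

def _notes_fields(notes_str: str) -> dict[str, str]:
    """Extract ``KEY: value`` lines from an SBML notes blob (HTML stripped)."""
    text = re.sub(r"<[^>]+>", "\n", notes_str)
    out = {}
    for line in text.splitlines():
        if ":" in line:
            key, _, value = line.partition(":")
            key = key.strip()
            if key and re.fullmatch(r"[A-Za-z_][A-Za-z0-9_ ]*", key):
                out[key] = value.strip()
    return out


def read_sbml(
    path: Union[str, Path],
    options: SbmlDialectOptions = DEFAULT_DIALECT,
) -> MetabolicNetwork:
    """Read a COBRA-dialect SBML Level 2 file into a MetabolicNetwork.

    Boundary species (flagged, or carrying the configured id suffix) are
    excluded from mass balance; the reaction carrying a nonzero objective
    coefficient becomes the biomass reaction.  Reactions touching exactly
    one balanced metabolite that is extracellular are classified as
    exchanges.  Gene products are collected from GPR strings with status
    functional; evolutionary status comes from a separate table
    (:func:`read_gene_status`).
    """
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        raise SbmlIOError(
            f"{path}: SBML parse error: "
            f"{doc.getError(0).getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise SbmlIOError(f"{path}: no model element")

    extracellular = set(options.extracellular_compartments)
    metabolites: dict[str, Metabolite] = {}
    for sp in model.getListOfSpecies():
        sid = sp.getId()
        if sid in metabolites:
            raise SbmlIOError(f"duplicate species id {sid}")
        is_boundary = bool(sp.getBoundaryCondition()) or sid.endswith(
            options.boundary_suffix
        )
        comp = (
            Compartment.EXTRACELLULAR
            if sp.getCompartment() in extracellular or is_boundary
            else Compartment.CYTOPLASM
        )
        metabolites[sid] = Metabolite(
            id=sid,
            name=sp.getName() or sid,
            compartment=comp,
            is_boundary=is_boundary,
        )

    reactions: list[Reaction] = []
    seen_rids: set[str] = set()
    genes: dict[str, GeneProduct] = {}
    objective_id: Optional[str] = None
    for rxn in model.getListOfReactions():
        rid = rxn.getId()
        if rid in seen_rids:
            raise SbmlIOError(f"duplicate reaction id {rid}")
        seen_rids.add(rid)

        stoich: dict[str, float] = {}
        for ref in rxn.getListOfReactants():
            sid = ref.getSpecies()
            stoich[sid] = stoich.get(sid, 0.0) - ref.getStoichiometry()
        for ref in rxn.getListOfProducts():
            sid = ref.getSpecies()
            stoich[sid] = stoich.get(sid, 0.0) + ref.getStoichiometry()

        lb = -UNBOUNDED_DEFAULT if rxn.getReversible() else 0.0
        ub = UNBOUNDED_DEFAULT
        obj_coef = 0.0
        klaw = rxn.getKineticLaw()
        if klaw is not None:
            for i in range(klaw.getNumParameters()):
                par = klaw.getParameter(i)
                if par.getId() == options.lower_bound_name:
                    lb = par.getValue()
                elif par.getId() == options.upper_bound_name:
                    ub = par.getValue()
                elif par.getId() == options.objective_name:
                    obj_coef = par.getValue()

        gpr: Optional[Gpr] = None
        pathway: Optional[str] = None
        if rxn.isSetNotes():
            fields = _notes_fields(rxn.getNotesString())
            ga = fields.get(options.gene_association_key, "")
            if ga:
                try:
                    gpr = parse_gpr(ga)
                except SbmlIOError as exc:
                    raise SbmlIOError(
                        f"reaction {rid}: cannot parse gene association: {exc}"
                    ) from exc
            pathway = fields.get("SUBSYSTEM") or None

        for g in gpr_genes(gpr):
            genes.setdefault(g, GeneProduct(g, GeneStatus.FUNCTIONAL))

        balanced = [
            sid for sid in stoich if not metabolites[sid].is_boundary
        ]
        if obj_coef != 0.0:
            kind = ReactionKind.BIOMASS
            objective_id = rid
        elif (
            len(balanced) == 1
            and metabolites[balanced[0]].compartment is Compartment.EXTRACELLULAR
        ):
            kind = ReactionKind.EXCHANGE
        else:
            kind = ReactionKind.INTERNAL

        reactions.append(
            Reaction(
                id=rid,
                name=rxn.getName() or "",
                stoichiometry=stoich,
                lower_bound=lb,
                upper_bound=ub,
                gpr=gpr,
                kind=kind,
                pathway=pathway,
            )
        )

    if objective_id is None:
        warnings.warn(
            f"{path}: no reaction with a nonzero objective coefficient; "
            "objective left unset",
            stacklevel=2,
        )
    net = MetabolicNetwork(
        genes=genes,
        metabolites=metabolites,
        reactions=reactions,
        objective_id=objective_id,
        id=model.getId() or "network",
    )
    net.validate()
    return net


UNBOUNDED_DEFAULT = 1e6


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def _fmt_bound(value: float) -> str:
    """Decimal rendering that survives a read/write round trip bit-exactly."""
    return repr(float(value))


def write_sbml(
    network: MetabolicNetwork,
    path: Union[str, Path],
    options: SbmlDialectOptions = DEFAULT_DIALECT,
) -> None:
    """Write a network as COBRA-dialect SBML Level 2.

    ``read_sbml(write_sbml(net))`` returns a structurally identical
    network: same ids, stoichiometry, bounds (bit-exact via decimal
    ``repr``), GPR trees and reaction kinds.
    """
    doc = libsbml.SBMLDocument(2, 4)
    model = doc.createModel()
    model.setId(network.id)

    comp_ids = {Compartment.CYTOPLASM: "c", Compartment.EXTRACELLULAR: "e"}
    for cid in ("c", "e"):
        comp = model.createCompartment()
        comp.setId(cid)
        comp.setSize(1.0)

    for met in network.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(comp_ids[met.compartment])
        sp.setBoundaryCondition(met.is_boundary)
        sp.setInitialConcentration(0.0)

    for r in network.reactions:
        rxn = model.createReaction()
        rxn.setId(r.id)
        if r.name:
            rxn.setName(r.name)
        rxn.setReversible(r.lower_bound < 0)
        for mid, coef in r.stoichiometry.items():
            if coef < 0:
                ref = rxn.createReactant()
                ref.setSpecies(mid)
                ref.setStoichiometry(-coef)
            elif coef > 0:
                ref = rxn.createProduct()
                ref.setSpecies(mid)
                ref.setStoichiometry(coef)
        note_lines = []
        if r.gpr is not None:
            note_lines.append(
                f"{options.gene_association_key}: {gpr_to_string(r.gpr)}"
            )
        if r.pathway:
            note_lines.append(f"SUBSYSTEM: {r.pathway}")
        if note_lines:
            body = "".join(f"<p>{line}</p>" for line in note_lines)
            rxn.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">{body}</body>'
            )
        klaw = rxn.createKineticLaw()
        klaw.setFormula("FLUX_VALUE")
        for pname, pval in (
            (options.lower_bound_name, r.lower_bound),
            (options.upper_bound_name, r.upper_bound),
            (
                options.objective_name,
                1.0 if r.id == network.objective_id else 0.0,
            ),
        ):
            par = klaw.createParameter()
            par.setId(pname)
            par.setValue(float(_fmt_bound(pval)))

    writer = libsbml.SBMLWriter()
    if not writer.writeSBMLToFile(doc, str(path)):
        raise SbmlIOError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# Tabular side formats
# ---------------------------------------------------------------------------

_STATUS_TOKENS = {s.value: s for s in GeneStatus}


def read_gene_status(path: Union[str, Path]) -> dict[str, GeneStatus]:
    """Read a two-column TSV of gene id and evolutionary status.

    Status vocabulary is strict: ``functional``, ``pseudogene`` or
    ``deleted``.  A duplicated gene with a conflicting status is an
    error; comment lines starting with ``#`` and a ``gene_id`` header
    line are skipped.
    """
    out: dict[str, GeneStatus] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = re.split(r"[\t,]| {2,}", line)
        parts = [p.strip() for p in parts if p.strip()]
        if len(parts) != 2:
            raise SbmlIOError(
                f"{path}:{lineno}: expected two columns, got {len(parts)}"
            )
        gene, token = parts
        if gene.lower() == "gene_id":
            continue
        status = _STATUS_TOKENS.get(token.lower())
        if status is None:
            raise SbmlIOError(
                f"{path}:{lineno}: unknown status token {token!r} "
                f"(expected one of {sorted(_STATUS_TOKENS)})"
            )
        if gene in out and out[gene] is not status:
            raise SbmlIOError(
                f"{path}:{lineno}: conflicting status for gene {gene}"
            )
        out[gene] = status
    return out


def write_gene_status(
    status: dict[str, GeneStatus], path: Union[str, Path]
) -> None:
    lines = ["gene_id\tstatus"]
    lines += [f"{g}\t{s.value}" for g, s in sorted(status.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def read_medium_table(path: Union[str, Path]):
    """Read a medium TSV: exchange_reaction_id, lower_bound, upper_bound."""
    from .fba_engine import Medium

    bounds: dict[str, tuple[float, float]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p for p in re.split(r"\t| +", line) if p]
        if parts[0].lower() in ("exchange_reaction_id", "reaction_id"):
            continue
        if len(parts) != 3:
            raise SbmlIOError(
                f"{path}:{lineno}: expected three columns, got {len(parts)}"
            )
        rid, lo, hi = parts
        bounds[rid] = (float(lo), float(hi))
    return Medium(bounds=bounds, name=Path(path).stem)


def write_medium_table(medium, path: Union[str, Path]) -> None:
    lines = ["exchange_reaction_id\tlower_bound\tupper_bound"]
    lines += [
        f"{rid}\t{lo!r}\t{hi!r}" for rid, (lo, hi) in sorted(medium.bounds.items())
    ]
    Path(path).write_text("\n".join(lines) + "\n")
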