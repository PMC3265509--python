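"""Flux balance analysis: the steady-state LP and its knockout variants.

The linear program is the standard one: maximise the flux through the
biomass reaction subject to mass balance ``S v = 0`` over the
non-boundary metabolites and box constraints ``lb <= v <= ub``.  The
external environment enters exclusively through the bounds of exchange
reactions (a negative lower bound permits uptake); gene and reaction
knockouts enter by clamping the affected reaction fluxes to zero.

Only the optimal objective value is treated as a contractual output.
Genome-scale FBA problems are massively degenerate, so the flux vector
returned is one optimum among many and downstream statistics in this
package never depend on individual fluxes.

Solved with the HiGHS solvers behind :func:`scipy.optimize.linprog`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model_core import (
    MetabolicNetwork,
    ModelError,
    Reaction,
    ReactionKind,
    evaluate_gpr,
)

#: Stand-in for an unconstrained flux bound (large finite value, the
#: convention of genome-scale reconstructions).
UNBOUNDED_FLUX = 1e6

#: Fluxes below this magnitude are reported as exactly zero.
FLUX_ZERO_TOL = 1e-9

#: Knockout growth at or below this absolute value counts as no growth.
LETHAL_TOL = 1e-9


class SolverStatus(enum.Enum):
    OPTIMAL = "optimal"
    INFEASIBLE = "infeasible"
    UNBOUNDED = "unbounded"


class SolverError(RuntimeError):
    """The LP solver failed for a reason other than in/unboundedness."""


class DefaultExchangePolicy(enum.Enum):
    """Bounds applied to exchange reactions a medium does not list."""

    SECRETION_ONLY = "secretion_only"  # (0, +unbounded): may leave, not enter
    CLOSED = "closed"                  # (0, 0): no exchange at all


@dataclass(frozen=True)
class Medium:
    """External environment as exchange-reaction bounds.

    ``bounds`` maps exchange reaction ids to (lower, upper) flux bounds in
    mmol gDW^-1 h^-1.  Exchanges not listed get the ``default_policy``
    bounds; the standard choice, matching the convention that unused
    external metabolites may only leave the system, is secretion-only.
    """

    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    default_policy: DefaultExchangePolicy = DefaultExchangePolicy.SECRETION_ONLY
    name: str = "medium"

    def __post_init__(self) -> None:
        for rid, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ModelError(
                    f"medium {self.name}: bounds for {rid} reversed ({lo}>{hi})"
                )
        object.__setattr__(self, "bounds", dict(self.bounds))

    def bounds_for(self, reaction: Reaction) -> tuple[float, float]:
        if reaction.id in self.bounds:
            return self.bounds[reaction.id]
        if self.default_policy is DefaultExchangePolicy.SECRETION_ONLY:
            return (0.0, UNBOUNDED_FLUX)
        return (0.0, 0.0)


@dataclass(frozen=True)
class FluxSolution:
    status: SolverStatus
    objective: float
    fluxes: Mapping[str, float]

    @property
    def growth(self) -> float:
        """Objective value with infeasibility reported as zero growth."""
        if self.status is SolverStatus.OPTIMAL:
            return self.objective
        return 0.0


# ---------------------------------------------------------------------------
# Media presets
# ---------------------------------------------------------------------------

def build_medium(
    carbon_sources: Mapping[str, float],
    oxygen_exchange: Optional[str] = None,
    oxygen_uptake: float = 20.0,
    free_exchanges: Sequence[str] = (),
    name: str = "medium",
) -> Medium:
    """Assemble a medium from uptake allowances.

    ``carbon_sources`` maps exchange ids to maximum uptake rates (positive
    numbers; the lower bound becomes their negation).  ``free_exchanges``
    are the inorganic exchanges (ammonia, water, phosphate, sulphate,
    potassium, sodium, iron(II), carbon dioxide, protons) left fully
    unconstrained.  Everything else is secretion-only.
    """
    bounds: dict[str, tuple[float, float]] = {}
    for rid, uptake in carbon_sources.items():
        if uptake < 0:
            raise ModelError(f"uptake rate for {rid} must be non-negative")
        bounds[rid] = (-float(uptake), UNBOUNDED_FLUX)
    if oxygen_exchange is not None:
        bounds[oxygen_exchange] = (-float(oxygen_uptake), UNBOUNDED_FLUX)
    for rid in free_exchanges:
        bounds[rid] = (-UNBOUNDED_FLUX, UNBOUNDED_FLUX)
    return Medium(bounds=bounds, name=name)


def build_medium_minimal_glucose(
    glucose_exchange: str,
    oxygen_exchange: Optional[str] = None,
    free_exchanges: Sequence[str] = (),
    glucose_uptake: float = 6.0,
    oxygen_uptake: float = 20.0,
) -> Medium:
    """Minimal aerobic medium: glucose sole carbon source.

    Glucose uptake capped at 6 and oxygen at 20 mmol gDW^-1 h^-1, the
    bounds of the reference *E. coli* iJR904 minimal-glucose condition;
    inorganics unconstrained; every other exchange secretion-only.
    """
    return build_medium(
        {glucose_exchange: glucose_uptake},
        oxygen_exchange,
        oxygen_uptake,
        free_exchanges,
        name="minimal_glucose",
    )


def build_medium_glc_arg(
    glucose_exchange: str,
    arginine_exchange: str,
    oxygen_exchange: Optional[str] = None,
    free_exchanges: Sequence[str] = (),
    uptake: float = 6.0,
    oxygen_uptake: float = 20.0,
) -> Medium:
    """Nutrient-limited medium: glucose and L-arginine only.

    Both organic uptakes capped at 6 mmol gDW^-1 h^-1 (the generic uptake
    bound used for every organic nutrient here).
    """
    return build_medium(
        {glucose_exchange: uptake, arginine_exchange: uptake},
        oxygen_exchange,
        oxygen_uptake,
        free_exchanges,
        name="glc_arg",
    )


def build_medium_rich(
    network: MetabolicNetwork,
    nutrient_exchanges: Sequence[str],
    oxygen_exchange: Optional[str] = None,
    free_exchanges: Sequence[str] = (),
    uptake: float = 6.0,
    oxygen_uptake: float = 20.0,
) -> Medium:
    """Nutrient-rich medium: a configured list of organics at uptake 6.

    Every listed exchange must exist in the network; a missing one raises
    :class:`ModelError` naming it, since a silently ignored nutrient would
    make the two media conditions incomparable.
    """
    known = {r.id for r in network.exchange_reactions()}
    for rid in nutrient_exchanges:
        if rid not in known:
            raise ModelError(f"no exchange reaction {rid} in network")
    return build_medium(
        {rid: uptake for rid in nutrient_exchanges},
        oxygen_exchange,
        oxygen_uptake,
        free_exchanges,
        name="rich",
    )


# ---------------------------------------------------------------------------
# The LP
# ---------------------------------------------------------------------------

class FbaProblem:
    """Reusable FBA linear program for one network under one medium.

    Builds the sparse stoichiometric matrix once; knockouts are applied
    per solve as zero-bound overrides, so deletion scans and reductive
    simulations pay only the LP solve per evaluation.
    """

    def __init__(self, network: MetabolicNetwork, medium: Medium):
        if network.objective_id is None:
            raise ModelError("network has no objective/biomass reaction")
        self.network = network
        self.medium = medium
        mets = network.balanced_metabolites()
        self._met_index = {m.id: i for i, m in enumerate(mets)}
        self._rxn_index = {r.id: j for j, r in enumerate(network.reactions)}
        rows, cols, vals = [], [], []
        lo = np.empty(len(network.reactions))
        hi = np.empty(len(network.reactions))
        for j, r in enumerate(network.reactions):
            if r.kind is ReactionKind.EXCHANGE:
                # Medium bounds replace the model's exchange bounds, except
                # that a (0, 0) clamp marks an exchange knocked out by
                # delete_reactions and is honoured as such.
                if r.lower_bound == 0.0 and r.upper_bound == 0.0:
                    lo[j], hi[j] = 0.0, 0.0
                else:
                    lo[j], hi[j] = medium.bounds_for(r)
            else:
                lo[j], hi[j] = r.lower_bound, r.upper_bound
            for mid, coef in r.stoichiometry.items():
                i = self._met_index.get(mid)
                if i is not None and coef != 0.0:
                    rows.append(i)
                    cols.append(j)
                    vals.append(float(coef))
        self._S = sparse.csr_matrix(
            (vals, (rows, cols)),
            shape=(len(mets), len(network.reactions)),
        )
        self._lo = lo
        self._hi = hi
        c = np.zeros(len(network.reactions))
        c[self._rxn_index[network.objective_id]] = -1.0  # linprog minimises
        self._c = c

    def solve(self, disabled: Iterable[str] = ()) -> FluxSolution:
        """Maximise biomass with the given reactions clamped to zero flux."""
        lo = self._lo.copy()
        hi = self._hi.copy()
        for rid in disabled:
            j = self._rxn_index.get(rid)
            if j is None:
                raise ModelError(f"unknown reaction {rid}")
            lo[j] = hi[j] = 0.0
        res = linprog(
            self._c,
            A_eq=self._S,
            b_eq=np.zeros(self._S.shape[0]),
            bounds=np.column_stack([lo, hi]),
            method="highs",
        )
        if res.status == 0:
            fluxes = {
                rid: (0.0 if abs(res.x[j]) < FLUX_ZERO_TOL else float(res.x[j]))
                for rid, j in self._rxn_index.items()
            }
            return FluxSolution(SolverStatus.OPTIMAL, float(-res.fun) + 0.0, fluxes)
        if res.status == 2:
            return FluxSolution(SolverStatus.INFEASIBLE, 0.0, {})
        if res.status == 3:
            return FluxSolution(SolverStatus.UNBOUNDED, float("inf"), {})
        raise SolverError(f"LP solver failed: status {res.status}: {res.message}")


def solve_fba(network: MetabolicNetwork, medium: Medium) -> FluxSolution:
    """One-shot FBA: maximise biomass flux under the given medium."""
    return FbaProblem(network, medium).solve()


# ---------------------------------------------------------------------------
# Knockouts
# ---------------------------------------------------------------------------

def reactions_disabled_by_genes(
    network: MetabolicNetwork, gene_ids: Iterable[str]
) -> frozenset[str]:
    """Reactions whose GPR evaluates false with the given genes inactive.

    Reactions without a gene assignment are never affected.
    """
    inactive = set(gene_ids)
    unknown = inactive - network.genes.keys()
    if unknown:
        raise ModelError(f"unknown genes: {sorted(unknown)}")
    out = set()
    for r in network.reactions:
        if r.gpr is not None and not evaluate_gpr(r.gpr, inactive):
            out.add(r.id)
    return frozenset(out)


def _constrain(network: MetabolicNetwork, rids: frozenset[str]) -> MetabolicNetwork:
    out = network.copy()
    out.reactions = [
        replace(r, lower_bound=0.0, upper_bound=0.0) if r.id in rids else r
        for r in network.reactions
    ]
    return out


def delete_reactions(
    network: MetabolicNetwork, reaction_ids: Iterable[str]
) -> MetabolicNetwork:
    """Knock out reactions by clamping their flux bounds to (0, 0).

    The network structure is otherwise untouched, so the deletion is
    reversible by restoring bounds.  Deleting the biomass reaction is
    rejected: it would make every downstream growth comparison vacuous.
    """
    rids = frozenset(reaction_ids)
    unknown = rids - set(network.reaction_ids)
    if unknown:
        raise ModelError(f"unknown reactions: {sorted(unknown)}")
    if network.objective_id in rids:
        raise ModelError("refusing to delete the biomass reaction")
    return _constrain(network, rids)


def delete_genes(
    network: MetabolicNetwork, gene_ids: Iterable[str]
) -> MetabolicNetwork:
    """Knock out genes: disable every reaction whose GPR fails without them."""
    return _constrain(network, reactions_disabled_by_genes(network, gene_ids))
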