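"""Ancestral-to-extant network derivation and reductive-evolution
simulation.

Two evolutionary operations live here.  :func:`derive_extant` applies a
table of gene statuses to an ancestral reconstruction: reactions whose
GPR cannot be satisfied once pseudogenes and deleted genes are switched
off are removed outright, and orphaned genes/metabolites pruned — this
is how a pseudogenised complex subunit drags its still-functional
partners out of the network.

:func:`reduce_once` performs one stochastic reductive-evolution run: the
internal reactions are visited in one uniformly random permutation; each
is tentatively clamped to zero flux, and the removal is made permanent
iff biomass production in the reduced network stays above a cutoff
fraction of the *original* wild-type rate.  Because adding constraints
can only lower an LP optimum, a reaction kept at its turn can never
become removable later — a single pass therefore yields a genuinely
minimal network at the given cutoff.  :func:`run_ensemble` repeats this
over replicates and cutoffs and summarises the resulting ensemble
(means, standard errors, core and always-absent sets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .fba_engine import FbaProblem, LETHAL_TOL, Medium
from .model_core import (
    GeneStatus,
    MetabolicNetwork,
    ModelError,
    ReactionKind,
    prune_orphans,
    simplify_gpr,
)

logger = logging.getLogger(__name__)

#: Strictness margin for the "above cutoff" survival test.
CUTOFF_MARGIN = 1e-9


# ---------------------------------------------------------------------------
# Ancestral -> extant derivation
# ---------------------------------------------------------------------------

def derive_extant(
    ancestral: MetabolicNetwork,
    status: Mapping[str, GeneStatus],
    network_id: Optional[str] = None,
) -> MetabolicNetwork:
    """Derive the extant (functional) network from gene statuses.

    Genes marked pseudogene or deleted are switched off; every reaction
    whose GPR evaluates false under that assignment is removed entirely
    (an AND complex dies with any one subunit; an OR isozyme set survives
    while one member is functional).  Genes and metabolites left without
    any reaction are pruned, and surviving genes carry their annotated
    status.  Reactions without a gene assignment are retained.
    """
    inactive = {
        g for g, s in status.items()
        if s in (GeneStatus.PSEUDOGENE, GeneStatus.DELETED)
    }
    unknown = inactive - ancestral.genes.keys()
    if unknown:
        raise ModelError(
            f"status table names genes absent from the network: "
            f"{sorted(unknown)[:5]}..."
            if len(unknown) > 5
            else f"status table names genes absent from the network: "
                 f"{sorted(unknown)}"
        )
    kept = []
    for r in ancestral.reactions:
        satisfiable, simplified = simplify_gpr(r.gpr, inactive)
        if satisfiable:
            # surviving reactions keep only their functional gene leaves
            kept.append(replace(r, gpr=simplified))
    kept_ids = {r.id for r in kept}
    if ancestral.objective_id is not None and (
        ancestral.objective_id not in kept_ids
    ):
        raise ModelError(
            "biomass reaction's GPR is disabled by the status table"
        )
    out = ancestral.copy()
    out.reactions = kept
    out.id = network_id or f"{ancestral.id}_extant"
    out = prune_orphans(out)
    out.genes = {
        g: type(gp)(g, status.get(g, GeneStatus.FUNCTIONAL))
        for g, gp in out.genes.items()
    }
    return out


def annotate_statuses(
    network: MetabolicNetwork, status: Mapping[str, GeneStatus]
) -> MetabolicNetwork:
    """Return a copy with gene statuses taken from the table (default
    functional)."""
    out = network.copy()
    out.genes = {
        g: type(gp)(g, status.get(g, GeneStatus.FUNCTIONAL))
        for g, gp in network.genes.items()
    }
    return out


# ---------------------------------------------------------------------------
# Reductive-evolution simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReductionConfig:
    """Parameters of the reductive-evolution ensemble.

    ``cutoffs`` are viability thresholds as fractions of the original
    wild-type biomass rate (the reference reduction study used 0.1, 0.05
    and 0.01 with 500 replicates each).  ``removable_kinds`` defaults to
    internal reactions only: the environment (exchanges) is fixed per
    condition and the biomass equation is the fitness proxy itself.
    """

    cutoffs: tuple[float, ...] = (0.1, 0.05, 0.01)
    replicates: int = 500
    seed: int = 0
    removable_kinds: tuple[ReactionKind, ...] = (ReactionKind.INTERNAL,)

    def __post_init__(self) -> None:
        for c in self.cutoffs:
            if not 0.0 < c < 1.0:
                raise ModelError(f"cutoff {c} outside (0, 1)")
        if self.replicates < 1:
            raise ModelError("replicates must be >= 1")
        if ReactionKind.BIOMASS in self.removable_kinds:
            raise ModelError("the biomass reaction is never removable")


@dataclass(frozen=True)
class MinimalNetwork:
    """One reductive-evolution outcome: what survived the run."""

    retained_reactions: frozenset[str]
    retained_genes: frozenset[str]
    cutoff: float
    seed: int
    replicate: int
    objective: float

    @property
    def n_internal_reactions(self) -> int:
        return len(self.retained_reactions)

    @property
    def n_genes(self) -> int:
        return len(self.retained_genes)


def _removable_ids(
    network: MetabolicNetwork, kinds: tuple[ReactionKind, ...]
) -> list[str]:
    return [
        r.id for r in network.reactions
        if r.kind in kinds and r.id != network.objective_id
    ]


def _replicate_rng(master_seed: int, cutoff_index: int, replicate: int):
    """Deterministic per-replicate generator: the master seed plus the
    (cutoff, replicate) counter pair as a spawn key."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(cutoff_index, replicate))
    )


def reduce_once(
    network: MetabolicNetwork,
    medium: Medium,
    cutoff: float,
    rng: np.random.Generator,
    removable_kinds: tuple[ReactionKind, ...] = (ReactionKind.INTERNAL,),
    problem: Optional[FbaProblem] = None,
    seed: int = -1,
    replicate: int = 0,
) -> MinimalNetwork:
    """One reductive-evolution run over a random reaction permutation.

    Every removable reaction is evaluated exactly once, in permutation
    order; a removal is kept when the reduced network's biomass rate
    stays strictly above ``cutoff`` times the original wild-type rate.
    The baseline never changes during the run.  Genes are retained iff
    they appear in at least one retained reaction's GPR, making the gene
    set a pure function of the surviving reaction set.
    """
    problem = problem or FbaProblem(network, medium)
    b0 = problem.solve().growth
    if b0 <= LETHAL_TOL:
        raise ModelError(
            f"wild type does not grow on {medium.name}; nothing to reduce"
        )
    threshold = cutoff * b0 + CUTOFF_MARGIN
    candidates = _removable_ids(network, removable_kinds)
    order = [candidates[i] for i in rng.permutation(len(candidates))]
    removed: set[str] = set()
    for rid in order:
        trial = problem.solve(removed | {rid}).growth
        if trial > threshold:
            removed.add(rid)
    retained = frozenset(
        r.id for r in network.internal_reactions() if r.id not in removed
    )
    genes = frozenset().union(
        *(
            network.reaction(rid).genes
            for rid in retained
        )
    ) if retained else frozenset()
    final = problem.solve(removed).growth
    return MinimalNetwork(
        retained_reactions=retained,
        retained_genes=genes,
        cutoff=cutoff,
        seed=seed,
        replicate=replicate,
        objective=final,
    )


@dataclass(frozen=True)
class CutoffSummary:
    cutoff: float
    n_replicates: int
    mean_reactions: float
    se_reactions: float
    mean_genes: float
    se_genes: float
    core_reactions: frozenset[str]
    absent_reactions: frozenset[str]
    core_genes: frozenset[str]
    absent_genes: frozenset[str]


@dataclass(frozen=True)
class EnsembleSummary:
    """Summary of a reductive-evolution ensemble over all cutoffs.

    ``core_*`` sets contain items present in every minimal network
    (pooled across cutoffs); ``absent_*`` sets items present in none.
    The pooled means aggregate all replicates of all cutoffs, mirroring
    the "total" column of ensemble-statistics tables.
    """

    network_id: str
    medium_name: str
    wild_type_growth: float
    all_internal_reactions: frozenset[str]
    all_genes: frozenset[str]
    per_cutoff: tuple[CutoffSummary, ...]
    replicates: tuple[MinimalNetwork, ...]

    @property
    def n_networks(self) -> int:
        return len(self.replicates)

    @property
    def mean_reactions(self) -> float:
        return float(np.mean([m.n_internal_reactions for m in self.replicates]))

    @property
    def se_reactions(self) -> float:
        return _standard_error([m.n_internal_reactions for m in self.replicates])

    @property
    def mean_genes(self) -> float:
        return float(np.mean([m.n_genes for m in self.replicates]))

    @property
    def se_genes(self) -> float:
        return _standard_error([m.n_genes for m in self.replicates])

    @property
    def core_reactions(self) -> frozenset[str]:
        return frozenset.intersection(
            *(m.retained_reactions for m in self.replicates)
        )

    @property
    def absent_reactions(self) -> frozenset[str]:
        return self.all_internal_reactions - frozenset.union(
            *(m.retained_reactions for m in self.replicates)
        )

    @property
    def core_genes(self) -> frozenset[str]:
        return frozenset.intersection(
            *(m.retained_genes for m in self.replicates)
        )

    @property
    def absent_genes(self) -> frozenset[str]:
        return self.all_genes - frozenset.union(
            *(m.retained_genes for m in self.replicates)
        )

    @property
    def core_reaction_fraction(self) -> float:
        """Core reactions as a fraction of the mean minimal-network size."""
        return len(self.core_reactions) / self.mean_reactions

    @property
    def core_gene_fraction(self) -> float:
        return len(self.core_genes) / self.mean_genes

    def to_table(self) -> pd.DataFrame:
        rows = []
        for cs in self.per_cutoff:
            rows.append(
                {
                    "cutoff": cs.cutoff,
                    "n_networks": cs.n_replicates,
                    "mean_genes": cs.mean_genes,
                    "se_genes": cs.se_genes,
                    "mean_reactions": cs.mean_reactions,
                    "se_reactions": cs.se_reactions,
                    "common_genes": len(cs.core_genes),
                    "absent_genes": len(cs.absent_genes),
                    "common_reactions": len(cs.core_reactions),
                    "absent_reactions": len(cs.absent_reactions),
                }
            )
        rows.append(
            {
                "cutoff": "pooled",
                "n_networks": self.n_networks,
                "mean_genes": self.mean_genes,
                "se_genes": self.se_genes,
                "mean_reactions": self.mean_reactions,
                "se_reactions": self.se_reactions,
                "common_genes": len(self.core_genes),
                "absent_genes": len(self.absent_genes),
                "common_reactions": len(self.core_reactions),
                "absent_reactions": len(self.absent_reactions),
            }
        )
        return pd.DataFrame(rows)


def _standard_error(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        return 0.0
    return float(arr.std(ddof=1) / np.sqrt(arr.size))


def run_ensemble(
    network: MetabolicNetwork,
    medium: Medium,
    config: ReductionConfig,
) -> EnsembleSummary:
    """Run replicates × cutoffs independent reductive-evolution runs.

    Per-replicate RNGs are derived from the master seed and a
    (cutoff index, replicate index) counter, so the ensemble is bitwise
    reproducible per seed and invariant to execution order.
    """
    problem = FbaProblem(network, medium)
    wt = problem.solve().growth
    all_internal = frozenset(r.id for r in network.internal_reactions())
    all_genes = frozenset(network.genes)
    minimals: list[MinimalNetwork] = []
    per_cutoff: list[CutoffSummary] = []
    for ci, cutoff in enumerate(config.cutoffs):
        batch = []
        for rep in range(config.replicates):
            rng = _replicate_rng(config.seed, ci, rep)
            m = reduce_once(
                network,
                medium,
                cutoff,
                rng,
                config.removable_kinds,
                problem=problem,
                seed=config.seed,
                replicate=rep,
            )
            batch.append(m)
        logger.info(
            "cutoff %.3g: %d replicates, mean %.2f reactions",
            cutoff,
            len(batch),
            np.mean([m.n_internal_reactions for m in batch]),
        )
        per_cutoff.append(
            CutoffSummary(
                cutoff=cutoff,
                n_replicates=len(batch),
                mean_reactions=float(
                    np.mean([m.n_internal_reactions for m in batch])
                ),
                se_reactions=_standard_error(
                    [m.n_internal_reactions for m in batch]
                ),
                mean_genes=float(np.mean([m.n_genes for m in batch])),
                se_genes=_standard_error([m.n_genes for m in batch]),
                core_reactions=frozenset.intersection(
                    *(m.retained_reactions for m in batch)
                ),
                absent_reactions=all_internal
                - frozenset.union(*(m.retained_reactions for m in batch)),
                core_genes=frozenset.intersection(
                    *(m.retained_genes for m in batch)
                ),
                absent_genes=all_genes
                - frozenset.union(*(m.retained_genes for m in batch)),
            )
        )
        minimals.extend(batch)
    return EnsembleSummary(
        network_id=network.id,
        medium_name=medium.name,
        wild_type_growth=wt,
        all_internal_reactions=all_internal,
        all_genes=all_genes,
        per_cutoff=tuple(per_cutoff),
        replicates=tuple(minimals),
    )


# ---------------------------------------------------------------------------
# Cross-condition classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossConditionClassification:
    """Essential / conditionally essential / disposable partition.

    * always-essential: core of the minimal-network ensembles under both
      the nutrient-limited and the nutrient-rich condition;
    * conditionally essential: core under the limited condition only —
      candidates for loss should the organism's environment stay rich;
    * disposable: absent from every minimal network under both.
    """

    always_essential_genes: frozenset[str]
    always_essential_reactions: frozenset[str]
    conditionally_essential_genes: frozenset[str]
    conditionally_essential_reactions: frozenset[str]
    disposable_genes: frozenset[str]
    disposable_reactions: frozenset[str]


def classify_across_conditions(
    summary_limited: EnsembleSummary,
    summary_rich: EnsembleSummary,
) -> CrossConditionClassification:
    """Compare minimal-network ensembles across two media."""
    if (
        summary_limited.all_internal_reactions
        != summary_rich.all_internal_reactions
        or summary_limited.all_genes != summary_rich.all_genes
    ):
        raise ModelError("summaries derive from different input networks")
    return CrossConditionClassification(
        always_essential_genes=(
            summary_limited.core_genes & summary_rich.core_genes
        ),
        always_essential_reactions=(
            summary_limited.core_reactions & summary_rich.core_reactions
        ),
        conditionally_essential_genes=(
            summary_limited.core_genes - summary_rich.core_genes
        ),
        conditionally_essential_reactions=(
            summary_limited.core_reactions - summary_rich.core_reactions
        ),
        disposable_genes=(
            summary_limited.absent_genes & summary_rich.absent_genes
        ),
        disposable_reactions=(
            summary_limited.absent_reactions & summary_rich.absent_reactions
        ),
    )


def audit_minimality(
    network: MetabolicNetwork,
    medium: Medium,
    minimal: MinimalNetwork,
    problem: Optional[FbaProblem] = None,
) -> bool:
    """Check that no single retained removable reaction can still go.

    Re-deletes each retained internal reaction from the final network and
    verifies the objective drops to or below cutoff x original wild type.
    LP monotonicity guarantees this for the single-pass procedure; the
    audit makes the guarantee observable.
    """
    problem = problem or FbaProblem(network, medium)
    b0 = problem.solve().growth
    threshold = minimal.cutoff * b0 + CUTOFF_MARGIN
    removed = frozenset(
        r.id for r in network.internal_reactions()
    ) - minimal.retained_reactions
    for rid in minimal.retained_reactions:
        if rid == network.objective_id:
            continue
        obj = problem.solve(removed | {rid}).growth
        if obj > threshold:
            return False
    return True
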