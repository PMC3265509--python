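"""Gene-knockout robustness scans.

Single-gene deletions classify every gene by the growth of its knockout
network relative to wild type; double-gene deletions over the singly
non-lethal genes enumerate synthetic-lethal pairs.  Two essentiality
notions coexist in the robustness literature and both are reported here:

* *lethal*: knockout growth indistinguishable from zero (absolute
  tolerance, default 1e-9) — the criterion behind "deletion renders a
  biomass production rate of 0";
* *essential_99*: knockout growth below 1% of wild type — the criterion
  behind "deletion decreases original biomass production by over 99%".

Lethal genes are a subset of essential_99 genes whenever wild-type
growth is positive.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .fba_engine import FbaProblem, LETHAL_TOL, Medium, reactions_disabled_by_genes
from .model_core import MetabolicNetwork, ModelError, evaluate_gpr, gpr_to_dnf

logger = logging.getLogger(__name__)

#: Default growth fraction below which a knockout counts as >99% impaired.
ESSENTIAL_FRACTION = 0.01


@dataclass(frozen=True)
class EssentialityReport:
    """Outcome of a single-gene deletion scan."""

    network_id: str
    medium_name: str
    wild_type_growth: float
    table: pd.DataFrame  # index: gene; columns: ko_growth, fraction, class
    lethal_tol: float = LETHAL_TOL
    essential_fraction: float = ESSENTIAL_FRACTION

    @property
    def lethal_genes(self) -> frozenset[str]:
        return frozenset(self.table.index[self.table["class"] == "lethal"])

    @property
    def essential_99_genes(self) -> frozenset[str]:
        """Genes whose loss removes >99% of growth (includes lethal ones)."""
        return frozenset(
            self.table.index[
                self.table["fraction"] < self.essential_fraction
            ]
        )

    @property
    def nonlethal_genes(self) -> frozenset[str]:
        return frozenset(self.table.index) - self.lethal_genes


@dataclass(frozen=True)
class SyntheticLethalSet:
    """Unordered gene pairs whose joint loss abolishes growth."""

    network_id: str
    medium_name: str
    pairs: frozenset[frozenset[str]]
    candidate_genes: frozenset[str]
    lethal_tol: float = LETHAL_TOL

    def __post_init__(self) -> None:
        for pair in self.pairs:
            if len(pair) != 2:
                raise ModelError(f"not a pair: {sorted(pair)}")
            if not pair <= self.candidate_genes:
                raise ModelError(
                    f"pair {sorted(pair)} contains a singly lethal gene"
                )

    def __len__(self) -> int:
        return len(self.pairs)


def single_gene_deletion_scan(
    network: MetabolicNetwork,
    medium: Medium,
    lethal_tol: float = LETHAL_TOL,
    essential_fraction: float = ESSENTIAL_FRACTION,
    problem: Optional[FbaProblem] = None,
) -> EssentialityReport:
    """Knock out each gene in turn and classify by relative growth.

    One LP per distinct disabled-reaction set: genes whose GPRs disable
    identical reaction sets share a solve, and genes disabling nothing
    (isozyme-buffered or absent from all GPRs) inherit wild-type growth
    without a solve.
    """
    problem = problem or FbaProblem(network, medium)
    wt = problem.solve().growth
    if wt <= lethal_tol:
        raise ModelError(
            f"wild type does not grow on {medium.name} "
            f"(objective {wt!r}); essentiality is undefined"
        )
    cache: dict[frozenset[str], float] = {frozenset(): wt}
    rows = []
    for i, gene in enumerate(sorted(network.genes)):
        disabled = reactions_disabled_by_genes(network, {gene})
        if disabled not in cache:
            cache[disabled] = problem.solve(disabled).growth
        growth = cache[disabled]
        fraction = min(max(growth / wt, 0.0), 1.0)
        if growth <= lethal_tol:
            cls = "lethal"
        elif fraction < essential_fraction:
            cls = "essential_99"
        else:
            cls = "nonessential"
        rows.append((gene, growth, fraction, cls))
        if (i + 1) % 50 == 0:
            logger.info("single-deletion scan: %d genes done", i + 1)
    table = pd.DataFrame(
        rows, columns=["gene", "ko_growth", "fraction", "class"]
    ).set_index("gene")
    return EssentialityReport(
        network_id=network.id,
        medium_name=medium.name,
        wild_type_growth=wt,
        table=table,
        lethal_tol=lethal_tol,
        essential_fraction=essential_fraction,
    )


def double_gene_deletion_scan(
    network: MetabolicNetwork,
    medium: Medium,
    report: EssentialityReport,
    lethal_tol: float = LETHAL_TOL,
    problem: Optional[FbaProblem] = None,
) -> SyntheticLethalSet:
    """Enumerate synthetic-lethal pairs among singly non-lethal genes.

    Restricting to non-lethal genes avoids the masking effect of genes
    that are already lethal on their own.  All n·(n-1)/2 unordered pairs
    are evaluated; a pair is synthetic lethal when the joint knockout's
    growth falls to zero (absolute tolerance).
    """
    if report.network_id != network.id:
        raise ModelError("essentiality report computed on a different network")
    problem = problem or FbaProblem(network, medium)
    candidates = sorted(report.nonlethal_genes)
    single_disabled = {
        g: reactions_disabled_by_genes(network, {g}) for g in candidates
    }
    # GPR evaluation is not modular (an isozyme pair falls only jointly),
    # so the joint disabled set must be recomputed per pair — but only
    # reactions whose GPR touches either gene can change state.
    touching: dict[str, list] = {g: [] for g in candidates}
    for r in network.reactions:
        if r.gpr is None:
            continue
        for g in r.genes:
            if g in touching:
                touching[g].append(r)
    cache: dict[frozenset[str], float] = {}
    pairs: set[frozenset[str]] = set()
    n_pairs = 0
    for g1, g2 in itertools.combinations(candidates, 2):
        inactive = {g1, g2}
        joint: set[str] = set()
        for r in touching[g1]:
            if not evaluate_gpr(r.gpr, inactive):
                joint.add(r.id)
        for r in touching[g2]:
            if not evaluate_gpr(r.gpr, inactive):
                joint.add(r.id)
        disabled = frozenset(joint)
        # A pair whose joint knockout equals a single non-lethal knockout
        # network inherits that growth without an LP.
        if disabled == single_disabled[g1]:
            growth = report.table.at[g1, "ko_growth"]
        elif disabled == single_disabled[g2]:
            growth = report.table.at[g2, "ko_growth"]
        else:
            if disabled not in cache:
                cache[disabled] = problem.solve(disabled).growth
            growth = cache[disabled]
        if growth <= lethal_tol:
            pairs.add(frozenset((g1, g2)))
        n_pairs += 1
        if n_pairs % 500 == 0:
            logger.info("double-deletion scan: %d pairs done", n_pairs)
    return SyntheticLethalSet(
        network_id=network.id,
        medium_name=medium.name,
        pairs=frozenset(pairs),
        candidate_genes=frozenset(candidates),
        lethal_tol=lethal_tol,
    )


def count_isozyme_reactions(network: MetabolicNetwork) -> int:
    """Number of reactions catalysed by alternative enzymes.

    A reaction counts when its GPR, normalised to disjunctive form with
    absorption, has at least two disjuncts — i.e. at least two distinct
    gene sets can each supply the activity.
    """
    return sum(
        1 for r in network.reactions if len(gpr_to_dnf(r.gpr)) >= 2
    )
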