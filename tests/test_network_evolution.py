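"""Extant derivation, reductive-evolution runs, and cross-condition sets."""

import numpy as np
import pytest

from redevo import (
    Compartment,
    FbaProblem,
    GeneProduct,
    GeneRef,
    GeneStatus,
    GprAnd,
    Medium,
    Metabolite,
    MetabolicNetwork,
    ModelError,
    Reaction,
    ReactionKind,
    ReductionConfig,
    audit_minimality,
    classify_across_conditions,
    derive_extant,
    make_pseudogenization_scenario,
    reduce_once,
    run_ensemble,
    single_gene_deletion_scan,
    solve_fba,
)
from redevo.network_evolution import _replicate_rng


class TestDeriveExtant:
    def test_all_functional_is_identity_after_pruning(self, toy):
        status = {g: GeneStatus.FUNCTIONAL for g in toy.network.genes}
        extant = derive_extant(toy.network, status)
        assert [r.id for r in extant.reactions] == \
            [r.id for r in toy.network.reactions]
        assert set(extant.genes) == set(toy.network.genes)

    def test_pseudogenised_pathway_reactions_removed(self, toy):
        status = make_pseudogenization_scenario(
            toy.network, ["glycogen-synthesis"]
        )
        extant = derive_extant(toy.network, status)
        gone = {"GLGC", "GLGA"}
        assert gone.isdisjoint({r.id for r in extant.reactions})
        assert "glgA" not in extant.genes and "glgC" not in extant.genes
        # orphaned metabolites pruned too
        assert "adpg" not in extant.metabolites

    def test_complex_partner_gene_dragged_out(self):
        """A functional subunit is removed when its complex partner is
        pseudogenised and it occurs nowhere else."""
        mets = {
            "x_e": Metabolite("x_e", compartment=Compartment.EXTRACELLULAR),
            "x": Metabolite("x"),
        }
        rxns = [
            Reaction("EX_x", {"x_e": -1}, -5, 1e6, kind=ReactionKind.EXCHANGE),
            Reaction("T", {"x_e": -1, "x": 1}, 0, 1e6,
                     GprAnd((GeneRef("g_f"), GeneRef("g_ps")))),
            Reaction("BM", {"x": -1}, 0, 1e6, kind=ReactionKind.BIOMASS),
        ]
        net = MetabolicNetwork(
            genes={"g_f": GeneProduct("g_f"), "g_ps": GeneProduct("g_ps")},
            metabolites=mets, reactions=rxns, objective_id="BM", id="mini",
        )
        net.validate()
        extant = derive_extant(net, {"g_ps": GeneStatus.PSEUDOGENE})
        assert {r.id for r in extant.reactions} == {"EX_x", "BM"}
        assert "g_f" not in extant.genes

    def test_isozyme_backup_preserves_reaction(self, toy):
        status = {g: GeneStatus.FUNCTIONAL for g in toy.network.genes}
        status["pfkA"] = GeneStatus.PSEUDOGENE
        extant = derive_extant(toy.network, status)
        assert "GLY1" in {r.id for r in extant.reactions}
        assert "pfkA" not in extant.genes and "pfkB" in extant.genes

    def test_unknown_status_gene_rejected(self, toy):
        with pytest.raises(ModelError):
            derive_extant(toy.network, {"ghost": GeneStatus.PSEUDOGENE})

    def test_disabled_biomass_gpr_rejected(self):
        mets = {
            "x_e": Metabolite("x_e", compartment=Compartment.EXTRACELLULAR),
            "x": Metabolite("x"),
        }
        rxns = [
            Reaction("EX_x", {"x_e": -1}, -5, 1e6, kind=ReactionKind.EXCHANGE),
            Reaction("T", {"x_e": -1, "x": 1}, 0, 1e6, None),
            Reaction("BM", {"x": -1}, 0, 1e6, GeneRef("g_bm"),
                     kind=ReactionKind.BIOMASS),
        ]
        net = MetabolicNetwork(
            genes={"g_bm": GeneProduct("g_bm")},
            metabolites=mets, reactions=rxns, objective_id="BM", id="mini",
        )
        with pytest.raises(ModelError, match="biomass"):
            derive_extant(net, {"g_bm": GeneStatus.PSEUDOGENE})


def _parallel_paths_network():
    """Two equivalent routes from substrate to biomass precursor."""
    mets = {
        "s_e": Metabolite("s_e", compartment=Compartment.EXTRACELLULAR),
        "a": Metabolite("a"),
        "b": Metabolite("b"),
    }
    rxns = [
        Reaction("EX_s", {"s_e": -1}, -10, 1e6, kind=ReactionKind.EXCHANGE),
        Reaction("T", {"s_e": -1, "a": 1}, 0, 1e6, GeneRef("gT")),
        Reaction("PATH_A", {"a": -1, "b": 1}, 0, 1e6, GeneRef("gA")),
        Reaction("PATH_B", {"a": -1, "b": 1}, 0, 1e6, GeneRef("gB")),
        Reaction("BM", {"b": -1}, 0, 1e6, kind=ReactionKind.BIOMASS),
    ]
    net = MetabolicNetwork(
        genes={g: GeneProduct(g) for g in ("gT", "gA", "gB")},
        metabolites=mets, reactions=rxns, objective_id="BM", id="parallel",
    )
    net.validate()
    return net, Medium(bounds={"EX_s": (-10, 1e6)}, name="ref")


class TestReduceOnce:
    def test_fully_essential_network_unchanged(self):
        net, medium = _parallel_paths_network()
        net2 = net.copy()
        net2.reactions = [r for r in net.reactions if r.id != "PATH_B"]
        rng = np.random.default_rng(0)
        minimal = reduce_once(net2, medium, 0.01, rng)
        assert minimal.retained_reactions == {"T", "PATH_A", "BM"}

    def test_parallel_paths_keep_exactly_one_each_run(self):
        net, medium = _parallel_paths_network()
        outcomes = set()
        for seed in range(8):
            rng = np.random.default_rng(seed)
            minimal = reduce_once(net, medium, 0.01, rng)
            kept_paths = minimal.retained_reactions & {"PATH_A", "PATH_B"}
            assert len(kept_paths) == 1
            outcomes |= kept_paths
        # both permutation classes occur across seeds
        assert outcomes == {"PATH_A", "PATH_B"}

    def test_gene_set_follows_reaction_set(self):
        net, medium = _parallel_paths_network()
        rng = np.random.default_rng(3)
        minimal = reduce_once(net, medium, 0.01, rng)
        expected = frozenset().union(
            *(net.reaction(rid).genes for rid in minimal.retained_reactions)
        )
        assert minimal.retained_genes == expected

    def test_minimality_audit_on_toy_runs(self, toy):
        problem = FbaProblem(toy.network, toy.glc_arg)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            minimal = reduce_once(
                toy.network, toy.glc_arg, 0.1, rng, problem=problem
            )
            assert audit_minimality(
                toy.network, toy.glc_arg, minimal, problem=problem
            )

    def test_objective_above_cutoff(self, toy):
        rng = np.random.default_rng(1)
        b0 = solve_fba(toy.network, toy.glc_arg).growth
        minimal = reduce_once(toy.network, toy.glc_arg, 0.05, rng)
        assert minimal.objective > 0.05 * b0
        assert "BIOMASS" in minimal.retained_reactions

    def test_refuses_nonviable_wild_type(self, toy):
        with pytest.raises(ModelError):
            reduce_once(
                toy.network, Medium(bounds={}, name="empty"), 0.1,
                np.random.default_rng(0),
            )


@pytest.fixture(scope="module")
def ensembles(toy):
    config = ReductionConfig(cutoffs=(0.1, 0.05, 0.01), replicates=8,
                             seed=123)
    limited = run_ensemble(toy.network, toy.glc_arg, config)
    rich = run_ensemble(toy.network, toy.rich, config)
    return limited, rich


class TestEnsemble:
    def test_bitwise_reproducible_per_seed(self, toy):
        config = ReductionConfig(cutoffs=(0.1,), replicates=3, seed=9)
        a = run_ensemble(toy.network, toy.glc_arg, config)
        b = run_ensemble(toy.network, toy.glc_arg, config)
        assert [m.retained_reactions for m in a.replicates] == \
            [m.retained_reactions for m in b.replicates]

    def test_different_seeds_differ(self, toy):
        c1 = ReductionConfig(cutoffs=(0.1,), replicates=4, seed=1)
        c2 = ReductionConfig(cutoffs=(0.1,), replicates=4, seed=2)
        a = run_ensemble(toy.network, toy.glc_arg, c1)
        b = run_ensemble(toy.network, toy.glc_arg, c2)
        assert [m.retained_reactions for m in a.replicates] != \
            [m.retained_reactions for m in b.replicates]

    def test_single_replicate_summary(self, toy):
        config = ReductionConfig(cutoffs=(0.1,), replicates=1, seed=4)
        s = run_ensemble(toy.network, toy.glc_arg, config)
        m = s.replicates[0]
        assert s.mean_reactions == m.n_internal_reactions
        assert s.se_reactions == 0.0
        assert s.core_reactions == m.retained_reactions

    def test_core_within_every_replicate(self, ensembles):
        limited, _ = ensembles
        for m in limited.replicates:
            assert limited.core_reactions <= m.retained_reactions
            assert limited.core_genes <= m.retained_genes

    def test_absent_disjoint_from_every_replicate(self, ensembles):
        limited, _ = ensembles
        for m in limited.replicates:
            assert limited.absent_reactions.isdisjoint(m.retained_reactions)
            assert limited.absent_genes.isdisjoint(m.retained_genes)

    def test_rich_core_nested_in_limited_core(self, ensembles):
        """A reaction essential under the rich medium (core of its minimal
        networks) must be essential under the nutrient-limited medium."""
        limited, rich = ensembles
        assert rich.core_reactions <= limited.core_reactions

    def test_rich_minimal_networks_smaller(self, ensembles):
        """Salvage transporters let the rich medium shed biosynthesis."""
        limited, rich = ensembles
        assert rich.mean_reactions < limited.mean_reactions

    def test_summary_table_layout(self, ensembles):
        limited, _ = ensembles
        table = limited.to_table()
        assert list(table["cutoff"]) == [0.1, 0.05, 0.01, "pooled"]
        assert (table["n_networks"][:3] == 8).all()
        assert table["n_networks"].iloc[-1] == 24

    def test_seed_scheme_counter_distinct(self):
        r1 = _replicate_rng(0, 0, 0).integers(0, 2**31)
        r2 = _replicate_rng(0, 0, 1).integers(0, 2**31)
        r3 = _replicate_rng(0, 1, 0).integers(0, 2**31)
        assert len({int(r1), int(r2), int(r3)}) == 3


class TestClassification:
    def test_handcrafted_set_algebra(self, toy):
        config = ReductionConfig(cutoffs=(0.1,), replicates=2, seed=7)
        limited = run_ensemble(toy.network, toy.glc_arg, config)
        rich = run_ensemble(toy.network, toy.rich, config)
        cls = classify_across_conditions(limited, rich)
        assert cls.always_essential_genes == \
            limited.core_genes & rich.core_genes
        assert cls.conditionally_essential_genes == \
            limited.core_genes - rich.core_genes
        assert cls.disposable_genes == \
            limited.absent_genes & rich.absent_genes
        assert cls.conditionally_essential_genes.isdisjoint(
            cls.always_essential_genes
        )

    def test_identical_summaries_nothing_conditional(self, toy):
        config = ReductionConfig(cutoffs=(0.1,), replicates=2, seed=7)
        s = run_ensemble(toy.network, toy.glc_arg, config)
        cls = classify_across_conditions(s, s)
        assert not cls.conditionally_essential_genes
        assert not cls.conditionally_essential_reactions

    def test_mismatched_networks_rejected(self, toy, toy_bypass):
        config = ReductionConfig(cutoffs=(0.1,), replicates=1, seed=7)
        a = run_ensemble(toy.network, toy.glc_arg, config)
        b = run_ensemble(toy_bypass.network, toy_bypass.glc_arg, config)
        with pytest.raises(ModelError):
            classify_across_conditions(a, b)


class TestLethalSetPersistence:
    def test_lethal_genes_persist_in_nested_subnetworks(self, toy):
        """Along a ladder of nested viable sub-networks, the lethal set can
        only grow: LP optima are monotone under added constraints."""
        report_full = single_gene_deletion_scan(toy.network, toy.glc_arg)
        # ladder: drop dispensable reactions one batch at a time
        batches = [["ACS"], ["ACS", "PYK"], ["ACS", "PYK", "ASPt"]]
        previous_lethal = report_full.lethal_genes
        for batch in batches:
            sub = toy.network.copy()
            sub.reactions = [r for r in toy.network.reactions
                             if r.id not in batch]
            sub.id = f"toycell_minus_{len(batch)}"
            from redevo import prune_orphans
            sub = prune_orphans(sub)
            assert solve_fba(sub, toy.glc_arg).growth > 1e-9
            report_sub = single_gene_deletion_scan(sub, toy.glc_arg)
            surviving = previous_lethal & set(sub.genes)
            assert surviving <= report_sub.lethal_genes
            previous_lethal = report_sub.lethal_genes
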