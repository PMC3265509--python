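"""Shared fixtures: toy cells, random network corpus, and GPR strategies."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import strategies as st

from redevo import (
    GeneRef,
    GprAnd,
    GprOr,
    make_random_network,
    make_toy_cell,
    ToyCellSpec,
)

GENE_POOL = [f"g{i}" for i in range(1, 7)]


@pytest.fixture(scope="session")
def toy():
    """Default toy cell: no glyoxylate bypass, salvage present."""
    return make_toy_cell()


@pytest.fixture(scope="session")
def toy_bypass():
    """Toy cell with the glyoxylate-bypass analogue (free-living-like)."""
    return make_toy_cell(ToyCellSpec(include_glyoxylate_analogue=True))


@pytest.fixture(scope="session", params=[1, 2, 3, 4])
def random_net(request):
    """Random feasible fixture networks across several seeds and sizes."""
    seed = request.param
    n = 12 + 5 * seed
    return make_random_network(n, n_isozymes=2, seed=seed)


def gpr_trees(max_leaves: int = 6):
    """Hypothesis strategy for GPR trees with at most ``max_leaves`` leaves."""
    leaves = st.sampled_from(GENE_POOL).map(GeneRef)

    def extend(children):
        return st.builds(
            lambda op, kids: op(tuple(kids)),
            st.sampled_from([GprAnd, GprOr]),
            st.lists(children, min_size=2, max_size=3),
        )

    trees = st.recursive(leaves, extend, max_leaves=max_leaves)
    return trees.filter(lambda t: len(_leaf_count(t)) <= max_leaves)


def _leaf_count(tree):
    if isinstance(tree, GeneRef):
        return [tree.gene]
    out = []
    for c in tree.children:
        out.extend(_leaf_count(c))
    return out


def truth_table_eval(tree, inactive: set[str]) -> bool:
    """Independent GPR oracle: recursion-free brute force.

    Enumerates the truth assignment implied by ``inactive`` and folds the
    tree bottom-up with explicit all()/any() over materialised child
    results — no shared code with redevo.evaluate_gpr beyond the node
    classes themselves.
    """
    if tree is None:
        return True
    stack = [(tree, False)]
    results: dict[int, bool] = {}
    while stack:
        node, expanded = stack.pop()
        if isinstance(node, GeneRef):
            results[id(node)] = node.gene not in inactive
            continue
        if not expanded:
            stack.append((node, True))
            stack.extend((c, False) for c in node.children)
            continue
        vals = [results[id(c)] for c in node.children]
        results[id(node)] = all(vals) if isinstance(node, GprAnd) else any(vals)
    return results[id(tree)]


def all_inactive_subsets(tree):
    """Every subset of the tree's gene set, for exhaustive evaluation."""
    genes = sorted(set(_leaf_count(tree)))
    for r in range(len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            yield set(combo)
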