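"""Shared fixtures: seeded simulations and tree-shape enumeration."""

from __future__ import annotations

import itertools

import pytest

from intronarch.parsimony import LineageTree, TreeNode
from intronarch.synthetic_data import SimulationConfig, simulate_family


@pytest.fixture(scope="session")
def default_truth():
    """One default-configuration family, shared read-only across tests."""
    return simulate_family(SimulationConfig(), 11)


@pytest.fixture(scope="session")
def unique_positions_truth():
    """Family with globally position-unique gains (overlay truth checks)."""
    return simulate_family(SimulationConfig(unique_gain_positions=True), 5)


def balanced_newick(n_leaves: int, inner: float = 0.02, terminal: float = 1.0) -> str:
    labels = [f"L{i:02d}" for i in range(n_leaves)]

    def build(ls):
        if len(ls) == 1:
            return f"{ls[0]}:{terminal}"
        m = len(ls) // 2
        return f"({build(ls[:m])},{build(ls[m:])}):{inner}"

    return build(labels) + ";"


def dense_gain_config(w: float) -> SimulationConfig:
    """Sixteen near-independent lineages sampling a small position pool:
    the high-power design for convergent-gain (proto-splice-site) effects."""
    return SimulationConfig(
        tree_newick=balanced_newick(16),
        fu_len_codons=40,
        gain_rate=6.0,
        loss_rate=0.0,
        proto_site_preference=w,
        min_gain_spacing=6,
    )


def tree_shapes(n: int, prefix: str = "L") -> list[LineageTree]:
    """All distinct rooted binary tree shapes with n canonically labelled
    leaves (1, 1, 2, 3, 6 shapes for n = 2..6)."""

    def build(k):
        if k == 1:
            return [None]
        out = []
        for split in range(1, k // 2 + 1):
            for left in build(split):
                for right in build(k - split):
                    out.append((left, right))
        return out

    trees = []
    for shape in {repr(s): s for s in build(n)}.values():
        leaf_counter = itertools.count()
        inner_counter = itertools.count()

        def label(node):
            if node is None:
                return TreeNode(name=f"{prefix}{next(leaf_counter)}", length=1.0)
            return TreeNode(
                name=f"{prefix}_inner{next(inner_counter)}",
                length=1.0,
                children=[label(node[0]), label(node[1])],
            )

        trees.append(LineageTree(root=label(shape), stem_length=1.0))
    return trees
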