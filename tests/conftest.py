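"""Shared fixtures: small trees, alignments and matrices built in code."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from genomeflux.trees import LabeledTree

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def uniform_freqs() -> np.ndarray:
    return np.full(61, 1.0 / 61.0)


@pytest.fixture()
def two_leaf_tree() -> LabeledTree:
    t = LabeledTree()
    r = t.add_node()
    t.add_node("A", r, 1.0, "x")
    t.add_node("B", r, 1.0, "x")
    return t


@pytest.fixture()
def balanced_four_leaf_tree() -> LabeledTree:
    t = LabeledTree()
    r = t.add_node()
    a = t.add_node(None, r, 1.0, "x")
    b = t.add_node(None, r, 1.0, "x")
    t.add_node("A", a, 1.0, "x")
    t.add_node("B", a, 1.0, "x")
    t.add_node("C", b, 1.0, "x")
    t.add_node("D", b, 1.0, "x")
    return t


def random_rooted_tree(rng: np.random.Generator, n_leaves: int) -> LabeledTree:
    """Random rooted binary tree with unit-ish branch lengths."""
    t = LabeledTree()
    root = t.add_node()
    leaves = [
        t.add_node("L0", root, float(rng.uniform(0.05, 1.0)), "x"),
        t.add_node("L1", root, float(rng.uniform(0.05, 1.0)), "x"),
    ]
    for i in range(2, n_leaves):
        # split a random leaf into an internal node with two leaves
        victim_id = leaves[rng.integers(len(leaves))]
        victim = t.nodes[victim_id]
        name = victim.name
        victim.name = None
        c1 = t.add_node(name, victim_id, float(rng.uniform(0.05, 1.0)), "x")
        c2 = t.add_node(f"L{i}", victim_id, float(rng.uniform(0.05, 1.0)), "x")
        leaves.remove(victim_id)
        leaves.extend([c1, c2])
    return t


def leaf_state_matrix(tree: LabeledTree, states: dict[str, int], family: str = "f") -> pd.DataFrame:
    return pd.DataFrame({name: [s] for name, s in states.items()}, index=[family])
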