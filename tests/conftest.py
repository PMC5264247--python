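import numpy as np
import pytest

from straintrace import make_marker_db


@pytest.fixture
def rng():
    return np.random.default_rng(20230917)


@pytest.fixture
def small_db():
    """2 species x 3 markers of 500 bp, with gene families."""
    return make_marker_db(2, 3, 500, seed=42, gene_families_per_species=3)


def random_additive_tree(n_leaves: int, rng: np.random.Generator):
    """A random binary tree with positive branch lengths and its exact
    leaf-to-leaf path-length matrix.

    Returns (labels, distance_matrix, splits) where splits is the set of
    non-trivial bipartitions as frozensets of leaf labels (smaller side).
    """
    labels = [f"L{i}" for i in range(n_leaves)]
    dist = np.zeros((n_leaves, n_leaves))
    # represent each cluster by the distances of its leaves to its root
    height = {lab: 0.0 for lab in labels}
    members = [[lab] for lab in labels]
    splits = set()
    idx = {lab: i for i, lab in enumerate(labels)}
    while len(members) > 1:
        i, j = sorted(rng.choice(len(members), size=2, replace=False))
        bi = float(rng.uniform(0.1, 1.0))
        bj = float(rng.uniform(0.1, 1.0))
        for a in members[i]:
            for b in members[j]:
                dist[idx[a], idx[b]] = dist[idx[b], idx[a]] = (
                    height[a] + bi + height[b] + bj
                )
        merged = members[i] + members[j]
        for a in members[i]:
            height[a] += bi
        for b in members[j]:
            height[b] += bj
        if 1 < len(merged) < n_leaves - 1:
            splits.add(frozenset(merged))
        for side in (members[i], members[j]):
            if 1 < len(side) < n_leaves - 1:
                splits.add(frozenset(side))
        members[i] = merged
        del members[j]
    return labels, dist, splits


def tree_splits(tree, labels):
    """Non-trivial bipartitions of an skbio tree, normalized to the smaller
    side (by the complement within ``labels``)."""
    all_leaves = frozenset(labels)
    out = set()
    for node in tree.traverse():
        if node.is_tip() or node.is_root():
            continue
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            comp = all_leaves - side
            out.add(side if len(side) <= len(comp) else comp)
            if len(side) == len(comp):
                out.add(comp)
    return out


def normalize_splits(splits, labels):
    all_leaves = frozenset(labels)
    out = set()
    for s in splits:
        comp = all_leaves - s
        out.add(s if len(s) <= len(comp) else comp)
        if len(s) == len(comp):
            out.add(comp)
    return out
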