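"""Shared fixtures and independent oracle helpers.

Oracles here are deliberately written as naive brute-force routines,
independent of the package's implementation paths, so tests compare two
genuinely different computations.
"""

from __future__ import annotations

import numpy as np
import pytest

AA20 = "ACDEFGHIKLMNPQRSTVWY"


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, length: int, alphabet: str = AA20) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def random_additive_tree(rng, n_leaves: int):
    """Random binary tree (dendropy) with branch lengths in [0.1, 1.0],
    built by sequential random attachment."""
    import dendropy

    labels = [f"t{i}" for i in range(n_leaves)]
    newick = f"({labels[0]}:{rng.uniform(0.1, 1.0):.6f},{labels[1]}:{rng.uniform(0.1, 1.0):.6f})"
    # grow by splitting a random leaf into a cherry
    tree = dendropy.Tree.get(data=newick + ";", schema="newick",
                             preserve_underscores=True)
    for label in labels[2:]:
        leaves = list(tree.leaf_node_iter())
        target = leaves[int(rng.integers(len(leaves)))]
        taxon = target.taxon
        target.taxon = None
        left = target.new_child()
        left.taxon = taxon
        left.edge.length = float(rng.uniform(0.1, 1.0))
        right = target.new_child()
        right.taxon = tree.taxon_namespace.require_taxon(label)
        right.edge.length = float(rng.uniform(0.1, 1.0))
    tree.is_rooted = False
    return tree


def patristic_matrix(tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path-length matrix via dendropy's own machinery."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted((leaf.taxon for leaf in tree.leaf_node_iter()),
                  key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return ids, mat


def graph_bipartitions(tree) -> set[frozenset]:
    """Independent split enumeration: cut each edge of the tree graph and
    read off the leaf components (networkx-based)."""
    import networkx as nx

    g = nx.Graph()
    labels = {}
    for node in tree.preorder_node_iter():
        if node.taxon is not None:
            labels[id(node)] = node.taxon.label
        if node.parent_node is not None:
            g.add_edge(id(node.parent_node), id(node))
    leaves = frozenset(labels.values())
    anchor = min(leaves)
    splits = set()
    for u, v in list(g.edges()):
        h = g.copy()
        h.remove_edge(u, v)
        comp = nx.node_connected_component(h, u)
        side = frozenset(labels[n] for n in comp if n in labels)
        side = side if anchor not in side else leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            splits.add(side)
    return splits


def needleman_wunsch(a: str, b: str, matrix, gap_open: float, gap_extend: float
                     ) -> float:
    """Affine-gap global alignment score by straight Gotoh dynamic
    programming (first gap position costs gap_open, later ones gap_extend)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])
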