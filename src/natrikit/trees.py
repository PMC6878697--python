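"""Tree building, gene-tree/species-taxonomy congruence, and parsimony
ancestral reconstruction.

The in-repo tree builder is Saitou–Nei neighbor-joining on p-distances
(optionally Poisson-corrected); externally built ML trees can be imported
as Newick and flow through the same congruence and ancestral analyses.
Congruence is quantified two ways: Robinson–Foulds distance against a
reference tree, and per-group monophyly (a group is monophyletic iff some
edge of the unrooted tree splits exactly that group from the rest).
Ancestral sequences are reconstructed per column by unweighted parsimony
(Fitch, generalised to multifurcating nodes via Hartigan's counting rule),
with root ties resolved alphabetically so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import SaturationError, ValidationError
from .io import GAP, Alignment

__all__ = [
    "DistanceMatrix",
    "CongruenceReport",
    "AncestralAssignment",
    "p_distance_matrix",
    "nj_tree",
    "tree_bipartitions",
    "rf_distance",
    "monophyly_report",
    "fitch_ancestral",
]


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValidationError(f"matrix shape {self.values.shape} != ({n},{n})")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be exactly 0")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValidationError("negative distances")


def p_distance_matrix(aln: Alignment, correction: str = "none") -> DistanceMatrix:
    """Pairwise p-distance with pairwise gap deletion; ``poisson`` applies
    d = -ln(1 - p)."""
    if len(aln.records) < 3:
        raise ValidationError("need at least 3 records for a distance matrix")
    if correction not in ("none", "poisson"):
        raise ValidationError(f"unknown correction {correction!r}")
    rows = [r.residues for r in aln.records]
    n = len(rows)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mism = compared = 0
            for a, b in zip(rows[i], rows[j]):
                if a == GAP or b == GAP:
                    continue
                compared += 1
                if a != b:
                    mism += 1
            if compared == 0:
                raise ValidationError(
                    f"no comparable columns between {aln.records[i].id!r} "
                    f"and {aln.records[j].id!r}")
            p = mism / compared
            if correction == "poisson":
                if p >= 1.0:
                    raise SaturationError(
                        f"p = 1 between {aln.records[i].id!r} and "
                        f"{aln.records[j].id!r}: Poisson correction undefined")
                p = -np.log(1.0 - p)
            mat[i, j] = mat[j, i] = p
    return DistanceMatrix(ids=tuple(r.id for r in aln.records), values=mat)


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;[] '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor-joining; returns an unrooted tree (trifurcating
    root) with branch lengths.

    Determinism: the joined pair is the lowest (i, j) index pair among
    Q-minima. Negative branch lengths are clamped to 0 with the deficit
    transferred to the sibling branch (their sum d_ij is preserved).
    """
    n = len(d.ids)
    if n < 3:
        raise ValidationError("neighbor-joining needs at least 3 taxa")
    dist = d.values.astype(float).copy()
    nodes = [_quote(t) for t in d.ids]  # newick fragments, no trailing length

    while len(nodes) > 3:
        m = len(nodes)
        r = dist.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-15:
                    best = (q, i, j)
        _, i, j = best
        vi = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = dist[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        new = f"({nodes[i]}:{vi:.12g},{nodes[j]}:{vj:.12g})"
        # distances from the new node to every remaining node
        keep = [k for k in range(m) if k not in (i, j)]
        du = 0.5 * (dist[i, keep] + dist[j, keep] - dist[i, j])
        du = np.maximum(du, 0.0)
        new_dist = np.zeros((m - 1, m - 1))
        new_dist[:-1, :-1] = dist[np.ix_(keep, keep)]
        new_dist[:-1, -1] = du
        new_dist[-1, :-1] = du
        nodes = [nodes[k] for k in keep] + [new]
        dist = new_dist

    a, b, c = dist[0, 1], dist[0, 2], dist[1, 2]
    va = max(0.0, (a + b - c) / 2)
    vb = max(0.0, (a + c - b) / 2)
    vc = max(0.0, (b + c - a) / 2)
    newick = (f"({nodes[0]}:{va:.12g},{nodes[1]}:{vb:.12g},{nodes[2]}:{vc:.12g});")
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tree_bipartitions(tree: dendropy.Tree, nontrivial_only: bool = True
                      ) -> set[frozenset]:
    """Edge-induced leaf bipartitions of the unrooted topology, each
    canonicalised as the side not containing the lexicographically smallest
    leaf."""
    leaves = frozenset(_leaf_labels(tree))
    anchor = min(leaves)
    splits: set[frozenset] = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(l.taxon.label for l in node.leaf_iter())
        side = below if anchor not in below else leaves - below
        if nontrivial_only and (len(side) < 2 or len(leaves - side) < 2):
            continue
        if len(side) == 0 or len(leaves - side) == 0:
            continue
        splits.add(side)
    return splits


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson–Foulds distance: symmetric difference of non-trivial
    bipartitions (unrooted comparison)."""
    l1, l2 = set(_leaf_labels(t1)), set(_leaf_labels(t2))
    if l1 != l2:
        raise ValidationError(
            f"leaf sets differ: {sorted(l1 ^ l2)} not shared")
    return len(tree_bipartitions(t1) ^ tree_bipartitions(t2))


@dataclass(frozen=True)
class CongruenceReport:
    per_group: dict[str, dict] = field(default_factory=dict)
    fraction_monophyletic: float = 0.0
    rf_distance: int | None = None
    rf_max: int | None = None


def monophyly_report(tree: dendropy.Tree, groups: dict[str, str],
                     reference: dendropy.Tree | None = None) -> CongruenceReport:
    """Check each taxonomy group for monophyly on the unrooted tree.

    ``groups`` maps every leaf label to a group name; groups with >= 2
    leaves are evaluated. A group is monophyletic iff its leaf set equals
    one side of some edge-induced bipartition (trivial splits included, so
    a full-tree group or a complement-of-one group is handled correctly).
    """
    leaves = frozenset(_leaf_labels(tree))
    unmapped = leaves - set(groups)
    if unmapped:
        raise ValidationError(f"leaves without group assignment: {sorted(unmapped)}")
    all_splits = tree_bipartitions(tree, nontrivial_only=False)
    anchor = min(leaves)
    by_group: dict[str, set] = {}
    for leaf in leaves:
        by_group.setdefault(groups[leaf], set()).add(leaf)
    per_group = {}
    for name, members in sorted(by_group.items()):
        if len(members) < 2:
            continue
        members = frozenset(members)
        side = members if anchor not in members else leaves - members
        mono = members == leaves or side in all_splits
        per_group[name] = {"monophyletic": bool(mono), "n_leaves": len(members)}
    if not per_group:
        raise ValidationError("no groups with >= 2 leaves to evaluate")
    fraction = sum(1 for g in per_group.values() if g["monophyletic"]) / len(per_group)
    rf = rf_max = None
    if reference is not None:
        rf = rf_distance(tree, reference)
        rf_max = 2 * (len(leaves) - 3)
    return CongruenceReport(per_group=per_group, fraction_monophyletic=fraction,
                            rf_distance=rf, rf_max=rf_max)


@dataclass(frozen=True)
class AncestralAssignment:
    """Parsimony ancestral sequences: one per internal node (labelled
    ``anc<N>`` in preorder), plus the total minimum-change score."""

    sequences: dict[str, str]
    parsimony_score: int
    root_label: str


def fitch_ancestral(tree: dendropy.Tree, aln: Alignment) -> AncestralAssignment:
    """Per-column parsimony reconstruction on (a copy of) ``tree``.

    Bottom-up, each node keeps the states attained by a maximum number of
    children (Hartigan's rule; for binary nodes this is the familiar
    intersection/union pass), adding (n_children - max_count) changes.
    Top-down, a node takes its parent's state when admissible, otherwise
    the alphabetically smallest admissible state; the root tie-breaks
    alphabetically. The score is invariant under re-rooting.
    """
    tree = tree.clone(depth=1)
    leaf_rows: dict[str, str] = {}
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in aln:
            raise ValidationError(f"leaf {label!r} has no sequence in the alignment")
        leaf_rows[label] = aln[label].residues
    n_cols = aln.n_columns

    internal = [nd for nd in tree.preorder_node_iter() if not nd.is_leaf()]
    for k, nd in enumerate(internal, start=1):
        nd.anc_label = f"anc{k}"

    assignments: dict[str, list[str]] = {nd.anc_label: [] for nd in internal}
    score = 0
    postorder = list(tree.postorder_node_iter())
    preorder = list(tree.preorder_node_iter())
    for col in range(n_cols):
        candidate: dict[int, frozenset] = {}
        for nd in postorder:
            if nd.is_leaf():
                candidate[id(nd)] = frozenset(leaf_rows[nd.taxon.label][col])
            else:
                counts: dict[str, int] = {}
                children = nd.child_nodes()
                for ch in children:
                    for state in candidate[id(ch)]:
                        counts[state] = counts.get(state, 0) + 1
                best = max(counts.values())
                candidate[id(nd)] = frozenset(s for s, c in counts.items() if c == best)
                score += len(children) - best
        chosen: dict[int, str] = {}
        for nd in preorder:
            states = candidate[id(nd)]
            if nd.parent_node is None:
                chosen[id(nd)] = min(states)
            else:
                parent_state = chosen[id(nd.parent_node)]
                chosen[id(nd)] = parent_state if parent_state in states else min(states)
            if not nd.is_leaf():
                assignments[nd.anc_label].append(chosen[id(nd)])

    sequences = {label: "".join(chars) for label, chars in assignments.items()}
    for label, row in leaf_rows.items():
        sequences[label] = row
    return AncestralAssignment(sequences=sequences, parsimony_score=score,
                               root_label=internal[0].anc_label)
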