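"""Distances, UPGMA clustering and outgroup designation.

The concatemer of all core genes is clustered with UPGMA (average linkage on
Jukes-Cantor distances) and the bipartition at the root of that tree — the
"first split" — defines the candidate ingroup and outgroup clades for the
McDonald-Kreitman test.  Per-gene trees are compared against that reference
split to flag genes whose history is incongruent with the core genome, the
signature of inter-taxon recombination.

JC69 is used instead of richer substitution models because it has a closed
form that is easy to validate; distances are computed with pairwise deletion
(each pair uses the columns where both sequences carry an unambiguous base).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Phylo

from .errors import DistanceError, InputError
from .sequence_io import GeneAlignment

_ACGT = tuple(ord(c) for c in "ACGT")


@dataclass(frozen=True)
class DistanceMatrix:
    labels: Tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self):
        v = self.values
        n = len(self.labels)
        if v.shape != (n, n):
            raise InputError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(v)):
            raise InputError("distance matrix contains non-finite entries")
        if np.any(v < 0):
            raise InputError("distance matrix contains negative entries")
        if not np.allclose(v, v.T):
            raise InputError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise InputError("distance matrix diagonal is not zero")

    def get(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


class TreeNode:
    """Node of a rooted ultrametric tree; height = distance to its leaves."""

    __slots__ = ("label", "height", "children")

    def __init__(self, label: Optional[str] = None, height: float = 0.0,
                 children: Optional[List["TreeNode"]] = None):
        self.label = label
        self.height = height
        self.children = children or []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_labels(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        out: List[str] = []
        for c in self.children:
            out.extend(c.leaf_labels())
        return out


@dataclass
class Tree:
    root: TreeNode

    def leaf_labels(self) -> List[str]:
        return self.root.leaf_labels()

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.10g}"

        return fmt(self.root, None) + ";"

    def root_to_leaf_depths(self) -> Dict[str, float]:
        depths: Dict[str, float] = {}

        def walk(node: TreeNode, depth: float) -> None:
            if node.is_leaf:
                depths[node.label] = depth
            for c in node.children:
                walk(c, depth + (node.height - c.height))

        walk(self.root, 0.0)
        return depths


@dataclass(frozen=True)
class TaxonSplit:
    """Unordered bipartition of the genome labels (the tree's first split)."""

    clade_a: FrozenSet[str]
    clade_b: FrozenSet[str]

    def __post_init__(self):
        if not self.clade_a or not self.clade_b:
            raise InputError("both clades of a split must be non-empty")
        if self.clade_a & self.clade_b:
            raise InputError("split clades must be disjoint")

    @property
    def labels(self) -> FrozenSet[str]:
        return self.clade_a | self.clade_b

    def __eq__(self, other) -> bool:
        if not isinstance(other, TaxonSplit):
            return NotImplemented
        return {self.clade_a, self.clade_b} == {other.clade_a, other.clade_b}

    def __hash__(self) -> int:
        return hash(frozenset((self.clade_a, self.clade_b)))

    def clades(self) -> Tuple[FrozenSet[str], FrozenSet[str]]:
        return self.clade_a, self.clade_b


# ---------------------------------------------------------------------------
# JC69 distances


def jc69_pairwise(seq_a: str, seq_b: str) -> float:
    """Jukes-Cantor distance for one pair, pairwise deletion of gapped sites.

    d = -3/4 ln(1 - 4p/3) where p is the mismatch proportion over columns
    where both sequences carry A/C/G/T.  p >= 0.75 has no finite JC distance.
    """
    a = np.frombuffer(seq_a.encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode(), dtype=np.uint8)
    ok = np.isin(a, _ACGT) & np.isin(b, _ACGT)
    n = int(ok.sum())
    if n == 0:
        raise DistanceError("no comparable (both non-gap) columns for this pair")
    p = float(((a != b) & ok).sum()) / n
    if p >= 0.75:
        raise DistanceError(f"saturated pair: mismatch proportion {p:.3f} >= 0.75")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc69_distance(alignment: GeneAlignment) -> DistanceMatrix:
    labels = tuple(alignment.labels)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jc69_pairwise(alignment[labels[i]], alignment[labels[j]])
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(matrix: DistanceMatrix) -> Tree:
    """Average-linkage agglomerative clustering into a rooted ultrametric tree.

    Node height is half the merge distance.  Ties are broken by merging the
    pair of clusters whose (lexicographically smallest member label) pair
    sorts first, which makes the output deterministic.
    """
    if len(matrix.labels) < 2:
        raise InputError("UPGMA needs at least 2 labels")

    # cluster id -> (node, size, min leaf label)
    clusters: Dict[int, Tuple[TreeNode, int, str]] = {
        i: (TreeNode(label=lab), 1, lab) for i, lab in enumerate(matrix.labels)
    }
    dist: Dict[Tuple[int, int], float] = {}
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(matrix.values[i, j])
    next_id = n

    def pair_key(i: int, j: int) -> Tuple[str, str]:
        return tuple(sorted((clusters[i][2], clusters[j][2])))

    while len(clusters) > 1:
        (i, j) = min(dist, key=lambda ij: (dist[ij], pair_key(*ij)))
        d_merge = dist[(i, j)]
        node_i, size_i, min_i = clusters[i]
        node_j, size_j, min_j = clusters[j]
        children = sorted([node_i, node_j], key=lambda nd: min(nd.leaf_labels()))
        new = TreeNode(height=d_merge / 2.0, children=children)
        new_id = next_id
        next_id += 1
        del clusters[i], clusters[j]
        new_dist: Dict[Tuple[int, int], float] = {}
        for (a, b), v in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new_dist[(a, b)] = v
        for k in clusters:
            d_ik = dist.get((min(i, k), max(i, k)))
            d_jk = dist.get((min(j, k), max(j, k)))
            merged = (size_i * d_ik + size_j * d_jk) / (size_i + size_j)
            new_dist[(min(k, new_id), max(k, new_id))] = merged
        clusters[new_id] = (new, size_i + size_j, min(min_i, min_j))
        dist = new_dist

    (root, _, _) = next(iter(clusters.values()))
    return Tree(root)


def clade_heights(tree: Tree) -> Dict[FrozenSet[str], float]:
    """Map every clade (as a frozenset of leaf labels) to its node height."""
    out: Dict[FrozenSet[str], float] = {}

    def walk(node: TreeNode) -> None:
        out[frozenset(node.leaf_labels())] = node.height
        for c in node.children:
            walk(c)

    walk(tree.root)
    return out


def distance_matrix_from_tree(tree: Tree) -> DistanceMatrix:
    """Patristic distances of an ultrametric tree: d(a, b) = 2 * MRCA height."""
    labels = sorted(tree.leaf_labels())

    def mrca_height(node: TreeNode, a: str, b: str) -> float:
        for c in node.children:
            leaves = set(c.leaf_labels())
            if a in leaves and b in leaves:
                return mrca_height(c, a, b)
        return node.height

    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = 2.0 * mrca_height(tree.root, labels[i], labels[j])
    return DistanceMatrix(tuple(labels), d)


# ---------------------------------------------------------------------------
# Splits and congruency


def first_split(tree: Tree) -> TaxonSplit:
    """Bipartition of the leaf labels induced by the root's children.

    For a multifurcating root the first child is taken against the rest.
    """
    root = tree.root
    if root.is_leaf or len(root.children) < 2:
        raise InputError("tree root does not define a split")
    a = frozenset(root.children[0].leaf_labels())
    b = frozenset(
        lab for c in root.children[1:] for lab in c.leaf_labels()
    )
    return TaxonSplit(a, b)


def is_congruent(gene_tree: Tree, reference_split: TaxonSplit) -> bool:
    """True iff the gene tree's first split equals the reference split."""
    leaves = frozenset(gene_tree.leaf_labels())
    if leaves != reference_split.labels:
        raise InputError("gene tree and reference split have different leaf sets")
    return first_split(gene_tree) == reference_split


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_newick(path) -> Tree:
    """Read a rooted (assumed ultrametric) Newick tree.

    Node heights are reconstructed as each node's distance to its deepest
    descendant leaf, which recovers the original heights exactly for
    ultrametric input.
    """
    clade_tree = Phylo.read(str(path), "newick")

    def convert(clade) -> TreeNode:
        if not clade.clades:
            return TreeNode(label=str(clade.name))
        children = [convert(c) for c in clade.clades]
        height = max(
            child.height + (c.branch_length or 0.0)
            for child, c in zip(children, clade.clades)
        )
        return TreeNode(height=height, children=children)

    return Tree(convert(clade_tree.root))
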