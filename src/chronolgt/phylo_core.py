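"""Dated ultrametric species trees: parsing, ages, LCA, time slices.

A :class:`DatedTree` stores a rooted binary phylogeny whose branch lengths
are measured in millions of years (my) and whose leaves are contemporaneous
(age 0).  Node ages before present are derived from the branch lengths and
validated for ultrametricity.  Every downstream rate in this package is
normalized against these ages, so the tree is the temporal backbone of the
whole analysis.

Node ids are assigned in deterministic post-order over the input child
order, which makes all downstream tie-breaking reproducible.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DatedTree",
    "TimeSlice",
    "parse_dated_newick",
    "lca",
    "contemporaneous",
    "subtree_branch_length",
    "build_time_slices",
    "read_clade_map",
    "write_tree_summary",
]

#: Relative ultrametricity tolerance (fraction of root age).  Real dated
#: trees carry rounding error in their printed branch lengths.
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for malformed or non-ultrametric input trees."""


@dataclass
class DatedTree:
    """Rooted binary ultrametric tree with node ages in my.

    Attributes
    ----------
    parent : list of int or None
        Parent id per node; ``None`` for the root.
    children : list of tuple of int
        Child ids per node (empty tuple for leaves, otherwise length 2;
        the root of a single-leaf tree may have one child).
    labels : list of str or None
        Genome identifier for leaves, ``None`` for internal nodes.
    ages : numpy.ndarray
        Age in my before present per node; leaves are exactly 0.
    root : int
        Node id of the root.
    clade_map : dict or None
        Optional genome id -> clade label mapping.
    """

    parent: list
    children: list
    labels: list
    ages: np.ndarray
    root: int
    clade_map: Optional[dict] = None
    _leaf_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        if not self._leaf_index:
            self._leaf_index = {
                lab: i for i, lab in enumerate(self.labels) if lab is not None
            }

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return len(self.children[node]) == 0

    @property
    def leaves(self) -> list:
        return [i for i in range(self.n_nodes) if self.is_leaf(i)]

    @property
    def leaf_labels(self) -> list:
        return [self.labels[i] for i in self.leaves]

    def leaf_id(self, label: str) -> int:
        try:
            return self._leaf_index[label]
        except KeyError:
            raise TreeError(f"unknown genome label: {label!r}") from None

    @property
    def root_age(self) -> float:
        return float(self.ages[self.root])

    def branch_length(self, node: int) -> float:
        """Length in my of the branch above ``node`` (parent age - node age)."""
        p = self.parent[node]
        if p is None:
            raise TreeError("root has no branch")
        return float(self.ages[p] - self.ages[node])

    def branch_interval(self, node: int) -> tuple:
        """Open time interval (parent age, node age) of the branch above ``node``."""
        p = self.parent[node]
        if p is None:
            raise TreeError("root has no branch")
        return (float(self.ages[p]), float(self.ages[node]))

    def branches(self) -> list:
        """All non-root node ids (each identifies the branch above it)."""
        return [i for i in range(self.n_nodes) if self.parent[i] is not None]

    def postorder(self) -> range:
        """Node ids in post-order (ids are assigned in post-order)."""
        return range(self.n_nodes)

    def ancestors(self, node: int) -> list:
        """Path of ancestor ids from ``node`` (exclusive) up to the root."""
        out = []
        p = self.parent[node]
        while p is not None:
            out.append(p)
            p = self.parent[p]
        return out

    def leaf_set(self, node: int) -> frozenset:
        """Labels of leaves descending from ``node`` (including itself)."""
        if self.is_leaf(node):
            return frozenset([self.labels[node]])
        acc = []
        stack = [node]
        while stack:
            v = stack.pop()
            if self.is_leaf(v):
                acc.append(self.labels[v])
            else:
                stack.extend(self.children[v])
        return frozenset(acc)

    def clade_of_branch(self, node: int) -> Optional[str]:
        """Clade label of a branch: the shared clade of its descendant leaves.

        Returns ``None`` (mixed ancestry) when descendants span clades or a
        leaf is missing from the clade map.
        """
        if self.clade_map is None:
            return None
        clades = {self.clade_map.get(lab) for lab in self.leaf_set(node)}
        if len(clades) == 1:
            return next(iter(clades))
        return None

    # -- output ------------------------------------------------------------
    def to_newick(self) -> str:
        """Newick string with branch lengths in my (round-trip safe)."""

        def fmt(node):
            if self.is_leaf(node):
                core = self.labels[node]
            else:
                core = "(" + ",".join(fmt(c) for c in self.children[node]) + ")"
            p = self.parent[node]
            if p is None:
                return core
            return f"{core}:{self.ages[p] - self.ages[node]:.10g}"

        return fmt(self.root) + ";"


def parse_dated_newick(text: str, clade_map: Optional[dict] = None) -> DatedTree:
    """Parse a Newick string into a validated :class:`DatedTree`.

    Branch lengths must be present, non-negative, and imply an ultrametric
    tree (all root-to-leaf path lengths equal within a relative tolerance of
    ``ULTRAMETRIC_RTOL`` of the root age).  Polytomies are rejected: the
    reconciliation machinery requires binary trees.
    """
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    seed = dtree.seed_node
    # Deterministic post-order ids following input child order.
    order = list(dtree.postorder_node_iter())
    ids = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    parent = [None] * n
    children = [()] * n
    labels = [None] * n
    depth = np.zeros(n)

    for node in dtree.preorder_node_iter():
        i = ids[id(node)]
        ch = node.child_nodes()
        if len(ch) not in (0, 2) and not (node is seed and len(ch) == 1):
            raise TreeError(
                f"polytomy or unary internal node with {len(ch)} children; "
                "binary trees required"
            )
        children[i] = tuple(ids[id(c)] for c in ch)
        for c in ch:
            j = ids[id(c)]
            parent[j] = i
            if c.edge.length is None:
                raise TreeError("missing branch length in Newick input")
            if c.edge.length < 0:
                raise TreeError("negative branch length in Newick input")
            depth[j] = depth[i] + c.edge.length
        if len(ch) == 0:
            if node.taxon is None or not node.taxon.label:
                raise TreeError("unlabelled leaf in Newick input")
            labels[i] = node.taxon.label.replace(" ", "_")

    if len(set(l for l in labels if l is not None)) != sum(
        1 for l in labels if l is not None
    ):
        raise TreeError("duplicate leaf labels")

    leaf_ids = [i for i in range(n) if not children[i]]
    root = ids[id(seed)]
    height = float(max(depth[i] for i in leaf_ids))
    tol = max(ULTRAMETRIC_RTOL * height, 1e-12)
    depths = {labels[i]: depth[i] for i in leaf_ids}
    worst = sorted(depths, key=lambda l: depths[l])
    if abs(depths[worst[0]] - depths[worst[-1]]) > tol:
        raise TreeError(
            "non-ultrametric tree: leaf depths differ beyond tolerance "
            f"({worst[0]!r}: {depths[worst[0]]:g} vs "
            f"{worst[-1]!r}: {depths[worst[-1]]:g})"
        )

    ages = height - depth
    ages[leaf_ids] = 0.0  # snap rounding noise
    for j in range(n):
        if parent[j] is not None and ages[parent[j]] <= ages[j]:
            raise TreeError(
                f"zero or negative branch duration above node {j}; every "
                "parent must be strictly older than its children"
            )
    return DatedTree(parent, children, labels, ages, root, clade_map=clade_map)


def lca(tree: DatedTree, genomes: Iterable[str]) -> int:
    """Lowest common ancestor node id of a set of genome labels."""
    labs = list(genomes)
    if not labs:
        raise TreeError("empty genome set")
    nodes = [tree.leaf_id(l) for l in labs]
    common = set([nodes[0]] + tree.ancestors(nodes[0]))
    for v in nodes[1:]:
        common &= set([v] + tree.ancestors(v))
    # youngest common ancestor
    return min(common, key=lambda v: (tree.ages[v], v))


def contemporaneous(tree: DatedTree, branch_u: int, branch_v: int) -> bool:
    """True iff the open time intervals of two branches intersect.

    Branches that meet only at a shared node age are *not* contemporaneous
    (open-interval convention): a transfer needs a positive-duration window
    in which both lineages exist.
    """
    hi_u, lo_u = tree.branch_interval(branch_u)
    hi_v, lo_v = tree.branch_interval(branch_v)
    return max(lo_u, lo_v) < min(hi_u, hi_v)


def subtree_branch_length(tree: DatedTree, genomes: Iterable[str]) -> float:
    """Total length (my) of the minimal subtree spanning the given leaves.

    Sums branches strictly between the leaves and their LCA; the LCA's own
    stem branch is excluded, so the statistic depends only on the spanned
    clade, not on where it attaches to the rest of the tree.
    """
    labs = set(genomes)
    if not labs:
        raise TreeError("empty genome set")
    anc = lca(tree, labs)
    onpath = set()
    for lab in labs:
        v = tree.leaf_id(lab)
        while v != anc:
            onpath.add(v)
            v = tree.parent[v]
    return float(sum(tree.branch_length(v) for v in onpath))


@dataclass
class TimeSlice:
    """Partition of the tree's time span into inter-node-age slices.

    ``boundaries`` are the distinct node ages sorted from root age down to 0;
    slice ``k`` is the open interval ``(boundaries[k], boundaries[k+1])``.
    Branches whose interval covers a slice are pairwise contemporaneous
    throughout it, which is what licenses transfers within a slice.
    """

    boundaries: np.ndarray
    alive: list  # list of tuples of branch ids per slice

    @property
    def n_slices(self) -> int:
        return len(self.alive)

    def interval(self, k: int) -> tuple:
        return (float(self.boundaries[k]), float(self.boundaries[k + 1]))

    def midpoint(self, k: int) -> float:
        hi, lo = self.interval(k)
        return 0.5 * (hi + lo)

    def slices_of_branch(self, branch: int) -> list:
        return [k for k in range(self.n_slices) if branch in self.alive[k]]


def build_time_slices(tree: DatedTree) -> TimeSlice:
    """Build the time-slice decomposition from the tree's distinct node ages."""
    bounds = np.array(sorted(set(float(a) for a in tree.ages), reverse=True))
    alive = []
    for k in range(len(bounds) - 1):
        hi, lo = bounds[k], bounds[k + 1]
        living = tuple(
            v
            for v in tree.branches()
            if tree.ages[tree.parent[v]] >= hi and tree.ages[v] <= lo
        )
        alive.append(living)
    ts = TimeSlice(bounds, alive)
    # sanity: every branch lives in >= 1 slice
    covered = set()
    for a in alive:
        covered.update(a)
    assert covered == set(tree.branches())
    return ts


def read_clade_map(path_or_buffer) -> dict:
    """Read a 2-column TSV (genome_id, clade_label) into a dict."""
    df = pd.read_csv(path_or_buffer, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise TreeError("clade map must have two columns: genome_id, clade_label")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_tree_summary(tree: DatedTree, path_or_buffer=None):
    """Tabulate nodes (node_id, age, parent, is_leaf, label) as TSV."""
    df = pd.DataFrame(
        {
            "node_id": list(range(tree.n_nodes)),
            "age": tree.ages,
            "parent": [-1 if p is None else p for p in tree.parent],
            "is_leaf": [int(tree.is_leaf(i)) for i in range(tree.n_nodes)],
            "label": ["" if l is None else l for l in tree.labels],
        }
    )
    if path_or_buffer is None:
        buf = io.StringIO()
        df.to_csv(buf, sep="\t", index=False)
        return buf.getvalue()
    df.to_csv(path_or_buffer, sep="\t", index=False)
    return None
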