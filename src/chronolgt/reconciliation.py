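"""Parsimony duplication-transfer-loss (DTL) reconciliation on dated trees.

A gene tree is embedded into the dated species tree by assigning every gene
lineage a species branch and a time, at minimum total event cost.  Because
the species tree is ultrametric, transfers can be restricted to pairs of
branches that coexist in time ("ultrametric mode"): the tree's time span is
cut into slices at the distinct node ages, and a transfer placed in a slice
may only connect branches alive throughout that slice.  This forbids
biologically impossible transfers, e.g. from an extant genome into a deep
ancestral lineage.

The exact optimum is found by dynamic programming over
(gene node x species branch x time slice), with transitions for

* speciation (free) at slice boundaries that are species nodes,
* duplication on a branch within a slice,
* transfer to any other branch alive in the same slice,
* loss when passing a speciation node on one side only, and
* the transfer-loss composite (a lineage jumps branches without leaving a
  gene-tree node behind).

Speciations cost nothing; a family absent from the root receives a free
origination on the first branch it occupies, so originations are counted
but never penalized.

:func:`enumerate_min_cost` is an independent cross-check that formulates
the same model as a shortest-path problem on the piece graph (branch x
slice) and exhaustively minimizes over every event placement; it shares no
code with the DP.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .phylo_core import DatedTree, TimeSlice, TreeError, build_time_slices
from .lgt_rates import TransferEvent

__all__ = [
    "EventCosts",
    "GeneTree",
    "Reconciliation",
    "parse_gene_newick",
    "gene_tree_rootings",
    "reconcile",
    "reconcile_family",
    "enumerate_min_cost",
    "ancestral_sizes",
    "select_event_costs",
    "events_table",
]

INF = math.inf
_EPS = 1e-9

#: LGT/loss weight candidates analyzed for event-cost selection.
DEFAULT_COST_CANDIDATES = None  # set after EventCosts definition


@dataclass(frozen=True)
class EventCosts:
    """Parsimony costs for duplication, transfer and loss (speciation = 0).

    The transfer:loss ratio is the "LGT/loss weight" used for cost
    selection; duplication defaults to twice the loss cost.
    """

    duplication: float = 2.0
    transfer: float = 3.0
    loss: float = 1.0

    def __post_init__(self):
        if min(self.duplication, self.transfer, self.loss) < 0:
            raise ValueError("event costs must be non-negative")

    @classmethod
    def from_lgt_loss_weight(cls, transfer: float, loss: float = 1.0):
        """Build costs from an "LGT:loss" weight pair (dup = 2 x loss)."""
        return cls(duplication=2.0 * loss, transfer=transfer, loss=loss)

    @property
    def lgt_loss_weight(self) -> float:
        return self.transfer / self.loss if self.loss > 0 else INF


DEFAULT_COST_CANDIDATES = tuple(
    EventCosts.from_lgt_loss_weight(w) for w in (10.0, 8.0, 5.0, 3.0)
)


# ---------------------------------------------------------------------------
# Gene trees
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """Rooted binary gene tree; leaves labelled by species-tree genomes.

    A leaf label ``"G3|2"`` denotes the second sampled copy in genome
    ``G3``: the species is the part before the first ``|``.
    """

    parent: list
    children: list
    species: list  # species label per leaf, None for internal
    root: int

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def is_leaf(self, node: int) -> bool:
        return len(self.children[node]) == 0

    @property
    def n_leaves(self) -> int:
        return sum(1 for i in range(self.n_nodes) if self.is_leaf(i))

    def postorder(self) -> range:
        return range(self.n_nodes)


def _from_dendropy(dtree: dendropy.Tree) -> GeneTree:
    order = list(dtree.postorder_node_iter())
    ids = {id(n): i for i, n in enumerate(order)}
    n = len(order)
    parent = [None] * n
    children = [()] * n
    species = [None] * n
    for node in order:
        i = ids[id(node)]
        ch = node.child_nodes()
        if len(ch) not in (0, 2):
            raise TreeError(
                f"gene tree node with {len(ch)} children; rooted binary "
                "gene trees required (root unrooted trees first)"
            )
        children[i] = tuple(ids[id(c)] for c in ch)
        for c in ch:
            parent[ids[id(c)]] = i
        if not ch:
            if node.taxon is None or not node.taxon.label:
                raise TreeError("unlabelled gene-tree leaf")
            species[i] = node.taxon.label.replace(" ", "_").split("|")[0]
    return GeneTree(parent, children, species, ids[id(dtree.seed_node)])


def parse_gene_newick(text: str) -> GeneTree:
    """Parse a rooted binary gene tree from Newick (lengths optional)."""
    dtree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    if len(dtree.seed_node.child_nodes()) == 1:
        # single-leaf gene family "(a);" or "a;"
        only = dtree.seed_node.child_nodes()[0]
        if only.is_leaf():
            lab = only.taxon.label.replace(" ", "_").split("|")[0]
            return GeneTree([None], [()], [lab], 0)
    return _from_dendropy(dtree)


def gene_tree_rootings(text: str) -> List[GeneTree]:
    """All rooted versions of a gene tree given as Newick.

    A bifurcating root is taken as given (one rooting); a trifurcating root
    marks the tree as unrooted and every edge is tried as the root position
    (2n-3 rootings for n leaves).
    """
    base = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True
    )
    if len(base.seed_node.child_nodes()) <= 2:
        return [parse_gene_newick(text)]
    out = []
    n_edges = sum(1 for e in base.preorder_edge_iter() if e.head_node is not base.seed_node)
    for k in range(n_edges):
        t = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
        edges = [e for e in t.preorder_edge_iter() if e.head_node is not t.seed_node]
        edge = edges[k]
        if edge.length is None:
            for e in edges:
                e.length = 1.0
        t.reroot_at_edge(edge, update_bipartitions=False)
        t.suppress_unifurcations()
        out.append(_from_dendropy(t))
    return out


# ---------------------------------------------------------------------------
# Species-side indexing (pieces = branch x slice)
# ---------------------------------------------------------------------------

class _SpeciesIndex:
    """Precomputed slice decomposition and per-slice branch bookkeeping."""

    def __init__(self, tree: DatedTree):
        self.tree = tree
        self.ts: TimeSlice = build_time_slices(tree)
        m = self.ts.n_slices
        self.m = m
        self.alive = [list(a) for a in self.ts.alive]
        self.pos = [
            {b: i for i, b in enumerate(a)} for a in self.alive
        ]
        # per slice: does branch x end (at node x) at the slice bottom?
        self.ends = []
        for k in range(m):
            lo = self.ts.boundaries[k + 1]
            self.ends.append(
                [tree.ages[x] == lo for x in self.alive[k]]
            )
        self.leaf_col = {}  # species leaf node id -> column in last slice
        for i, b in enumerate(self.alive[m - 1]):
            if tree.is_leaf(b):
                self.leaf_col[b] = i
        self.root_children = list(tree.children[tree.root])


def _species_index(tree: DatedTree) -> _SpeciesIndex:
    idx = getattr(tree, "_recon_index", None)
    if idx is None or idx.tree is not tree:
        idx = _SpeciesIndex(tree)
        tree._recon_index = idx
    return idx


def _min_excluding_self(v: np.ndarray) -> np.ndarray:
    """For each i, min over j != i of v[j] (inf for length-1 input)."""
    n = len(v)
    out = np.full(n, INF)
    if n < 2:
        return out
    order = np.argsort(v, kind="stable")
    m1, i1 = v[order[0]], order[0]
    m2 = v[order[1]]
    out[:] = m1
    out[i1] = m2
    return out


# ---------------------------------------------------------------------------
# Reconciliation result
# ---------------------------------------------------------------------------

@dataclass
class Reconciliation:
    """Event-labelled embedding of a gene tree into the species tree."""

    gene_tree: GeneTree
    species_tree: DatedTree
    costs: EventCosts
    total_cost: float
    #: per gene node: ("leaf"|"speciation"|"duplication"|"transfer", species node id)
    node_events: dict
    transfers: List[TransferEvent]
    #: implied loss count per species branch (branch = node below it)
    losses: dict
    #: species branches carrying >=1 gene copy ("stem" marks the root edge)
    coverage: set
    #: species nodes through which >=1 gene copy passes (leaves: present in
    #: the sampled genome; internal: present in that ancestral genome)
    node_presence: set
    #: branch carrying the family's origination
    origin_branch: object
    family: Optional[str] = None
    n_optima: Optional[int] = None

    @property
    def n_transfers(self) -> int:
        return len(self.transfers)

    @property
    def n_losses(self) -> int:
        return sum(self.losses.values())


# ---------------------------------------------------------------------------
# The DP
# ---------------------------------------------------------------------------

def reconcile(
    gene_tree: GeneTree,
    species_tree: DatedTree,
    costs: EventCosts = EventCosts(),
    family: Optional[str] = None,
    count_optima: bool = False,
) -> Reconciliation:
    """Minimum-cost time-consistent DTL reconciliation.

    Ties are broken deterministically (speciation before duplication before
    transfer, then lowest species node id), so repeated runs return the
    same embedding.  ``count_optima`` additionally counts co-optimal
    slice-resolved scenarios (metadata; scenarios differing only in which
    slice hosts an event are counted separately).
    """
    sp = _species_index(species_tree)
    known = set(l for l in species_tree.labels if l is not None)
    for i in range(gene_tree.n_nodes):
        if gene_tree.is_leaf(i) and gene_tree.species[i] not in known:
            raise TreeError(
                f"gene-tree leaf maps to unknown genome {gene_tree.species[i]!r}"
            )

    D, T, L = costs.duplication, costs.transfer, costs.loss
    m = sp.m
    tree = species_tree

    # C[u][k] : min cost with lineage of u present on branch (column) in slice
    # k; B[u][k] is the same before the transfer-loss relaxation (needed to
    # price single, unchained transfer-loss jumps during backtracking).
    C = [[None] * m for _ in range(gene_tree.n_nodes)]
    B = [[None] * m for _ in range(gene_tree.n_nodes)]
    Cstem = [INF] * gene_tree.n_nodes

    for u in gene_tree.postorder():
        is_leaf_u = gene_tree.is_leaf(u)
        if not is_leaf_u:
            u1, u2 = gene_tree.children[u]
        for k in range(m - 1, -1, -1):
            alive = sp.alive[k]
            n = len(alive)
            base = np.full(n, INF)
            for i, x in enumerate(alive):
                if sp.ends[k][i]:
                    if tree.is_leaf(x):
                        if is_leaf_u and gene_tree.species[u] == tree.labels[x]:
                            base[i] = 0.0
                    else:
                        c1, c2 = tree.children[x]
                        p1 = sp.pos[k + 1][c1]
                        p2 = sp.pos[k + 1][c2]
                        best = L + min(C[u][k + 1][p1], C[u][k + 1][p2])
                        if not is_leaf_u:
                            s = min(
                                C[u1][k + 1][p1] + C[u2][k + 1][p2],
                                C[u1][k + 1][p2] + C[u2][k + 1][p1],
                            )
                            best = min(best, s)
                        base[i] = best
                else:
                    base[i] = C[u][k + 1][sp.pos[k + 1][x]]
            if not is_leaf_u:
                a1, a2 = C[u1][k], C[u2][k]
                np.minimum(base, D + a1 + a2, out=base)
                if n > 1:
                    np.minimum(
                        base,
                        T + np.minimum(
                            a1 + _min_excluding_self(a2),
                            a2 + _min_excluding_self(a1),
                        ),
                        out=base,
                    )
            # transfer-loss composite: jump to another contemporaneous branch
            B[u][k] = base
            if n > 1:
                relaxed = np.minimum(base, T + L + _min_excluding_self(base))
            else:
                relaxed = base.copy()
            C[u][k] = relaxed
        # stem (above the species root; only one lineage can live here)
        rc = sp.root_children
        if len(rc) == 1:
            stem_bottom = C[u][0][sp.pos[0][rc[0]]]
        else:
            p1, p2 = sp.pos[0][rc[0]], sp.pos[0][rc[1]]
            stem_bottom = L + min(C[u][0][p1], C[u][0][p2])
            if not is_leaf_u:
                stem_bottom = min(
                    stem_bottom,
                    C[u1][0][p1] + C[u2][0][p2],
                    C[u1][0][p2] + C[u2][0][p1],
                )
        if not is_leaf_u:
            stem_bottom = min(stem_bottom, D + Cstem[u1] + Cstem[u2])
        Cstem[u] = stem_bottom

    r = gene_tree.root
    best_cost = Cstem[r]
    best_state = ("stem", r)
    for k in range(m):
        i = int(np.argmin(C[r][k]))
        if C[r][k][i] < best_cost - _EPS:
            best_cost = C[r][k][i]
            best_state = ("slice", r, k, i)

    recon = _backtrack(
        gene_tree, tree, sp, costs, C, B, Cstem, best_state, best_cost, family
    )
    if count_optima:
        recon.n_optima = _count_optima(
            gene_tree, tree, sp, costs, C, B, Cstem, best_cost
        )
    return recon


def _candidates(gene_tree, tree, sp, costs, C, B, Cstem, state):
    """Enumerate (cost, descriptor) moves from a DP state, in tie-break order.

    Order: leaf arrival, speciation, pass-through, loss, duplication,
    transfer (recipients by ascending species id), transfer-loss.
    """
    D, T, L = costs.duplication, costs.transfer, costs.loss
    out = []
    if state[0] == "stem":
        u = state[1]
        is_leaf_u = gene_tree.is_leaf(u)
        rc = sp.root_children
        if len(rc) == 1:
            out.append((C[u][0][sp.pos[0][rc[0]]], ("pass_root", u, rc[0])))
        else:
            c1, c2 = sorted(rc)
            p1, p2 = sp.pos[0][c1], sp.pos[0][c2]
            if not is_leaf_u:
                u1, u2 = gene_tree.children[u]
                out.append(
                    (C[u1][0][p1] + C[u2][0][p2], ("spec_root", u, (c1, c2)))
                )
                out.append(
                    (C[u1][0][p2] + C[u2][0][p1], ("spec_root", u, (c2, c1)))
                )
            out.append((L + C[u][0][p1], ("loss_root", u, c1, c2)))
            out.append((L + C[u][0][p2], ("loss_root", u, c2, c1)))
        if not is_leaf_u:
            u1, u2 = gene_tree.children[u]
            out.append((D + Cstem[u1] + Cstem[u2], ("dup_stem", u)))
        return out

    _, u, k, i = state
    x = sp.alive[k][i]
    is_leaf_u = gene_tree.is_leaf(u)
    if sp.ends[k][i]:
        if tree.is_leaf(x):
            if is_leaf_u and gene_tree.species[u] == tree.labels[x]:
                out.append((0.0, ("leaf", u, x)))
        else:
            c1, c2 = sorted(tree.children[x])
            p1, p2 = sp.pos[k + 1][c1], sp.pos[k + 1][c2]
            if not is_leaf_u:
                u1, u2 = gene_tree.children[u]
                out.append(
                    (C[u1][k + 1][p1] + C[u2][k + 1][p2], ("spec", u, x, (c1, c2)))
                )
                out.append(
                    (C[u1][k + 1][p2] + C[u2][k + 1][p1], ("spec", u, x, (c2, c1)))
                )
            out.append((L + C[u][k + 1][p1], ("loss", u, k, c1, c2)))
            out.append((L + C[u][k + 1][p2], ("loss", u, k, c2, c1)))
    else:
        out.append((C[u][k + 1][sp.pos[k + 1][x]], ("pass", u, k, x)))
    if not is_leaf_u:
        u1, u2 = gene_tree.children[u]
        a1, a2 = C[u1][k], C[u2][k]
        out.append((D + a1[i] + a2[i], ("dup", u, k, x)))
        for j in sorted(range(len(sp.alive[k])), key=lambda j: sp.alive[k][j]):
            if j == i:
                continue
            y = sp.alive[k][j]
            out.append((T + a1[i] + a2[j], ("transfer", u, k, x, y, 0)))
            out.append((T + a2[i] + a1[j], ("transfer", u, k, x, y, 1)))
    # transfer-loss: priced against the jump target's pre-relaxation value
    # so jumps never chain (a chained jump is never cheaper than a direct
    # one, so excluding chains loses no optima).
    for j in sorted(range(len(sp.alive[k])), key=lambda j: sp.alive[k][j]):
        if j == i:
            continue
        y = sp.alive[k][j]
        out.append((T + L + B[u][k][j], ("tl", u, k, x, y, True)))
    return out


def _backtrack(gene_tree, tree, sp, costs, C, B, Cstem, start, total, family):
    node_events = {}
    transfers = []
    losses = {}
    coverage = set()
    node_presence = set()
    origin = {"branch": None}

    def go(state, target, allow_tl=True):
        # resolve one DP state; recurse into successors
        if state[0] == "slice":
            _, u, k, i = state
            coverage.add(sp.alive[k][i])
            if origin["branch"] is None:
                origin["branch"] = sp.alive[k][i]
        else:
            coverage.add("stem")
            if origin["branch"] is None:
                origin["branch"] = "stem"
        for cost, move in _candidates(gene_tree, tree, sp, costs, C, B, Cstem, state):
            if not allow_tl and move[0] == "tl":
                continue
            if not (cost <= target + _EPS):
                continue
            kind = move[0]
            if kind == "leaf":
                node_events[move[1]] = ("leaf", move[2])
                node_presence.add(move[2])
                return
            if kind in ("spec", "spec_root"):
                u = move[1]
                u1, u2 = gene_tree.children[u]
                if kind == "spec":
                    node_events[u] = ("speciation", move[2])
                    node_presence.add(move[2])
                    cA, cB = move[3]
                    knext = state[2] + 1
                else:
                    node_events[u] = ("speciation", tree.root)
                    node_presence.add(tree.root)
                    cA, cB = move[2]
                    knext = 0
                go(("slice", u1, knext, sp.pos[knext][cA]),
                   C[u1][knext][sp.pos[knext][cA]])
                go(("slice", u2, knext, sp.pos[knext][cB]),
                   C[u2][knext][sp.pos[knext][cB]])
                return
            if kind in ("loss", "loss_root"):
                u = move[1]
                if kind == "loss":
                    k, csurv, clost = move[2], move[3], move[4]
                    knext = k + 1
                    node_presence.add(tree.parent[csurv])
                else:
                    csurv, clost = move[2], move[3]
                    knext = 0
                    node_presence.add(tree.root)
                losses[clost] = losses.get(clost, 0) + 1
                go(("slice", u, knext, sp.pos[knext][csurv]),
                   C[u][knext][sp.pos[knext][csurv]])
                return
            if kind == "pass":
                u, k, x = move[1], move[2], move[3]
                go(("slice", u, k + 1, sp.pos[k + 1][x]),
                   C[u][k + 1][sp.pos[k + 1][x]])
                return
            if kind == "pass_root":
                u, c = move[1], move[2]
                node_presence.add(tree.root)
                go(("slice", u, 0, sp.pos[0][c]), C[u][0][sp.pos[0][c]])
                return
            if kind == "dup":
                u, k, x = move[1], move[2], move[3]
                node_events[u] = ("duplication", x)
                u1, u2 = gene_tree.children[u]
                i = sp.pos[k][x]
                go(("slice", u1, k, i), C[u1][k][i])
                go(("slice", u2, k, i), C[u2][k][i])
                return
            if kind == "dup_stem":
                u = move[1]
                node_events[u] = ("duplication", tree.root)
                u1, u2 = gene_tree.children[u]
                go(("stem", u1), Cstem[u1])
                go(("stem", u2), Cstem[u2])
                return
            if kind == "transfer":
                u, k, x, y, swap = move[1], move[2], move[3], move[4], move[5]
                node_events[u] = ("transfer", x)
                transfers.append(
                    TransferEvent(
                        family=family,
                        recipient=y,
                        donor=x,
                        time_my=sp.ts.midpoint(k),
                        gene_node=u,
                        kind="transfer",
                    )
                )
                u1, u2 = gene_tree.children[u]
                stay, move_child = (u1, u2) if swap == 0 else (u2, u1)
                go(("slice", stay, k, sp.pos[k][x]), C[stay][k][sp.pos[k][x]])
                go(("slice", move_child, k, sp.pos[k][y]),
                   C[move_child][k][sp.pos[k][y]])
                return
            if kind == "tl":
                u, k, x, y = move[1], move[2], move[3], move[4]
                transfers.append(
                    TransferEvent(
                        family=family,
                        recipient=y,
                        donor=x,
                        time_my=sp.ts.midpoint(k),
                        gene_node=u,
                        kind="transfer_loss",
                    )
                )
                losses[x] = losses.get(x, 0) + 1
                go(("slice", u, k, sp.pos[k][y]), B[u][k][sp.pos[k][y]],
                   allow_tl=False)
                return
        raise AssertionError("backtracking failed to reproduce the optimum")

    go(start, total)
    return Reconciliation(
        gene_tree=gene_tree,
        species_tree=tree,
        costs=costs,
        total_cost=float(total),
        node_events=node_events,
        transfers=transfers,
        losses=losses,
        coverage=coverage,
        node_presence=node_presence,
        origin_branch=origin["branch"],
        family=family,
    )


def _count_optima(gene_tree, tree, sp, costs, C, B, Cstem, best_cost):
    """Count co-optimal slice-resolved scenarios by a (min, count) sweep."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def cnt(state, no_tl=False):
        if state[0] == "stem":
            val = Cstem[state[1]]
        elif no_tl:
            val = B[state[1]][state[2]][state[3]]
        else:
            val = C[state[1]][state[2]][state[3]]
        total = 0
        for cost, move in _candidates(gene_tree, tree, sp, costs, C, B, Cstem, state):
            if no_tl and move[0] == "tl":
                continue
            if not (abs(cost - val) <= _EPS):
                continue
            kind = move[0]
            if kind == "leaf":
                total += 1
            elif kind in ("spec", "spec_root"):
                u = move[1]
                u1, u2 = gene_tree.children[u]
                if kind == "spec":
                    knext = state[2] + 1
                    cA, cB = move[3]
                else:
                    knext = 0
                    cA, cB = move[2]
                total += cnt(("slice", u1, knext, sp.pos[knext][cA])) * cnt(
                    ("slice", u2, knext, sp.pos[knext][cB])
                )
            elif kind in ("loss", "loss_root"):
                u = move[1]
                knext = move[2] + 1 if kind == "loss" else 0
                csurv = move[3] if kind == "loss" else move[2]
                total += cnt(("slice", u, knext, sp.pos[knext][csurv]))
            elif kind == "pass":
                u, k, x = move[1], move[2], move[3]
                total += cnt(("slice", u, k + 1, sp.pos[k + 1][x]))
            elif kind == "pass_root":
                total += cnt(("slice", move[1], 0, sp.pos[0][move[2]]))
            elif kind == "dup":
                u, k, x = move[1], move[2], move[3]
                u1, u2 = gene_tree.children[u]
                i = sp.pos[k][x]
                total += cnt(("slice", u1, k, i)) * cnt(("slice", u2, k, i))
            elif kind == "dup_stem":
                u1, u2 = gene_tree.children[move[1]]
                total += cnt(("stem", u1)) * cnt(("stem", u2))
            elif kind == "transfer":
                u, k, x, y, swap = move[1], move[2], move[3], move[4], move[5]
                u1, u2 = gene_tree.children[u]
                stay, mv = (u1, u2) if swap == 0 else (u2, u1)
                total += cnt(("slice", stay, k, sp.pos[k][x])) * cnt(
                    ("slice", mv, k, sp.pos[k][y])
                )
            elif kind == "tl":
                u, k, x, y = move[1], move[2], move[3], move[4]
                total += cnt(("slice", u, k, sp.pos[k][y]), True)
        return total

    r = gene_tree.root
    total = 0
    if abs(Cstem[r] - best_cost) <= _EPS:
        total += cnt(("stem", r))
    for k in range(sp.m):
        for i in range(len(sp.alive[k])):
            if abs(C[r][k][i] - best_cost) <= _EPS:
                total += cnt(("slice", r, k, i))
    return total


# ---------------------------------------------------------------------------
# Independent oracle: shortest paths on the piece graph
# ---------------------------------------------------------------------------

def enumerate_min_cost(
    gene_tree: GeneTree,
    species_tree: DatedTree,
    costs: EventCosts = EventCosts(),
    max_leaves: int = 7,
) -> float:
    """Exhaustive minimum DTL cost via the piece-graph formulation.

    Builds the graph of (branch x slice) pieces whose edges are the legal
    lineage moves (descend through time for free, survive a speciation on
    one side for one loss, jump to a contemporaneous branch for
    transfer+loss) and minimizes, over every placement of every gene-tree
    event on every piece, path costs plus event costs.  Structured entirely
    differently from :func:`reconcile`'s slice DP, so the two serve as
    mutual cross-checks.  Capped at ``max_leaves`` gene-tree leaves.
    """
    if gene_tree.n_leaves > max_leaves:
        raise ValueError(f"oracle capped at {max_leaves} gene-tree leaves")
    sp = _species_index(species_tree)
    tree = species_tree
    D, T, L = costs.duplication, costs.transfer, costs.loss

    G = nx.DiGraph()
    pieces = [("stem",)]
    for k in range(sp.m):
        for x in sp.alive[k]:
            pieces.append((k, x))
    G.add_nodes_from(pieces)
    rc = sp.root_children
    if len(rc) == 1:
        G.add_edge(("stem",), (0, rc[0]), weight=0.0)
    else:
        for c in rc:
            G.add_edge(("stem",), (0, c), weight=L)
    for k in range(sp.m):
        for i, x in enumerate(sp.alive[k]):
            if sp.ends[k][i]:
                if not tree.is_leaf(x):
                    for c in tree.children[x]:
                        G.add_edge((k, x), (k + 1, c), weight=L)
            else:
                G.add_edge((k, x), (k + 1, x), weight=0.0)
            for y in sp.alive[k]:
                if y != x:
                    G.add_edge((k, x), (k, y), weight=T + L)

    dist = dict(nx.all_pairs_dijkstra_path_length(G))

    def d(p, q):
        return dist.get(p, {}).get(q, INF)

    terminal = {}
    for leaf, col in sp.leaf_col.items():
        terminal[tree.labels[leaf]] = (sp.m - 1, leaf)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def best_from(u, p):
        """Min cost of subtree u given its lineage currently sits at piece p."""
        if gene_tree.is_leaf(u):
            return d(p, terminal[gene_tree.species[u]])
        u1, u2 = gene_tree.children[u]
        best = INF
        for q in pieces:
            dq = d(p, q)
            if dq == INF:
                continue
            if q == ("stem",):
                best = min(best, dq + D + best_from(u1, q) + best_from(u2, q))
                if len(rc) == 2:
                    best = min(
                        best,
                        dq
                        + best_from(u1, (0, rc[0]))
                        + best_from(u2, (0, rc[1])),
                        dq
                        + best_from(u1, (0, rc[1]))
                        + best_from(u2, (0, rc[0])),
                    )
                continue
            k, x = q
            best = min(best, dq + D + best_from(u1, q) + best_from(u2, q))
            i = sp.pos[k][x]
            if sp.ends[k][i] and not tree.is_leaf(x):
                c1, c2 = tree.children[x]
                best = min(
                    best,
                    dq + best_from(u1, (k + 1, c1)) + best_from(u2, (k + 1, c2)),
                    dq + best_from(u1, (k + 1, c2)) + best_from(u2, (k + 1, c1)),
                )
            for y in sp.alive[k]:
                if y == x:
                    continue
                best = min(
                    best,
                    dq + T + best_from(u1, q) + best_from(u2, (k, y)),
                    dq + T + best_from(u2, q) + best_from(u1, (k, y)),
                )
        return best

    return float(min(best_from(gene_tree.root, p) for p in pieces))


# ---------------------------------------------------------------------------
# Family-level wrappers and genome-size selection
# ---------------------------------------------------------------------------

def reconcile_family(
    gene_trees: Sequence,
    species_tree: DatedTree,
    costs: EventCosts = EventCosts(),
    family: Optional[str] = None,
    unrooted: bool = False,
) -> Reconciliation:
    """Best reconciliation over the supplied gene trees for one family.

    Each entry may be a :class:`GeneTree` or a Newick string.  With
    ``unrooted=True``, Newick entries are additionally swept over all
    rootings.  Ties are broken by input order (then rooting order).
    """
    if len(gene_trees) == 0:
        raise ValueError("at least one gene tree required per family")
    candidates = []
    for g in gene_trees:
        if isinstance(g, GeneTree):
            candidates.append(g)
        elif unrooted:
            candidates.extend(gene_tree_rootings(g))
        else:
            candidates.append(parse_gene_newick(g))
    best = None
    for g in candidates:
        rec = reconcile(g, species_tree, costs, family=family)
        if best is None or rec.total_cost < best.total_cost - _EPS:
            best = rec
    return best


def ancestral_sizes(reconciliations: Sequence[Reconciliation],
                    species_tree: DatedTree):
    """Per-node ancestral genome sizes and the mean parent-daughter change.

    A node's size is the number of families with at least one gene copy
    present at that node: at a leaf, families observed in the sampled
    genome; at an internal node, families whose lineage crosses that
    speciation.  The mean change is the average of
    |size(parent) - size(child)| over all parent-child edges; absolute
    values are used so gains and losses do not cancel.
    """
    tree = species_tree
    sizes = np.zeros(tree.n_nodes, dtype=int)
    for rec in reconciliations:
        for v in rec.node_presence:
            sizes[v] += 1
    changes = [
        abs(int(sizes[tree.parent[v]]) - int(sizes[v])) for v in tree.branches()
    ]
    mean_change = float(np.mean(changes)) if changes else 0.0
    df = pd.DataFrame(
        {
            "node_id": range(tree.n_nodes),
            "size": sizes,
            "is_leaf": [int(tree.is_leaf(i)) for i in range(tree.n_nodes)],
            "label": ["" if l is None else l for l in tree.labels],
        }
    )
    return df, mean_change


def select_event_costs(
    candidates: Sequence[EventCosts],
    families: dict,
    species_tree: DatedTree,
    unrooted: bool = False,
):
    """Pick event costs minimizing mean parent-daughter genome-size change.

    ``families`` maps family id -> list of gene trees (or Newick strings).
    Returns ``(chosen_costs, table, reconciliations_under_chosen)`` where
    the table lists the mean size change per candidate; ties go to the
    first candidate in input order.
    """
    if len(candidates) == 0:
        raise ValueError("at least one candidate cost setting required")
    rows = []
    recs_by_cand = []
    for costs in candidates:
        recs = [
            reconcile_family(trees, species_tree, costs, family=fam,
                             unrooted=unrooted)
            for fam, trees in families.items()
        ]
        _, mean_change = ancestral_sizes(recs, species_tree)
        rows.append(
            {
                "lgt_loss_weight": costs.lgt_loss_weight,
                "duplication": costs.duplication,
                "transfer": costs.transfer,
                "loss": costs.loss,
                "mean_size_change": mean_change,
            }
        )
        recs_by_cand.append(recs)
    table = pd.DataFrame(rows)
    best_i = int(table["mean_size_change"].idxmin())
    return candidates[best_i], table, recs_by_cand[best_i]


def events_table(reconciliations: Sequence[Reconciliation]) -> pd.DataFrame:
    """Flatten reconciliations into a per-event table (TSV-ready)."""
    rows = []
    for rec in reconciliations:
        fam = rec.family if rec.family is not None else ""
        for u, (event, node) in sorted(rec.node_events.items()):
            if event == "leaf":
                continue
            rows.append(
                {
                    "family": fam,
                    "event": event,
                    "gene_node": u,
                    "species_branch": node,
                    "donor": "",
                    "time_my": "",
                }
            )
        for ev in rec.transfers:
            rows.append(
                {
                    "family": fam,
                    "event": ev.kind,
                    "gene_node": "" if ev.gene_node is None else ev.gene_node,
                    "species_branch": ev.recipient,
                    "donor": ev.donor,
                    "time_my": ev.time_my,
                }
            )
        for b, n in sorted(rec.losses.items()):
            rows.append(
                {
                    "family": fam,
                    "event": "loss",
                    "gene_node": "",
                    "species_branch": b,
                    "donor": "",
                    "time_my": n,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["family", "event", "gene_node", "species_branch", "donor", "time_my"],
    )
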