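"""Synthetic data with ground truth for every pipeline stage.

The generator produces (i) dated pure-birth species trees with two deep
clades, (ii) gene-content histories evolving by origination, loss and
time-consistent transfer — with the true event log and the true per-family
gene genealogies, (iii) codon sequence pairs with separate synonymous and
nonsynonymous substitution rates, and (iv) BGC domain strings with a
tunable fraction of phylogenetically restricted families.  Everything is
driven by one seed and is byte-reproducible.

Model sketch for gene content: a family originates either before the root
(present in the root genome) or at a point on a branch; every gene copy is
lost at ``loss_rate`` per my, multiplied by ``post_transfer_loss_multiplier``
for horizontally acquired copies and their descendants (the mechanism that
makes old transfers fade from view); acquisition events arrive on each
recipient lineage at ``transfer_rate`` per my, the donor being drawn from
the recipient's clade with probability ``within_clade_bias`` and from the
opposite clade otherwise, uniformly among lineages alive at that moment.
The transferred family is chosen uniformly among families carried by the
donor.  Gene trees record the true copy genealogy, with transfers as
grafts, so reconciliation can be validated end to end.

The generative model and its defaults are artifact choices (no published
generative parameters exist for these processes); they are documented in
the package's methods note.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .phylo_core import DatedTree, parse_dated_newick
from .pangenome import GeneFamilyMatrix
from .lgt_rates import TransferEvent
from . import mutation_rates as mr

__all__ = [
    "SimConfig",
    "EventLog",
    "EventRecord",
    "simulate_dated_tree",
    "simulate_gene_content",
    "simulate_codon_pair",
    "simulate_bgc_families",
]


@dataclass
class SimConfig:
    """Simulation parameters; all rates are per my unless noted.

    Defaults emulate a deep, two-clade actinobacterial genus radiation:
    root age 380 my, tens of taxa, mostly ancestral gene families with
    slow turnover, transfer intensity of a few percent per lineage per my,
    and a within-clade donor preference.
    """

    seed: int = 0
    n_taxa: int = 50
    root_age: float = 380.0
    #: minimum my between the root and each clade's first internal split
    clade_split_depth: float = 30.0
    #: family originations per lineage per my (used when n_families is None)
    gain_rate: float = 0.01
    #: losses per gene copy per my
    loss_rate: float = 0.01
    #: acquisitions per recipient lineage per my
    transfer_rate: float = 0.05
    #: probability the donor comes from the recipient's own clade
    within_clade_bias: float = 0.7
    #: loss-rate factor for horizontally acquired copies (>= 1)
    post_transfer_loss_multiplier: float = 2.0
    #: substitutions per synonymous / nonsynonymous site per year
    syn_rate: float = 1.62e-8
    nonsyn_rate: float = 1.78e-9
    #: total families; None draws the count from the gain process
    n_families: Optional[int] = 500
    #: fraction of families already present in the root genome
    root_family_fraction: float = 0.5
    # BGC generator
    n_bgc_families: int = 40
    n_domain_types: int = 200
    archetype_length: int = 8
    domain_mutation_prob: float = 0.05
    restricted_fraction: float = 0.8

    def validate(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.root_age <= 0:
            raise ValueError("root_age must be positive")
        for name in ("gain_rate", "loss_rate", "transfer_rate",
                     "syn_rate", "nonsyn_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.within_clade_bias <= 1):
            raise ValueError("within_clade_bias must be in [0, 1]")
        if self.post_transfer_loss_multiplier < 1:
            raise ValueError("post_transfer_loss_multiplier must be >= 1")
        if not (0 <= self.root_family_fraction <= 1):
            raise ValueError("root_family_fraction must be in [0, 1]")
        if not (0 <= self.restricted_fraction <= 1):
            raise ValueError("restricted_fraction must be in [0, 1]")
        if self.archetype_length < 3:
            raise ValueError(
                "archetype_length must be >= 3 (clusters below 3 domains "
                "are filtered out of the analysis)"
            )
        return self

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Dated species trees
# ---------------------------------------------------------------------------

def simulate_dated_tree(
    n_taxa: int,
    root_age: float,
    seed: int,
    clade_split_depth: float = 0.0,
    min_clade_fraction: float = 0.2,
) -> DatedTree:
    """Pure-birth dated tree with two deep clades, rescaled to the root age.

    The two children of the root define clade labels "I" and "II" (stored
    in the tree's clade map).  Because the analyses contrast two major
    clades, the topology is conditioned on each root child subtending at
    least ``min_clade_fraction`` of the taxa (set 0 for an unconditioned
    pure-birth split, which is uniform and frequently very lopsided).
    ``clade_split_depth`` additionally forces each clade's first internal
    split at least that many my below the root, keeping the clades well
    separated.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    rng = np.random.default_rng(seed)
    min_size = max(1, int(math.ceil(min_clade_fraction * n_taxa)))

    # forward-time pure birth from the root split (rate 1, rescaled later)
    for _attempt in range(1000):
        next_id = [0]

        def new_node(t):
            next_id[0] += 1
            return {"id": next_id[0], "t": t, "children": []}

        root = new_node(0.0)
        a, b = new_node(None), new_node(None)
        root["children"] = [a, b]
        active = [a, b]
        side = {id(a): 0, id(b): 1}
        sizes = [1, 1]
        t = 0.0
        while len(active) < n_taxa:
            t += rng.exponential(1.0 / len(active))
            i = int(rng.integers(len(active)))
            node = active[i]
            node["t"] = t
            c1, c2 = new_node(None), new_node(None)
            node["children"] = [c1, c2]
            s = side.pop(id(node))
            side[id(c1)] = side[id(c2)] = s
            sizes[s] += 1
            active[i] = c1
            active.append(c2)
        if min(sizes) >= min_size:
            break
    else:
        raise ValueError(
            f"could not draw a tree with both clades >= {min_size} taxa"
        )
    present = t + rng.exponential(1.0 / n_taxa)

    scale = root_age / present
    leaf_counter = [0]

    def age_of(node):
        return root_age - node["t"] * scale if node["children"] else 0.0

    # enforce the clade split depth by shrinking each root-child subtree
    sub_scale = {}
    for child in root["children"]:
        if child["children"]:
            cap = root_age - clade_split_depth
            ca = age_of(child)
            sub_scale[id(child)] = min(1.0, cap / ca) if ca > 0 else 1.0
        else:
            sub_scale[id(child)] = 1.0

    def newick(node, factor):
        if not node["children"]:
            leaf_counter[0] += 1
            return f"G{leaf_counter[0]:03d}", 0.0
        parts = []
        my_age = age_of(node) * factor
        for c in node["children"]:
            f = factor if node is not root else sub_scale[id(c)]
            s, ca = newick(c, f)
            parts.append(f"{s}:{(my_age if node is not root else root_age) - ca:.12g}")
        return "(" + ",".join(parts) + ")", my_age if node is not root else root_age

    s, _ = newick(root, 1.0)
    tree = parse_dated_newick(s + ";")
    # clade labels from the root split
    cmap = {}
    for side, label in zip(tree.children[tree.root], ("I", "II")):
        for leaf in tree.leaf_set(side):
            cmap[leaf] = label
    tree.clade_map = cmap
    return tree


# ---------------------------------------------------------------------------
# Gene content with true event log and genealogies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EventRecord:
    """One ground-truth event: gain, loss or transfer."""

    family: str
    kind: str                    # "gain" | "loss" | "transfer"
    branch: int                  # species branch carrying the event
    time_my: float
    donor: Optional[int] = None  # transfer donor branch
    detectable: Optional[bool] = None  # transfer copy survives to a leaf


@dataclass
class EventLog:
    """Ground-truth event list with convenience accessors."""

    records: List[EventRecord] = field(default_factory=list)
    n_skipped_transfers: int = 0  # arrivals whose donor carried no family

    def of_kind(self, kind: str) -> List[EventRecord]:
        return [r for r in self.records if r.kind == kind]

    def transfer_events(self, detectable_only: bool = False) -> List[TransferEvent]:
        out = []
        for r in self.of_kind("transfer"):
            if detectable_only and not r.detectable:
                continue
            out.append(
                TransferEvent(
                    family=r.family,
                    recipient=r.branch,
                    donor=r.donor,
                    time_my=r.time_my,
                    kind="simulated",
                    detectable=r.detectable,
                )
            )
        return out

    def to_tsv(self, path_or_buffer):
        pd.DataFrame(
            [
                {
                    "family": r.family,
                    "kind": r.kind,
                    "branch": r.branch,
                    "time_my": f"{r.time_my:.10g}",
                    "donor": "" if r.donor is None else r.donor,
                    "detectable": "" if r.detectable is None else int(r.detectable),
                }
                for r in self.records
            ],
            columns=["family", "kind", "branch", "time_my", "donor", "detectable"],
        ).to_csv(path_or_buffer, sep="\t", index=False)


class _Copy:
    """A live gene copy on a species branch during the sweep."""

    __slots__ = ("family", "branch", "acquired", "tip", "death_age")

    def __init__(self, family, branch, acquired, tip, death_age):
        self.family = family
        self.branch = branch
        self.acquired = acquired
        self.tip = tip
        self.death_age = death_age


def simulate_gene_content(tree: DatedTree, config: SimConfig):
    """Evolve gene families along the dated tree.

    Returns ``(matrix, log, gene_trees)`` where ``gene_trees`` maps family
    id to the Newick of its true copy genealogy (families extinct at the
    present are absent from the matrix and map to ``None``).  Leaf labels
    are ``genome`` or ``genome|k`` for additional copies.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_nodes = tree.n_nodes
    root = tree.root

    branch_len = {b: tree.branch_length(b) for b in tree.branches()}
    total_len = sum(branch_len.values())
    clade_of = {b: tree.clade_of_branch(b) for b in tree.branches()}

    # -- family originations ----------------------------------------------
    if config.n_families is not None:
        n_fam = config.n_families
        n_root = int(round(config.root_family_fraction * n_fam))
    else:
        n_branch = rng.poisson(config.gain_rate * total_len)
        n_root = rng.poisson(
            config.gain_rate * total_len * config.root_family_fraction
            / max(1e-12, 1.0 - config.root_family_fraction)
        ) if config.root_family_fraction > 0 else 0
        n_fam = n_root + n_branch
    fam_ids = [f"F{i:05d}" for i in range(n_fam)]
    branches = sorted(branch_len)
    weights = np.array([branch_len[b] for b in branches])
    weights = weights / weights.sum()
    origin = {}
    for i, fam in enumerate(fam_ids):
        if i < n_root:
            origin[fam] = (root, float(tree.ages[root]))
        else:
            b = branches[int(rng.choice(len(branches), p=weights))]
            hi, lo = tree.branch_interval(b)
            origin[fam] = (b, float(rng.uniform(lo, hi)))

    # -- transfer arrivals per recipient branch ---------------------------
    arrivals = []  # (age, seq, recipient)
    for b in branches:
        hi, lo = tree.branch_interval(b)
        n = rng.poisson(config.transfer_rate * (hi - lo))
        for t in rng.uniform(lo, hi, size=n):
            arrivals.append((float(t), b))

    # -- chronological sweep (ages decreasing toward the present) ---------
    seq = [0]

    def push(heap, age, kind, payload):
        seq[0] += 1
        heapq.heappush(heap, (-age, seq[0], kind, payload))

    heap = []
    for v in range(n_nodes):
        if v != root:
            push(heap, float(tree.ages[v]), "node", v)
    for t, b in arrivals:
        push(heap, t, "arrival", b)

    log = EventLog()
    presence: Dict[int, Dict[str, list]] = {b: {} for b in branches}
    gene_nodes: Dict[str, list] = {f: [] for f in fam_ids}
    copies: Dict[int, _Copy] = {}
    copy_seq = [0]
    transfer_tips = []  # (record index, tip node id) for detectability

    def new_gene_node(fam, label=None):
        nodes = gene_nodes[fam]
        nodes.append({"children": [], "label": label, "dead": False})
        return len(nodes) - 1

    mult = config.post_transfer_loss_multiplier

    def draw_death(age, acquired):
        rate = config.loss_rate * (mult if acquired else 1.0)
        if rate <= 0:
            return -math.inf
        return age - rng.exponential(1.0 / rate)

    def place_copy(fam, branch, age, acquired, tip):
        death = draw_death(age, acquired)
        copy_seq[0] += 1
        cid = copy_seq[0]
        c = _Copy(fam, branch, acquired, tip, death)
        copies[cid] = c
        presence[branch].setdefault(fam, []).append(cid)
        if death > float(tree.ages[branch]):
            push(heap, death, "death", cid)
        return cid

    def remove_copy(cid):
        c = copies.pop(cid)
        lst = presence[c.branch][c.family]
        lst.remove(cid)
        if not lst:
            del presence[c.branch][c.family]
        return c

    # seed root-present families and branch originations
    rc = list(tree.children[root])
    for fam in fam_ids:
        b, t0 = origin[fam]
        log.records.append(EventRecord(fam, "gain", b, t0))
        if b == root:
            gnode = new_gene_node(fam)
            for child in rc:
                tip = new_gene_node(fam)
                gene_nodes[fam][gnode]["children"].append(tip)
                place_copy(fam, child, t0, False, tip)
        else:
            tip = new_gene_node(fam)
            place_copy(fam, b, t0, False, tip)

    def alive_branches(t):
        return [
            b
            for b in branches
            if tree.ages[tree.parent[b]] > t > tree.ages[b]
        ]

    while heap:
        neg_age, _, kind, payload = heapq.heappop(heap)
        age = -neg_age
        if kind == "death":
            cid = payload
            if cid not in copies:
                continue
            c = copies[cid]
            if c.death_age != age:  # stale entry after a split
                continue
            remove_copy(cid)
            gene_nodes[c.family][c.tip]["dead"] = True
            log.records.append(EventRecord(c.family, "loss", c.branch, age))
        elif kind == "arrival":
            recipient = payload
            hi, lo = tree.branch_interval(recipient)
            if not (hi > age > lo):
                continue  # defensive; arrivals are sampled inside
            alive = [b for b in alive_branches(age) if b != recipient]
            if not alive:
                log.n_skipped_transfers += 1
                continue
            own = clade_of[recipient]
            same = [b for b in alive if clade_of[b] == own]
            other = [b for b in alive if clade_of[b] != own]
            if not same or not other:
                # while the recipient is its clade's only lineage no
                # within-clade donor exists; dropping the whole arrival
                # (not just redirecting it) keeps the donor-clade draw
                # independent of the recipient for every logged event
                log.n_skipped_transfers += 1
                continue
            pool = same if rng.random() < config.within_clade_bias else other
            donor = pool[int(rng.integers(len(pool)))]
            donor_fams = list(presence[donor])
            if not donor_fams:
                log.n_skipped_transfers += 1
                continue
            fam = donor_fams[int(rng.integers(len(donor_fams)))]
            src_cid = presence[donor][fam][
                int(rng.integers(len(presence[donor][fam])))
            ]
            src = remove_copy(src_cid)
            # graft: donor copy splits into (stays on donor, new on recipient)
            parent_tip = src.tip
            stay_tip = new_gene_node(fam)
            new_tip = new_gene_node(fam)
            gene_nodes[fam][parent_tip]["children"] = [stay_tip, new_tip]
            place_copy(fam, donor, age, src.acquired, stay_tip)
            place_copy(fam, recipient, age, True, new_tip)
            log.records.append(
                EventRecord(fam, "transfer", recipient, age, donor=donor)
            )
            transfer_tips.append((len(log.records) - 1, fam, new_tip))
        elif kind == "node":
            v = payload
            live = list(presence[v].items())
            if tree.is_leaf(v):
                for fam, cids in live:
                    for k, cid in enumerate(list(cids)):
                        c = remove_copy(cid)
                        label = tree.labels[v] if k == 0 else f"{tree.labels[v]}|{k}"
                        gene_nodes[fam][c.tip]["label"] = label
            else:
                ch = tree.children[v]
                for fam, cids in live:
                    for cid in list(cids):
                        c = remove_copy(cid)
                        for child in ch:
                            tip = new_gene_node(fam)
                            gene_nodes[fam][c.tip]["children"].append(tip)
                            place_copy(fam, child, age, c.acquired, tip)

    # -- assemble outputs ---------------------------------------------------
    genomes = sorted(tree.leaf_labels)
    newicks = {}
    surviving = {}
    survival_mark = {}
    for fam in fam_ids:
        nodes = gene_nodes[fam]
        alive_mask = [False] * len(nodes)

        def mark(i):
            node = nodes[i]
            if node["label"] is not None:
                alive_mask[i] = True
                return True
            ok = False
            for c in node["children"]:
                if mark(c):
                    ok = True
            alive_mask[i] = ok
            return ok

        # node 0 is always the family root by construction
        mark(0)
        survival_mark[fam] = alive_mask

        def prune(i):
            node = nodes[i]
            if node["label"] is not None:
                return node["label"]
            kids = [prune(c) for c in node["children"] if alive_mask[c]]
            kids = [k for k in kids if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            return "(" + ",".join(kids) + ")"

        nwk = prune(0) if alive_mask[0] else None
        if nwk is None:
            newicks[fam] = None
            surviving[fam] = set()
        else:
            newicks[fam] = nwk + ";"
            leaves = set()
            for i, node in enumerate(nodes):
                if alive_mask[i] and node["label"] is not None:
                    leaves.add(node["label"].split("|")[0])
            surviving[fam] = leaves

    # detectability of transfers: acquired copy has surviving descendants
    for rec_i, fam, tip in transfer_tips:
        r = log.records[rec_i]
        log.records[rec_i] = EventRecord(
            r.family, r.kind, r.branch, r.time_my, r.donor,
            detectable=bool(survival_mark[fam][tip]),
        )

    extant = [f for f in fam_ids if surviving[f]]
    data = pd.DataFrame(
        {f: [1 if g in surviving[f] else 0 for g in genomes] for f in extant},
        index=pd.Index(genomes, name="genome"),
    )
    matrix = GeneFamilyMatrix(data, clades=dict(tree.clade_map or {}))
    return matrix, log, newicks


# ---------------------------------------------------------------------------
# Codon pairs
# ---------------------------------------------------------------------------

def simulate_codon_pair(
    n_codons: int,
    divergence_time_my: float,
    syn_rate: float,
    nonsyn_rate: float,
    seed: int,
) -> mr.CodonAlignment:
    """Two codon sequences diverged for T my from a random ancestor.

    Substitutions follow a continuous-time chain per codon: synonymous
    single-nucleotide changes fire at ``syn_rate`` per synonymous site per
    year (the codon's fractional site count), nonsynonymous likewise, and
    each event picks uniformly among the corresponding non-stop neighbor
    codons, so stop codons are never produced.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    T = divergence_time_my * 1e6
    exp_subs = (syn_rate + nonsyn_rate) * 2 * T
    if exp_subs > 1:
        import warnings

        warnings.warn(
            f"expected substitutions per site {exp_subs:.2f} > 1: "
            "saturation regime",
            UserWarning,
            stacklevel=2,
        )
    sense = mr.SENSE_CODONS
    ancestor = [sense[i] for i in rng.integers(len(sense), size=n_codons)]

    def evolve(codon):
        t = 0.0
        while True:
            s, n = mr.codon_site_counts(codon)
            syn_nb = mr.synonymous_neighbors(codon)
            non_nb = mr.nonsynonymous_neighbors(codon)
            lam_s = syn_rate * s if syn_nb else 0.0
            lam_n = nonsyn_rate * n if non_nb else 0.0
            lam = lam_s + lam_n
            if lam <= 0:
                return codon
            t += rng.exponential(1.0 / lam)
            if t >= T:
                return codon
            if rng.random() < lam_s / lam:
                codon = syn_nb[int(rng.integers(len(syn_nb)))]
            else:
                codon = non_nb[int(rng.integers(len(non_nb)))]

    seq_a = "".join(evolve(c) for c in ancestor)
    seq_b = "".join(evolve(c) for c in ancestor)
    return mr.CodonAlignment(["lineage_a", "lineage_b"], [seq_a, seq_b])


# ---------------------------------------------------------------------------
# BGC domain strings
# ---------------------------------------------------------------------------

def simulate_bgc_families(tree: DatedTree, config: SimConfig):
    """BGC domain-string families with planted phylogenetic restriction.

    Each true family has an archetype domain string; restricted families
    place members on the leaves of one randomly chosen clade (of 2 to half
    the taxa), dispersed families on an equally sized uniform random leaf
    set, so restricted and dispersed families share the same size
    distribution.  Members are perturbed copies of the archetype
    (per-domain substitution, insertion, deletion at the configured
    probability), never shorter than 3 domains.

    Returns ``(clusters, true_family, true_restricted)`` where clusters is
    a list of :class:`~chronolgt.bgc_families.BGCluster`.
    """
    from .bgc_families import BGCluster

    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    leaves = sorted(tree.leaf_labels)
    n = len(leaves)
    eligible = [
        v
        for v in range(tree.n_nodes)
        if not tree.is_leaf(v) and 2 <= len(tree.leaf_set(v)) <= max(2, n // 2)
    ]
    if not eligible:
        raise ValueError("tree too small to place restricted families")
    domains = [f"d{i:03d}" for i in range(config.n_domain_types)]
    p = config.domain_mutation_prob

    def perturb(arch):
        out = []
        for d in arch:
            if rng.random() < p:  # substitution
                d = domains[int(rng.integers(len(domains)))]
            if rng.random() < p / 2 and len(arch) + len(out) > 3:  # deletion
                continue
            out.append(d)
            if rng.random() < p / 2:  # insertion
                out.append(domains[int(rng.integers(len(domains)))])
        while len(out) < 3:
            out.append(domains[int(rng.integers(len(domains)))])
        return tuple(out)

    clusters = []
    true_family = {}
    true_restricted = {}
    for f in range(config.n_bgc_families):
        fam = f"BGCF{f:03d}"
        restricted = bool(rng.random() < config.restricted_fraction)
        arch = tuple(
            domains[int(rng.integers(len(domains)))]
            for _ in range(config.archetype_length)
        )
        clade = eligible[int(rng.integers(len(eligible)))]
        size = len(tree.leaf_set(clade))
        if restricted:
            taxa = sorted(tree.leaf_set(clade))
        else:
            taxa = sorted(
                leaves[i] for i in rng.choice(n, size=size, replace=False)
            )
        for genome in taxa:
            cid = f"{fam}_{genome}"
            clusters.append(BGCluster(cid, genome, perturb(arch)))
            true_family[cid] = fam
        true_restricted[fam] = restricted
    return clusters, true_family, true_restricted
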