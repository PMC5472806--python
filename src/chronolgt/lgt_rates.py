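"""Clock-calibrated lateral gene transfer rates.

Turns a list of transfer events (simulated ground truth or reconciliation
output) into the rate summaries a dated tree makes possible: per-clade
acquisition rates normalized by the clade ancestor's age, a donor-source
classification with an exact contingency test for within-clade bias, and
per-branch rates with a log-log power-law fit capturing how detectable LGT
declines on long branches (old acquisitions have had more time to be lost
again).

Rate conventions
----------------
The headline clade rate divides the acquisition count by the age of the
clade's last common ancestor (events per my); the per-node variant further
divides by the number of branches in the clade.  A third normalization,
events per lineage-my (count divided by the summed branch time of the
clade), is also reported because it is the direct estimator of a per-
lineage transfer intensity.  Events on the clade ancestor's stem branch
count as acquisitions by the clade, since the whole clade inherits them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_core import DatedTree, TreeError, lca

__all__ = [
    "TransferEvent",
    "PowerLawFit",
    "classify_events",
    "clade_rate",
    "rate_table",
    "donor_bias_table",
    "branch_rates",
    "fit_power_law",
    "read_events_tsv",
    "write_events_tsv",
]

CATEGORIES = ("within_clade", "cross_clade", "other_lineage", "outgroup")


@dataclass(frozen=True)
class TransferEvent:
    """One gene acquisition: family, recipient branch, donor, time (my).

    ``recipient`` and ``donor`` are species-tree branch ids (the node below
    the branch); ``donor`` may be ``None`` for an unknown/outgroup source.
    ``kind`` distinguishes node-witnessed transfers from transfer-loss
    composites and simulated truth; ``detectable`` marks simulated events
    whose acquired copy survives in at least one sampled genome.
    """

    family: Optional[str]
    recipient: int
    donor: Optional[int] = None
    time_my: float = float("nan")
    donor_category: Optional[str] = None
    gene_node: Optional[int] = None
    kind: str = "transfer"
    detectable: Optional[bool] = None


@dataclass
class PowerLawFit:
    """rate ~ c * length^alpha fitted by OLS on the log-log scale."""

    alpha: float
    c: float
    r_squared: float
    n_points: int
    n_zero_excluded: int
    points: pd.DataFrame


def _check_branch(tree: DatedTree, b) -> int:
    b = int(b)
    if b < 0 or b >= tree.n_nodes or tree.parent[b] is None:
        raise TreeError(f"event references unknown or root branch {b}")
    return b


def classify_events(
    events: Sequence[TransferEvent], tree: DatedTree
) -> List[TransferEvent]:
    """Label each event's donor source relative to its recipient's clade.

    A branch belongs to a clade when all its descendant leaves share that
    clade label; branches with mixed descendants (deep ancestral lineages)
    classify as ``other_lineage`` donors.  Events without a donor branch
    keep a pre-assigned category or fall back to ``outgroup``.
    """
    if tree.clade_map is None:
        raise TreeError("species tree has no clade map")
    out = []
    for ev in events:
        rec = _check_branch(tree, ev.recipient)
        rclade = tree.clade_of_branch(rec)
        if ev.donor is None:
            cat = ev.donor_category or "outgroup"
        else:
            don = _check_branch(tree, ev.donor)
            dclade = tree.clade_of_branch(don)
            if dclade is None:
                cat = "other_lineage"
            elif rclade is not None and dclade == rclade:
                cat = "within_clade"
            elif rclade is not None:
                cat = "cross_clade"
            else:
                cat = "other_lineage"
        out.append(replace(ev, donor_category=cat))
    return out


def _clade_branch_set(tree: DatedTree, clade: str):
    """Branches of a clade: everything below its LCA plus the LCA's stem."""
    if tree.clade_map is None:
        raise TreeError("species tree has no clade map")
    members = [g for g, c in tree.clade_map.items() if c == clade]
    if not members:
        raise TreeError(f"no genomes labelled with clade {clade!r}")
    if len(members) == 1:
        raise TreeError(
            f"clade {clade!r} has a single genome: its LCA age is 0 and no "
            "clock-normalized rate exists"
        )
    anc = lca(tree, members)
    below = set()
    stack = list(tree.children[anc])
    while stack:
        v = stack.pop()
        below.add(v)
        stack.extend(tree.children[v])
    branches = set(below)
    if tree.parent[anc] is not None:
        branches.add(anc)  # the stem: acquisitions here are inherited by all
    return members, anc, branches


def clade_rate(
    events: Sequence[TransferEvent], tree: DatedTree, clade: str
) -> dict:
    """Acquisition rates into one clade, under three normalizations.

    Returns a dict with the event count, the clade LCA age, the clade-total
    rate (count / age), the per-node rate (count / n_branches / age) and
    the per-lineage-my rate (count / summed branch time of the clade).
    """
    members, anc, branches = _clade_branch_set(tree, clade)
    age = float(tree.ages[anc])
    count = sum(1 for ev in events if int(ev.recipient) in branches)
    total_time = float(sum(tree.branch_length(b) for b in branches))
    n_branches = len(branches)
    return {
        "clade": clade,
        "n_genomes": len(members),
        "lca_age_my": age,
        "n_branches": n_branches,
        "n_events": count,
        "clade_total_rate_per_my": count / age,
        "per_node_rate_per_my": count / (n_branches * age),
        "per_lineage_rate_per_my": count / total_time if total_time > 0 else math.nan,
        "lineage_time_my": total_time,
    }


def rate_table(
    events: Sequence[TransferEvent],
    tree: DatedTree,
    clades: Sequence[str] = ("I", "II"),
) -> pd.DataFrame:
    """Source-by-recipient-clade rate matrix (one row per pair).

    Events are classified against the tree's clade map first; counts are
    normalized by the recipient clade's LCA age and branch count.
    """
    classified = classify_events(events, tree)
    rows = []
    for clade in clades:
        _, anc, branches = _clade_branch_set(tree, clade)
        age = float(tree.ages[anc])
        n_br = len(branches)
        into = [ev for ev in classified if int(ev.recipient) in branches]
        for cat in CATEGORIES + ("total",):
            sub = into if cat == "total" else [
                ev for ev in into if ev.donor_category == cat
            ]
            rows.append(
                {
                    "recipient_clade": clade,
                    "source": cat,
                    "n_events": len(sub),
                    "lca_age_my": age,
                    "n_branches": n_br,
                    "rate_per_my": len(sub) / age,
                    "per_node_rate_per_my": len(sub) / (n_br * age),
                }
            )
    return pd.DataFrame(rows)


def donor_bias_table(
    events: Sequence[TransferEvent],
    tree: DatedTree,
    clades: Sequence[str] = ("I", "II"),
):
    """2x2 recipient-clade x donor-clade table with Fisher's exact test.

    Restricted to events whose recipient and donor branches both fall
    cleanly inside the two major clades; a diagonal-heavy table means
    lineages preferentially receive genes from their own clade.  Returns
    ``(table_df, p_value)`` with the two-sided exact hypergeometric p.
    """
    if len(clades) != 2:
        raise ValueError("donor bias test requires exactly two clades")
    classified = classify_events(events, tree)
    table = np.zeros((2, 2), dtype=int)
    cl = {c: i for i, c in enumerate(clades)}
    for ev in classified:
        if ev.donor is None:
            continue
        rclade = tree.clade_of_branch(int(ev.recipient))
        dclade = tree.clade_of_branch(int(ev.donor))
        if rclade in cl and dclade in cl:
            table[cl[rclade], cl[dclade]] += 1
    if table.sum() == 0:
        raise TreeError("no events with both donor and recipient in the clades")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    df = pd.DataFrame(
        table,
        index=pd.Index(clades, name="recipient_clade"),
        columns=pd.Index(clades, name="donor_clade"),
    )
    return df, float(p)


def branch_rates(
    events: Sequence[TransferEvent], tree: DatedTree
) -> pd.DataFrame:
    """Events and events-per-my on every branch of the tree.

    Zero-duration branches cannot occur in a validated dated tree, but any
    encountered are excluded and counted in ``df.attrs['n_zero_length']``.
    """
    counts = {}
    for ev in events:
        b = _check_branch(tree, ev.recipient)
        counts[b] = counts.get(b, 0) + 1
    rows = []
    n_zero = 0
    for b in tree.branches():
        length = tree.branch_length(b)
        if length <= 0:
            n_zero += 1
            continue
        n = counts.get(b, 0)
        rows.append(
            {
                "branch": b,
                "length_my": length,
                "n_events": n,
                "rate_per_my": n / length,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["n_zero_length"] = n_zero
    return df


def fit_power_law(
    branch_table: pd.DataFrame, pseudo_count: float = 0.0
) -> PowerLawFit:
    """OLS fit of log(rate) on log(branch length): rate = c * L^alpha.

    Branches with zero rate are excluded (log 0 undefined) and counted,
    unless ``pseudo_count`` adds a fractional event to every branch before
    computing rates.
    """
    df = branch_table.copy()
    if pseudo_count > 0:
        df["rate_per_my"] = (df["n_events"] + pseudo_count) / df["length_my"]
    usable = df[df["rate_per_my"] > 0]
    n_zero = int(len(df) - len(usable))
    if len(usable) < 3:
        raise ValueError(
            f"power-law fit needs >=3 branches with positive rate, got {len(usable)}"
        )
    x = np.log(usable["length_my"].to_numpy())
    y = np.log(usable["rate_per_my"].to_numpy())
    res = stats.linregress(x, y)
    return PowerLawFit(
        alpha=float(res.slope),
        c=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue**2),
        n_points=len(usable),
        n_zero_excluded=n_zero,
        points=usable.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

_EVENT_COLS = [
    "family",
    "recipient",
    "donor",
    "time_my",
    "donor_category",
    "kind",
    "detectable",
]


def write_events_tsv(events: Sequence[TransferEvent], path_or_buffer):
    rows = [
        {
            "family": ev.family,
            "recipient": ev.recipient,
            "donor": "" if ev.donor is None else ev.donor,
            "time_my": ev.time_my,
            "donor_category": ev.donor_category or "",
            "kind": ev.kind,
            "detectable": "" if ev.detectable is None else int(ev.detectable),
        }
        for ev in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(
        path_or_buffer, sep="\t", index=False
    )


def read_events_tsv(path_or_buffer) -> List[TransferEvent]:
    df = pd.read_csv(path_or_buffer, sep="\t", dtype={"family": str})
    out = []
    for _, r in df.iterrows():
        donor = r.get("donor")
        donor = None if pd.isna(donor) or donor == "" else int(donor)
        det = r.get("detectable")
        det = None if pd.isna(det) or det == "" else bool(int(det))
        cat = r.get("donor_category")
        cat = None if pd.isna(cat) or cat == "" else str(cat)
        out.append(
            TransferEvent(
                family=str(r["family"]),
                recipient=int(r["recipient"]),
                donor=donor,
                time_my=float(r["time_my"]),
                donor_category=cat,
                kind=str(r.get("kind", "transfer")),
                detectable=det,
            )
        )
    return out
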