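"""Synonymous/nonsynonymous mutation rates from codon alignments.

Site and difference counting follows the pathway-counting approach: each
codon position contributes fractional synonymous/nonsynonymous site counts
according to which of its three possible single-nucleotide changes
preserve the amino acid (changes creating stop codons are excluded from
the denominator), and a differing codon pair is scored by averaging the
per-step classification over all shortest mutational paths between the
two codons, discarding paths that pass through a stop codon.  An optional
Jukes-Cantor-style correction converts the per-site proportions pS and pN
into multiple-hit-corrected distances.

Clock calibration divides the per-site divergence by twice the pair's
divergence time (both lineages accumulate changes independently since
their common ancestor), yielding rates per site per year; genome-wide
totals per my follow by scaling the sampled site counts to the genome's
total protein-coding length.

The genetic code is the bacterial table (translation table 11), taken
from Biopython.
"""

from __future__ import annotations

import functools
import itertools
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CodonAlignment",
    "SiteCounts",
    "ClockRates",
    "SENSE_CODONS",
    "STOP_CODONS",
    "codon_site_counts",
    "pair_difference_counts",
    "alignment_counts",
    "clock_rates",
    "genome_extrapolation",
    "rate_vs_divergence",
]

_NT = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE.stop_codons)
AMINO = dict(_TABLE.forward_table)
SENSE_CODONS = tuple(sorted(AMINO))


def _neighbors(codon: str):
    for pos in range(3):
        for nt in _NT:
            if nt != codon[pos]:
                yield codon[:pos] + nt + codon[pos + 1 :], pos


# Per-codon fractional site counts and neighbor classification, cached.
_SITES = {}
_SYN_NEIGHBORS = {}
_NONSYN_NEIGHBORS = {}
for _c in SENSE_CODONS:
    syn = 0.0
    nonsyn = 0.0
    sn, nn = [], []
    for pos in range(3):
        muts = [_c[:pos] + nt + _c[pos + 1 :] for nt in _NT if nt != _c[pos]]
        valid = [m for m in muts if m not in STOP_CODONS]
        s = sum(1 for m in valid if AMINO[m] == AMINO[_c])
        frac = s / len(valid) if valid else 0.0
        syn += frac
        nonsyn += 1.0 - frac
        sn.extend(m for m in valid if AMINO[m] == AMINO[_c])
        nn.extend(m for m in valid if AMINO[m] != AMINO[_c])
    _SITES[_c] = (syn, nonsyn)
    _SYN_NEIGHBORS[_c] = tuple(sn)
    _NONSYN_NEIGHBORS[_c] = tuple(nn)


def codon_site_counts(codon: str) -> Tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of a sense codon.

    The two counts always sum to exactly 3; stop-codon mutations are
    excluded from each position's denominator.
    """
    codon = codon.upper()
    if codon not in _SITES:
        raise ValueError(f"not a sense codon: {codon!r}")
    return _SITES[codon]


def synonymous_neighbors(codon: str) -> tuple:
    """Sense codons one synonymous substitution away."""
    return _SYN_NEIGHBORS[codon.upper()]


def nonsynonymous_neighbors(codon: str) -> tuple:
    """Sense codons one nonsynonymous substitution away."""
    return _NONSYN_NEIGHBORS[codon.upper()]


@functools.lru_cache(maxsize=8192)
def pair_difference_counts(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """Average (synonymous, nonsynonymous) differences between two codons.

    All orderings of the differing positions are enumerated (1, 2 or 6
    paths); each step is classified against the genetic code and paths
    passing through a stop codon are discarded, renormalizing over the
    rest.  If every path is blocked by stops, all paths are kept and
    steps into or out of a stop codon count as nonsynonymous.
    """
    a, b = codon_a.upper(), codon_b.upper()
    for c in (a, b):
        if c not in AMINO:
            raise ValueError(f"not a sense codon: {c!r}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return (0.0, 0.0)

    def walk(order, allow_stops):
        cur = a
        s = n = 0.0
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and not allow_stops:
                return None
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                n += 1.0  # only reachable in the all-blocked fallback
            elif AMINO[cur] == AMINO[nxt]:
                s += 1.0
            else:
                n += 1.0
            cur = nxt
        return (s, n)

    paths = [w for order in itertools.permutations(diff)
             if (w := walk(order, False)) is not None]
    if not paths:
        paths = [walk(order, True) for order in itertools.permutations(diff)]
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return (s, n)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """In-frame aligned nucleotide sequences (equal length, multiple of 3)."""

    ids: List[str]
    seqs: List[str]

    def __post_init__(self):
        if len(self.ids) != len(self.seqs) or len(self.seqs) < 2:
            raise ValueError("need >=2 sequences with matching ids")
        L = len(self.seqs[0])
        for s in self.seqs:
            if len(s) != L:
                raise ValueError("sequences must be aligned (equal length)")
        if L % 3 != 0:
            raise ValueError("alignment length must be a multiple of 3")
        bad = set("".join(self.seqs).upper()) - set("ACGT-N")
        if bad:
            raise ValueError(f"unexpected characters in alignment: {sorted(bad)}")
        self.seqs = [s.upper() for s in self.seqs]

    @property
    def n_codons(self) -> int:
        return len(self.seqs[0]) // 3

    def codons(self, which: int):
        s = self.seqs[which]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    def index_of(self, seq_id: str) -> int:
        try:
            return self.ids.index(seq_id)
        except ValueError:
            raise ValueError(f"sequence {seq_id!r} not in alignment") from None

    @classmethod
    def from_fasta(cls, path_or_handle):
        recs = list(SeqIO.parse(path_or_handle, "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])

    def to_fasta(self, path_or_handle):
        recs = [
            SeqRecord(Seq(s), id=i, description="")
            for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(recs, path_or_handle, "fasta")


@dataclass
class SiteCounts:
    """Summed site and difference counts for one sequence pair."""

    S: float          # synonymous sites (averaged over the two sequences)
    N: float          # nonsynonymous sites
    Sd: float         # synonymous differences
    Nd: float         # nonsynonymous differences
    n_codons: int     # comparable codons counted
    n_skipped: int    # codons skipped for gaps/ambiguity/stops
    corrected: bool = False

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S > 0 else math.nan

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N > 0 else math.nan

    def _jc(self, p: float) -> float:
        if math.isnan(p):
            return math.nan
        if p >= 0.75:
            return math.inf  # saturated beyond correction
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    @property
    def dS(self) -> float:
        """pS, Jukes-Cantor corrected for multiple hits if enabled."""
        return self._jc(self.pS) if self.corrected else self.pS

    @property
    def dN(self) -> float:
        return self._jc(self.pN) if self.corrected else self.pN


def alignment_counts(
    alignment: CodonAlignment,
    pair: Tuple = (0, 1),
    correction: bool = True,
) -> SiteCounts:
    """Site and difference counts for one pair of aligned sequences.

    Codons containing gaps, ambiguity codes or stop codons in either
    sequence are skipped and tallied.  Site counts are averaged over the
    two sequences, the standard symmetric convention.
    """
    ia = pair[0] if isinstance(pair[0], int) else alignment.index_of(pair[0])
    ib = pair[1] if isinstance(pair[1], int) else alignment.index_of(pair[1])
    S = N = Sd = Nd = 0.0
    n_ok = n_skip = 0
    for ca, cb in zip(alignment.codons(ia), alignment.codons(ib)):
        if ca not in AMINO or cb not in AMINO:
            n_skip += 1
            continue
        sa, na = _SITES[ca]
        sb, nb = _SITES[cb]
        S += 0.5 * (sa + sb)
        N += 0.5 * (na + nb)
        ds, dn = pair_difference_counts(ca, cb)
        Sd += ds
        Nd += dn
        n_ok += 1
    if n_ok == 0:
        raise ValueError("no comparable codons in the chosen pair")
    return SiteCounts(S, N, Sd, Nd, n_ok, n_skip, corrected=correction)


@dataclass
class ClockRates:
    """Per-site-per-year rates calibrated by a divergence time in my."""

    syn_rate: float
    nonsyn_rate: float
    divergence_time_my: float
    counts: SiteCounts


def clock_rates(counts: SiteCounts, divergence_time_my: float) -> ClockRates:
    """Convert per-site divergence into rates per site per year.

    Divides by 2 x T: the two lineages have each been accumulating changes
    for T my since their common ancestor.
    """
    if divergence_time_my <= 0:
        raise ValueError("divergence time must be positive")
    denom = 2.0 * divergence_time_my * 1e6
    return ClockRates(
        syn_rate=counts.dS / denom,
        nonsyn_rate=counts.dN / denom,
        divergence_time_my=divergence_time_my,
        counts=counts,
    )


def genome_extrapolation(
    rates: ClockRates,
    genome_total_cds_length: float,
) -> dict:
    """Genome-wide mutation totals per my from sampled-alignment rates.

    Scales the sampled synonymous/nonsynonymous site counts by the ratio
    of the genome's total protein-coding length to the sampled alignment
    length, then multiplies by the per-site-per-year rate over 1 my.
    """
    c = rates.counts
    sampled_len = c.S + c.N
    if sampled_len <= 0 or genome_total_cds_length <= 0:
        raise ValueError("site totals and genome CDS length must be positive")
    scale = genome_total_cds_length / sampled_len
    syn_sites = c.S * scale
    nonsyn_sites = c.N * scale
    return {
        "syn_sites_genome": syn_sites,
        "nonsyn_sites_genome": nonsyn_sites,
        "syn_mutations_per_my": rates.syn_rate * 1e6 * syn_sites,
        "nonsyn_mutations_per_my": rates.nonsyn_rate * 1e6 * nonsyn_sites,
    }


def rate_vs_divergence(
    pairs: Sequence[Tuple[str, SiteCounts, float]],
    time_cutoff_my: float = 100.0,
):
    """Per-pair rates and medians over pairs younger than a cutoff.

    ``pairs`` holds (pair id, SiteCounts, divergence time my) records.
    Observed rates fall with divergence time once sites saturate, so the
    median is taken over the closely related pairs only; the full table is
    returned so the divergence dependence stays visible.
    """
    rows = []
    for pid, counts, t in pairs:
        r = clock_rates(counts, t)
        rows.append(
            {
                "pair": pid,
                "T_my": t,
                "S": counts.S,
                "N": counts.N,
                "Sd": counts.Sd,
                "Nd": counts.Nd,
                "pS": counts.pS,
                "pN": counts.pN,
                "syn_rate": r.syn_rate,
                "nonsyn_rate": r.nonsyn_rate,
            }
        )
    df = pd.DataFrame(rows)
    under = df[df["T_my"] < time_cutoff_my]
    if under.empty:
        raise ValueError(f"no pair with divergence time < {time_cutoff_my} my")
    medians = {
        "cutoff_my": time_cutoff_my,
        "n_pairs": int(len(under)),
        "median_syn_rate": float(under["syn_rate"].median()),
        "median_nonsyn_rate": float(under["nonsyn_rate"].median()),
    }
    return df, medians
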