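"""Gene-family presence/absence matrices and pan-genome summaries.

Presence is binary: a family is either represented in a genome or not,
copy number ignored.  Conservation summaries count, for a group of
genomes, the families present, conserved at a threshold fraction, unique
to the group, and unique-and-conserved.  Pairwise sharing uses the Jaccard
index of family sets (shared over union), reported alongside a supplied
per-pair distance such as divergence time, which is how shared gene
content is related to phylogenetic distance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = ["GeneFamilyMatrix", "conservation_summary", "pairwise_sharing"]


class MatrixError(ValueError):
    pass


@dataclass
class GeneFamilyMatrix:
    """Binary genomes x families matrix backed by a pandas DataFrame."""

    data: pd.DataFrame  # index: genome ids, columns: family ids, values 0/1
    clades: Optional[dict] = None

    def __post_init__(self):
        df = self.data
        if df.index.duplicated().any():
            raise MatrixError("duplicate genome ids")
        if df.columns.duplicated().any():
            raise MatrixError("duplicate family ids")
        vals = df.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise MatrixError("matrix values must be 0/1")
        if (vals.sum(axis=0) == 0).any():
            empty = [c for c in df.columns if df[c].sum() == 0]
            raise MatrixError(f"families present in no genome: {empty[:5]}")
        self.data = df.astype(np.int8)

    @property
    def genomes(self) -> list:
        return list(self.data.index)

    @property
    def families(self) -> list:
        return list(self.data.columns)

    @property
    def n_genomes(self) -> int:
        return self.data.shape[0]

    @property
    def n_families(self) -> int:
        return self.data.shape[1]

    def family_count(self, genome: str) -> int:
        return int(self.data.loc[genome].sum())

    def families_of(self, genome: str) -> set:
        row = self.data.loc[genome]
        return set(row.index[row == 1])

    @classmethod
    def from_tsv(cls, path_or_buffer, clades: Optional[dict] = None):
        df = pd.read_csv(path_or_buffer, sep="\t", index_col=0)
        return cls(df, clades=clades)

    def to_tsv(self, path_or_buffer):
        self.data.to_csv(path_or_buffer, sep="\t")


def conservation_summary(
    matrix: GeneFamilyMatrix, group: Iterable[str], threshold: float = 0.95
) -> dict:
    """Pan-genome counts for a genome group at a conservation threshold.

    present: families with >=1 member in the group; conserved: present in
    >= ``threshold`` fraction of the group; unique: present in the group
    and absent from every other genome; unique_conserved: both.
    """
    group = list(dict.fromkeys(group))
    if not group:
        raise MatrixError("empty genome group")
    missing = set(group) - set(matrix.genomes)
    if missing:
        raise MatrixError(f"genomes not in matrix: {sorted(missing)[:5]}")
    if not (0 < threshold <= 1):
        raise MatrixError("threshold must be in (0, 1]")
    sub = matrix.data.loc[group]
    others = matrix.data.drop(index=group)
    in_group = sub.sum(axis=0)
    present = in_group >= 1
    conserved = in_group >= threshold * len(group)
    unique = present & (others.sum(axis=0) == 0 if len(others) else True)
    return {
        "n_group": len(group),
        "threshold": threshold,
        "present": int(present.sum()),
        "conserved": int(conserved.sum()),
        "unique": int(unique.sum()),
        "unique_conserved": int((unique & conserved).sum()),
        "total_families": matrix.n_families,
    }


def pairwise_sharing(
    matrix: GeneFamilyMatrix, distances: Optional[pd.DataFrame] = None
) -> pd.DataFrame:
    """Jaccard shared-family fraction for every genome pair.

    ``distances``, if given, must hold columns (genome_a, genome_b,
    distance) covering every unordered pair; the sharing table is joined
    with it so shared content can be regressed on e.g. divergence time.
    """
    X = matrix.data.to_numpy(dtype=np.int64)
    inter = X @ X.T
    sizes = X.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    genomes = matrix.genomes
    rows = []
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            u = union[i, j]
            rows.append(
                {
                    "genome_a": genomes[i],
                    "genome_b": genomes[j],
                    "jaccard": inter[i, j] / u if u > 0 else 0.0,
                }
            )
    df = pd.DataFrame(rows)
    if distances is not None:
        d = distances.copy()
        need = {"genome_a", "genome_b", "distance"}
        if not need.issubset(d.columns):
            raise MatrixError("distances needs columns genome_a, genome_b, distance")
        key = lambda a, b: tuple(sorted((a, b)))
        dmap = {
            key(r.genome_a, r.genome_b): r.distance for r in d.itertuples()
        }
        missing = [
            (r.genome_a, r.genome_b)
            for r in df.itertuples()
            if key(r.genome_a, r.genome_b) not in dmap
        ]
        if missing:
            raise MatrixError(f"distance missing for pairs: {missing[:5]}")
        df["distance"] = [
            dmap[key(r.genome_a, r.genome_b)] for r in df.itertuples()
        ]
    return df
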