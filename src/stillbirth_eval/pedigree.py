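"""Additive relationship matrices for sire-maternal-grandsire pedigrees.

In a sire-MGS evaluation every genetic effect belongs to a bull, and the
pedigree records for each bull his sire and his maternal grandsire (MGS).
A calf receives half of its sire's additive value and a quarter of its
MGS's value, so the numerator relationship matrix A obeys the recursion

    a_ij = 1/2 a_{s(i),j} + 1/4 a_{m(i),j}   (j earlier than i),
    a_ii = 1,

with unknown ancestors contributing nothing.  Inbreeding is ignored, which
keeps the Mendelian-sampling variances closed-form:

    d_i = 11/16  (sire and MGS known)
          3/4    (sire only)
          15/16  (MGS only)
          1      (founder)

and makes A^{-1} directly assemblable from per-bull contributions
(1/d_i) * k k' with k = (1, -1/2, -1/4) on (bull, sire, MGS).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

UNKNOWN = "0"

__all__ = [
    "UNKNOWN",
    "PedigreeError",
    "SireMgsPedigree",
    "RelationshipInverse",
    "build_a_inverse",
    "relationship_matrix_bruteforce",
]


class PedigreeError(ValueError):
    """Raised for cyclic, unordered or otherwise invalid pedigrees."""


@dataclass
class SireMgsPedigree:
    """Ordered bull pedigree: each entry is (bull, sire-or-0, MGS-or-0, birth year).

    Ancestors must precede descendants; the constructor verifies this and
    rejects self-ancestry.  Unknown parents are the literal ``"0"``.
    """

    entries: pd.DataFrame  # columns: bull_id, sire_id, mgs_id, birth_year
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        df = self.entries
        required = ["bull_id", "sire_id", "mgs_id", "birth_year"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise PedigreeError(f"pedigree missing columns: {missing}")
        df = df.astype({"bull_id": str, "sire_id": str, "mgs_id": str})
        df["birth_year"] = df["birth_year"].astype(int)
        self.entries = df.reset_index(drop=True)
        ids = self.entries["bull_id"].tolist()
        if len(set(ids)) != len(ids):
            raise PedigreeError("duplicate bull ids in pedigree")
        self._index = {b: i for i, b in enumerate(ids)}
        for i, (bull, sire, mgs) in enumerate(
            self.entries[["bull_id", "sire_id", "mgs_id"]].itertuples(index=False)
        ):
            for anc in (sire, mgs):
                if anc == UNKNOWN:
                    continue
                if anc == bull:
                    raise PedigreeError(f"bull {bull} is its own ancestor")
                j = self._index.get(anc)
                if j is None:
                    raise PedigreeError(f"ancestor {anc} of {bull} not in pedigree")
                if j >= i:
                    raise PedigreeError(
                        f"pedigree not topologically ordered: {anc} after {bull}"
                    )

    @property
    def n_bulls(self) -> int:
        return len(self.entries)

    @property
    def bull_ids(self) -> list[str]:
        return self.entries["bull_id"].tolist()

    def index_of(self, bull_id: str) -> int:
        return self._index[bull_id]

    def __contains__(self, bull_id: str) -> bool:
        return bull_id in self._index

    def birth_year_of(self, bull_id: str) -> int:
        return int(self.entries.loc[self._index[bull_id], "birth_year"])

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SireMgsPedigree":
        return cls(pd.read_csv(path, dtype={"bull_id": str, "sire_id": str, "mgs_id": str}))


@dataclass
class RelationshipInverse:
    """Sparse A^{-1} over bulls plus the bull-id -> row map."""

    matrix: sp.csr_matrix
    index_map: dict

    @property
    def n_bulls(self) -> int:
        return self.matrix.shape[0]

    def to_triplets(self, path) -> None:
        """Export nonzeros as delimited (row, col, value) text."""
        coo = self.matrix.tocoo()
        pd.DataFrame({"row": coo.row, "col": coo.col, "value": coo.data}).to_csv(
            path, index=False
        )


def _mendelian_d(sire_known: bool, mgs_known: bool) -> float:
    if sire_known and mgs_known:
        return 11.0 / 16.0
    if sire_known:
        return 3.0 / 4.0
    if mgs_known:
        return 15.0 / 16.0
    return 1.0


def build_a_inverse(pedigree: SireMgsPedigree) -> RelationshipInverse:
    """Assemble sparse A^{-1} by the sire-MGS rules (no inbreeding)."""
    n = pedigree.n_bulls
    rows, cols, vals = [], [], []
    idx = pedigree._index
    for i, (bull, sire, mgs) in enumerate(
        pedigree.entries[["bull_id", "sire_id", "mgs_id"]].itertuples(index=False)
    ):
        members = [(i, 1.0)]
        if sire != UNKNOWN:
            members.append((idx[sire], -0.5))
        if mgs != UNKNOWN:
            members.append((idx[mgs], -0.25))
        dinv = 1.0 / _mendelian_d(sire != UNKNOWN, mgs != UNKNOWN)
        for a, ka in members:
            for b, kb in members:
                rows.append(a)
                cols.append(b)
                vals.append(dinv * ka * kb)
    mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return RelationshipInverse(matrix=mat, index_map=dict(idx))


def relationship_matrix_bruteforce(pedigree: SireMgsPedigree, max_bulls: int = 2000) -> np.ndarray:
    """Dense A by the tabular method; a test oracle for :func:`build_a_inverse`.

    The diagonal is the generative-model variance under the fixed
    Mendelian-sampling terms, a_ii = d_i + 1/4 a_ss + 1/16 a_mm + 1/4 a_sm,
    which reduces to 1 whenever a bull's sire and MGS are unrelated
    founder-descendants.  This is the exact inverse partner of
    :func:`build_a_inverse` for every pedigree.
    """
    n = pedigree.n_bulls
    if n > max_bulls:
        raise PedigreeError(f"brute-force oracle capped at {max_bulls} bulls, got {n}")
    idx = pedigree._index
    a = np.zeros((n, n))
    for i, (bull, sire, mgs) in enumerate(
        pedigree.entries[["bull_id", "sire_id", "mgs_id"]].itertuples(index=False)
    ):
        s = idx[sire] if sire != UNKNOWN else None
        m = idx[mgs] if mgs != UNKNOWN else None
        for j in range(i):
            v = 0.0
            if s is not None:
                v += 0.5 * a[s, j]
            if m is not None:
                v += 0.25 * a[m, j]
            a[i, j] = a[j, i] = v
        d = _mendelian_d(s is not None, m is not None)
        v = d
        if s is not None:
            v += 0.25 * a[s, s]
        if m is not None:
            v += (1.0 / 16.0) * a[m, m]
        if s is not None and m is not None:
            v += 0.25 * a[s, m]
        a[i, i] = v
    return a
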