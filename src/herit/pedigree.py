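"""Pedigree records and the expected additive relationship matrix.

The additive relationship matrix ``A`` gives, for every pair of individuals,
twice their kinship coefficient — the expected fraction of the genome shared
identical by descent under the pedigree.  ``build_A`` implements the tabular
method (one pass in topological order); ``kinship_oracle`` is an independent
pairwise recursion kept deliberately separate so the two can be checked
against each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

__all__ = ["PedigreeTable", "PedigreeError", "build_A", "kinship_oracle"]

#: tokens that denote an unknown parent in pedigree files
UNKNOWN_TOKENS = {"", "0", "NA", "na", ".", "none", "None"}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates, ...)."""


@dataclass
class PedigreeTable:
    """Ordered parent/offspring records.

    Records keep the order in which they were supplied; a topological order
    (parents before offspring) is validated and computed at construction and
    exposed as :attr:`topo`.  Parent indices are ``-1`` when unknown.
    """

    ids: list[str]
    sire: np.ndarray  # index into ids, -1 = unknown
    dam: np.ndarray
    sex: np.ndarray  # 'M' / 'F' / 'U'
    cohort: np.ndarray  # small integer, founders = 1
    topo: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.ids = [str(t) for t in self.ids]
        n = len(self.ids)
        self.sire = np.asarray(self.sire, dtype=int)
        self.dam = np.asarray(self.dam, dtype=int)
        self.sex = np.asarray(self.sex, dtype=object)
        self.cohort = np.asarray(self.cohort, dtype=int)
        if len(set(self.ids)) != n:
            counts = pd.Series(self.ids).value_counts()
            raise PedigreeError(
                f"duplicate individual ids: {sorted(counts[counts > 1].index)}"
            )
        for arr, what in ((self.sire, "sire"), (self.dam, "dam")):
            if arr.shape != (n,):
                raise PedigreeError(f"{what} array length mismatch")
            bad = (arr < -1) | (arr >= n)
            if bad.any():
                raise PedigreeError(f"{what} index out of range at rows {np.where(bad)[0]}")
        if np.any((self.sire == np.arange(n)) | (self.dam == np.arange(n))):
            raise PedigreeError("individual listed as its own parent")
        self.topo = self._topological_order()

    # ------------------------------------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PedigreeTable":
        """Build from a frame with columns id, sire, dam[, sex, cohort].

        Unknown parents are encoded as "0" (or NA).  Every named parent must
        itself appear as a record.
        """
        ids = [str(t) for t in df["id"]]
        index = {t: k for k, t in enumerate(ids)}

        def parent_idx(col: pd.Series) -> np.ndarray:
            out = np.full(len(ids), -1, dtype=int)
            for k, raw in enumerate(col):
                tok = "" if pd.isna(raw) else str(raw).strip()
                if tok in UNKNOWN_TOKENS:
                    continue
                if tok not in index:
                    raise PedigreeError(
                        f"parent {tok!r} of {ids[k]!r} has no individual record"
                    )
                out[k] = index[tok]
            return out

        sex = (
            np.asarray([str(s).upper()[:1] if not pd.isna(s) else "U" for s in df["sex"]], dtype=object)
            if "sex" in df
            else np.full(len(ids), "U", dtype=object)
        )
        cohort = df["cohort"].to_numpy(int) if "cohort" in df else np.ones(len(ids), int)
        return cls(ids=ids, sire=parent_idx(df["sire"]), dam=parent_idx(df["dam"]),
                   sex=sex, cohort=cohort)

    def to_frame(self) -> pd.DataFrame:
        def tok(arr: np.ndarray) -> list[str]:
            return [self.ids[k] if k >= 0 else "0" for k in arr]

        return pd.DataFrame(
            {"id": self.ids, "sire": tok(self.sire), "dam": tok(self.dam),
             "sex": self.sex, "cohort": self.cohort}
        )

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def is_founder(self) -> np.ndarray:
        return (self.sire < 0) & (self.dam < 0)

    @property
    def is_topologically_sorted(self) -> bool:
        idx = np.arange(self.n)
        return bool(np.all((self.sire < idx) & (self.dam < idx)))

    def first_unordered_record(self) -> str | None:
        """Id of the first record whose parent appears later in the file."""
        for k in range(self.n):
            if self.sire[k] >= k or self.dam[k] >= k:
                return self.ids[k]
        return None

    def _topological_order(self) -> np.ndarray:
        """Kahn's algorithm over parent->child edges; cycles are fatal."""
        n = self.n
        children: list[list[int]] = [[] for _ in range(n)]
        indeg = np.zeros(n, dtype=int)
        for k in range(n):
            for p in (self.sire[k], self.dam[k]):
                if p >= 0:
                    children[p].append(k)
                    indeg[k] += 1
        order: list[int] = []
        queue = [k for k in range(n) if indeg[k] == 0]
        while queue:
            k = queue.pop()
            order.append(k)
            for c in children[k]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != n:
            cycle = [self.ids[k] for k in range(n) if indeg[k] > 0]
            raise PedigreeError(f"pedigree contains a cycle among: {cycle}")
        return np.asarray(order, dtype=int)


# ----------------------------------------------------------------------
def build_A(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Expected additive relationship matrix by the tabular method.

    Processing individuals in topological order,

    * ``A[i, i] = 1 + 0.5 * A[sire(i), dam(i)]`` (an unknown parent
      contributes 0, so founders get ``A[i, i] = 1``), and
    * ``A[i, j] = 0.5 * (A[sire(i), j] + A[dam(i), j])`` for every ``j``
      already processed.

    Unknown parents are treated as unrelated, non-inbred founders.
    """
    n = pedigree.n
    perm = pedigree.topo
    pos = np.empty(n, dtype=int)
    pos[perm] = np.arange(n)
    # parent positions in the permuted (topological) frame
    sire_p = np.array([pos[s] if s >= 0 else -1 for s in pedigree.sire[perm]])
    dam_p = np.array([pos[d] if d >= 0 else -1 for d in pedigree.dam[perm]])

    Ap = np.zeros((n, n))
    for k in range(n):
        s, d = sire_p[k], dam_p[k]
        if k:
            row = np.zeros(k)
            if s >= 0:
                row += Ap[s, :k]
            if d >= 0:
                row += Ap[d, :k]
            row *= 0.5
            Ap[k, :k] = row
            Ap[:k, k] = row
        Ap[k, k] = 1.0 + (0.5 * Ap[s, d] if (s >= 0 and d >= 0) else 0.0)

    A = Ap[np.ix_(pos, pos)]
    return RelationshipMatrix(ids=list(pedigree.ids), values=A, kind="pedigree_A")


def kinship_oracle(pedigree: PedigreeTable, i: str, j: str) -> float:
    """Additive relationship between ``i`` and ``j`` from pairwise kinship.

    Memoized recursion on the kinship coefficient phi:
    ``phi(i, i) = 0.5 * (1 + phi(sire, dam))`` and, expanding whichever
    member of a pair is later in topological order,
    ``phi(i, j) = 0.5 * (phi(sire(i), j) + phi(dam(i), j))``.
    Returns ``2 * phi(i, j)``; on the diagonal that equals ``1 + F_i``.

    Independent of :func:`build_A` on purpose — it is the test oracle.
    """
    index = {t: k for k, t in enumerate(pedigree.ids)}
    for t in (i, j):
        if t not in index:
            raise KeyError(f"unknown individual id {t!r}")
    pos = np.empty(pedigree.n, dtype=int)
    pos[pedigree.topo] = np.arange(pedigree.n)
    memo: dict[tuple[int, int], float] = {}

    def phi(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        key = (a, b) if a <= b else (b, a)
        if key in memo:
            return memo[key]
        if a == b:
            val = 0.5 * (1.0 + phi(pedigree.sire[a], pedigree.dam[a]))
        else:
            # expand the individual appearing later in topological order;
            # it cannot be an ancestor of the other one
            late, other = (a, b) if pos[a] > pos[b] else (b, a)
            val = 0.5 * (phi(pedigree.sire[late], other) + phi(pedigree.dam[late], other))
        memo[key] = val
        return val

    return 2.0 * phi(index[i], index[j])
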