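"""Symmetric relationship matrices over study individuals.

A :class:`RelationshipMatrix` holds either the pedigree-expected additive
relationship matrix ``A`` (entries are twice the kinship coefficients) or the
marker-realized genomic relationship matrix ``G``.  Both are dense, symmetric
and positive semidefinite (``G`` only up to floating-point noise), and carry
the ordered individual ids so downstream model fitting can align phenotypes.

Text I/O follows the two conventions used in the field: GCTA-style lower
triangle triplets with a companion ``.id`` file, and a square TSV with a
header row of ids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger("herit")

__all__ = ["RelationshipMatrix"]


@dataclass
class RelationshipMatrix:
    """A symmetric kernel over individuals.

    Parameters
    ----------
    ids
        Ordered individual tokens, one per row/column of ``values``.
    values
        Symmetric ``n x n`` array.
    kind
        ``"pedigree_A"`` or ``"genomic_G"``.
    n_markers
        Number of SNPs behind a genomic matrix; 0 for a pedigree matrix.
    """

    ids: list[str]
    values: np.ndarray
    kind: str = "pedigree_A"
    n_markers: int = 0
    jitter_applied: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        self.ids = [str(t) for t in self.ids]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )
        if self.kind not in ("pedigree_A", "genomic_G"):
            raise ValueError(f"unknown relationship-matrix kind {self.kind!r}")
        asym = np.max(np.abs(self.values - self.values.T)) if n else 0.0
        tol = 0.0 if self.kind == "pedigree_A" else 1e-12
        if asym > tol:
            raise ValueError(f"matrix not symmetric (max asymmetry {asym:g})")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])

    def with_jitter(self, eig_floor: float = 1e-10, jitter: float = 1e-8) -> "RelationshipMatrix":
        """Return a PSD-repaired copy: add ``jitter * I`` when the smallest
        eigenvalue falls below ``eig_floor``.  The repair is logged; pedigree
        matrices are PSD by construction and normally pass through unchanged.
        """
        lam = self.min_eigenvalue()
        if lam < eig_floor:
            log.info(
                "%s matrix min eigenvalue %.3g < %.1g; adding %.1g jitter to the diagonal",
                self.kind, lam, eig_floor, jitter,
            )
            return replace(
                self,
                values=self.values + jitter * np.eye(self.n),
                jitter_applied=self.jitter_applied + jitter,
            )
        return self

    def reorder(self, ids: list[str]) -> "RelationshipMatrix":
        """Return a copy restricted/permuted to ``ids`` (all must be present)."""
        index = {t: k for k, t in enumerate(self.ids)}
        missing = [t for t in ids if t not in index]
        if missing:
            raise KeyError(f"ids absent from relationship matrix: {missing[:10]}")
        idx = np.array([index[t] for t in ids])
        return replace(self, ids=list(ids), values=self.values[np.ix_(idx, idx)])

    # ------------------------------------------------------------------
    # text I/O
    def write_square_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", index_label="id", float_format="%.10g"
        )

    @classmethod
    def read_square_tsv(cls, path: str | Path, kind: str = "pedigree_A") -> "RelationshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.columns.astype(str)), values=df.to_numpy(float), kind=kind)

    def write_grm(self, prefix: str | Path) -> None:
        """Write GCTA-style text triplets ``<prefix>.grm.txt`` (1-based lower
        triangle: i, j, marker count, value) and ids to ``<prefix>.grm.id``.
        """
        prefix = str(prefix)
        with open(prefix + ".grm.id", "w") as fh:
            for t in self.ids:
                fh.write(f"{t}\t{t}\n")
        with open(prefix + ".grm.txt", "w") as fh:
            for i in range(self.n):
                for j in range(i + 1):
                    fh.write(f"{i + 1}\t{j + 1}\t{self.n_markers}\t{self.values[i, j]:.10g}\n")

    @classmethod
    def read_grm(cls, prefix: str | Path, kind: str = "genomic_G") -> "RelationshipMatrix":
        prefix = str(prefix)
        ids = [line.split()[1] for line in open(prefix + ".grm.id") if line.strip()]
        n = len(ids)
        values = np.zeros((n, n))
        n_markers = 0
        with open(prefix + ".grm.txt") as fh:
            for line in fh:
                i_s, j_s, m_s, v_s = line.split()
                i, j = int(i_s) - 1, int(j_s) - 1
                values[i, j] = values[j, i] = float(v_s)
                n_markers = int(m_s)
        return cls(ids=ids, values=values, kind=kind, n_markers=n_markers)
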