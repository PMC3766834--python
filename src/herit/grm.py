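"""Genotype QC, binomial imputation, and the genomic relationship matrix.

The genomic relationship matrix (GRM) entry between individuals ``i`` and
``k`` is the average over SNPs of the product of their standardized allele
counts,

    G_ik = (1/p) * sum_j (x_ij - 2*theta_j) * (x_kj - 2*theta_j)
                       / (2 * theta_j * (1 - theta_j)),

where ``x_ij`` counts the allele coded 1 and ``theta_j`` is its empirical
frequency.  The diagonal uses the same formula (no special case).  Under
this standardization the expectation of ``G_ik`` over the segregation
process equals the pedigree relationship ``A_ik``; realized values scatter
around it because of Mendelian sampling.

Pipeline order is fixed: filter individuals -> filter SNPs -> freeze theta
-> impute missing genotypes -> compute G.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .relmat import RelationshipMatrix

log = logging.getLogger("herit")

__all__ = [
    "GenotypeMatrix",
    "GAComparison",
    "filter_genotypes",
    "impute_missing",
    "compute_G",
    "compare_G_A",
]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts with per-SNP frequency metadata.

    ``counts`` holds 0/1/2 dosages of the allele coded 1, with ``nan`` for
    missing.  ``theta`` is the frozen per-SNP frequency of the coded allele;
    when not supplied it is estimated from the non-missing entries.
    ``theta_true`` optionally carries the generative founder frequencies of a
    simulated dataset (used to scale causal effects, never for G).
    """

    ids: list[str]
    snp_ids: list[str]
    counts: np.ndarray
    theta: np.ndarray | None = None
    theta_true: np.ndarray | None = field(default=None, compare=False)
    exclusion_log: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.ids = [str(t) for t in self.ids]
        self.snp_ids = [str(t) for t in self.snp_ids]
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.ids)}, {len(self.snp_ids)})"
            )
        obs = self.counts[~np.isnan(self.counts)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if self.theta is None:
            self.theta = self.estimate_theta()
        else:
            self.theta = np.asarray(self.theta, dtype=float)
            if self.theta.shape != (len(self.snp_ids),):
                raise ValueError("theta length does not match snp_ids")

    # ------------------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def p(self) -> int:
        return len(self.snp_ids)

    def estimate_theta(self) -> np.ndarray:
        """Empirical coded-allele frequency from non-missing entries only
        (nan for all-missing columns); no pseudo-counts.
        """
        n_obs = (~np.isnan(self.counts)).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            # all-missing columns get nan (no pseudo-counts anywhere)
            return np.nansum(self.counts, axis=0) / (2.0 * n_obs)

    @property
    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)

    @property
    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=1)

    @property
    def maf(self) -> np.ndarray:
        th = self.estimate_theta()
        return np.minimum(th, 1.0 - th)

    def flip_coding(self) -> "GenotypeMatrix":
        """Swap which allele is counted: x -> 2 - x, theta -> 1 - theta."""
        return GenotypeMatrix(
            ids=list(self.ids), snp_ids=list(self.snp_ids),
            counts=2.0 - self.counts, theta=1.0 - self.theta,
            theta_true=None if self.theta_true is None else 1.0 - self.theta_true,
        )


# ----------------------------------------------------------------------
def filter_genotypes(
    raw: GenotypeMatrix,
    min_call_rate: float = 0.90,
    min_maf: float = 0.005,
) -> GenotypeMatrix:
    """Apply call-rate and minor-allele-frequency exclusions.

    Individuals with call rate below ``min_call_rate`` are removed first;
    SNP call rates and allele frequencies are then recomputed on the
    remaining individuals, and SNPs failing the call-rate or MAF threshold
    are removed.  The surviving matrix has ``theta`` frozen from this
    post-filter recomputation, and ``exclusion_log`` lists every removal
    with its reason and offending value.
    """
    if not (0 < min_call_rate < 1 and 0 < min_maf < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    records: list[dict] = []

    ind_cr = raw.sample_call_rate
    keep_ind = ind_cr >= min_call_rate
    for k in np.where(~keep_ind)[0]:
        records.append({"token": raw.ids[k], "kind": "individual",
                       "reason": "call_rate", "value": ind_cr[k]})
    if not keep_ind.any():
        raise ValueError("all individuals removed by the call-rate filter")

    counts = raw.counts[keep_ind]
    ids = [t for t, k in zip(raw.ids, keep_ind) if k]
    sub = GenotypeMatrix(ids=ids, snp_ids=list(raw.snp_ids), counts=counts,
                         theta_true=raw.theta_true)
    snp_cr = sub.snp_call_rate
    maf = sub.maf  # nan for all-missing columns; comparisons below are False
    fail_cr = snp_cr < min_call_rate
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < min_maf))
    for j in np.where(fail_cr)[0]:
        records.append({"token": raw.snp_ids[j], "kind": "snp",
                       "reason": "call_rate", "value": snp_cr[j]})
    for j in np.where(fail_maf)[0]:
        records.append({"token": raw.snp_ids[j], "kind": "snp",
                       "reason": "maf", "value": maf[j]})
    keep_snp = ~(fail_cr | fail_maf)
    if not keep_snp.any():
        raise ValueError("all SNPs removed by QC filters")

    out = GenotypeMatrix(
        ids=ids,
        snp_ids=[s for s, k in zip(sub.snp_ids, keep_snp) if k],
        counts=counts[:, keep_snp],
        theta_true=None if raw.theta_true is None else raw.theta_true[keep_snp],
    )
    out.exclusion_log = pd.DataFrame(
        records, columns=["token", "kind", "reason", "value"]
    )
    log.info(
        "QC: removed %d/%d individuals and %d/%d SNPs (call rate < %g or MAF < %g)",
        (~keep_ind).sum(), raw.n, (~keep_snp).sum(), raw.p, min_call_rate, min_maf,
    )
    return out


def impute_missing(g: GenotypeMatrix, seed: int | np.random.Generator) -> GenotypeMatrix:
    """Fill missing genotypes with Binomial(2, theta_j) draws.

    Assumes Hardy-Weinberg equilibrium at the frozen empirical frequency
    ``theta_j``; theta is NOT re-estimated afterwards.  A column with no
    observed genotypes has no frequency to draw from and is an error.
    """
    undefined = np.isnan(g.theta)
    if undefined.any():
        bad = [g.snp_ids[j] for j in np.where(undefined)[0]]
        raise ValueError(f"no non-missing entries to estimate theta for SNPs: {bad[:10]}")
    miss = np.isnan(g.counts)
    if not miss.any():
        return GenotypeMatrix(ids=list(g.ids), snp_ids=list(g.snp_ids),
                              counts=g.counts.copy(), theta=g.theta.copy(),
                              theta_true=g.theta_true)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = g.counts.copy()
    rows, cols = np.where(miss)
    counts[rows, cols] = rng.binomial(2, g.theta[cols])
    return GenotypeMatrix(ids=list(g.ids), snp_ids=list(g.snp_ids), counts=counts,
                          theta=g.theta.copy(), theta_true=g.theta_true)


def compute_G(g: GenotypeMatrix) -> RelationshipMatrix:
    """Marker-derived relationship matrix from standardized allele counts.

    Requires a complete matrix (impute first) and polymorphic SNPs
    (0 < theta_j < 1); monomorphic columns make the standardization divide
    by zero and must be removed by :func:`filter_genotypes`.
    """
    if np.isnan(g.counts).any():
        raise ValueError("genotypes contain missing entries; run impute_missing first")
    theta = np.asarray(g.theta, dtype=float)
    mono = (theta <= 0.0) | (theta >= 1.0)
    if mono.any():
        bad = [g.snp_ids[j] for j in np.where(mono)[0]]
        raise ValueError(
            f"theta in {{0,1}} for SNPs {bad[:10]}: remove monomorphic SNPs "
            "with filter_genotypes before computing G"
        )
    z = (g.counts - 2.0 * theta) / np.sqrt(2.0 * theta * (1.0 - theta))
    G = (z @ z.T) / g.p
    G = 0.5 * (G + G.T)  # scrub float asymmetry from the matmul
    return RelationshipMatrix(ids=list(g.ids), values=G, kind="genomic_G",
                              n_markers=g.p)


# ----------------------------------------------------------------------
@dataclass
class GAComparison:
    """Pairwise comparison of realized (G) vs expected (A) relationships.

    ``pairs`` has one row per unordered pair i<j with columns
    ``id_i, id_j, A, G, d`` (``d = G - A``); ``diagonal`` the per-individual
    diagonals; ``summary`` per pedigree-relationship level the count, mean
    and variance of G and the mean deviation.
    """

    pairs: pd.DataFrame
    diagonal: pd.DataFrame
    summary: pd.DataFrame

    def plot(self, path) -> None:
        """Scatter of G against pedigree level, with dashed horizontal
        reference lines at each expected coefficient."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        rng = np.random.default_rng(0)
        x = self.pairs["A"] + rng.uniform(-0.01, 0.01, len(self.pairs))
        ax.plot(x, self.pairs["G"], ".", ms=2, alpha=0.4, color="tab:blue")
        for level in self.summary["level"]:
            ax.axhline(level, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("pedigree relationship $A_{ij}$")
        ax.set_ylabel("genomic relationship $G_{ij}$")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def compare_G_A(G: RelationshipMatrix, A: RelationshipMatrix) -> GAComparison:
    """Tabulate realized vs expected relationships for all pairs.

    Pairs are binned by their exact pedigree level (0, 0.125, 0.25, 0.5, ...).
    Requires identical id sets; ``G`` is permuted to ``A``'s order if needed.
    """
    if set(G.ids) != set(A.ids):
        only_g = sorted(set(G.ids) - set(A.ids))[:10]
        only_a = sorted(set(A.ids) - set(G.ids))[:10]
        raise ValueError(
            f"id sets differ: only in G {only_g}, only in A {only_a}"
        )
    if G.ids != A.ids:
        G = G.reorder(A.ids)
    iu, ju = np.triu_indices(A.n, k=1)
    ids = np.asarray(A.ids, dtype=object)
    pairs = pd.DataFrame({
        "id_i": ids[iu], "id_j": ids[ju],
        "A": A.values[iu, ju], "G": G.values[iu, ju],
    })
    pairs["d"] = pairs["G"] - pairs["A"]
    # pedigree levels are dyadic rationals; round only to collapse float dust
    pairs["level"] = pairs["A"].round(12)
    grp = pairs.groupby("level")["G"]
    summary = pd.DataFrame({
        "level": grp.mean().index,
        "n_pairs": grp.size().to_numpy(),
        "mean_G": grp.mean().to_numpy(),
        "var_G": grp.var(ddof=1).to_numpy(),
        "mean_d": pairs.groupby("level")["d"].mean().to_numpy(),
    }).reset_index(drop=True)
    diagonal = pd.DataFrame({
        "id": A.ids,
        "A": np.diag(A.values),
        "G": np.diag(G.values),
    })
    return GAComparison(pairs=pairs.drop(columns="level"), diagonal=diagonal,
                        summary=summary)
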