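"""Synthetic multi-generation family studies with known genetic truth.

The generator emulates a three-generation human family design: founders are
drawn with allele frequencies from a configurable law, genotypes descend by
gene dropping (each offspring inherits one uniformly chosen allele from each
parent, independently per SNP), and phenotypes follow an additive model

    y = covariate effects + u + eps,

where the additive genetic value ``u`` is either a sum of random SNP effects
(``marker_effects``) or a multivariate normal draw with covariance
``A * sigma2_u`` (``infinitesimal``), and the residual variance is set so the
narrow-sense heritability ``sigma2_u / (sigma2_u + sigma2_e)`` equals the
requested ``true_h2``.

All randomness flows from the single seed in :class:`SimulationSpec` through
a splittable generator, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grm import GenotypeMatrix
from .pedigree import PedigreeTable
from .relmat import RelationshipMatrix

log = logging.getLogger("herit")

__all__ = [
    "SimulationSpec",
    "TruthRecord",
    "simulate_pedigree",
    "gene_drop",
    "simulate_covariates",
    "simulate_phenotype",
    "inject_missingness",
    "simulate_spirometry",
]

#: default covariate effects; sex is coded female = 1, cohort dummies are
#: against the founder generation
DEFAULT_COVARIATE_EFFECTS = {
    "sex": -0.96,
    "age": -0.032,
    "pc1": 0.10,
    "pc2": 0.10,
    "cohort2": 0.28,
    "cohort3": 0.44,
}


@dataclass
class SimulationSpec:
    """Study design for one synthetic family dataset.

    Parameters
    ----------
    n_founders
        Founder count (>= 2, split half male / half female).
    n_generations
        Total generations including founders (>= 1).
    offspring_per_mating
        Children per monogamous couple.
    n_snps
        Number of independently segregating biallelic SNPs.
    maf_range
        ``(low, high)`` of the uniform law for founder coded-allele
        frequencies; must exclude 0 and 1.  Default (0.05, 0.5) keeps every
        SNP polymorphic and QC-survivable.
    true_h2
        Narrow-sense heritability of the simulated trait, in [0, 1].
    total_variance
        Genetic-plus-residual phenotype variance (sigma2_u + sigma2_e).
    covariate_effects
        Coefficients for sex, age, pc1, pc2 and cohort dummies
        (``cohort2``, ``cohort3``, ...).
    genetic_model
        ``"marker_effects"`` (u from per-SNP causal effects) or
        ``"infinitesimal"`` (u ~ MVN(0, A * sigma2_u)).
    missing_rate
        Probability that a genotype entry is masked, in [0, 1).
    seed
        Root seed for every random draw.
    """

    n_founders: int = 100
    n_generations: int = 3
    offspring_per_mating: int = 2
    n_snps: int = 5000
    maf_range: tuple[float, float] = (0.05, 0.5)
    true_h2: float = 0.5
    total_variance: float = 2.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    genetic_model: str = "marker_effects"
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders < 2: cannot form matings")
        for name in ("n_generations", "offspring_per_mating", "n_snps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if not 0.0 <= self.true_h2 <= 1.0:
            raise ValueError("true_h2 must lie in [0, 1]")
        if self.total_variance <= 0:
            raise ValueError("total_variance must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must lie strictly inside (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.genetic_model not in ("marker_effects", "infinitesimal"):
            raise ValueError(f"unknown genetic_model {self.genetic_model!r}")

    @property
    def sigma2_u(self) -> float:
        return self.true_h2 * self.total_variance

    @property
    def sigma2_e(self) -> float:
        return (1.0 - self.true_h2) * self.total_variance

@dataclass
class TruthRecord:
    """Ground truth carried alongside a simulated phenotype."""

    ids: list[str]
    true_breeding_values: np.ndarray
    true_sigma2_u: float
    true_sigma2_e: float
    causal_effects: np.ndarray | None = None  # marker_effects mode only

    @property
    def true_h2(self) -> float:
        tot = self.true_sigma2_u + self.true_sigma2_e
        return self.true_sigma2_u / tot if tot > 0 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "true_u": self.true_breeding_values})


# ----------------------------------------------------------------------
def _split(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def _balanced_sexes(n: int, rng: np.random.Generator) -> np.ndarray:
    """n//2 males and the rest females, in shuffled order."""
    sexes = np.array(["M"] * (n // 2) + ["F"] * (n - n // 2), dtype=object)
    rng.shuffle(sexes)
    return sexes


def simulate_pedigree(spec: SimulationSpec) -> PedigreeTable:
    """Random monogamous multi-generation pedigree.

    Within each generation, males and females are paired uniformly at random
    into ``min(n_males, n_females)`` non-overlapping couples; each couple has
    ``offspring_per_mating`` children.  Sexes are assigned half-and-half at
    random, so generation sizes are deterministic given the spec.  There is
    no selfing and no overlap between generations.
    """
    rng = _split(spec.seed, 0)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[str] = []
    cohort: list[int] = []

    current: list[int] = []  # row indices of the current generation
    for k in range(spec.n_founders):
        ids.append(f"g1_{k + 1:04d}")
        sire.append(-1)
        dam.append(-1)
        cohort.append(1)
        current.append(k)
    founder_sexes = _balanced_sexes(spec.n_founders, rng)
    sex.extend(founder_sexes)

    for gen in range(2, spec.n_generations + 1):
        males = [k for k in current if sex[k] == "M"]
        females = [k for k in current if sex[k] == "F"]
        rng.shuffle(males)
        rng.shuffle(females)
        couples = list(zip(males, females))
        if not couples:
            raise ValueError(f"generation {gen - 1} has no matable couples")
        n_children = len(couples) * spec.offspring_per_mating
        child_sexes = _balanced_sexes(n_children, rng)
        nxt: list[int] = []
        child = 0
        for s, d in couples:
            for _ in range(spec.offspring_per_mating):
                row = len(ids)
                ids.append(f"g{gen}_{child + 1:04d}")
                sire.append(s)
                dam.append(d)
                sex.append(child_sexes[child])
                cohort.append(gen)
                nxt.append(row)
                child += 1
        current = nxt

    return PedigreeTable(ids=ids, sire=np.asarray(sire), dam=np.asarray(dam),
                         sex=np.asarray(sex, dtype=object),
                         cohort=np.asarray(cohort))


def draw_founder_frequencies(spec: SimulationSpec) -> np.ndarray:
    rng = _split(spec.seed, 1)
    lo, hi = spec.maf_range
    return rng.uniform(lo, hi, spec.n_snps)


def gene_drop(
    pedigree: PedigreeTable,
    theta: np.ndarray,
    seed: int | np.random.Generator,
) -> GenotypeMatrix:
    """Drop alleles down the pedigree, one SNP at a time, independently.

    Founders receive two alleles i.i.d. Bernoulli(theta_j) per SNP; every
    non-founder inherits one uniformly chosen allele from each parent's two.
    The realized allele sharing therefore scatters around its pedigree
    expectation purely through Mendelian sampling.  Output dosages are the
    complete 0/1/2 counts of the coded allele.
    """
    theta = np.asarray(theta, dtype=float)
    if np.any((theta < 0) | (theta > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    if not pedigree.is_topologically_sorted:
        bad = pedigree.first_unordered_record()
        raise ValueError(
            f"pedigree records are not in topological order: individual "
            f"{bad!r} appears before one of its parents"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, p = pedigree.n, theta.size
    hap = np.empty((n, 2, p), dtype=np.int8)
    for k in range(n):
        s, d = pedigree.sire[k], pedigree.dam[k]
        if s < 0 and d < 0:
            hap[k] = rng.random((2, p)) < theta
        else:
            # one allele from each parent; an unknown parent (should not
            # occur in simulated pedigrees) contributes a population draw
            for slot, parent in enumerate((s, d)):
                if parent >= 0:
                    pick = rng.integers(0, 2, p)
                    hap[k, slot] = hap[parent, pick, np.arange(p)]
                else:
                    hap[k, slot] = rng.random(p) < theta
    counts = hap.sum(axis=1).astype(float)
    return GenotypeMatrix(
        ids=list(pedigree.ids),
        snp_ids=[f"snp{j + 1}" for j in range(p)],
        counts=counts,
        theta_true=theta,
    )


def simulate_covariates(pedigree: PedigreeTable, spec: SimulationSpec) -> pd.DataFrame:
    """Covariate table: sex from the pedigree (female = 1), age uniform on
    the study's adult range 19-92 years, two standard-normal ancestry-proxy
    principal components, and cohort = generation index."""
    rng = _split(spec.seed, 2)
    n = pedigree.n
    return pd.DataFrame({
        "id": pedigree.ids,
        "sex": (np.asarray(pedigree.sex) == "F").astype(int),
        "age": rng.uniform(19.0, 92.0, n),
        "pc1": rng.standard_normal(n),
        "pc2": rng.standard_normal(n),
        "cohort": pedigree.cohort,
    })


def simulate_phenotype(
    pedigree: PedigreeTable,
    spec: SimulationSpec,
    genotypes: GenotypeMatrix | None = None,
    A: RelationshipMatrix | None = None,
    covariates: pd.DataFrame | None = None,
    trait: str = "pheno",
) -> tuple[pd.DataFrame, TruthRecord]:
    """Additive phenotype with known variance components.

    Exactly one of ``genotypes`` (marker_effects mode) or ``A``
    (infinitesimal mode) must be supplied, matching ``spec.genetic_model``.

    marker_effects: ``u_i = sum_j (x_ij - 2*theta_j) * a_j`` with causal
    effects ``a_j ~ N(0, sigma2_u / sum_j 2*theta_j*(1-theta_j))``, so that
    the variance of ``u`` in an equilibrium population targets ``sigma2_u``
    and the scaling agrees with the GRM standardization.

    infinitesimal: ``u ~ MVN(0, A * sigma2_u)`` via a Cholesky factor.
    """
    has_g = genotypes is not None
    has_a = A is not None
    if has_g == has_a:
        raise ValueError("supply exactly one of genotypes / A")
    if spec.genetic_model == "marker_effects" and not has_g:
        raise ValueError("marker_effects mode needs genotypes")
    if spec.genetic_model == "infinitesimal" and not has_a:
        raise ValueError("infinitesimal mode needs the A matrix")

    rng = _split(spec.seed, 3)
    n = pedigree.n
    s2u, s2e = spec.sigma2_u, spec.sigma2_e
    if s2e == 0.0 and spec.total_variance > 0:
        log.warning("true_h2 = 1: residual variance is exactly zero (degenerate)")

    causal: np.ndarray | None = None
    if s2u == 0.0:
        u = np.zeros(n)
    elif spec.genetic_model == "marker_effects":
        if genotypes.ids != list(pedigree.ids):
            raise ValueError("genotype ids do not match the pedigree")
        theta = genotypes.theta_true if genotypes.theta_true is not None else genotypes.theta
        denom = float(np.sum(2.0 * theta * (1.0 - theta)))
        causal = rng.normal(0.0, np.sqrt(s2u / denom), genotypes.p)
        x = np.nan_to_num(genotypes.counts, nan=0.0) if np.isnan(genotypes.counts).any() else genotypes.counts
        u = (x - 2.0 * theta) @ causal
    else:
        K = A.reorder(list(pedigree.ids)) if A.ids != list(pedigree.ids) else A
        try:
            L = np.linalg.cholesky(K.values)
        except np.linalg.LinAlgError:
            w, V = np.linalg.eigh(K.values)
            L = V * np.sqrt(np.clip(w, 0.0, None))
        u = np.sqrt(s2u) * (L @ rng.standard_normal(n))

    eps = rng.normal(0.0, np.sqrt(s2e), n)
    cov = covariates if covariates is not None else simulate_covariates(pedigree, spec)
    eff = spec.covariate_effects
    fixed = (
        eff.get("sex", 0.0) * cov["sex"].to_numpy(float)
        + eff.get("age", 0.0) * cov["age"].to_numpy(float)
        + eff.get("pc1", 0.0) * cov["pc1"].to_numpy(float)
        + eff.get("pc2", 0.0) * cov["pc2"].to_numpy(float)
    )
    for level in np.unique(cov["cohort"]):
        if level > 1:
            fixed = fixed + eff.get(f"cohort{level}", 0.0) * (
                cov["cohort"].to_numpy(int) == level
            )

    pheno = cov.copy()
    pheno[trait] = fixed + u + eps
    truth = TruthRecord(
        ids=list(pedigree.ids),
        true_breeding_values=u,
        true_sigma2_u=s2u,
        true_sigma2_e=s2e,
        causal_effects=causal,
    )
    return pheno, truth


def inject_missingness(
    genotypes: GenotypeMatrix, rate: float, seed: int | np.random.Generator
) -> GenotypeMatrix:
    """Mask each genotype entry independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    if rate == 0.0:
        return genotypes
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = genotypes.counts.copy()
    counts[rng.random(counts.shape) < rate] = np.nan
    return GenotypeMatrix(ids=list(genotypes.ids), snp_ids=list(genotypes.snp_ids),
                          counts=counts, theta_true=genotypes.theta_true)


# ----------------------------------------------------------------------
def simulate_spirometry(n: int, seed: int = 0) -> pd.DataFrame:
    """Toy spirometry triple (FEV1, FVC, FEV1/FVC) with a shared lung-size
    factor.

    FVC is driven by overall lung size; FEV1 is a fraction of FVC perturbed
    by an independent airway factor.  This reproduces the qualitative
    pattern of real spirometry — FEV1 and FVC highly correlated, the ratio
    nearly uncorrelated with FVC — and is used only for correlation-shape
    checks, not for heritability analysis.
    """
    rng = np.random.default_rng(seed)
    size = rng.standard_normal(n)
    fvc = 4.0 + 0.9 * size + 0.18 * rng.standard_normal(n)
    airway = 0.8 + 0.06 * rng.standard_normal(n)
    fev1 = airway * fvc
    return pd.DataFrame({"fev1": fev1, "fvc": fvc, "ratio": fev1 / fvc})
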