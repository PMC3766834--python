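# Methods

## The model

`herit` estimates the narrow-sense heritability of a quantitative trait
measured on a multi-generation family sample, twice: once from the pedigree
and once from genome-wide SNP genotypes, holding everything else fixed so
the two estimates are directly comparable.

The analysis outcome `y` is the residual of an ordinary least-squares
regression of the raw trait on sex, age, the first two ancestry principal
components, and cohort (dummy-coded against the earliest cohort).  The
residuals then enter the additive model

    y = 1·β₀ + u + ε,    u ~ N(0, K·σ²_u),    ε ~ N(0, I·σ²_ε),

with the kernel K either

* **A**, the pedigree additive relationship matrix (twice the kinship
  coefficients) — the *expected* genome sharing under the pedigree — or
* **G**, the genomic relationship matrix with entries
  `G_ik = (1/p) Σ_j (x_ij − 2θ_j)(x_kj − 2θ_j) / (2θ_j(1−θ_j))` —
  the *realized* sharing at p genotyped SNPs, with `x_ij` the count of the
  allele coded 1 and `θ_j` its empirical frequency.  The diagonal uses the
  same formula; G is invariant to which allele is coded.

Heritability is `h² = σ²_u / (σ²_u + σ²_ε)`.  Because realized sharing
scatters around its expectation through Mendelian sampling
(`G_ij = A_ij + d_ij`, `E[d_ij] = 0`), the two kernels measure the same
quantity through different windows; on family data the estimates should
nearly coincide, which is the package's central reproducible claim.

## Genotype QC and imputation

Fixed order, each step logged with counts: (1) drop individuals with call
rate < 90%; (2) recompute per-SNP call rate and allele frequency on the
survivors, drop SNPs with call rate < 90% or MAF < 0.5%; (3) freeze θ;
(4) impute remaining missing genotypes as Binomial(2, θ_j) draws
(Hardy–Weinberg at the frozen frequency).  θ is *not* re-estimated after
imputation; at ~1% missingness the alternative changes G only in the third
decimal.  Monomorphic SNPs must be (and are) removed before G, since the
standardization divides by 2θ(1−θ).

## Bayesian fit

Both variances carry scaled-inverse-χ² priors with density
`(σ²)^−(ν/2+1)·exp(−S/2σ²)`, S = 2, ν = 5 (prior mean S/(ν−2) = 2/3) — a
weakly informative conjugate choice; the intercept has an improper flat
prior.  The sampler eigendecomposes K = U·D·Uᵀ once and works in the
rotated basis, where the genetic effects have independent Gaussian full
conditionals and each Gibbs sweep is O(n): effects, intercept, σ²_u from
scaled-inv-χ²(ν + rank K, S + Σ u*²_m/D_m), σ²_ε from
scaled-inv-χ²(ν + n, S + RSS).  Eigenvalues below 1e−10 of the largest
carry no genetic signal and their modes are pinned at zero.  Defaults:
30 000 sweeps, 5 000 burn-in, thinning 5 — sized so that ESS(h²) exceeds
several hundred at n ≈ 1000; a warning is attached when ESS(h²) < 100.
h² is computed per stored draw and summarized by posterior mean and SD
(reported as "h²% ± SD").

The reported "log-likelihood" is the Gaussian marginal
log N(y; 1β₀, K·σ²_u + I·σ²_ε) evaluated at the posterior means, and is
labeled as such — a Bayesian fit has no unique likelihood value, so the
definition is stated rather than implied.

Predicted genetic values û are posterior means of u; individual-level
predictions combine the stage-1 fixed-effect fitted value with û.  The
A-vs-G prediction report also gives the correlation of the genetic parts
alone, since the shared fixed part inflates the total correlation.

### Independent cross-checks

Two oracles are kept deliberately separate from the sampler: a profile
maximum-likelihood scan over h² (intercept and total variance profiled in
closed form on the same eigenbasis), and the exact marginal posterior
surface of (σ²_u, σ²_ε) with the intercept and genetic effects integrated
analytically.  Tests require the sampler's high-density region to coincide
with the brute-force surface's maximum, and the variance full conditional
with no data to reproduce the prior mean 2/3.  With K = I the two variance
components are non-identifiable and the h² profile is exactly flat — a
documented degenerate case, not an error.

## Synthetic family studies

The generator emulates a three-generation human family design.  Pedigree:
founders split half male / half female, random monogamous non-overlapping
couples within each generation (`min(males, females)` pairs, no selfing,
no assortative mating), a fixed number of children per couple with
balanced random sexes — the simplest scheme matching a family study, with
deterministic generation sizes.  Genotypes descend by gene dropping:
founder alleles i.i.d. Bernoulli(θ_j) with θ_j ~ Uniform(0.05, 0.5)
(keeps every SNP polymorphic and QC-survivable), each child inheriting one
uniformly chosen allele per parent, independently per SNP.  Covariates:
sex from the pedigree (female = 1), age ~ Uniform(19, 92) years matching
an adult study range, cohort = generation, PC1/PC2 ~ N(0,1) ancestry
proxies.  Default covariate effects (sex −0.96, age −0.032 per year,
cohort2 +0.28, cohort3 +0.44) are realistic lung-volume-scale values for a
spirometry-like trait.

Genetic values: in `marker_effects` mode
`u_i = Σ_j (x_ij − 2θ_j)·a_j` with `a_j ~ N(0, σ²_u / Σ_j 2θ_j(1−θ_j))`,
so Var(u) targets σ²_u and the scaling agrees with the G standardization;
in `infinitesimal` mode `u ~ MVN(0, A·σ²_u)` via a Cholesky factor.
Residual variance is set by `σ²_u = h²·V`, `σ²_ε = (1−h²)·V` with default
total V = 2.  All randomness flows from one root seed through a splittable
generator; reruns are byte-identical.

**What the generator does not emulate.**  SNPs segregate independently:
there is no linkage map.  Independent dropping preserves E[G_ij] = A_ij
exactly but understates Var(G_ij | A_ij), so the empirical fact that the
scatter of G around A widens at higher relationship levels is reproduced
only qualitatively; per-level variances are reported descriptively, and no
test asserts the variance ordering.  There are also no genotyping errors,
no X chromosome, and no dominance/epistatic variance.  Passing tests
therefore demonstrate correctness of the estimators under an additive,
unlinked, error-free world — not robustness to the full messiness of real
genotype data.

**A note on centering.**  The identity E[G_ij] = A_ij holds when G is
standardized by the founder allele frequencies.  With frequencies
estimated in-sample (as in the real pipeline), G is effectively
sample-centered and all entries shift down by roughly the average sample
relatedness; tests of the Mendelian-sampling identity therefore
standardize by the known founder θ, while the analysis pipeline uses the
empirical θ as any real study must.

## Numerical choices

* Pedigree A is built by the tabular method in topological order; founders
  are assumed non-inbred, and an unknown parent contributes nothing to the
  recursion (equivalent to an unrelated non-inbred founder).  A is dense —
  at the study scale (≤ ~10⁴ individuals) this fits memory comfortably and
  the sampler consumes the kernel itself, never A⁻¹.
* G gets a PSD repair of +1e−8·I (logged) when its smallest eigenvalue
  falls below 1e−10; A is PSD by construction.
* OLS uses a QR-based solve; rank deficiency is an error naming the
  collinear columns.  Residuals are exactly orthogonal to the design, so
  mean(y) = 0 and the two-stage analysis is well-posed.
* The two-stage analysis (pre-adjust, then fit the genetic model on
  residuals) is intentional, matching standard practice for this design
  even though a joint fit is statistically preferable; the stage-1
  coefficient table is reported alongside so the choice is visible.
* Sex is coded female = 1; the choice is logged and configurable, and only
  flips coefficient signs.
* Ties/degenerate inputs: h² = 1 (σ²_ε = 0) is permitted in the generator
  but logged as degenerate; zero-variance traits make correlations NaN
  with a warning rather than an error.

## Problem sizes used in the checks

The bundled verification runs use a 1008-member three-generation study
with 5000 SNPs for the pedigree-vs-marker comparison (estimates at this
scale carry replicate-to-replicate spread of a few percentage points in
h²), 200 gene-drop replicates of a small fixed pedigree for the
E[G] = A identity, and a 200×200 posterior-surface grid at n ≈ 200 for
sampler validation.  These sizes give Monte-Carlo error comfortably inside
each assertion's tolerance while keeping the whole suite fast.

## Known limitations

* No REML path: the grid profile likelihood exists only as a test oracle.
* One kernel at a time: no joint A + G model, no multi-trait model.
* No LD pruning or alternative GRM estimators (e.g. observed-allele-count
  weighting variants); the single stated G formula is the point.
* The pipeline's resumable state marker trusts file contents; it
  invalidates on configuration change but not on manual artifact edits.
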