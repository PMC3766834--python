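"""Bayesian variance-component model for heritability estimation.

Fits the additive model

    y = 1*beta0 + u + eps,   u ~ N(0, K * sigma2_u),   eps ~ N(0, I * sigma2_e)

for a relationship kernel K (pedigree A or genomic G) by Gibbs sampling.
Both variances carry scaled-inverse-chi-square priors with density
p(s2) ∝ (s2)^-(nu/2 + 1) * exp(-S / (2 s2)) — i.e. Inv-Gamma(nu/2, S/2),
prior mean S / (nu - 2) — with the conventional weakly informative setting
S = 2, nu = 5; the intercept gets an improper flat prior.

Narrow-sense heritability is computed per posterior draw as
h2 = sigma2_u / (sigma2_u + sigma2_e) and summarized by its posterior mean
and SD.  Predicted genetic values are the posterior means of u.

The sampler works in the eigenbasis of K (decomposed once): with
K = U D U', rotating y makes the genetic effects conditionally independent,
so every Gibbs sweep is O(n).  A frequentist grid profile of the Gaussian
marginal likelihood over h2 is provided as an independent cross-check
(:func:`grid_ml_oracle`); it is never used for fitting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adjust import AdjustedPhenotype
from .relmat import RelationshipMatrix

log = logging.getLogger("herit")

__all__ = [
    "PriorSpec",
    "GibbsConfig",
    "PosteriorSummary",
    "HeritabilityEstimate",
    "sample_scaled_inv_chi2",
    "fit_model",
    "grid_ml_oracle",
    "log_likelihood",
    "log_marginal_posterior",
    "compare_predicted_values",
    "effective_sample_size",
]

#: eigenvalues below this fraction of the largest carry no genetic signal
#: and their rotated effects are pinned at zero
EIG_REL_FLOOR = 1e-10


@dataclass
class PriorSpec:
    """Scaled-inverse-chi-square prior for both variance components.

    ``scale`` (S) and ``df`` (nu) parameterize the density
    (s2)^-(nu/2+1) exp(-S/(2 s2)); the prior mean is S/(nu-2) for nu > 2.
    The default S = 2, nu = 5 (prior mean 2/3) is a relatively
    un-informative choice.
    """

    scale: float = 2.0
    df: float = 5.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.df <= 0:
            raise ValueError("prior scale and df must be positive")

    @property
    def mean(self) -> float:
        if self.df <= 2:
            raise ValueError("prior mean undefined for df <= 2")
        return self.scale / (self.df - 2.0)

    def log_density(self, s2: np.ndarray | float) -> np.ndarray | float:
        s2 = np.asarray(s2, dtype=float)
        return -(self.df / 2.0 + 1.0) * np.log(s2) - self.scale / (2.0 * s2)


@dataclass
class GibbsConfig:
    """MCMC settings: total sweeps, burn-in, thinning, seed, start value."""

    n_iter: int = 30000
    burn_in: int = 5000
    thin: int = 5
    seed: int = 0
    init_h2: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if not 0.0 < self.init_h2 < 1.0:
            raise ValueError("init_h2 must lie in (0, 1)")


@dataclass
class HeritabilityEstimate:
    """One study-table row: trait, kernel, h2 posterior mean/SD, log-likelihood."""

    trait: str
    kernel: str
    h2_mean: float
    h2_sd: float
    log_likelihood: float

    def formatted(self) -> str:
        return f"{100 * self.h2_mean:.2f}% ± {self.h2_sd:.2f}"


@dataclass
class PosteriorSummary:
    """Thinned post-burn-in samples and their summaries."""

    ids: list[str]
    samples: pd.DataFrame  # iteration, beta0, sigma2_u, sigma2_e, h2
    means: dict[str, float]
    sds: dict[str, float]
    ess: dict[str, float]
    u_hat: np.ndarray  # posterior-mean genetic values, order = ids
    log_likelihood: float
    kernel_kind: str
    warnings: list[str] = field(default_factory=list)

    def estimate(self, trait: str = "pheno") -> HeritabilityEstimate:
        return HeritabilityEstimate(
            trait=trait,
            kernel=self.kernel_kind,
            h2_mean=self.means["h2"],
            h2_sd=self.sds["h2"],
            log_likelihood=self.log_likelihood,
        )

    def predicted_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "u_hat": self.u_hat})


# ----------------------------------------------------------------------
def sample_scaled_inv_chi2(
    rng: np.random.Generator, df: float, scale: float, size: int | None = None
) -> np.ndarray | float:
    """Draw from the scaled-inverse-chi-square distribution.

    Parameterized so the density is (s2)^-(df/2+1) exp(-scale/(2 s2));
    a draw is ``scale / chi2(df)`` and the mean is ``scale / (df - 2)``.
    With no data contribution this reproduces the prior itself — a
    conjugacy identity the tests exploit.
    """
    return scale / rng.chisquare(df, size=size)


def _coerce_y(y, K: RelationshipMatrix) -> tuple[np.ndarray, list[str], RelationshipMatrix]:
    """Align a phenotype (AdjustedPhenotype, Series or array) with K."""
    if isinstance(y, AdjustedPhenotype):
        ids, vals = y.ids, np.asarray(y.y, float)
    elif isinstance(y, pd.Series):
        ids, vals = [str(t) for t in y.index], y.to_numpy(float)
    else:
        vals = np.asarray(y, float)
        if vals.shape[0] != K.n:
            raise ValueError("bare phenotype vector length must match the kernel")
        ids = list(K.ids)
    if np.isnan(vals).any():
        raise ValueError("phenotype contains NaN")
    if set(ids) - set(K.ids):
        raise KeyError(f"phenotyped ids missing from kernel: {sorted(set(ids) - set(K.ids))[:10]}")
    K = K.reorder(ids) if list(K.ids) != list(ids) else K
    return vals, list(ids), K


def _eigen(K: RelationshipMatrix) -> tuple[np.ndarray, np.ndarray]:
    D, U = np.linalg.eigh(K.values)
    if D[0] < -1e-8 * max(D[-1], 1.0):
        raise ValueError(
            f"kernel is not PSD beyond jitter tolerance (min eigenvalue {D[0]:.3g}); "
            "repair it with RelationshipMatrix.with_jitter"
        )
    return np.clip(D, 0.0, None), U


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by Geyer's initial positive sequence on the autocorrelation."""
    x = np.asarray(x, float)
    n = x.size
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    m = 1 << (2 * n - 1).bit_length()
    ac = np.fft.irfft(np.abs(np.fft.rfft(xc, m)) ** 2)[:n]
    rho = ac / ac[0]
    tau = 1.0
    for k in range(1, n // 2):
        gamma = rho[2 * k - 1] + rho[2 * k]
        if gamma <= 0:
            break
        tau += 2.0 * gamma
    return float(n / tau)


# ----------------------------------------------------------------------
def fit_model(
    y,
    K: RelationshipMatrix,
    prior: PriorSpec | None = None,
    config: GibbsConfig | None = None,
) -> PosteriorSummary:
    """Gibbs sampler for the additive model on kernel K.

    The kernel is eigendecomposed once, K = U D U'; in the rotated basis
    z = U'y the model is z = w*beta0 + u* + e with independent
    u*_m ~ N(0, D_m * sigma2_u).  Each sweep draws, in turn,

    1. the rotated genetic effects u*_m from their independent Gaussian
       full conditionals (variance (1/(D_m s2u) + 1/s2e)^-1; modes with
       near-zero eigenvalue are pinned at zero),
    2. the intercept beta0 from its Gaussian full conditional (flat prior),
    3. sigma2_u from scaled-inv-chi2(nu + rank K, S + sum u*_m^2 / D_m),
    4. sigma2_e from scaled-inv-chi2(nu + n, S + residual sum of squares).

    Heritability is computed per stored draw.  The reported log-likelihood
    is the Gaussian marginal log N(y; 1*beta0, K*s2u + I*s2e) evaluated at
    the posterior means — labeled as such because a Bayesian fit has no
    unique "the" likelihood value.
    """
    prior = prior or PriorSpec()
    config = config or GibbsConfig()
    yv, ids, K = _coerce_y(y, K)
    n = yv.size
    warnings: list[str] = []
    if n < 30:
        warnings.append(f"n = {n} < 30: posterior will be prior-dominated")
        log.warning("fit_model: %s", warnings[-1])

    D, U = _eigen(K)
    active = D > EIG_REL_FLOOR * max(D[-1], 1.0)
    rank = int(active.sum())
    Da = D[active]
    z = U.T @ yv
    w = U.T @ np.ones(n)
    rng = np.random.default_rng(config.seed)

    vary = float(np.var(yv)) or 1.0
    s2u = config.init_h2 * vary
    s2e = (1.0 - config.init_h2) * vary
    beta0 = float(yv.mean())
    ustar = np.zeros(n)
    nu, S = prior.df, prior.scale

    kept = (config.n_iter - config.burn_in) // config.thin
    out = np.empty((kept, 4))
    u_acc = np.zeros(n)
    stored = 0
    za, wa = z[active], w[active]

    for it in range(config.n_iter):
        # (1) rotated genetic effects
        r = za - wa * beta0
        prec = 1.0 / (Da * s2u) + 1.0 / s2e
        mean = (r / s2e) / prec
        ustar[active] = mean + rng.standard_normal(rank) / np.sqrt(prec)
        # (2) intercept (flat prior)
        beta0 = rng.normal(float(w @ (z - ustar)) / n, np.sqrt(s2e / n))
        # (3) genetic variance
        ss_u = float(np.sum(ustar[active] ** 2 / Da))
        s2u = sample_scaled_inv_chi2(rng, nu + rank, S + ss_u)
        # (4) residual variance
        rss = float(np.sum((z - w * beta0 - ustar) ** 2))
        s2e = sample_scaled_inv_chi2(rng, nu + n, S + rss)

        if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
            out[stored] = (beta0, s2u, s2e, s2u / (s2u + s2e))
            u_acc += ustar
            stored += 1

    samples = pd.DataFrame(out[:stored], columns=["beta0", "sigma2_u", "sigma2_e", "h2"])
    samples.insert(0, "iteration",
                   config.burn_in + config.thin * np.arange(stored))
    means = {c: float(samples[c].mean()) for c in ("beta0", "sigma2_u", "sigma2_e", "h2")}
    sds = {c: float(samples[c].std(ddof=1)) for c in ("beta0", "sigma2_u", "sigma2_e", "h2")}
    ess = {c: effective_sample_size(samples[c].to_numpy())
           for c in ("beta0", "sigma2_u", "sigma2_e", "h2")}
    if ess["h2"] < 100:
        warnings.append(f"ESS(h2) = {ess['h2']:.0f} < 100: chain may not have converged")
        log.warning("fit_model: %s", warnings[-1])

    u_hat = U @ (u_acc / max(stored, 1))
    if abs(u_hat.mean()) > 0.1 * np.std(yv):
        warnings.append("posterior-mean genetic values are far from centered")

    ll = _log_likelihood_eig(z, w, D, means["beta0"], means["sigma2_u"], means["sigma2_e"])
    return PosteriorSummary(
        ids=ids, samples=samples, means=means, sds=sds, ess=ess,
        u_hat=u_hat, log_likelihood=ll, kernel_kind=K.kind, warnings=warnings,
    )


# ----------------------------------------------------------------------
def _log_likelihood_eig(z, w, D, beta0, s2u, s2e) -> float:
    v = s2u * D + s2e
    if np.any(v <= 0):
        raise ValueError("singular covariance: sigma2_u * D + sigma2_e has a zero mode")
    r = z - w * beta0
    return float(-0.5 * (np.sum(np.log(2.0 * np.pi * v)) + np.sum(r * r / v)))


def log_likelihood(
    y, K: RelationshipMatrix, beta0: float, s2u: float, s2e: float
) -> float:
    """Gaussian marginal log-density of y ~ N(1*beta0, K*s2u + I*s2e)."""
    if s2u < 0 or s2e <= 0:
        raise ValueError("need sigma2_u >= 0 and sigma2_e > 0")
    yv, _, K = _coerce_y(y, K)
    D, U = _eigen(K)
    return _log_likelihood_eig(U.T @ yv, U.T @ np.ones(yv.size), D, beta0, s2u, s2e)


@dataclass
class GridMLResult:
    sigma2_u: float
    sigma2_e: float
    log_likelihood: float
    profile: pd.DataFrame  # h2, sigma2_u, sigma2_e, beta0, log_likelihood


def grid_ml_oracle(
    y, K: RelationshipMatrix, grid: np.ndarray | int = 201
) -> GridMLResult:
    """Profile maximum likelihood over a heritability grid.

    At each h2 on the grid the covariance is sigma2_t * (h2*K + (1-h2)*I);
    the intercept (GLS) and total variance have closed-form profiles, so
    the 2-parameter search reduces to a 1-D scan.  This is the independent
    frequentist oracle for the Gibbs sampler — deliberately a different
    computation path.  Note that when K = I the two components are not
    identifiable and the profile is exactly flat in h2.
    """
    if isinstance(grid, (int, np.integer)):
        grid = np.linspace(0.0, 0.99, int(grid))
    grid = np.asarray(grid, float)
    if grid.size == 0:
        raise ValueError("empty h2 grid")
    yv, _, K = _coerce_y(y, K)
    n = yv.size
    D, U = _eigen(K)
    z = U.T @ yv
    w = U.T @ np.ones(n)

    rows = []
    for h2 in grid:
        alpha = h2 * D + (1.0 - h2)
        if np.any(alpha <= 0):
            rows.append((h2, np.nan, np.nan, np.nan, -np.inf))
            continue
        beta0 = float(np.sum(w * z / alpha) / np.sum(w * w / alpha))
        r = z - w * beta0
        s2t = float(np.sum(r * r / alpha) / n)
        ll = -0.5 * (n * np.log(2.0 * np.pi * s2t) + float(np.sum(np.log(alpha))) + n)
        rows.append((h2, h2 * s2t, (1.0 - h2) * s2t, beta0, ll))
    profile = pd.DataFrame(rows, columns=["h2", "sigma2_u", "sigma2_e", "beta0",
                                          "log_likelihood"])
    best = profile["log_likelihood"].idxmax()
    return GridMLResult(
        sigma2_u=float(profile.loc[best, "sigma2_u"]),
        sigma2_e=float(profile.loc[best, "sigma2_e"]),
        log_likelihood=float(profile.loc[best, "log_likelihood"]),
        profile=profile,
    )


def log_marginal_posterior(
    y,
    K: RelationshipMatrix,
    prior: PriorSpec,
    s2u: np.ndarray,
    s2e: np.ndarray,
) -> np.ndarray:
    """Log posterior density surface of (sigma2_u, sigma2_e), up to a constant.

    The intercept is integrated out analytically under its flat prior and
    the genetic effects under their Gaussian law, leaving the exact marginal
    the Gibbs sampler targets:

        log p(s2u, s2e | y) = log N(y; 1*b_gls, V) + 0.5*log(2*pi)
                              - 0.5*log(1' V^-1 1) + log prior(s2u)
                              + log prior(s2e) + const,  V = K*s2u + I*s2e.

    ``s2u`` and ``s2e`` broadcast (pass a meshgrid for a full surface).
    """
    yv, _, K = _coerce_y(y, K)
    n = yv.size
    D, U = _eigen(K)
    z = U.T @ yv
    w = U.T @ np.ones(n)

    s2u = np.asarray(s2u, float)
    s2e = np.asarray(s2e, float)
    shape = np.broadcast_shapes(s2u.shape, s2e.shape)
    v = (np.expand_dims(s2u, -1) * D + np.expand_dims(s2e, -1) * np.ones_like(D))
    winv = (w * w) / v
    sw = winv.sum(axis=-1)
    beta0 = (w * z / v).sum(axis=-1) / sw
    quad = (z * z / v).sum(axis=-1) - beta0**2 * sw  # ||z - w b||^2_Vinv at GLS b
    ll = -0.5 * (np.log(v).sum(axis=-1) + quad) + 0.5 * (np.log(2.0 * np.pi) - np.log(sw))
    return (ll + prior.log_density(s2u) + prior.log_density(s2e)).reshape(shape)


# ----------------------------------------------------------------------
@dataclass
class PredictionComparison:
    """Individual-level agreement between pedigree- and marker-based
    predicted values (fixed-effect part + posterior-mean genetic value)."""

    table: pd.DataFrame  # id, fixed, u_A, u_G, pred_A, pred_G
    correlation: float  # between total predictions
    correlation_random: float  # between genetic parts alone
    correlation_fixed: float  # trivially 1: the fixed part is shared

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.table["pred_A"], self.table["pred_G"], ".", ms=3, alpha=0.5)
        lims = [self.table[["pred_A", "pred_G"]].min().min(),
                self.table[["pred_A", "pred_G"]].max().max()]
        ax.plot(lims, lims, "--", lw=0.8, color="grey")
        ax.set_xlabel("pedigree-based predicted value")
        ax.set_ylabel("SNP-based predicted value")
        ax.set_title(f"r = {self.correlation:.3f}")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def compare_predicted_values(
    fit_A: PosteriorSummary,
    fit_G: PosteriorSummary,
    covariate_fit: AdjustedPhenotype,
) -> PredictionComparison:
    """Correlate per-individual predictions under the two kernels.

    Each prediction is the stage-1 fixed-effect fitted value plus the
    kernel's posterior-mean genetic value.  The random-only correlation is
    reported too, making visible how much of the agreement rides on the
    shared fixed part.
    """
    if set(fit_A.ids) != set(fit_G.ids):
        raise ValueError(
            f"fits cover different individuals: {sorted(set(fit_A.ids) ^ set(fit_G.ids))[:10]}"
        )
    order = {t: k for k, t in enumerate(fit_G.ids)}
    gperm = np.array([order[t] for t in fit_A.ids])
    fixed_map = dict(zip(covariate_fit.ids, covariate_fit.fitted))
    missing = [t for t in fit_A.ids if t not in fixed_map]
    if missing:
        raise ValueError(f"no covariate fit for individuals: {missing[:10]}")
    fixed = np.array([fixed_map[t] for t in fit_A.ids])
    u_a = fit_A.u_hat
    u_g = fit_G.u_hat[gperm]
    pred_a, pred_g = fixed + u_a, fixed + u_g
    table = pd.DataFrame({
        "id": fit_A.ids, "fixed": fixed, "u_A": u_a, "u_G": u_g,
        "pred_A": pred_a, "pred_G": pred_g,
    })
    return PredictionComparison(
        table=table,
        correlation=float(np.corrcoef(pred_a, pred_g)[0, 1]),
        correlation_random=float(np.corrcoef(u_a, u_g)[0, 1]),
        correlation_fixed=1.0,
    )
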