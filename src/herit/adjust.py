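"""Fixed-effect pre-adjustment of phenotypes.

The genetic models downstream consume the residual of an ordinary
least-squares regression of each trait on sex, age, the first two ancestry
principal components, and cohort (dummy-coded against the first cohort).
This module produces those residuals together with a coefficient table
(estimate, standard error, p-value per covariate) in the usual
study-report shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

log = logging.getLogger("herit")

__all__ = [
    "AdjustedPhenotype",
    "fit_fixed_effects",
    "phenotype_correlations",
    "latest_exam",
]

DEFAULT_COVARIATES = ("sex", "age", "pc1", "pc2", "cohort")


@dataclass
class AdjustedPhenotype:
    """Residual phenotype after fixed-effect regression.

    ``y`` is the residual vector (mean zero, orthogonal to every design
    column), ``fitted`` the fixed-effect predictions on the same rows,
    ``coefficients`` the per-term estimate / SE / p-value table, and
    ``dropped_ids`` the individuals excluded for a missing phenotype or
    covariate.
    """

    ids: list[str]
    y: np.ndarray
    fitted: np.ndarray
    coefficients: pd.DataFrame
    n_used: int
    trait: str = "pheno"
    dropped_ids: list[str] | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "y": self.y})


def _design_matrix(
    df: pd.DataFrame, covariates: tuple[str, ...] | list[str]
) -> pd.DataFrame:
    """Intercept + covariates, with cohort dummy-coded against its first
    (smallest) level."""
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df))}
    for cov in covariates:
        if cov == "cohort":
            levels = np.sort(df["cohort"].unique())
            for lv in levels[1:]:
                cols[f"cohort{lv}"] = (df["cohort"] == lv).to_numpy(float)
        else:
            cols[cov] = df[cov].to_numpy(float)
    return pd.DataFrame(cols, index=df.index)


def fit_fixed_effects(
    pheno: pd.DataFrame,
    trait: str = "pheno",
    covariates: tuple[str, ...] | list[str] = DEFAULT_COVARIATES,
) -> AdjustedPhenotype:
    """OLS of ``trait`` on the covariates; returns residuals + coefficients.

    Rows with a missing phenotype or covariate are dropped (and logged).
    The fit uses a QR-based least-squares solve (statsmodels OLS), so the
    residuals are orthogonal to the design to numerical precision.  A
    rank-deficient design is an error naming the collinear columns.
    """
    covariates = [c for c in covariates if c in pheno.columns]
    needed = [trait] + covariates
    complete = pheno[needed].notna().all(axis=1)
    dropped = [str(t) for t in pheno.loc[~complete, "id"]] if "id" in pheno else []
    if dropped:
        log.info("fit_fixed_effects(%s): dropped %d rows with missing data", trait, len(dropped))
    df = pheno.loc[complete].reset_index(drop=True)

    X = _design_matrix(df, covariates)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n = {n} rows is not more than {k} parameters")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        # name columns whose QR diagonal collapses
        _, R = np.linalg.qr(X.to_numpy())
        bad = [X.columns[j] for j in range(k) if abs(R[j, j]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")

    res = sm.OLS(df[trait].to_numpy(float), X).fit()
    coef = pd.DataFrame({
        "term": X.columns,
        "estimate": res.params.to_numpy(),
        "se": res.bse.to_numpy(),
        "p_value": res.pvalues.to_numpy(),
    })
    ids = [str(t) for t in df["id"]] if "id" in df else [str(i) for i in range(n)]
    return AdjustedPhenotype(
        ids=ids,
        y=np.asarray(res.resid, float),
        fitted=np.asarray(res.fittedvalues, float),
        coefficients=coef,
        n_used=n,
        trait=trait,
        dropped_ids=dropped,
    )


def phenotype_correlations(
    pheno: pd.DataFrame, traits: list[str] = ("fev1", "fvc", "ratio")
) -> pd.DataFrame:
    """Pairwise Pearson correlations among traits, with the n behind each.

    Zero-variance columns yield an undefined (NaN) correlation and a
    warning rather than an error.
    """
    traits = [t for t in traits if t in pheno.columns]
    rows = []
    for a_i, a in enumerate(traits):
        for b in traits[a_i + 1:]:
            sub = pheno[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 complete rows for ({a}, {b})")
            sa, sb = sub[a].std(ddof=1), sub[b].std(ddof=1)
            if sa == 0 or sb == 0:
                log.warning("zero-variance column in (%s, %s); correlation undefined", a, b)
                r = np.nan
            else:
                r = float(np.corrcoef(sub[a], sub[b])[0, 1])
            rows.append({"trait_a": a, "trait_b": b, "r": r, "n": len(sub)})
    return pd.DataFrame(rows)


def latest_exam(pheno: pd.DataFrame, id_col: str = "id", exam_col: str = "exam") -> pd.DataFrame:
    """Keep, for each individual, the record from the highest exam index.

    Utility for repeated-measure study files where one phenotype per person
    (the most recent) enters the analysis.
    """
    idx = pheno.groupby(id_col)[exam_col].idxmax()
    return pheno.loc[idx].reset_index(drop=True)
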