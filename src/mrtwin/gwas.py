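"""Marginal association scans and instrument selection.

Produces the external "summary statistics" consumed by the MR estimators and
the family-based test: per-SNP simple linear regressions of each phenotype on
each SNP (with intercept, optionally with covariates projected out), followed
by the instrument filters used in practice — a Bonferroni threshold on the
exposure p-value and, optionally, the weak-instrument F >= 10 rule.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import NoInstrumentsError, SchemaError

__all__ = ["marginal_gwas", "summary_stats", "select_instruments", "f_statistics"]

SUMMARY_COLUMNS = [
    "snp_id",
    "beta_exposure",
    "se_exposure",
    "p_exposure",
    "beta_outcome",
    "se_outcome",
    "p_outcome",
    "n",
]


def _residualize(y: np.ndarray, covariates: np.ndarray) -> tuple[np.ndarray, int]:
    """Project out an intercept plus covariates; return residuals and the
    number of fitted columns (for degrees of freedom)."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), covariates])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef, design.shape[1]


def marginal_gwas(
    genotypes: np.ndarray,
    phenotype: np.ndarray,
    snp_ids: list[str] | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-SNP simple OLS of ``phenotype`` on each genotype column.

    Returns a frame with columns ``snp_id, beta, se, p, n``. Monomorphic
    SNPs (zero genotype variance) are excluded with a warning. The closed
    form is the textbook one: beta = S_xy / S_xx, se from the residual mean
    square, two-sided p from Student's t with n-2 (minus covariate count)
    degrees of freedom. Covariates, when given, are projected out of both
    the phenotype and the genotypes (Frisch-Waugh-Lovell).
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if g.ndim != 2 or g.shape[0] != y.shape[0]:
        raise SchemaError("genotypes must be (n x m) with one phenotype value per row")
    n, m = g.shape
    if n < 3:
        raise SchemaError("marginal GWAS requires n >= 3")
    if snp_ids is None:
        snp_ids = [f"snp{j}" for j in range(m)]

    df_extra = 0
    if covariates is not None:
        y, k = _residualize(y, covariates)
        for j in range(m):
            g[:, j], _ = _residualize(g[:, j], covariates)
        df_extra = k - 1  # intercept already counted below

    xc = g - g.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    poly = sxx <= 0
    if poly.any():
        warnings.warn(
            f"excluding {int(poly.sum())} monomorphic SNP(s): "
            + ", ".join(np.asarray(snp_ids)[poly][:5]),
            stacklevel=2,
        )
    keep = ~poly
    sxy = xc[:, keep].T @ yc
    sxx_k = sxx[keep]
    beta = sxy / sxx_k
    dof = n - 2 - df_extra
    syy = yc @ yc
    ssr = np.maximum(syy - beta * sxy, 0.0)
    se = np.sqrt(ssr / dof / sxx_k)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "snp_id": np.asarray(snp_ids)[keep],
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
        }
    )


def summary_stats(
    genotypes: np.ndarray,
    exposure: np.ndarray,
    outcome: np.ndarray,
    snp_ids: list[str] | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """External-cohort summary statistics for both traits, one row per SNP."""
    ge = marginal_gwas(genotypes, exposure, snp_ids=snp_ids, covariates=covariates)
    go = marginal_gwas(genotypes, outcome, snp_ids=snp_ids, covariates=covariates)
    merged = ge.merge(go, on=["snp_id", "n"], suffixes=("_exposure", "_outcome"))
    return merged[SUMMARY_COLUMNS]


def f_statistics(stats: pd.DataFrame) -> np.ndarray:
    """Per-SNP instrument-strength F statistic.

    For a single-regressor fit, F equals the squared t statistic
    (beta / se)^2 of the SNP-exposure association.
    """
    return (stats["beta_exposure"].to_numpy() / stats["se_exposure"].to_numpy()) ** 2


def select_instruments(
    stats: pd.DataFrame,
    m: int | None = None,
    bonferroni_alpha: float | None = 0.05,
    f_threshold: float | None = None,
) -> list[str]:
    """Select instrument SNPs from summary statistics.

    Retains SNPs whose exposure p-value is below ``bonferroni_alpha / m``
    (``m`` defaults to the number of SNPs tested) and, when ``f_threshold``
    is set, whose instrument-strength F statistic meets it. Passing
    ``bonferroni_alpha=None`` disables the p-value filter (the "unfiltered"
    mode). Raises :class:`NoInstrumentsError` when nothing survives.
    """
    missing = [c for c in ("snp_id", "beta_exposure", "se_exposure", "p_exposure") if c not in stats]
    if missing:
        raise SchemaError(f"summary statistics lack required column(s): {missing}")
    mask = np.ones(len(stats), dtype=bool)
    if bonferroni_alpha is not None:
        m_eff = len(stats) if m is None else m
        mask &= stats["p_exposure"].to_numpy() < bonferroni_alpha / m_eff
    if f_threshold is not None:
        mask &= f_statistics(stats) >= f_threshold
    selected = stats.loc[mask, "snp_id"].tolist()
    if not selected:
        raise NoInstrumentsError(
            "no SNPs pass the instrument filters; the downstream test refuses to run"
        )
    return selected
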