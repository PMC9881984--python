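"""Summary-statistic MR estimators of the exposure-outcome effect.

These serve two roles: as standalone baselines (the estimators whose false
positive rates inflate under population stratification) and as the source of
the fixed effect estimate plugged into the family-based test statistic.

All three take per-instrument GWAS estimates (beta_XE, se_XE, beta_XO,
se_XO) and return a point estimate of beta_EO:

* ratio  — single instrument, beta_XO / beta_XE, delta-method SE;
* IVW    — fixed-effect inverse-variance weighting of per-instrument ratios,
           equivalently weighted regression of beta_XO on beta_XE through
           the origin with weights 1/se_XO^2;
* Egger  — the same weighted regression with an intercept absorbing
           directional pleiotropy, after orienting instruments to
           beta_XE >= 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import SchemaError

__all__ = ["MrEstimate", "ratio_estimate", "ivw_estimate", "egger_estimate", "estimate"]


@dataclass(frozen=True)
class MrEstimate:
    """Scalar exposure-outcome effect estimate with uncertainty."""

    beta_EO: float
    se: float
    method: str
    p_value: float
    intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    n_instruments: int = 1


def _columns(stats: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for c in ("beta_exposure", "beta_outcome", "se_outcome"):
        if c not in stats:
            raise SchemaError(f"summary statistics lack required column {c!r}")
    return (
        stats["beta_exposure"].to_numpy(dtype=float),
        stats["beta_outcome"].to_numpy(dtype=float),
        stats["se_outcome"].to_numpy(dtype=float),
    )


def ratio_estimate(beta_xe: float, beta_xo: float, se_xo: float) -> MrEstimate:
    """Single-instrument (Wald) ratio: beta_XO / beta_XE.

    The standard error is first-order delta method, se_XO / |beta_XE|,
    which treats beta_XE as measured without error.
    """
    if beta_xe == 0:
        raise ZeroDivisionError("ratio estimate undefined for beta_XE = 0")
    beta = beta_xo / beta_xe
    se = se_xo / abs(beta_xe)
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    return MrEstimate(
        beta_EO=float(beta),
        se=float(se),
        method="ratio",
        p_value=float(2 * sps.norm.sf(abs(z))),
        n_instruments=1,
    )


def ivw_estimate(stats: pd.DataFrame) -> MrEstimate:
    """Fixed-effect inverse-variance weighted estimate over J instruments.

    With per-instrument ratios r_j = beta_XO,j / beta_XE,j and weights
    w_j = (beta_XE,j / se_XO,j)^2, the estimate is sum(w r) / sum(w) with
    standard error 1 / sqrt(sum w). J = 1 reduces exactly to the ratio
    estimator. Instruments with beta_XE = 0 are rejected with a warning.
    """
    bxe, bxo, se = _columns(stats)
    if np.any(se <= 0):
        raise SchemaError("all se_outcome values must be positive")
    bad = bxe == 0
    if bad.any():
        warnings.warn(f"rejecting {int(bad.sum())} instrument(s) with beta_XE = 0", stacklevel=2)
        bxe, bxo, se = bxe[~bad], bxo[~bad], se[~bad]
    if bxe.size == 0:
        raise SchemaError("no usable instruments for IVW")
    w = (bxe / se) ** 2
    beta = float(np.sum(w * (bxo / bxe)) / np.sum(w))
    se_beta = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se_beta
    return MrEstimate(
        beta_EO=beta,
        se=se_beta,
        method="ivw",
        p_value=float(2 * sps.norm.sf(abs(z))),
        n_instruments=int(bxe.size),
    )


def egger_estimate(stats: pd.DataFrame) -> MrEstimate:
    """MR-Egger: weighted regression of beta_XO on beta_XE with intercept.

    Instruments are oriented so every beta_XE is non-negative (flipping
    beta_XO along with it); weights are 1/se_XO^2. The slope estimates
    beta_EO and the intercept the average directional pleiotropy. The
    residual dispersion is estimated, so on noise-free collinear inputs the
    fit is exact with zero standard error; the slope p-value uses Student's
    t with J-2 degrees of freedom.
    """
    bxe, bxo, se = _columns(stats)
    j = bxe.size
    if j < 3:
        raise SchemaError("MR-Egger requires at least 3 instruments")
    if np.any(se <= 0):
        raise SchemaError("all se_outcome values must be positive")
    flip = np.sign(bxe)
    flip[flip == 0] = 1.0
    x = bxe * flip
    y = bxo * flip
    w = 1.0 / se**2

    design = np.column_stack([np.ones(j), x])
    xtwx = design.T @ (design * w[:, None])
    xtwy = design.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - design @ coef
    s2 = float(np.sum(w * resid**2) / (j - 2))
    cov = s2 * np.linalg.inv(xtwx)
    intercept, slope = coef
    se_slope = float(np.sqrt(max(cov[1, 1], 0.0)))
    se_int = float(np.sqrt(max(cov[0, 0], 0.0)))
    if se_slope > 0:
        p = float(2 * sps.t.sf(abs(slope / se_slope), j - 2))
    else:
        p = 0.0 if slope != 0 else 1.0
    return MrEstimate(
        beta_EO=float(slope),
        se=se_slope,
        method="egger",
        p_value=p,
        intercept=float(intercept),
        intercept_se=se_int,
        n_instruments=j,
    )


def estimate(stats: pd.DataFrame, method: str = "ivw") -> MrEstimate:
    """Dispatch by method name (``ivw``, ``egger`` or ``ratio``).

    ``ratio`` requires exactly one instrument row.
    """
    if method == "ivw":
        return ivw_estimate(stats)
    if method == "egger":
        return egger_estimate(stats)
    if method == "ratio":
        if len(stats) != 1:
            raise SchemaError("ratio estimator is defined for a single instrument")
        row = stats.iloc[0]
        return ratio_estimate(
            float(row["beta_exposure"]), float(row["beta_outcome"]), float(row["se_outcome"])
        )
    raise SchemaError(f"unknown MR method {method!r}")
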