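"""The family-conditional randomization test (the MR-Twin test).

The test asks whether offspring genotypes predict the outcome trait better
than chance, *conditionally on the family genotypes*. Under the null of no
exposure-outcome effect (and no horizontal pleiotropy), the true offspring
genotypes are exchangeable with digital twins drawn from the same family
conditional distribution, so the observed statistic's rank among B twin
statistics yields an exact, distribution-free p-value — regardless of
population stratification, assortative mating or dynastic effects, all of
which act only through the parents.

The statistic scores the genetically predicted outcome against the observed
one with external GWAS weights held fixed:

    Ehat_n = sum_j beta_XE,j X_nj        (predicted exposure)
    Ohat_n = beta_EO * Ehat_n            (predicted outcome)
    t      = -sum_n (Ohat_n - O_n)^2     (negative squared error)

beta_XE and beta_EO come from the external summary data only and are never
re-fit per twin replicate; exchangeability holds because the offspring
genotypes are independent of the external estimates given the parents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import MrEstimate, estimate
from .exceptions import AlignmentError, DesignError
from .twins import FamilySet, TwinBatch, generate_twin_batch

__all__ = ["CrtResult", "mrtwin_statistic", "mrtwin_test"]


@dataclass
class CrtResult:
    """Outcome of one conditional randomization test."""

    t_star: float
    t_null: np.ndarray
    p_value: float
    B: int
    beta_EO_used: MrEstimate
    seed: int | None
    n_families: int
    n_instruments: int
    design: str = "trio"

    def __repr__(self) -> str:  # compact: the null vector is large
        return (
            f"CrtResult(p_value={self.p_value:.4g}, t_star={self.t_star:.4g}, "
            f"B={self.B}, design={self.design!r}, "
            f"beta_EO={self.beta_EO_used.beta_EO:.4g} [{self.beta_EO_used.method}], "
            f"n_families={self.n_families}, n_instruments={self.n_instruments})"
        )


def mrtwin_statistic(
    genotypes: np.ndarray,
    outcomes: np.ndarray,
    beta_xe: np.ndarray,
    beta_eo: float | MrEstimate,
) -> float:
    """Negative squared prediction error of the outcome from genotypes.

    ``genotypes`` is (N x M) over the instrument SNPs, aligned with
    ``beta_xe``. Larger (closer to zero) means the genetic prediction fits
    the outcome better.
    """
    g = np.asarray(genotypes, dtype=float)
    o = np.asarray(outcomes, dtype=float)
    b = np.asarray(beta_xe, dtype=float)
    if g.ndim != 2 or g.shape[1] != b.shape[0]:
        raise AlignmentError("genotype columns and beta_XE are misaligned")
    if g.shape[0] != o.shape[0]:
        raise AlignmentError("one outcome value per genotype row is required")
    if not (np.all(np.isfinite(o)) and np.all(np.isfinite(b))):
        raise AlignmentError("non-finite outcome or weight values")
    coef = beta_eo.beta_EO if isinstance(beta_eo, MrEstimate) else float(beta_eo)
    pred = coef * (g @ b)
    return float(-np.sum((pred - o) ** 2))


def _batch_statistics(
    batch: TwinBatch, outcomes: np.ndarray, beta_xe: np.ndarray, coef: float
) -> np.ndarray:
    """Vectorized statistic over all twin replicates: (B,) array."""
    ehat = np.tensordot(batch.twins.astype(float), beta_xe, axes=([2], [0]))  # (B, N)
    resid = coef * ehat - outcomes[None, :]
    return -np.einsum("bn,bn->b", resid, resid)


def mrtwin_test(
    families: FamilySet,
    stats: pd.DataFrame,
    instruments: list[str] | None = None,
    B: int = 100,
    method: str = "ivw",
    seed: int | None = 0,
    n_jobs: int = 1,
    two_sided: bool = False,
    check_mendelian: bool = True,
    allow_mendel_errors: bool = False,
) -> CrtResult:
    """Run the conditional randomization test on family data.

    Parameters
    ----------
    families
        Trio, duo or sibling family data with offspring outcomes.
    stats
        External summary statistics (one row per SNP).
    instruments
        SNP ids to use; defaults to every SNP present in both ``stats`` and
        the family panel, in the summary-statistics order.
    B
        Number of digital-twin replicates. 100 is adequate for replicated
        simulation studies; 1000 or more is recommended for a one-off
        analysis (the attainable p-value floor is 1/(B+1)).
    method
        Estimator for the fixed beta_EO weight: ``ivw``, ``egger`` or
        ``ratio``.
    two_sided
        Also count twins with statistics <= t* and double the smaller tail
        (capped at 1). Off by default: the statistic is one-sided by
        construction (larger t = better genetic prediction of O).

    Mendelian consistency of offspring with available parents is checked
    before testing; SNPs with inconsistencies are dropped family-wide when
    ``allow_mendel_errors`` is set, otherwise the test raises.
    """
    if B < 1:
        raise DesignError("B must be >= 1")
    if instruments is None:
        in_family = set(families.snp_ids)
        instruments = [s for s in stats["snp_id"] if s in in_family]
    if not instruments:
        from .exceptions import NoInstrumentsError

        raise NoInstrumentsError("no instrument SNPs shared between summary stats and families")
    sub_stats = stats.set_index("snp_id").loc[instruments].reset_index()
    fam = families.subset_snps(instruments)

    if check_mendelian:
        bad = fam.check_mendelian(allow_errors=allow_mendel_errors)
        if bad.any():
            keep = [s for s, drop in zip(fam.snp_ids, bad.any(axis=0)) if not drop]
            if not keep:
                from .exceptions import NoInstrumentsError

                raise NoInstrumentsError("every instrument SNP shows Mendelian inconsistencies")
            fam = fam.subset_snps(keep)
            sub_stats = sub_stats.set_index("snp_id").loc[keep].reset_index()

    est = estimate(sub_stats, method=method)
    beta_xe = sub_stats["beta_exposure"].to_numpy(dtype=float)

    t_star = mrtwin_statistic(fam.offspring, fam.outcomes, beta_xe, est)
    batch = generate_twin_batch(fam, B=B, seed=seed, n_jobs=n_jobs)
    t_null = _batch_statistics(batch, fam.outcomes, beta_xe, est.beta_EO)

    p_upper = (1 + int(np.sum(t_null >= t_star))) / (1 + B)
    if two_sided:
        p_lower = (1 + int(np.sum(t_null <= t_star))) / (1 + B)
        p = min(1.0, 2.0 * min(p_upper, p_lower))
    else:
        p = p_upper
    return CrtResult(
        t_star=t_star,
        t_null=t_null,
        p_value=float(p),
        B=B,
        beta_EO_used=est,
        seed=seed,
        n_families=fam.n_families,
        n_instruments=fam.n_snps,
        design=fam.design,
    )
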