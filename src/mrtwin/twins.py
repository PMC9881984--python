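"""Digital-twin genotype sampling conditional on family data.

A digital twin is a synthetic offspring genotype drawn from its family's
genotypes under Mendelian inheritance, so that the twin has the same
conditional distribution as the true offspring given the family data. Because
the instrument SNPs are treated as independent (the usual situation for MR
instruments after LD pruning), inheritance factorizes over SNPs and no
phasing is needed:

* trio mode — both parents observed; each twin allele is an independent
  Bernoulli draw from each parent's allele dosage: ``D ~ Bern(P1/2) + Bern(P2/2)``.
* duo mode — one parent observed; the allele from the unobserved parent is
  fixed from the offspring, and only the observed parent's transmission is
  resampled. If the observed parent is homozygous the twin equals the
  offspring; if heterozygous, ``D ~ Bern(1/2) + Bern(X/2)``.
* sibling mode — no parents observed; the twin's two alleles are drawn
  independently and uniformly from the 2S pooled alleles of the S observed
  siblings at each SNP (the "shuffling" approximation).

Only trio mode yields a twin distribution exactly equal to the offspring's
conditional law; duo and sibling modes are approximations and are not fully
calibrated under strong confounding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DesignError, InvalidGenotypeError, MendelianError

__all__ = [
    "FamilySet",
    "TwinBatch",
    "mendelian_sample",
    "mendelian_violations",
    "sample_twin_trio",
    "sample_twin_duo",
    "sample_twin_sibling",
    "generate_twin_batch",
]

GENOTYPE_DTYPE = np.int8


def _check_genotypes(g: np.ndarray, name: str = "genotypes") -> np.ndarray:
    g = np.asarray(g)
    if g.size and (not np.issubdtype(g.dtype, np.number) or np.any((g < 0) | (g > 2))):
        raise InvalidGenotypeError(f"{name} must be additive-coded in {{0,1,2}}")
    return g.astype(GENOTYPE_DTYPE, copy=False)


def mendelian_sample(parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw offspring genotypes from two parental genotype arrays.

    Per SNP the offspring dosage is ``Bern(P1/2) + Bern(P2/2)`` with all draws
    independent across parents and SNPs. Arrays may be vectors (one family)
    or matrices (families x SNPs); shapes must match.
    """
    p1 = _check_genotypes(parent1, "parent1")
    p2 = _check_genotypes(parent2, "parent2")
    if p1.shape != p2.shape:
        raise DesignError("parental genotype arrays must have identical shapes")
    a1 = rng.binomial(1, p1 / 2.0)
    a2 = rng.binomial(1, p2 / 2.0)
    return (a1 + a2).astype(GENOTYPE_DTYPE)


def mendelian_violations(
    offspring: np.ndarray, parent1: np.ndarray, parent2: np.ndarray
) -> np.ndarray:
    """Boolean mask of entries where the offspring genotype is impossible
    given the parents (e.g. parents (0,0) with offspring 1)."""
    x = np.asarray(offspring)
    p1 = np.asarray(parent1)
    p2 = np.asarray(parent2)
    lo = (p1 == 2).astype(int) + (p2 == 2).astype(int)
    hi = 2 - (p1 == 0).astype(int) - (p2 == 0).astype(int)
    return (x < lo) | (x > hi)


@dataclass
class FamilySet:
    """Indexed collection of families over a shared SNP panel.

    ``offspring`` is the (N families x M SNPs) matrix of index-individual
    genotypes and ``outcomes`` their outcome-trait values. Depending on
    ``design``, parental or sibling genotypes are attached:

    * ``trio`` — ``parent1`` and ``parent2``, each (N x M);
    * ``duo``  — ``parent1`` only;
    * ``sibling`` — ``siblings``: list of (S_n x M) arrays per family with
      S_n >= 2, where row 0 is the index individual itself.
    """

    design: str
    offspring: np.ndarray
    outcomes: np.ndarray
    parent1: np.ndarray | None = None
    parent2: np.ndarray | None = None
    siblings: list[np.ndarray] | None = None
    snp_ids: list[str] = field(default_factory=list)
    family_ids: list[str] = field(default_factory=list)
    exposures: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.offspring = _check_genotypes(self.offspring, "offspring")
        if self.offspring.ndim != 2:
            raise DesignError("offspring genotypes must be a 2-D (families x SNPs) array")
        self.outcomes = np.asarray(self.outcomes, dtype=float)
        n, m = self.offspring.shape
        if self.outcomes.shape != (n,):
            raise DesignError("outcomes must have one value per family")
        if not np.all(np.isfinite(self.outcomes)):
            raise DesignError("outcomes contain non-finite values")
        if not self.snp_ids:
            self.snp_ids = [f"snp{j}" for j in range(m)]
        if len(self.snp_ids) != m:
            raise DesignError("snp_ids length must match the SNP dimension")
        if not self.family_ids:
            self.family_ids = [f"fam{i}" for i in range(n)]

        if self.design == "trio":
            if self.parent1 is None or self.parent2 is None:
                raise DesignError("trio design requires both parental genotype matrices")
            self.parent1 = _check_genotypes(self.parent1, "parent1")
            self.parent2 = _check_genotypes(self.parent2, "parent2")
            if self.parent1.shape != (n, m) or self.parent2.shape != (n, m):
                raise DesignError("parental matrices must match offspring shape")
        elif self.design == "duo":
            if self.parent1 is None:
                raise DesignError("duo design requires one parental genotype matrix")
            if self.parent2 is not None:
                raise DesignError("duo design takes exactly one parent; got two")
            self.parent1 = _check_genotypes(self.parent1, "parent1")
            if self.parent1.shape != (n, m):
                raise DesignError("parental matrix must match offspring shape")
        elif self.design == "sibling":
            if not self.siblings or len(self.siblings) != n:
                raise DesignError("sibling design requires a sibling array per family")
            sibs = []
            for i, s in enumerate(self.siblings):
                s = _check_genotypes(s, f"siblings[{i}]")
                if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] != m:
                    raise DesignError(
                        "each family needs >= 2 sibling genotype rows over the shared SNP panel"
                    )
                sibs.append(s)
            self.siblings = sibs
        else:
            raise DesignError(f"unknown design {self.design!r}; expected trio, duo or sibling")

    @property
    def n_families(self) -> int:
        return self.offspring.shape[0]

    @property
    def n_snps(self) -> int:
        return self.offspring.shape[1]

    def check_mendelian(self, allow_errors: bool = False) -> np.ndarray:
        """Verify offspring transmission feasibility against available parents.

        Returns the violation mask. Raises :class:`MendelianError` unless
        ``allow_errors`` (in which case a count is warned and the caller may
        drop the flagged SNPs).
        """
        if self.design == "trio":
            bad = mendelian_violations(self.offspring, self.parent1, self.parent2)
        elif self.design == "duo":
            # single parent: offspring needs at least one allele compatible
            lo = (self.parent1 == 2).astype(int)
            hi = 1 + (self.parent1 > 0).astype(int)
            bad = (self.offspring < lo) | (self.offspring > hi)
        else:
            bad = np.zeros_like(self.offspring, dtype=bool)
        if bad.any():
            if not allow_errors:
                raise MendelianError(
                    f"{int(bad.sum())} offspring genotype(s) inconsistent with parents; "
                    "pass allow_errors=True to drop the affected SNPs"
                )
            warnings.warn(
                f"{int(bad.sum())} Mendelian inconsistencies detected", stacklevel=2
            )
        return bad

    def subset_snps(self, snp_ids) -> "FamilySet":
        """Return a FamilySet restricted to ``snp_ids``, in the given order."""
        index = {s: j for j, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            from .exceptions import AlignmentError

            raise AlignmentError(f"SNPs not present in family data: {missing[:5]}")
        cols = [index[s] for s in snp_ids]
        return FamilySet(
            design=self.design,
            offspring=self.offspring[:, cols],
            outcomes=self.outcomes,
            parent1=None if self.parent1 is None else self.parent1[:, cols],
            parent2=None if self.parent2 is None else self.parent2[:, cols],
            siblings=None if self.siblings is None else [s[:, cols] for s in self.siblings],
            snp_ids=list(snp_ids),
            family_ids=list(self.family_ids),
            exposures=self.exposures,
        )

    def to_duo(self, keep_parent: int = 1) -> "FamilySet":
        """Degrade a trio set to a duo set by dropping one parent."""
        if self.design != "trio":
            raise DesignError("to_duo requires a trio FamilySet")
        parent = self.parent1 if keep_parent == 1 else self.parent2
        return FamilySet(
            design="duo",
            offspring=self.offspring,
            outcomes=self.outcomes,
            parent1=parent,
            snp_ids=list(self.snp_ids),
            family_ids=list(self.family_ids),
            exposures=self.exposures,
        )


@dataclass
class TwinBatch:
    """B independent digital-twin replicates: tensor of shape (B, N, M)."""

    twins: np.ndarray
    seed: int | None
    design: str

    @property
    def B(self) -> int:
        return self.twins.shape[0]


def sample_twin_trio(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Trio-mode twin: identical in law to a true offspring given the parents."""
    if parent1 is None or parent2 is None:
        raise DesignError("trio twin sampling requires both parents")
    return mendelian_sample(parent1, parent2, rng)


def sample_twin_duo(
    parent: np.ndarray, offspring: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Duo-mode twin: resample only the observed parent's transmission.

    Homozygous parent SNPs transmit a fixed allele, so the twin equals the
    offspring there; heterozygous SNPs give ``Bern(1/2) + Bern(X/2)`` where
    the second term stands in for the unobserved parent's (fixed, unknown
    phase) contribution inferred from the offspring dosage.
    """
    p = _check_genotypes(parent, "parent")
    x = _check_genotypes(offspring, "offspring")
    if x is None or x.shape != p.shape:
        raise DesignError("duo twin sampling requires offspring genotypes matching the parent")
    het = p == 1
    d = x.copy()
    if het.any():
        a_obs = rng.binomial(1, np.full(het.sum(), 0.5))
        a_other = rng.binomial(1, x[het] / 2.0)
        d[het] = (a_obs + a_other).astype(GENOTYPE_DTYPE)
    return d


def sample_twin_sibling(
    siblings: np.ndarray,
    rng: np.random.Generator,
    distinct_siblings: bool = False,
) -> np.ndarray:
    """Sibling-mode twin by allele shuffling.

    With ``distinct_siblings=False`` (default) the twin's two alleles are two
    independent uniform draws from the 2S pooled sibling alleles at each SNP,
    i.e. ``Binomial(2, sum(G_s)/(2S))`` per SNP. With ``distinct_siblings=True``
    one allele is drawn from each of two distinct randomly chosen siblings.
    """
    g = _check_genotypes(siblings, "siblings")
    if g.ndim != 2 or g.shape[0] < 2:
        raise DesignError("sibling twin sampling requires >= 2 sibling genotype rows")
    s, m = g.shape
    if not distinct_siblings:
        freq = g.sum(axis=0) / (2.0 * s)
        return rng.binomial(2, freq).astype(GENOTYPE_DTYPE)
    i = rng.integers(s, size=m)
    j = (i + 1 + rng.integers(s - 1, size=m)) % s  # distinct from i, uniform over the rest
    a1 = rng.binomial(1, g[i, np.arange(m)] / 2.0)
    a2 = rng.binomial(1, g[j, np.arange(m)] / 2.0)
    return (a1 + a2).astype(GENOTYPE_DTYPE)


def _sample_replicate(
    families: FamilySet, rng: np.random.Generator, distinct_siblings: bool
) -> np.ndarray:
    if families.design == "trio":
        return sample_twin_trio(families.parent1, families.parent2, rng)
    if families.design == "duo":
        return sample_twin_duo(families.parent1, families.offspring, rng)
    out = np.empty_like(families.offspring)
    for i, sibs in enumerate(families.siblings):
        out[i] = sample_twin_sibling(sibs, rng, distinct_siblings=distinct_siblings)
    return out


def generate_twin_batch(
    families: FamilySet,
    B: int,
    seed: int | np.random.SeedSequence | None = 0,
    n_jobs: int = 1,
    distinct_siblings: bool = False,
) -> TwinBatch:
    """Generate ``B`` independent twin replicates for every family.

    The result is a deterministic function of ``(families, B, seed)``: each
    replicate draws from its own generator spawned from a single seed
    sequence, so chunking across workers cannot change the output.
    """
    if B < 1:
        raise DesignError("B must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(B)

    def one(child):
        return _sample_replicate(
            families, np.random.Generator(np.random.PCG64(child)), distinct_siblings
        )

    if n_jobs != 1:
        from joblib import Parallel, delayed  # optional; only for parallel batches

        reps = Parallel(n_jobs=n_jobs)(delayed(one)(c) for c in children)
    else:
        reps = [one(c) for c in children]
    twins = np.stack(reps).astype(GENOTYPE_DTYPE)
    seed_out = seed.entropy if isinstance(seed, np.random.SeedSequence) else seed
    return TwinBatch(twins=twins, seed=seed_out, design=families.design)
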