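"""Balding-Nichols two-population simulator with confounded phenotypes.

Generates the study conditions used to benchmark family-based MR against
standard summary-statistic MR: two subpopulations whose per-SNP allele
frequencies diverge from a shared ancestral frequency according to the
Balding-Nichols Beta model with dispersion set by F_ST; an "external" cohort
of unrelated individuals (standing in for a biobank GWAS sample); and trio
families whose parents are drawn from the same population frequencies, with
offspring produced by Mendelian transmission.

Phenotypes follow a linear model in which a binary population label acts as
a confounder of both traits:

    E = X @ beta_XE + gamma * pop + eps_E      (exposure)
    O = beta_EO * E + gamma * pop + eps_O      (outcome)

``beta_XE`` is nonzero for ``m_causal`` SNPs and scaled so the genetic
component explains ``h2`` of Var(E) when gamma = 0; noise variances are set
so each phenotype has unit variance at gamma = 0. A nonzero ``gamma`` with
``beta_causal_EO = 0`` produces the confounded null in which naive MR is
biased but the family-conditional test remains valid.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .exceptions import ConfigError
from .twins import FamilySet, GENOTYPE_DTYPE, mendelian_sample

__all__ = [
    "PopSimConfig",
    "SimDataset",
    "simulate_genotypes",
    "sample_offspring",
    "simulate_phenotypes",
    "simulate_dataset",
]


@dataclass(frozen=True)
class PopSimConfig:
    """Parameters of the two-population simulation.

    Defaults follow the benchmark's reduced scale; the full-scale false
    positive rate experiments use ``n_external=50000`` and power experiments
    ``n_external=100000`` with ``n_families=1000`` and ``m_snps=100``
    (``m_causal=50``, ``fst=0.01``, ``h2=0.2``).
    """

    n_external: int = 2000
    n_families: int = 200
    m_snps: int = 50
    m_causal: int = 25
    fst: float = 0.01
    h2: float = 0.2
    gamma_confound: float = 0.0
    beta_causal_EO: float = 0.0
    pop_split: float = 0.5
    seed: int = 0
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    gamma_confound_outcome: Optional[float] = None  # defaults to gamma_confound

    def __post_init__(self) -> None:
        if not 0.0 <= self.fst < 1.0:
            raise ConfigError("fst must be in [0, 1)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigError("h2 must be in [0, 1]")
        if self.m_causal > self.m_snps:
            raise ConfigError("m_causal cannot exceed m_snps")
        if self.m_snps < 1 or self.n_external < 0 or self.n_families < 0:
            raise ConfigError("counts must be non-negative (m_snps >= 1)")
        lo, hi = self.ancestral_freq_range
        if not (0.0 < lo < hi < 1.0):
            raise ConfigError("ancestral_freq_range must be strictly inside (0, 1)")
        if not 0.0 <= self.pop_split <= 1.0:
            raise ConfigError("pop_split must be in [0, 1]")
        if self.beta_causal_EO**2 >= 1.0:
            raise ConfigError(
                "beta_causal_EO**2 must be < 1 so the outcome noise variance stays positive"
            )

    @property
    def gamma_outcome(self) -> float:
        g = self.gamma_confound_outcome
        return self.gamma_confound if g is None else g


@dataclass
class SimDataset:
    """One realization of the simulation: external cohort plus trio families."""

    external_genotypes: np.ndarray
    external_exposure: np.ndarray
    external_outcome: np.ndarray
    families: FamilySet
    external_pop: np.ndarray
    family_pop: np.ndarray
    true_beta_XE: np.ndarray
    snp_ids: list[str]
    config: PopSimConfig


def _population_frequencies(config: PopSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw (2, M) population-specific allele frequencies.

    Ancestral frequency p_j ~ Uniform(ancestral_freq_range); population k's
    frequency is Beta(p_j (1-F)/F, (1-p_j)(1-F)/F), whose mean is p_j and
    whose variance is F p_j (1-p_j). F=0 collapses to the point mass at p_j.
    """
    lo, hi = config.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=config.m_snps)
    if config.fst == 0.0:
        return np.vstack([p_anc, p_anc])
    scale = (1.0 - config.fst) / config.fst
    a = p_anc * scale
    b = (1.0 - p_anc) * scale
    return rng.beta(a, b, size=(2, config.m_snps))


def _pop_labels(n: int, split: float) -> np.ndarray:
    """Deterministic 0/1 labels with round(n * split) individuals in pop 1."""
    n1 = int(round(n * split))
    labels = np.zeros(n, dtype=np.int8)
    labels[:n1] = 1
    return labels


def simulate_genotypes(
    config: PopSimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], np.ndarray, np.ndarray]:
    """Simulate external genotypes and trio-parent genotypes.

    Returns ``(external, (parent1, parent2), external_pop, family_pop)``.
    External individuals and the parents of each family are drawn from the
    same realization of the population frequencies, so the external and
    family cohorts share the same structure; both parents in a family belong
    to the same population.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    freqs = _population_frequencies(config, rng)

    external_pop = _pop_labels(config.n_external, config.pop_split)
    external = rng.binomial(2, freqs[external_pop]).astype(GENOTYPE_DTYPE)

    family_pop = _pop_labels(config.n_families, config.pop_split)
    parent1 = rng.binomial(2, freqs[family_pop]).astype(GENOTYPE_DTYPE)
    parent2 = rng.binomial(2, freqs[family_pop]).astype(GENOTYPE_DTYPE)
    return external, (parent1, parent2), external_pop, family_pop


def sample_offspring(
    parent1: np.ndarray, parent2: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Mendelian transmission: per SNP, ``Bern(P1/2) + Bern(P2/2)``.

    Shares its implementation with trio-mode digital-twin sampling — the two
    are the same conditional law by construction.
    """
    return mendelian_sample(parent1, parent2, rng)


def _draw_effects(
    genotypes: np.ndarray, config: PopSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Per-SNP exposure effects: i.i.d. Gaussian on a random causal subset,
    rescaled so the genetic component has empirical variance h2."""
    beta = np.zeros(config.m_snps)
    if config.m_causal == 0 or config.h2 == 0.0:
        return beta
    causal = rng.choice(config.m_snps, size=config.m_causal, replace=False)
    raw = rng.standard_normal(config.m_causal)
    beta[causal] = raw
    g = genotypes @ beta
    v = g.var()
    if v > 0:
        beta *= np.sqrt(config.h2 / v)
    return beta


def simulate_phenotypes(
    genotypes: np.ndarray,
    pop_labels: np.ndarray,
    config: PopSimConfig,
    rng: np.random.Generator,
    beta_xe: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate (exposure, outcome) for one cohort.

    If ``beta_xe`` is None, effects are drawn and scaled on this cohort;
    passing a vector reuses effects across cohorts (external and families
    must share the same true genetic architecture).
    """
    genotypes = np.asarray(genotypes)
    pop = np.asarray(pop_labels, dtype=float)
    if genotypes.shape[0] != pop.shape[0]:
        raise ConfigError("genotypes and population labels are not conformable")
    if beta_xe is None:
        beta_xe = _draw_effects(genotypes, config, rng)

    n = genotypes.shape[0]
    g = genotypes @ beta_xe
    eps_e = rng.standard_normal(n) * np.sqrt(max(1.0 - config.h2, 0.0))
    exposure = g + config.gamma_confound * pop + eps_e

    var_eps_o = 1.0 - config.beta_causal_EO**2
    eps_o = rng.standard_normal(n) * np.sqrt(var_eps_o)
    outcome = config.beta_causal_EO * exposure + config.gamma_outcome * pop + eps_o
    return exposure, outcome, beta_xe


def simulate_dataset(config: PopSimConfig, n_siblings: int = 1) -> SimDataset:
    """Run the full generative model and package the result.

    ``n_siblings > 1`` additionally simulates extra offspring per family
    (sharing the index offspring's parents) and attaches them so the family
    data can be degraded to a sibling design.
    """
    rng = np.random.default_rng(config.seed)
    external, (p1, p2), ext_pop, fam_pop = simulate_genotypes(config, rng)
    offspring = sample_offspring(p1, p2, rng)

    ext_e, ext_o, beta_xe = simulate_phenotypes(external, ext_pop, config, rng)
    fam_e, fam_o, _ = simulate_phenotypes(offspring, fam_pop, config, rng, beta_xe=beta_xe)

    snp_ids = [f"snp{j}" for j in range(config.m_snps)]
    siblings = None
    if n_siblings > 1:
        extra = [sample_offspring(p1, p2, rng) for _ in range(n_siblings - 1)]
        siblings = [
            np.vstack([offspring[i : i + 1]] + [e[i : i + 1] for e in extra])
            for i in range(config.n_families)
        ]
    families = FamilySet(
        design="trio",
        offspring=offspring,
        outcomes=fam_o,
        parent1=p1,
        parent2=p2,
        snp_ids=snp_ids,
        exposures=fam_e,
    )
    families.siblings = siblings  # carried for .to_sibling-style degradation
    return SimDataset(
        external_genotypes=external,
        external_exposure=ext_e,
        external_outcome=ext_o,
        families=families,
        external_pop=ext_pop,
        family_pop=fam_pop,
        true_beta_XE=beta_xe,
        snp_ids=snp_ids,
        config=config,
    )


def sibling_families(dataset: SimDataset) -> FamilySet:
    """View a simulated trio dataset as a sibling design (parents hidden)."""
    fam = dataset.families
    if fam.siblings is None:
        raise ConfigError("dataset was simulated without extra siblings; use n_siblings >= 2")
    return FamilySet(
        design="sibling",
        offspring=fam.offspring,
        outcomes=fam.outcomes,
        siblings=fam.siblings,
        snp_ids=list(fam.snp_ids),
        family_ids=list(fam.family_ids),
        exposures=fam.exposures,
    )


def scaled_config(base: PopSimConfig, **overrides) -> PopSimConfig:
    """Convenience: a copy of ``base`` with fields replaced."""
    return replace(base, **overrides)
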