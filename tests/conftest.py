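import numpy as np
import pytest

import mrtwin as mt


def hudson_fst(geno_pop1: np.ndarray, geno_pop2: np.ndarray) -> float:
    """Hudson estimator of F_ST from two diploid genotype matrices.

    Ratio-of-averages form: for each SNP, numerator
    (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1) and denominator
    p1(1-p2) + p2(1-p1), with p_k the sample allele frequency and n_k the
    haploid sample size. Independent oracle used to check the simulator.
    """
    n1 = 2 * geno_pop1.shape[0]
    n2 = 2 * geno_pop2.shape[0]
    p1 = geno_pop1.mean(axis=0) / 2.0
    p2 = geno_pop2.mean(axis=0) / 2.0
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return float(num.sum() / den.sum())


def empirical_pmf(draws: np.ndarray) -> dict[int, float]:
    values, counts = np.unique(draws, return_counts=True)
    return {int(v): c / draws.size for v, c in zip(values, counts)}


@pytest.fixture(scope="session")
def small_dataset() -> mt.SimDataset:
    """Unconfounded null dataset shared by fast tests."""
    config = mt.PopSimConfig(
        n_external=2000, n_families=100, m_snps=20, m_causal=10, seed=1
    )
    return mt.simulate_dataset(config)


@pytest.fixture(scope="session")
def small_stats(small_dataset):
    return mt.summary_stats(
        small_dataset.external_genotypes,
        small_dataset.external_exposure,
        small_dataset.external_outcome,
        snp_ids=small_dataset.snp_ids,
    )
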