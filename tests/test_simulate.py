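"""Simulator checks: Balding-Nichols structure, Mendelian transmission,
phenotype architecture, determinism."""

import numpy as np
import pytest

import mrtwin as mt
from mrtwin.simulate import _population_frequencies

from conftest import hudson_fst, empirical_pmf


class TestGenotypes:
    def test_fst_zero_collapses_to_shared_frequency(self):
        config = mt.PopSimConfig(fst=0.0, m_snps=30, seed=3)
        freqs = _population_frequencies(config, np.random.default_rng(3))
        np.testing.assert_array_equal(freqs[0], freqs[1])

    def test_hudson_fst_recovers_target(self):
        # 10,000 diploid samples per population, 200 SNPs, target F_ST = 0.01
        config = mt.PopSimConfig(
            n_external=20000, n_families=0, m_snps=200, m_causal=0, fst=0.01, seed=4
        )
        ext, _, pop, _ = mt.simulate_genotypes(config)
        fst_hat = hudson_fst(ext[pop == 0], ext[pop == 1])
        assert abs(fst_hat - 0.01) < 0.005

    def test_external_matrix_shape_and_coding(self):
        config = mt.PopSimConfig(n_external=50000, n_families=0, m_snps=100, m_causal=50, seed=5)
        ext, _, pop, _ = mt.simulate_genotypes(config)
        assert ext.shape == (50000, 100)
        assert set(np.unique(ext)) <= {0, 1, 2}
        assert pop.sum() == 25000  # even split

    def test_divergence_increases_with_fst(self):
        rng_seed = 6
        divergences = []
        for fst in (0.0, 0.01, 0.05, 0.1):
            config = mt.PopSimConfig(fst=fst, m_snps=500, seed=rng_seed)
            freqs = _population_frequencies(config, np.random.default_rng(rng_seed))
            divergences.append(np.abs(freqs[0] - freqs[1]).mean())
        assert all(a < b for a, b in zip(divergences, divergences[1:]))

    def test_mendelian_consistency_of_simulated_offspring(self, small_dataset):
        fam = small_dataset.families
        bad = mt.mendelian_violations(fam.offspring, fam.parent1, fam.parent2)
        assert not bad.any()

    def test_fixed_seed_is_bit_identical(self):
        config = mt.PopSimConfig(n_external=200, n_families=20, m_snps=10, m_causal=5, seed=7)
        d1 = mt.simulate_dataset(config)
        d2 = mt.simulate_dataset(config)
        np.testing.assert_array_equal(d1.external_genotypes, d2.external_genotypes)
        np.testing.assert_array_equal(d1.families.offspring, d2.families.offspring)
        np.testing.assert_array_equal(d1.external_exposure, d2.external_exposure)
        np.testing.assert_array_equal(d1.true_beta_XE, d2.true_beta_XE)


class TestOffspringSampling:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (2, 2, {2: 1.0}),
            (0, 2, {1: 1.0}),
            (0, 0, {0: 1.0}),
            (1, 1, {0: 0.25, 1: 0.5, 2: 0.25}),
        ],
    )
    def test_transmission_law(self, p1, p2, expected):
        rng = np.random.default_rng(8)
        n = 100_000
        draws = mt.sample_offspring(np.full(n, p1), np.full(n, p2), rng)
        pmf = empirical_pmf(draws)
        assert set(pmf) == set(expected)
        for k, prob in expected.items():
            assert pmf[k] == pytest.approx(prob, abs=0.01)

    def test_invalid_genotype_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(mt.InvalidGenotypeError):
            mt.sample_offspring(np.array([3]), np.array([0]), rng)
        with pytest.raises(mt.InvalidGenotypeError):
            mt.sample_offspring(np.array([0]), np.array([-1]), rng)


class TestPhenotypes:
    def test_heritability_recovered_by_regression(self):
        config = mt.PopSimConfig(
            n_external=50000, n_families=0, m_snps=50, m_causal=25, h2=0.2, seed=9
        )
        d = mt.simulate_dataset(config)
        causal = np.flatnonzero(d.true_beta_XE)
        x = np.column_stack([np.ones(50000), d.external_genotypes[:, causal]])
        coef, *_ = np.linalg.lstsq(x, d.external_exposure, rcond=None)
        resid = d.external_exposure - x @ coef
        r2 = 1 - resid.var() / d.external_exposure.var()
        assert r2 == pytest.approx(0.2, abs=0.02)

    def test_unconfounded_null_traits_uncorrelated(self):
        config = mt.PopSimConfig(
            n_external=50000, n_families=0, m_snps=20, m_causal=10,
            gamma_confound=0.0, beta_causal_EO=0.0, seed=10,
        )
        d = mt.simulate_dataset(config)
        r = np.corrcoef(d.external_exposure, d.external_outcome)[0, 1]
        assert abs(r) < 0.02

    def test_confounded_null_traits_correlated(self):
        config = mt.PopSimConfig(
            n_external=20000, n_families=0, m_snps=20, m_causal=10,
            gamma_confound=0.8, beta_causal_EO=0.0, seed=11,
        )
        d = mt.simulate_dataset(config)
        r = np.corrcoef(d.external_exposure, d.external_outcome)[0, 1]
        assert r > 0.05

    def test_unit_variance_at_zero_confounding(self):
        config = mt.PopSimConfig(n_external=50000, n_families=0, m_snps=20, m_causal=10, seed=12)
        d = mt.simulate_dataset(config)
        assert d.external_exposure.var() == pytest.approx(1.0, abs=0.05)
        assert d.external_outcome.var() == pytest.approx(1.0, abs=0.05)

    def test_pop_label_independent_of_phenotype_without_confounding(self):
        config = mt.PopSimConfig(
            n_external=50000, n_families=0, m_snps=20, m_causal=10, fst=0.0,
            gamma_confound=0.0, seed=13,
        )
        d = mt.simulate_dataset(config)
        r = np.corrcoef(d.external_pop, d.external_exposure)[0, 1]
        assert abs(r) < 0.02

    def test_h2_zero_gives_null_effects(self):
        config = mt.PopSimConfig(n_external=500, n_families=0, m_snps=10, m_causal=5, h2=0.0, seed=14)
        d = mt.simulate_dataset(config)
        assert np.all(d.true_beta_XE == 0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fst": 1.0},
            {"fst": -0.1},
            {"h2": 1.5},
            {"m_snps": 10, "m_causal": 11},
            {"ancestral_freq_range": (0.0, 0.95)},
            {"ancestral_freq_range": (0.9, 0.1)},
            {"beta_causal_EO": 1.0},
            {"pop_split": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(mt.ConfigError):
            mt.PopSimConfig(**kwargs)

    def test_gamma_outcome_override(self):
        config = mt.PopSimConfig(gamma_confound=0.4, gamma_confound_outcome=0.1)
        assert config.gamma_outcome == 0.1
        assert mt.PopSimConfig(gamma_confound=0.4).gamma_outcome == 0.4
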