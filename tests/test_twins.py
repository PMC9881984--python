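"""Digital-twin sampler checks: per-SNP inheritance laws for each family
design, batch determinism, and Mendelian-consistency properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import mrtwin as mt
from mrtwin.twins import sample_twin_duo, sample_twin_sibling, sample_twin_trio

from conftest import empirical_pmf

N_DRAWS = 100_000


def _trio_families(offspring, p1, p2, outcomes=None):
    n = offspring.shape[0]
    return mt.FamilySet(
        design="trio",
        offspring=offspring,
        outcomes=np.zeros(n) if outcomes is None else outcomes,
        parent1=p1,
        parent2=p2,
    )


class TestTrioLaw:
    @pytest.mark.parametrize(
        "p1,p2,expected",
        [
            (0, 0, {0: 1.0}),
            (1, 2, {1: 0.5, 2: 0.5}),
            (1, 1, {0: 0.25, 1: 0.5, 2: 0.25}),
        ],
    )
    def test_per_snp_distribution(self, p1, p2, expected):
        rng = np.random.default_rng(30)
        draws = sample_twin_trio(np.full(N_DRAWS, p1), np.full(N_DRAWS, p2), rng)
        pmf = empirical_pmf(draws)
        assert set(pmf) == set(expected)
        for k, prob in expected.items():
            assert pmf[k] == pytest.approx(prob, abs=0.01)

    def test_twin_law_matches_offspring_law(self):
        # same parents, same conditional law: compare empirical pmfs
        rng = np.random.default_rng(31)
        p1 = np.full(N_DRAWS, 1)
        p2 = np.full(N_DRAWS, 1)
        twins = sample_twin_trio(p1, p2, rng)
        offspring = mt.sample_offspring(p1, p2, rng)
        pmf_t = empirical_pmf(twins)
        pmf_o = empirical_pmf(offspring)
        for k in (0, 1, 2):
            assert pmf_t[k] == pytest.approx(pmf_o[k], abs=0.01)

    def test_missing_parent_rejected(self):
        with pytest.raises(mt.DesignError):
            sample_twin_trio(None, np.array([1]), np.random.default_rng(0))

    @settings(derandomize=True, max_examples=25)
    @given(
        parents=arrays(np.int8, shape=(2, 12), elements=st.integers(0, 2)),
        seed=st.integers(0, 2**16),
    )
    def test_twin_always_mendelian_consistent(self, parents, seed):
        rng = np.random.default_rng(seed)
        twin = sample_twin_trio(parents[0], parents[1], rng)
        assert set(np.unique(twin)) <= {0, 1, 2}
        assert not mt.mendelian_violations(twin, parents[0], parents[1]).any()


class TestDuoLaw:
    def test_homozygous_parent_fixes_twin_to_offspring(self):
        rng = np.random.default_rng(32)
        parent = np.array([0, 0, 2, 2] * 25)
        offspring = np.array([0, 1, 1, 2] * 25)
        twin = sample_twin_duo(parent, offspring, rng)
        np.testing.assert_array_equal(twin, offspring)

    @pytest.mark.parametrize(
        "x,expected",
        [
            (2, {1: 0.5, 2: 0.5}),  # Bern(1/2) + Bern(1)
            (0, {0: 0.5, 1: 0.5}),  # Bern(1/2) + Bern(0)
            (1, {0: 0.25, 1: 0.5, 2: 0.25}),
        ],
    )
    def test_heterozygous_parent_distribution(self, x, expected):
        rng = np.random.default_rng(33)
        twin = sample_twin_duo(np.full(N_DRAWS, 1), np.full(N_DRAWS, x), rng)
        pmf = empirical_pmf(twin)
        assert set(pmf) == set(expected)
        for k, prob in expected.items():
            assert pmf[k] == pytest.approx(prob, abs=0.01)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(mt.DesignError):
            sample_twin_duo(np.array([1, 1]), np.array([1]), np.random.default_rng(0))


class TestSiblingLaw:
    def test_identical_homozygous_siblings_fix_twin(self):
        rng = np.random.default_rng(34)
        sibs = np.full((2, 50), 2)
        np.testing.assert_array_equal(sample_twin_sibling(sibs, rng), np.full(50, 2))

    def test_opposite_homozygotes_pool_to_half(self):
        # siblings (0, 2): pooled alleles {0,0,1,1} -> Binomial(2, 1/2)
        rng = np.random.default_rng(35)
        sibs = np.vstack([np.zeros(N_DRAWS), np.full(N_DRAWS, 2)]).astype(np.int8)
        pmf = empirical_pmf(sample_twin_sibling(sibs, rng))
        assert pmf[0] == pytest.approx(0.25, abs=0.01)
        assert pmf[1] == pytest.approx(0.5, abs=0.01)
        assert pmf[2] == pytest.approx(0.25, abs=0.01)

    def test_distinct_sibling_variant(self):
        # drawing one allele from each of the two distinct siblings (0, 2)
        # gives Bern(0) + Bern(1) = 1 always
        rng = np.random.default_rng(36)
        sibs = np.vstack([np.zeros(100), np.full(100, 2)]).astype(np.int8)
        twin = sample_twin_sibling(sibs, rng, distinct_siblings=True)
        np.testing.assert_array_equal(twin, np.ones(100))

    def test_single_sibling_rejected(self):
        with pytest.raises(mt.DesignError):
            sample_twin_sibling(np.zeros((1, 5)), np.random.default_rng(0))


class TestBatches:
    def test_seed_determinism_across_worker_counts(self, small_dataset):
        fam = small_dataset.families
        serial = mt.generate_twin_batch(fam, B=8, seed=42, n_jobs=1)
        parallel = mt.generate_twin_batch(fam, B=8, seed=42, n_jobs=2)
        np.testing.assert_array_equal(serial.twins, parallel.twins)
        again = mt.generate_twin_batch(fam, B=8, seed=42)
        np.testing.assert_array_equal(serial.twins, again.twins)

    def test_trio_twin_mean_converges_to_parental_mean(self):
        rng = np.random.default_rng(37)
        p1 = rng.integers(0, 3, size=(5, 4)).astype(np.int8)
        p2 = rng.integers(0, 3, size=(5, 4)).astype(np.int8)
        fam = _trio_families(mt.mendelian_sample(p1, p2, rng), p1, p2)
        batch = mt.generate_twin_batch(fam, B=4000, seed=1)
        np.testing.assert_allclose(
            batch.twins.mean(axis=0), (p1 + p2) / 2.0, atol=0.06
        )

    def test_b_must_be_positive(self, small_dataset):
        with pytest.raises(mt.DesignError):
            mt.generate_twin_batch(small_dataset.families, B=0, seed=0)


class TestFamilySetValidation:
    def test_trio_requires_both_parents(self):
        with pytest.raises(mt.DesignError):
            mt.FamilySet(
                design="trio", offspring=np.zeros((2, 3)), outcomes=np.zeros(2),
                parent1=np.zeros((2, 3)),
            )

    def test_sibling_requires_two_rows(self):
        with pytest.raises(mt.DesignError):
            mt.FamilySet(
                design="sibling", offspring=np.zeros((1, 3)), outcomes=np.zeros(1),
                siblings=[np.zeros((1, 3))],
            )

    def test_unknown_design(self):
        with pytest.raises(mt.DesignError):
            mt.FamilySet(design="quad", offspring=np.zeros((1, 2)), outcomes=np.zeros(1))

    def test_subset_snps_alignment_error(self, small_dataset):
        with pytest.raises(mt.AlignmentError):
            small_dataset.families.subset_snps(["nonexistent_snp"])

    def test_mendelian_check_raises_then_warns(self):
        p1 = np.zeros((1, 2), dtype=np.int8)
        p2 = np.zeros((1, 2), dtype=np.int8)
        bad_child = np.array([[1, 0]], dtype=np.int8)  # impossible given (0,0)
        fam = _trio_families(bad_child, p1, p2)
        with pytest.raises(mt.MendelianError):
            fam.check_mendelian()
        with pytest.warns(UserWarning, match="Mendelian"):
            mask = fam.check_mendelian(allow_errors=True)
        assert mask.sum() == 1 and mask[0, 0]
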