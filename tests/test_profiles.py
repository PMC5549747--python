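import numpy as np
import pytest

from scalescape import (
    NucleobaseTarget,
    ProfileCache,
    mrna_density_profile,
    pair_correlation,
    protein_profile,
    protein_window_matrix,
    proteome_mean_R,
    pyr_density_profile,
    sample_random_scales,
)

from oracles import naive_mrna_profile, naive_pearson, naive_protein_profile

PUR = NucleobaseTarget.PUR


class TestMrnaDensityProfile:
    def test_single_window_one_purine_per_codon(self):
        cds = "GCT" * 21 + "TAA"
        np.testing.assert_allclose(mrna_density_profile(cds, PUR), [1.0 / 3.0])

    def test_all_purine_codons_give_unit_density(self):
        cds = "AAG" * 25 + "TAA"
        np.testing.assert_allclose(mrna_density_profile(cds, PUR), np.ones(5))

    def test_two_point_profile_matches_direct_counting(self):
        cds = "AAA" * 11 + "TTT" * 11 + "TAA"
        profile = mrna_density_profile(cds, PUR)
        np.testing.assert_allclose(profile, naive_mrna_profile(cds, ("A", "G")))
        assert profile.shape == (2,)

    def test_cds_shorter_than_one_window_rejected(self):
        with pytest.raises(ValueError, match="full window"):
            mrna_density_profile("AAA" * 15 + "TAA", PUR)

    @pytest.mark.parametrize("target", list(NucleobaseTarget))
    def test_matches_brute_force_counter_on_random_cds(self, target, varied_proteome):
        for pair in varied_proteome.pairs[:10]:
            np.testing.assert_allclose(
                mrna_density_profile(pair.cds, target),
                naive_mrna_profile(pair.cds, target.bases),
                atol=1e-12,
            )

    def test_purine_density_is_ade_plus_gua(self, varied_proteome):
        for pair in varied_proteome.pairs[:10]:
            np.testing.assert_allclose(
                mrna_density_profile(pair.cds, PUR),
                mrna_density_profile(pair.cds, NucleobaseTarget.ADE)
                + mrna_density_profile(pair.cds, NucleobaseTarget.GUA),
                atol=1e-12,
            )

    def test_values_within_unit_interval(self, varied_proteome):
        for pair in varied_proteome:
            profile = mrna_density_profile(pair.cds, PUR)
            assert profile.min() >= 0.0 and profile.max() <= 1.0
            assert profile.size == pair.length - 20


class TestProteinProfiles:
    def test_homopolymer_window_matrix(self):
        M = protein_window_matrix("K" * 21)
        assert M.shape == (1, 20)
        k_col = "ACDEFGHIKLMNPQRSTVWY".index("K")
        assert M[0, k_col] == 1.0 and M.sum() == 1.0

    def test_rows_sum_to_one(self, varied_proteome):
        for pair in varied_proteome.pairs[:10]:
            M = protein_window_matrix(pair.protein)
            np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)

    def test_matrix_times_scale_equals_naive_window_mean(self):
        protein = "KF" + "A" * 20
        M = protein_window_matrix(protein)
        for scale in sample_random_scales(100, seed=42):
            np.testing.assert_allclose(
                M @ scale.vector,
                naive_protein_profile(protein, scale.weights),
                atol=1e-12,
            )

    def test_uniform_scale_gives_constant_profile(self):
        from scalescape import AffinityScale

        profile = protein_profile("KFWA" * 8, AffinityScale.uniform(3.5))
        np.testing.assert_allclose(profile, 3.5)

    def test_affine_property_exact(self, varied_proteome):
        (scale,) = sample_random_scales(1, seed=3)
        protein = varied_proteome[0].protein
        base = protein_profile(protein, scale.vector)
        np.testing.assert_allclose(
            protein_profile(protein, 2.5 * scale.vector - 1.0),
            2.5 * base - 1.0,
            atol=1e-12,
        )


class TestPairCorrelation:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3], [5, 5, 5], 0.0),  # zero-variance convention
        ],
    )
    def test_examples(self, x, y, expected):
        assert pair_correlation(np.array(x, float), np.array(y, float)) == pytest.approx(expected)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            pair_correlation(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            pair_correlation(np.ones(1), np.ones(1))

    def test_agrees_with_scipy_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x, y = rng.random(30), rng.random(30)
            assert pair_correlation(x, y) == pytest.approx(naive_pearson(x, y), abs=1e-12)


class TestFitness:
    def test_single_pair_mean_is_that_pairs_R(self, varied_proteome):
        from scalescape import Proteome

        (scale,) = sample_random_scales(1, seed=9)
        single = Proteome("one", [varied_proteome[0]])
        result = proteome_mean_R(single, scale, PUR)
        assert result.n_pairs == 1
        assert result.mean_R == pytest.approx(result.per_pair_R[0])

    def test_uniform_scale_has_zero_fitness(self, small_proteome):
        from scalescape import AffinityScale

        result = proteome_mean_R(small_proteome, AffinityScale.uniform(1.0), PUR)
        assert result.mean_R == 0.0

    def test_mean_is_mean_of_per_pair(self, small_cache):
        (scale,) = sample_random_scales(1, seed=1)
        result = small_cache.fitness(scale, PUR)
        assert result.mean_R == pytest.approx(result.per_pair_R.mean(), abs=1e-15)

    def test_cache_equals_from_scratch(self, small_proteome, small_cache):
        for scale in sample_random_scales(5, seed=2):
            fast = small_cache.mean_R(scale, PUR)
            slow = proteome_mean_R(small_proteome, scale, PUR).mean_R
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_affine_invariance_and_sign_flip(self, small_cache):
        (scale,) = sample_random_scales(1, seed=4)
        base = small_cache.mean_R(scale.vector, PUR)
        assert small_cache.mean_R(3.0 * scale.vector + 2.0, PUR) == pytest.approx(base, abs=1e-12)
        assert small_cache.mean_R(-1.5 * scale.vector, PUR) == pytest.approx(-base, abs=1e-12)

    def test_empty_proteome_rejected(self):
        from scalescape import Proteome

        with pytest.raises(ValueError, match="empty"):
            ProfileCache(Proteome("x", []))


class TestPyrHelper:
    def test_all_purine_cds_has_zero_pyr_density(self):
        cds = "AAG" * 25 + "TAA"
        np.testing.assert_allclose(pyr_density_profile(cds), np.zeros(5), atol=1e-15)

    def test_direct_pyrimidine_counting(self, varied_proteome):
        for pair in varied_proteome.pairs[:10]:
            np.testing.assert_allclose(
                pyr_density_profile(pair.cds),
                naive_mrna_profile(pair.cds, ("C", "T")),
                atol=1e-12,
            )

    def test_antisymmetry_of_correlations(self, varied_proteome):
        (scale,) = sample_random_scales(1, seed=6)
        for pair in varied_proteome.pairs[:10]:
            p = protein_profile(pair.protein, scale)
            r_pur = pair_correlation(mrna_density_profile(pair.cds, PUR), p)
            r_pyr = pair_correlation(pyr_density_profile(pair.cds), p)
            assert r_pyr == pytest.approx(-r_pur, abs=1e-12)
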