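"""Mean-centered PLS: SVD contracts, permutation and bootstrap inference."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from envtails.errors import ValidationError
from envtails.pls import (
    average_site_scores,
    bootstrap_test,
    mean_centered_svd,
    permutation_test,
)


def _planted(n_per_group=20, n_features=8, delta=10.0, seed=0):
    """Two groups separated by `delta` SDs on the first feature."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per_group, n_features))
    X[n_per_group:, 0] += delta
    labels = np.repeat([0, 1], n_per_group)
    return X, labels


class TestMeanCenteredSvd:
    def test_hand_worked_two_group_example(self):
        """Group means [[0,0],[0,2]]: S=[sqrt(2)], contrast prop to
        [-1,1]/sqrt(2), salience prop to [0,1], all to 1e-10."""
        X = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 2.0], [0.0, 2.0]])
        model = mean_centered_svd(X, np.array([0, 0, 1, 1]))
        np.testing.assert_allclose(model.singular_values, [np.sqrt(2)], atol=1e-10)
        np.testing.assert_allclose(model.centered, [[0, -1], [0, 1]], atol=1e-10)
        u, v = model.contrasts[:, 0], model.saliences[:, 0]
        sign = np.sign(u[1])
        np.testing.assert_allclose(sign * u, [-1, 1] / np.sqrt(2), atol=1e-10)
        np.testing.assert_allclose(sign * v, [0, 1], atol=1e-10)
        # reconstruction of the centered matrix
        np.testing.assert_allclose(
            model.contrasts @ np.diag(model.singular_values) @ model.saliences.T,
            model.centered,
            atol=1e-10,
        )

    def test_identical_group_means_give_zero_singulars(self):
        X = np.tile([1.0, 2.0, 3.0], (6, 1))
        model = mean_centered_svd(X, np.repeat([0, 1, 2], 2))
        np.testing.assert_allclose(model.singular_values, 0.0, atol=1e-12)
        np.testing.assert_allclose(model.explained, 0.0)

    @pytest.mark.parametrize("G,F", [(5, 16), (3, 2), (2, 30)])
    def test_svd_invariants_random(self, G, F):
        rng = np.random.default_rng(G * 100 + F)
        X = rng.standard_normal((G * 4, F))
        model = mean_centered_svd(X, np.repeat(np.arange(G), 4))
        L = model.n_latent
        assert L == min(G - 1, F)
        np.testing.assert_allclose(model.contrasts.T @ model.contrasts, np.eye(L), atol=1e-10)
        np.testing.assert_allclose(model.saliences.T @ model.saliences, np.eye(L), atol=1e-10)
        # energy conservation
        assert np.sum(model.singular_values**2) == pytest.approx(
            np.sum(model.centered**2), rel=1e-10
        )
        assert np.all(np.diff(model.singular_values) <= 1e-12)

    def test_sign_convention_largest_contrast_entry_positive(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((20, 6))
        model = mean_centered_svd(X, np.repeat(np.arange(5), 4))
        for k in range(model.n_latent):
            u = model.contrasts[:, k]
            assert u[np.argmax(np.abs(u))] > 0

    def test_empty_group_and_bad_shapes(self):
        with pytest.raises(ValidationError):
            mean_centered_svd(np.ones((4, 2)), np.array([0, 0, 0, 0]))
        with pytest.raises(ValidationError):
            mean_centered_svd(np.ones((4, 2)), np.array([0, 1]))


class TestPermutationTest:
    def test_planted_separation_attains_minimum_p(self):
        X, labels = _planted(delta=10.0)
        result = permutation_test(X, labels, 199, seed=1)
        assert result.p_values[0] == pytest.approx(1 / 200)
        assert result.null_singulars.shape == (199, 1)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5))
        result = permutation_test(X, np.repeat(np.arange(3), 10), 99, seed=2)
        assert np.all(result.p_values > 0) and np.all(result.p_values <= 1)
        assert np.all(result.p_values >= 1 / 100)

    def test_fixed_seed_reproducible(self):
        X, labels = _planted(delta=1.0)
        a = permutation_test(X, labels, 50, seed=7)
        b = permutation_test(X, labels, 50, seed=7)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.null_singulars, b.null_singulars)

    def test_null_rejection_rate_roughly_alpha(self):
        """Smoke-scale type-I check (the full calibration runs in the
        acceptance suite): 100 null runs, binomial 99.9% band around 0.05."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(100):
            X = rng.standard_normal((50, 6))
            p = permutation_test(X, np.repeat(np.arange(5), 10), 100, rng.integers(2**31)).p_values[0]
            rejections += p < 0.05
        assert 0 <= rejections <= 14


class TestBootstrapTest:
    def test_planted_channels_dominate_bootstrap_ratios(self):
        """Monte-Carlo oracle over 20 seeds: mean |BSR| on planted features
        exceeds the mean over noise features."""
        planted_means, noise_means = [], []
        for seed in range(20):
            X, labels = _planted(n_per_group=15, n_features=6, delta=2.0, seed=seed)
            bsr = bootstrap_test(X, labels, 100, seed=seed).bsr[:, 0]
            planted_means.append(abs(bsr[0]))
            noise_means.append(np.abs(bsr[1:]).mean())
        assert np.mean(planted_means) > np.mean(noise_means)

    def test_procrustes_alignment_removes_sign_flip(self):
        """A sign-flipped copy of the saliences rotates back exactly onto the
        original, so aligned replicates correlate non-negatively."""
        rng = np.random.default_rng(9)
        V = np.linalg.qr(rng.standard_normal((6, 3)))[0]
        R, _ = orthogonal_procrustes(-V, V)
        np.testing.assert_allclose(-V @ R, V, atol=1e-12)

    def test_fixed_seed_bitwise_identical(self):
        X, labels = _planted(delta=2.0)
        a = bootstrap_test(X, labels, 60, seed=5)
        b = bootstrap_test(X, labels, 60, seed=5)
        np.testing.assert_array_equal(a.bsr, b.bsr)

    def test_degenerate_feature_flagged_nan(self):
        X, labels = _planted(n_per_group=10, n_features=3, delta=3.0)
        X[:, 2] = 7.0  # constant feature: zero bootstrap SE
        result = bootstrap_test(X, labels, 50, seed=6)
        assert np.all(np.isnan(result.bsr[2]))
        assert np.all(result.se[2] == 0)
        assert np.all(np.isfinite(result.bsr[:2]))

    def test_group_of_one_rejected(self):
        X = np.random.default_rng(0).standard_normal((3, 2))
        with pytest.raises(ValidationError):
            bootstrap_test(X, np.array([0, 1, 1]), 10, seed=0)


class TestSignSymmetry:
    def test_negating_data_flips_saliences_only(self):
        X, labels = _planted(delta=3.0)
        m1 = mean_centered_svd(X, labels)
        m2 = mean_centered_svd(-X, labels)
        np.testing.assert_allclose(m1.singular_values, m2.singular_values, atol=1e-10)
        p1 = permutation_test(X, labels, 50, seed=3).p_values
        p2 = permutation_test(-X, labels, 50, seed=3).p_values
        np.testing.assert_array_equal(p1, p2)
        b1 = bootstrap_test(X, labels, 50, seed=4).bsr
        b2 = bootstrap_test(-X, labels, 50, seed=4).bsr
        np.testing.assert_allclose(np.abs(b1), np.abs(b2), atol=1e-8)


class TestAverageSiteScores:
    def test_pair_mean(self):
        sites, vals = average_site_scores(np.array([1.0, 3.0]), np.array([0, 0]))
        assert list(sites) == [0]
        assert vals[0] == 2.0

    def test_gradiometer_layout_204_to_102(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal(204)
        site_id = np.arange(204) // 2
        sites, site_vals = average_site_scores(values, site_id)
        assert len(site_vals) == 102
        np.testing.assert_allclose(site_vals, values.reshape(102, 2).mean(axis=1))

    def test_singleton_site_passthrough_and_order(self):
        sites, vals = average_site_scores(np.array([5.0, 1.0, 3.0]), np.array([7, 2, 2]))
        assert list(sites) == [2, 7]
        np.testing.assert_allclose(vals, [2.0, 5.0])
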