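"""Exact information-theoretic primitives on Gaussian/categorical densities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from bdc import (
    CategoricalDensity,
    GaussianDensity,
    evidence_label,
    kl_categorical,
    kl_gaussian,
    logdet_psd,
    negative_entropy,
    probability_from_difference,
    softmax_from_logevidence,
)
from bdc.gaussian import DegeneratePosteriorError

from conftest import random_spd

LOG_2PI_E = np.log(2 * np.pi * np.e)


class TestGaussianDensity:
    def test_rejects_asymmetric_covariance(self):
        with pytest.raises(ValueError, match="symmetric"):
            GaussianDensity([0, 0], [[1.0, 0.5], [0.2, 1.0]])

    def test_rejects_indefinite_covariance(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            GaussianDensity([0, 0], [[1.0, 2.0], [2.0, 1.0]])

    def test_rejects_shape_mismatch(self):
        with pytest.raises(ValueError, match="labels"):
            GaussianDensity([0, 0], np.eye(2), ["a"])

    def test_marginal_selects_by_label(self):
        d = GaussianDensity([1, 2, 3], np.diag([1.0, 2.0, 3.0]), ["a", "b", "c"])
        m = d.marginal(["c", "a"])
        assert m.labels == ("c", "a")
        np.testing.assert_allclose(m.mean, [3, 1])
        np.testing.assert_allclose(m.cov, np.diag([3.0, 1.0]))


class TestNegativeEntropy:
    @pytest.mark.parametrize(
        "cov, expected",
        [
            ([[1 / (2 * np.pi * np.e)]], 0.0),
            (np.eye(2), -LOG_2PI_E),
            (np.diag([0.5, 2.0]), -LOG_2PI_E),  # det = 1, same as identity
        ],
    )
    def test_closed_forms(self, cov, expected):
        d = GaussianDensity(np.zeros(np.shape(cov)[0]), cov)
        assert negative_entropy(d) == pytest.approx(expected, abs=1e-12)

    def test_matches_monte_carlo_entropy(self, rng):
        # -E[ln N(x)] estimated from samples of N(0, diag(0.5, 2))
        cov = np.diag([0.5, 2.0])
        d = GaussianDensity([0.0, 0.0], cov)
        x = rng.multivariate_normal([0, 0], cov, size=1_000_000)
        logpdf = -0.5 * (
            2 * np.log(2 * np.pi) + np.log(np.linalg.det(cov))
            + np.einsum("ni,ij,nj->n", x, np.linalg.inv(cov), x)
        )
        assert negative_entropy(d) == pytest.approx(np.mean(logpdf), abs=0.01)

    def test_invariant_to_subset_ordering(self, rng):
        cov = random_spd(rng, 4)
        d = GaussianDensity(np.zeros(4), cov, ["a", "b", "c", "d"])
        assert negative_entropy(d, ["a", "c"]) == pytest.approx(
            negative_entropy(d, ["c", "a"]), abs=1e-12
        )

    def test_covariance_scaling_shifts_by_half_d_log_c(self, rng):
        cov = random_spd(rng, 3)
        d = GaussianDensity(np.zeros(3), cov)
        for c in (1.5, 4.0):
            scaled = GaussianDensity(np.zeros(3), c * cov)
            assert negative_entropy(d) - negative_entropy(scaled) == pytest.approx(
                1.5 * np.log(c), abs=1e-9
            )

    def test_degenerate_posterior_names_labels(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        d = GaussianDensity([0, 0], cov, ["scene", "object"])
        with pytest.raises(DegeneratePosteriorError, match="scene.*object"):
            negative_entropy(d)


class TestKlGaussian:
    def test_identical_densities_give_zero(self, rng):
        cov = random_spd(rng, 3)
        d = GaussianDensity(rng.normal(size=3), cov)
        assert kl_gaussian(d, d) == pytest.approx(0.0, abs=1e-10)

    def test_unit_mean_shift_matches_quadrature(self):
        q = GaussianDensity([1.0], [[1.0]])
        p = GaussianDensity([0.0], [[1.0]])
        assert kl_gaussian(q, p) == pytest.approx(0.5, abs=1e-12)
        # independent check: numerically integrate q ln(q/p)
        integrand = lambda x: (
            np.exp(-0.5 * (x - 1) ** 2) / np.sqrt(2 * np.pi) * (0.5 * x**2 - 0.5 * (x - 1) ** 2)
        )
        val, _ = quad(integrand, -10, 12)
        assert kl_gaussian(q, p) == pytest.approx(val, abs=1e-8)

    def test_two_dim_mean_shift(self):
        q = GaussianDensity([2.0, 0.0], np.eye(2))
        p = GaussianDensity([0.0, 0.0], np.eye(2))
        assert kl_gaussian(q, p) == pytest.approx(2.0, abs=1e-12)

    def test_label_mismatch_rejected(self):
        q = GaussianDensity([0], [[1.0]], ["a"])
        p = GaussianDensity([0], [[1.0]], ["b"])
        with pytest.raises(ValueError, match="label"):
            kl_gaussian(q, p)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), d=st.integers(1, 5))
    def test_non_negative_for_random_spd_pairs(self, seed, d):
        r = np.random.default_rng(seed)
        q = GaussianDensity(r.normal(size=d), random_spd(r, d))
        p = GaussianDensity(r.normal(size=d), random_spd(r, d))
        assert kl_gaussian(q, p) >= 0.0


class TestKlCategorical:
    def test_uniform_carries_no_information(self):
        for k in (1, 3, 10):
            assert kl_categorical(CategoricalDensity(np.full(k, 1 / k))) == pytest.approx(0.0, abs=1e-12)

    def test_delta_reaches_log_k(self):
        post = CategoricalDensity([1.0] + [0.0] * 9)
        assert kl_categorical(post) == pytest.approx(np.log(10), abs=1e-12)

    def test_mass_split_between_two_models(self):
        post = CategoricalDensity([0.5, 0.5] + [0.0] * 8)
        assert kl_categorical(post) == pytest.approx(1.6094, abs=1e-4)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), k=st.integers(1, 12))
    def test_softmax_posterior_bounded_by_log_k(self, seed, k):
        F = np.random.default_rng(seed).normal(scale=5, size=k)
        val = kl_categorical(softmax_from_logevidence(F))
        assert 0.0 <= val <= np.log(k) + 1e-12


class TestSoftmax:
    def test_paper_pairwise_value(self):
        post = softmax_from_logevidence([1.64, 0.0])
        np.testing.assert_allclose(post.probabilities, [0.8375, 0.1625], atol=5e-5)
        post = softmax_from_logevidence([1.82, 0.0])
        np.testing.assert_allclose(post.probabilities, [0.8606, 0.1394], atol=5e-5)

    def test_shift_invariance_gives_uniform_for_constants(self):
        for c in (-100.0, 0.0, 42.0):
            post = softmax_from_logevidence([c] * 5)
            np.testing.assert_allclose(post.probabilities, np.full(5, 0.2), atol=1e-12)

    def test_shift_invariance_general(self, rng):
        F = rng.normal(size=6)
        a = softmax_from_logevidence(F).probabilities
        b = softmax_from_logevidence(F + 123.4).probabilities
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            softmax_from_logevidence([np.nan, 0.0])

    @pytest.mark.parametrize(
        "delta, pct, digits",
        [(1.64, 84, 0), (1.82, 86.06, 2), (1.31, 78.75, 2), (0.33, 58.18, 2), (1.34, 79, 0)],
    )
    def test_two_way_softmax_reproduces_printed_percentages(self, delta, pct, digits):
        assert round(probability_from_difference(delta), digits) == pct

    def test_zero_difference_is_even_odds(self):
        assert probability_from_difference(0.0) == pytest.approx(50.0, abs=1e-12)


class TestEvidenceLabel:
    @pytest.mark.parametrize(
        "delta, category",
        [
            (0.0, "inconclusive"),
            (1.0, "inconclusive"),
            (1.1, "positive"),  # boundary falls in the upper bin
            (1.64, "positive"),
            (3.0, "strong"),
            (3.5, "strong"),
            (5.0, "very_strong"),
            (12.0, "very_strong"),
        ],
    )
    def test_kass_raftery_bins(self, delta, category):
        assert evidence_label(delta).category == category

    def test_negative_difference_rejected(self):
        with pytest.raises(ValueError):
            evidence_label(-0.1)


class TestLogdetPsd:
    def test_identity_and_reciprocal_diagonal(self):
        assert logdet_psd(np.eye(7)) == pytest.approx(0.0, abs=1e-12)
        assert logdet_psd(np.diag([2.0, 0.5])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_eigenvalue_oracle(self, rng):
        a = random_spd(rng, 5)
        assert logdet_psd(a) == pytest.approx(np.sum(np.log(np.linalg.eigvalsh(a))), abs=1e-10)

    def test_indefinite_matrix_fails_loudly(self):
        with pytest.raises(np.linalg.LinAlgError):
            logdet_psd(np.diag([1.0, -1.0]))
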