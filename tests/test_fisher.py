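import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from popinfo import (
    InformationProfile,
    PseudoInverseWarning,
    differential_covariance,
    eigen_information,
    information_ratio_2d,
    linear_fisher,
    minimum_information_covariance,
    optimal_output,
    output_information,
    output_information_direct,
    shuffled_information,
    total_information,
)

from conftest import random_psd


def optimal_linear_estimator_variance(f_prime, sigma):
    """Oracle: variance of the minimum-variance unbiased linear readout.

    Solve min w^T Sigma w subject to w^T f' = 1 via the KKT system; the
    linear Fisher information is the reciprocal of that variance.
    """
    n = f_prime.shape[0]
    kkt = np.zeros((n + 1, n + 1))
    kkt[:n, :n] = 2 * sigma
    kkt[:n, n] = -f_prime
    kkt[n, :n] = f_prime
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    sol = np.linalg.solve(kkt, rhs)
    w = sol[:n]
    return float(w @ sigma @ w)


class TestLinearFisher:
    def test_unit_cases(self):
        assert linear_fisher(np.array([1.0, 0.0]), np.eye(2)) == pytest.approx(1.0)
        assert linear_fisher(np.array([3.0, 4.0]), 25 * np.eye(2)) == pytest.approx(1.0)

    def test_matches_estimator_variance_oracle(self, rng):
        fp = rng.standard_normal(50)
        sigma = random_psd(rng, 50)
        info = linear_fisher(fp, sigma)
        assert info == pytest.approx(1.0 / optimal_linear_estimator_variance(fp, sigma), rel=1e-8)

    def test_singular_support_uses_pseudo_inverse_with_warning(self, rng):
        fp = rng.standard_normal(10)
        sigma = differential_covariance(fp, 7.0)
        with pytest.warns(PseudoInverseWarning):
            assert linear_fisher(fp, sigma) == pytest.approx(7.0, rel=1e-8)

    def test_signal_outside_singular_support_rejected(self):
        sigma = np.diag([1.0, 0.0])
        with pytest.raises(ValueError, match="support"):
            linear_fisher(np.array([1.0, 1.0]), sigma)

    def test_non_psd_rejected(self):
        with pytest.raises(ValueError):
            linear_fisher(np.ones(2), np.diag([1.0, -1.0]))


class TestOutputInformation:
    def test_noiseless_identity_channel_loses_nothing(self, rng):
        fp = rng.standard_normal(8)
        sigma_xi = random_psd(rng, 8)
        # vanishing output noise: Sigma_y -> 0, so use a tiny iid floor
        i_y = output_information(fp, sigma_xi, np.eye(8), 1e-14 * np.eye(8))
        assert i_y == pytest.approx(linear_fisher(fp, sigma_xi), rel=1e-6)

    def test_diagonal_closed_form(self, rng):
        v = rng.uniform(0.5, 2.0, 10)
        s2 = 0.7
        fp = rng.standard_normal(10)
        i_y = output_information(fp, np.diag(v), np.eye(10), s2 * np.eye(10))
        assert i_y == pytest.approx(np.sum(fp**2 / (v + s2)), rel=1e-10)

    def test_zero_weights_transmit_nothing(self, rng):
        fp = rng.standard_normal(5)
        i_y = output_information_direct(
            fp, random_psd(rng, 5), np.zeros((7, 5)), np.eye(7)
        )
        assert i_y == 0.0

    def test_direct_form_with_zero_input_noise(self, rng):
        fp = rng.standard_normal(6)
        sigma_eta = random_psd(rng, 6)
        i_y = output_information_direct(fp, np.zeros((6, 6)), np.eye(6), sigma_eta)
        assert i_y == pytest.approx(linear_fisher(fp, sigma_eta), rel=1e-10)

    def test_woodbury_equivalence_on_random_instances(self, rng):
        # the two output-information forms are algebraically identical
        for _ in range(30):
            n_in = int(rng.integers(2, 20))
            n_out = int(rng.integers(n_in, 30))
            fp = rng.standard_normal(n_in)
            sigma_xi = random_psd(rng, n_in)
            w = rng.standard_normal((n_out, n_in))
            sigma_eta = random_psd(rng, n_out)
            a = output_information(fp, sigma_xi, w, sigma_eta)
            b = output_information_direct(fp, sigma_xi, w, sigma_eta)
            assert a == pytest.approx(b, rel=1e-8)

    def test_data_processing_inequality_identity_weights(self, rng):
        for _ in range(20):
            fp = rng.standard_normal(12)
            sigma_xi = random_psd(rng, 12)
            sigma_eta = random_psd(rng, 12)
            i_x = linear_fisher(fp, sigma_xi)
            i_y = output_information(fp, sigma_xi, np.eye(12), sigma_eta)
            assert i_y <= i_x * (1 + 1e-12)

    def test_underdetermined_channel_requires_direct_form(self, rng):
        fp = rng.standard_normal(10)
        w = rng.standard_normal((4, 10))  # fewer output cells than input
        with pytest.raises(ValueError, match="direct"):
            output_information(fp, random_psd(rng, 10), w, np.eye(4))
        assert output_information_direct(fp, random_psd(rng, 10), w, np.eye(4)) > 0


class TestShuffledInformation:
    def test_diagonal_covariance_unchanged(self, rng):
        fp = rng.standard_normal(6)
        d = rng.uniform(0.5, 2.0, 6)
        assert shuffled_information(fp, np.diag(d)) == pytest.approx(
            linear_fisher(fp, np.diag(d))
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            shuffled_information(np.ones(2), np.diag([1.0, 0.0]))


class TestOptimalOutput:
    @pytest.mark.parametrize(
        "i_x,i_eta,expected",
        [(10.0, 10.0, 5.0), (100.0, 1.0, 100.0 / 101.0), (3.0, 1e12, 3.0)],
    )
    def test_closed_forms(self, i_x, i_eta, expected):
        assert optimal_output(i_x, i_eta) == pytest.approx(expected, rel=1e-6)

    def test_bounded_by_both_informations(self):
        assert optimal_output(7.0, 3.0) <= min(7.0, 3.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            optimal_output(-1.0, 1.0)


class TestEigenInformation:
    def test_aligned_with_leading_eigenvector(self):
        v = np.eye(3)
        fp = np.array([2.0, 0.0, 0.0])
        lam = np.array([4.0, 1.0, 1.0])
        assert eigen_information(fp, lam, v) == pytest.approx(4.0 / 4.0)

    def test_isotropic_spectrum(self, rng):
        fp = rng.standard_normal(7)
        assert eigen_information(fp, 2.5 * np.ones(7), np.eye(7)) == pytest.approx(
            fp @ fp / 2.5
        )

    def test_reconstruction_matches_linear_fisher(self, rng):
        sigma = random_psd(rng, 12)
        lam, v = np.linalg.eigh(sigma)
        fp = rng.standard_normal(12)
        assert eigen_information(fp, lam, v) == pytest.approx(
            linear_fisher(fp, sigma), rel=1e-10
        )

    def test_non_orthonormal_basis_rejected(self, rng):
        v = rng.standard_normal((5, 5))
        with pytest.raises(ValueError, match="orthonormal"):
            eigen_information(np.ones(5), np.ones(5), v)


class TestInformationRatio2d:
    def test_aligned_closed_form(self):
        assert information_ratio_2d(2.0, 1.0, 0.0, 1.0) == pytest.approx(4.0 / 5.0)

    def test_no_added_noise_keeps_everything(self, rng):
        for theta in rng.uniform(0, math.pi, 5):
            assert information_ratio_2d(3.0, 1.0, theta, 0.0) == pytest.approx(1.0)

    def test_orthogonal_closed_form(self):
        assert information_ratio_2d(10.0, 1.0, math.pi / 2, 1.0) == pytest.approx(0.5)

    def test_ordering_convention_enforced(self):
        with pytest.raises(ValueError):
            information_ratio_2d(1.0, 2.0, 0.0, 1.0)

    def test_agrees_with_full_matrix_computation(self, rng):
        for _ in range(20):
            s1, s2 = np.sort(rng.uniform(0.5, 3.0, 2))[::-1]
            theta = rng.uniform(0, math.pi)
            s2add = rng.uniform(0, 2.0)
            # principal axes on the coordinate axes, signal at angle theta
            fp = np.array([math.cos(theta), math.sin(theta)])
            sigma = np.diag([s1**2, s2**2])
            i_x = linear_fisher(fp, sigma)
            i_y = linear_fisher(fp, sigma + s2add * np.eye(2))
            assert i_y / i_x == pytest.approx(
                information_ratio_2d(s1, s2, theta, s2add), rel=1e-10
            )


class TestMinimumInformation:
    def test_two_dimensional_example(self):
        sigma, i_min = minimum_information_covariance(np.array([1.0, 0.0]), 1.0)
        assert np.array_equal(sigma, np.array([[1.0, 0.0], [0.0, 0.0]]))
        assert i_min == 1.0

    def test_information_scales_inversely_with_budget(self, rng):
        fp = rng.standard_normal(9)
        _, i1 = minimum_information_covariance(fp, 2.0)
        _, i2 = minimum_information_covariance(fp, 4.0)
        assert i2 == pytest.approx(i1 / 2)

    def test_differential_ratio_identity_weights_iid_noise(self, rng):
        # I_x/I_eta = sigma_eta^2 / (N <sigma_x^2>) for differential input noise
        n = 40
        fp = rng.standard_normal(n)
        i_x = 11.0
        sigma_xi = differential_covariance(fp, i_x)
        s_eta2 = 0.9
        i_eta = linear_fisher(fp, s_eta2 * np.eye(n))
        mean_var = np.trace(sigma_xi) / n
        assert i_x / i_eta == pytest.approx(s_eta2 / (n * mean_var), rel=1e-8)


class TestTotalInformation:
    def test_constant_information_no_jitter(self):
        assert total_information(0.0, np.full(5, 8.0), np.full(5, 0.2)) == pytest.approx(8.0)

    def test_constant_information_with_jitter(self):
        v, i = 0.01, 50.0
        got = total_information(v, np.full(4, i), np.full(4, 0.25))
        assert got == pytest.approx(1.0 / (v + 1.0 / i))

    def test_matches_adaptive_quadrature(self):
        # Gaussian stimulus jitter around s0, smoothly varying information
        s0, sd, v = 3.0, 0.05, 2e-4
        info = lambda s: 40.0 + 10.0 * s
        grid = np.linspace(s0 - 6 * sd, s0 + 6 * sd, 4001)
        w = norm.pdf(grid, s0, sd)
        w /= w.sum()
        got = total_information(v, info(grid), w)
        integral, _ = quad(lambda s: norm.pdf(s, s0, sd) / info(s), s0 - 8 * sd, s0 + 8 * sd)
        assert got == pytest.approx(1.0 / (v + integral), rel=1e-6)

    def test_zero_information_at_weighted_stimulus_rejected(self):
        with pytest.raises(ValueError):
            total_information(0.0, np.array([1.0, 0.0]), np.array([0.5, 0.5]))


def test_information_profile_csv_round_trip(tmp_path):
    import pandas as pd

    grid = np.linspace(0, 2 * math.pi, 10, endpoint=False)
    prof = InformationProfile(stimuli=grid, i_x=np.arange(10.0) + 1, i_y=np.arange(10.0))
    assert prof.mean("i_x") == pytest.approx(5.5)
    path = tmp_path / "profile.csv"
    prof.to_csv(path)
    back = pd.read_csv(path)
    assert list(back.columns) == ["stimulus", "I_x", "I_y"]
    assert np.allclose(back["I_x"], prof.i_x)
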