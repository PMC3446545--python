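"""Sigma points, unscented transform, and the UKF predict/update cycle."""

import numpy as np
import pytest

from hemodual.ukf import (
    ConditioningError,
    Dimensions,
    GaussianBelief,
    NoiseSpec,
    UTConfig,
    augment_dimensions,
    generate_sigma_points,
    ukf_predict,
    ukf_update,
    unscented_transform,
)

from _kalman import kalman_filter, random_stable_system, simulate_linear

CFG = UTConfig()


def random_spd(rng, dim):
    A = rng.normal(size=(dim, dim))
    return A @ A.T + dim * np.eye(dim) * 0.1


class TestSigmaPoints:
    def test_one_dimensional_closed_form(self):
        mu, var = 2.0, 4.0
        sp = generate_sigma_points(GaussianBelief([mu], [[var]]), CFG)
        lam = CFG.scaling(1)
        spread = np.sqrt((1 + lam) * var)
        np.testing.assert_allclose(
            sorted(sp.points.ravel()), sorted([mu, mu + spread, mu - spread])
        )
        assert sp.mean_weights.sum() == pytest.approx(1.0, abs=1e-14)

    @pytest.mark.parametrize("dim", [1, 2, 4, 5, 9, 11, 19])
    def test_moment_capture(self, dim, rng):
        """Weighted sigma-point moments reproduce the source belief."""
        mean = rng.normal(size=dim)
        cov = random_spd(rng, dim)
        sp = generate_sigma_points(GaussianBelief(mean, cov), CFG)
        assert sp.points.shape == (2 * dim + 1, dim)
        assert sp.mean_weights.sum() == pytest.approx(1.0, abs=1e-14)
        np.testing.assert_allclose(sp.mean_weights @ sp.points, mean, atol=1e-12)
        d = sp.points - mean
        cov_hat = (sp.cov_weights[:, None] * d).T @ d
        np.testing.assert_allclose(cov_hat, cov, rtol=1e-10, atol=1e-12)

    def test_identity_covariance_2d(self):
        sp = generate_sigma_points(GaussianBelief(np.zeros(2), np.eye(2)), CFG)
        d = sp.points
        cov_hat = (sp.cov_weights[:, None] * d).T @ d
        np.testing.assert_allclose(cov_hat, np.eye(2), atol=1e-12)

    def test_conditioning_error_on_indefinite_covariance(self):
        bad = GaussianBelief(np.zeros(2), np.array([[1.0, 0.0], [0.0, -1.0]]))
        with pytest.raises(ConditioningError), pytest.warns(UserWarning):
            generate_sigma_points(bad, CFG)


class TestUnscentedTransform:
    def test_identity_map(self, rng):
        belief = GaussianBelief(rng.normal(size=3), random_spd(rng, 3))
        sp = generate_sigma_points(belief, CFG)
        out, _ = unscented_transform(sp, lambda x: x)
        np.testing.assert_allclose(out.mean, belief.mean, atol=1e-12)
        np.testing.assert_allclose(out.cov, belief.cov, rtol=1e-10, atol=1e-12)

    def test_affine_map_closed_form(self, rng):
        belief = GaussianBelief(rng.normal(size=3), random_spd(rng, 3))
        A = rng.normal(size=(2, 3))
        b = rng.normal(size=2)
        sp = generate_sigma_points(belief, CFG)
        out, _ = unscented_transform(sp, lambda x: x @ A.T + b)
        np.testing.assert_allclose(out.mean, A @ belief.mean + b, rtol=1e-12)
        np.testing.assert_allclose(out.cov, A @ belief.cov @ A.T, rtol=1e-10, atol=1e-12)

    def test_quadratic_map_standard_normal(self):
        """E[x^2] = 1 for x ~ N(0,1); the UT is exact for quadratics."""
        sp = generate_sigma_points(GaussianBelief([0.0], [[1.0]]), CFG)
        out, _ = unscented_transform(sp, lambda x: x**2)
        assert out.mean[0] == pytest.approx(1.0, abs=1e-12)


class TestPredictUpdate:
    def test_identity_transition_zero_noise(self, rng):
        belief = GaussianBelief(rng.normal(size=3), random_spd(rng, 3))
        out = ukf_predict(belief, lambda x: x, np.zeros((3, 3)), CFG)
        np.testing.assert_allclose(out.mean, belief.mean, atol=1e-12)
        np.testing.assert_allclose(out.cov, belief.cov, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("augmented", [False, True])
    def test_linear_prediction_matches_kalman(self, augmented, rng):
        dim = 3
        belief = GaussianBelief(rng.normal(size=dim), random_spd(rng, dim))
        A = rng.normal(size=(dim, dim)) * 0.5
        Q = random_spd(rng, dim) * 0.1
        out = ukf_predict(belief, lambda x: x @ A.T, Q, CFG, augmented=augmented)
        np.testing.assert_allclose(out.mean, A @ belief.mean, atol=1e-10)
        np.testing.assert_allclose(
            out.cov, A @ belief.cov @ A.T + Q, rtol=1e-10, atol=1e-12
        )

    def test_zero_innovation_keeps_mean(self, rng):
        prior = GaussianBelief(rng.normal(size=2), random_spd(rng, 2))
        H = np.array([[1.0, 0.5]])
        y = H @ prior.mean
        post, rec = ukf_update(prior, lambda x: x @ H.T, y, [[0.1]], CFG)
        np.testing.assert_allclose(post.mean, prior.mean, atol=1e-12)
        np.testing.assert_allclose(rec.innovation, 0.0, atol=1e-12)

    def test_scalar_conjugate_gaussian_update(self):
        # prior N(1, 4), observation y = x + n, n ~ N(0, 1), y = 3
        post, _ = ukf_update(
            GaussianBelief([1.0], [[4.0]]), lambda x: x, [3.0], [[1.0]], CFG
        )
        assert post.mean[0] == pytest.approx(1.0 + 4.0 / 5.0 * 2.0, abs=1e-12)
        assert post.cov[0, 0] == pytest.approx(4.0 - 16.0 / 5.0, abs=1e-12)

    def test_infinite_noise_carries_no_information(self, rng):
        prior = GaussianBelief(rng.normal(size=2), np.eye(2))
        post, _ = ukf_update(prior, lambda x: x[:, :1], [5.0], [[1e12]], CFG)
        np.testing.assert_allclose(post.mean, prior.mean, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(post.cov, prior.cov, rtol=1e-6)

    def test_singular_innovation_raises(self):
        # constant observation map with R = 0 gives a singular innovation
        prior = GaussianBelief(np.zeros(2), np.eye(2))
        with pytest.raises(ConditioningError):
            ukf_update(prior, lambda x: 0.0 * x[:, :1], [0.0], [[0.0]], CFG)


@pytest.mark.parametrize("augmented", [False, True])
def test_full_ukf_matches_textbook_kalman(augmented):
    """Master oracle: UKF trajectory equals an independent linear KF."""
    rng = np.random.default_rng(7)
    for trial in range(3):
        dim = int(rng.integers(2, 5))
        A, b, H, c, Q, R = random_stable_system(rng, dim)
        ys = simulate_linear(rng, A, b, H, c, Q, R, 100, np.zeros(dim))
        km, kP = kalman_filter(np.zeros(dim), np.eye(dim), A, b, Q, H, c, R, ys)

        belief = GaussianBelief(np.zeros(dim), np.eye(dim))
        for y, m_ref, P_ref in zip(ys, km, kP):
            belief = ukf_predict(
                belief, lambda x: x @ A.T + b, Q, CFG, augmented=augmented
            )
            belief, _ = ukf_update(
                belief, lambda x: x @ H.T + c, y, R, CFG, augmented=augmented
            )
            np.testing.assert_allclose(belief.mean, m_ref, rtol=1e-8, atol=1e-10)
            np.testing.assert_allclose(belief.cov, P_ref, rtol=1e-8, atol=1e-12)


def test_augmented_equals_plain_for_additive_noise(rng):
    """A full filtering pass in the two modes agrees for additive noise."""
    dim = 3
    A, b, H, c, Q, R = random_stable_system(rng, dim)
    ys = simulate_linear(rng, A, b, H, c, Q, R, 50, np.zeros(dim))

    def run(augmented):
        belief = GaussianBelief(np.zeros(dim), np.eye(dim))
        out = []
        for y in ys:
            belief = ukf_predict(
                belief, lambda x: np.tanh(x @ A.T) + b, Q, CFG, augmented=augmented
            )
            belief, _ = ukf_update(
                belief, lambda x: x @ H.T + c, y, R, CFG, augmented=augmented
            )
            out.append((belief.mean.copy(), belief.cov.copy()))
        return out

    for (m0, P0), (m1, P1) in zip(run(False), run(True)):
        np.testing.assert_allclose(m0, m1, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(P0, P1, rtol=1e-10, atol=1e-12)


class TestDimensions:
    def test_state_filter_augmentation(self):
        dims = augment_dimensions(Dimensions(L_x=4, L_v=4, L_n=1))
        assert dims.L_aug == 9

    def test_parameter_filter_augmentation(self):
        dims = augment_dimensions(Dimensions(L_x=5, L_v=5, L_n=1, L_w=5))
        assert dims.L_aug == 11

    def test_joint_filter_augmentation(self):
        dims = augment_dimensions(Dimensions(L_x=9, L_v=9, L_n=1, L_w=5))
        assert dims.L_aug == 19


def test_noise_spec_rejects_asymmetric():
    with pytest.raises(ValueError):
        NoiseSpec(Q=np.array([[1.0, 0.5], [0.0, 1.0]]), R=[[1.0]], R_r=np.eye(5))
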