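"""GP surrogate: kernel algebra, marginal likelihood, predictions vs dense oracles."""

import numpy as np
import pytest

from ssdopt import GaussianProcess, GPHyperparams, fit_gp
from ssdopt.gp import log_marginal_likelihood, se_kernel, se_kernel_matrix


def dense_lml(X, y, noise, hp):
    """Independent oracle: explicit inverse and determinant."""
    K = se_kernel_matrix(X, X, hp) + np.diag(noise)
    n = len(y)
    return float(
        -0.5 * y @ np.linalg.inv(K) @ y
        - 0.5 * np.log(np.linalg.det(K))
        - 0.5 * n * np.log(2 * np.pi)
    )


class TestKernel:
    def test_zero_distance_returns_signal_variance(self):
        hp = GPHyperparams(2.5, np.array([0.3, 0.7]))
        assert se_kernel([0.1, 0.2], [0.1, 0.2], hp) == pytest.approx(2.5)

    def test_unit_case_direct_substitution(self):
        hp = GPHyperparams(1.0, np.array([1.0]))
        assert se_kernel([0.0], [1.0], hp) == pytest.approx(np.exp(-1.0))

    def test_symmetry_on_random_pairs(self, rng):
        hp = GPHyperparams(1.3, np.array([0.4, 0.9, 2.0]))
        for _ in range(100):
            a, b = rng.random(3), rng.random(3)
            assert se_kernel(a, b, hp) == pytest.approx(se_kernel(b, a, hp), abs=1e-14)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            se_kernel([0.0], [0.0, 1.0], GPHyperparams(1.0, np.array([1.0])))

    @pytest.mark.parametrize("bad", [0.0, -1.0, np.inf])
    def test_hyperparams_must_be_positive_finite(self, bad):
        with pytest.raises(ValueError):
            GPHyperparams(bad, np.array([1.0]))


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        hp = GPHyperparams(0.7, np.array([1.0]))
        omega2 = 0.04
        got = log_marginal_likelihood(np.array([[0.5]]), np.array([0.0]), [omega2], hp)
        assert got == pytest.approx(-0.5 * np.log(0.7 + omega2) - 0.5 * np.log(2 * np.pi))

    def test_matches_dense_oracle_on_random_points(self, rng):
        X = rng.random((3, 2))
        y = rng.standard_normal(3)
        noise = rng.uniform(0.01, 0.1, 3)
        hp = GPHyperparams(0.8, np.array([0.5, 1.5]))
        assert log_marginal_likelihood(X, y, noise, hp) == pytest.approx(
            dense_lml(X, y, noise, hp), abs=1e-8
        )

    def test_duplicated_point_does_not_blow_up(self, rng):
        X = np.array([[0.2], [0.2], [0.8]])
        y = np.array([0.1, 0.1, -0.2])
        hp = GPHyperparams(1.0, np.array([0.5]))
        val = log_marginal_likelihood(X, y, [0.01, 0.01, 0.01], hp)
        assert np.isfinite(val)
        val0 = log_marginal_likelihood(X, y, [1e-12, 1e-12, 1e-12], hp)
        assert np.isfinite(val0)


class TestPredict:
    def test_two_point_dense_matrix_oracle(self, rng):
        X = np.array([[0.2], [0.7]])
        y = np.array([0.3, -0.1])
        noise = np.array([0.02, 0.05])
        gp = GaussianProcess(bounds=(np.zeros(1), np.ones(1)), n_restarts=2).fit(
            X, y, noise_var=noise
        )
        hp = gp.hyperparams_
        xs = np.array([0.4])
        K = se_kernel_matrix(X, X, hp) + np.diag(noise)
        kstar = se_kernel_matrix(xs[None, :], X, hp)[0]
        yc = y - y.mean()
        m_oracle = kstar @ np.linalg.solve(K, yc) + y.mean()
        v_oracle = hp.signal_variance - kstar @ np.linalg.solve(K, kstar)
        m, s = gp.predict(xs[None, :], return_std=True)
        assert m[0] == pytest.approx(m_oracle, abs=1e-10)
        assert s[0] ** 2 == pytest.approx(v_oracle, abs=1e-10)

    def test_noiseless_interpolation(self, rng):
        X = rng.random((8, 1))
        y = np.sin(4 * X[:, 0])
        gp = GaussianProcess(bounds=(np.zeros(1), np.ones(1))).fit(
            X, y, noise_var=np.zeros(8)
        )
        m, s = gp.predict(X, return_std=True)
        np.testing.assert_allclose(m, y, atol=1e-4)
        assert np.all(s**2 < 1e-4)

    def test_prior_reversion_far_from_data(self, rng):
        X = rng.random((6, 2))
        y = rng.standard_normal(6)
        gp = GaussianProcess(bounds=(np.zeros(2), np.ones(2))).fit(
            X, y, noise_var=np.full(6, 0.01)
        )
        m, s = gp.predict(np.array([[60.0, 60.0]]), return_std=True)
        assert m[0] == pytest.approx(gp.y_offset_, abs=1e-8)
        assert s[0] ** 2 == pytest.approx(gp.hyperparams_.signal_variance, rel=1e-6)

    def test_observation_never_increases_variance_at_its_location(self, rng):
        X = rng.random((10, 1))
        y = np.cos(3 * X[:, 0])
        noise = np.full(10, 0.01)
        x_new = np.array([[0.55]])
        gp_small = GaussianProcess(bounds=(np.zeros(1), np.ones(1)), n_restarts=3).fit(
            X, y, noise_var=noise
        )
        hp = gp_small.hyperparams_
        _, s_before = gp_small.predict(x_new, return_std=True)
        # refit with the same hyperparameters frozen via narrow bounds is
        # fragile; instead compare posterior algebra directly at fixed hp.
        from ssdopt.gp import se_kernel_matrix as K_

        def var_at(Xtr, ns):
            K = K_(Xtr, Xtr, hp) + np.diag(ns)
            ks = K_(x_new, Xtr, hp)[0]
            return hp.signal_variance - ks @ np.linalg.solve(K, ks)

        Xs = gp_small._scale(X)
        xn = gp_small._scale(x_new)
        v1 = var_at(Xs, noise)
        v2 = var_at(np.vstack([Xs, xn]), np.append(noise, 0.01))
        assert v2 <= v1 + 1e-12
        assert s_before[0] ** 2 == pytest.approx(v1, abs=1e-10)


class TestFit:
    def test_constant_targets_predict_the_constant(self):
        X = np.linspace(0, 1, 6)[:, None]
        y = np.full(6, 0.42)
        gp = fit_gp(X, y, np.full(6, 1e-4), bounds=(np.zeros(1), np.ones(1)))
        m = gp.predict(np.array([[0.33], [0.91]]))
        np.testing.assert_allclose(m, 0.42, atol=1e-6)

    def test_permutation_invariance(self, rng):
        X = rng.random((12, 2))
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        noise = rng.uniform(0.001, 0.01, 12)
        perm = rng.permutation(12)
        gp1 = fit_gp(X, y, noise, bounds=(np.zeros(2), np.ones(2)), random_state=1)
        gp2 = fit_gp(
            X[perm], y[perm], noise[perm], bounds=(np.zeros(2), np.ones(2)), random_state=1
        )
        q = rng.random((5, 2))
        # refits agree to optimiser tolerance; with hyperparameters frozen
        # the posterior algebra is permutation-invariant to solver precision
        np.testing.assert_allclose(gp1.predict(q), gp2.predict(q), atol=1e-6)
        gp3 = GaussianProcess(bounds=(np.zeros(2), np.ones(2)))
        gp3.scale_lower_, gp3.scale_width_ = gp1.scale_lower_, gp1.scale_width_
        gp3.hyperparams_, gp3.y_offset_ = gp1.hyperparams_, float(y[perm].mean())
        from scipy import linalg

        K = se_kernel_matrix(X[perm], X[perm], gp1.hyperparams_) + np.diag(noise[perm])
        gp3._chol_ = linalg.cho_factor(K, lower=True)
        gp3._alpha_ = linalg.cho_solve(gp3._chol_, y[perm] - y.mean())
        gp3.X_train_ = X[perm]
        np.testing.assert_allclose(gp1.predict(q), gp3.predict(q), atol=1e-8)

    def test_lengthscale_recovery_within_factor_two(self):
        rng = np.random.default_rng(5)
        true_hp = GPHyperparams(1.0, np.array([0.3]))
        X = rng.random((40, 1))
        K = se_kernel_matrix(X, X, true_hp) + 1e-8 * np.eye(40)
        y = np.linalg.cholesky(K) @ rng.standard_normal(40)
        gp = fit_gp(X, y, np.full(40, 1e-6), bounds=(np.zeros(1), np.ones(1)))
        lam = gp.hyperparams_.length_scales[0]
        assert 0.15 <= lam <= 0.6

    def test_achieved_lml_beats_every_start(self, rng):
        X = rng.random((15, 1))
        y = np.sin(5 * X[:, 0]) + 0.05 * rng.standard_normal(15)
        gp = GaussianProcess(bounds=(np.zeros(1), np.ones(1)), n_restarts=6).fit(
            X, y, noise_var=np.full(15, 0.01)
        )
        # the model's LML at the chosen point must beat a fresh random probe
        probe = GPHyperparams(0.5, np.array([0.05]))
        assert gp.log_marginal_likelihood_value_ >= log_marginal_likelihood(
            gp.X_train_, y - gp.y_offset_, gp.noise_var_, probe
        ) - 1e-9

    def test_affine_input_scaling_is_internal(self, rng):
        X = rng.random((10, 2))
        y = X[:, 0] * 2 + np.sin(X[:, 1])
        noise = np.full(10, 0.01)
        gp_raw = fit_gp(X, y, noise, bounds=(np.zeros(2), np.ones(2)), random_state=2)
        X_big = X * np.array([1000.0, 0.01]) + np.array([5.0, -3.0])
        gp_big = fit_gp(
            X_big,
            y,
            noise,
            bounds=(np.array([5.0, -3.0]), np.array([1005.0, -2.99])),
            random_state=2,
        )
        q = rng.random((4, 2))
        q_big = q * np.array([1000.0, 0.01]) + np.array([5.0, -3.0])
        np.testing.assert_allclose(gp_raw.predict(q), gp_big.predict(q_big), atol=1e-6)

    def test_requires_two_points_and_finite_targets(self):
        with pytest.raises(ValueError):
            fit_gp(np.array([[0.5]]), np.array([1.0]), [0.1])
        with pytest.raises(ValueError):
            fit_gp(np.array([[0.1], [0.2]]), np.array([np.nan, 1.0]), [0.1, 0.1])


class TestAgainstSklearn:
    """Independent route: sklearn's GP with a matched kernel, fixed hyperparams."""

    def test_predictions_match_sklearn_gpr(self, rng):
        from sklearn.gaussian_process import GaussianProcessRegressor
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        X = rng.random((9, 1))
        y = np.sin(6 * X[:, 0])
        yc = y - y.mean()
        noise = rng.uniform(0.001, 0.01, 9)
        sigma, lam = 0.6, 0.25
        hp = GPHyperparams(sigma, np.array([lam]))
        # sklearn RBF uses exp(-d^2 / (2 l^2)); ours exp(-d^2 / lambda^2)
        sk = GaussianProcessRegressor(
            kernel=ConstantKernel(sigma, "fixed") * RBF(lam / np.sqrt(2), "fixed"),
            alpha=noise,
            optimizer=None,
        ).fit(X, yc)
        m_sk, s_sk = sk.predict(np.array([[0.42]]), return_std=True)

        gp = GaussianProcess(bounds=(np.zeros(1), np.ones(1)))
        gp.scale_lower_, gp.scale_width_ = np.zeros(1), np.ones(1)
        gp.hyperparams_, gp.y_offset_ = hp, float(y.mean())
        gp.X_train_, gp.y_train_, gp.noise_var_ = X, y, noise
        from scipy import linalg

        K = se_kernel_matrix(X, X, hp) + np.diag(noise)
        gp._chol_ = linalg.cho_factor(K, lower=True)
        gp._alpha_ = linalg.cho_solve(gp._chol_, yc)
        m, s = gp.predict(np.array([[0.42]]), return_std=True)
        assert m[0] - gp.y_offset_ == pytest.approx(m_sk[0], abs=1e-8)
        assert s[0] == pytest.approx(s_sk[0], abs=1e-6)

        sk_lml = sk.log_marginal_likelihood()
        ours = log_marginal_likelihood(X, yc, noise, hp)
        assert ours == pytest.approx(sk_lml, abs=1e-8)


def test_gp_beats_constant_predictor_on_power_surface():
    """On the analytic cluster-power surface the GP should cut RMSE >= 5x."""
    from scipy.stats import qmc

    from ssdopt.problems import ClusterTrialParams, cluster_power_analytic

    params = ClusterTrialParams()
    lo, hi = np.array([10.0, 100.0]), np.array([100.0, 500.0])
    X = lo + qmc.Sobol(2, scramble=True, seed=0).random_base2(6)[:50] * (hi - lo)
    y = cluster_power_analytic(X, params)
    gp = fit_gp(X, y, np.zeros(50), bounds=(lo, hi))
    rng = np.random.default_rng(1)
    grid = lo + rng.random((300, 2)) * (hi - lo)
    truth = cluster_power_analytic(grid, params)
    rmse_gp = np.sqrt(np.mean((gp.predict(grid) - truth) ** 2))
    rmse_const = np.sqrt(np.mean((y.mean() - truth) ** 2))
    assert rmse_gp * 5 <= rmse_const
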