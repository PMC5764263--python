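import numpy as np
import pytest
from scipy.stats import multivariate_normal

from eegdcm import bms, dcm_core
from eegdcm import synthetic_data as sd
from eegdcm.errors import ShapeError
from eegdcm.pipeline import trial_inputs


@pytest.fixture(scope="module")
def space():
    return bms.build_model_space()


@pytest.fixture(scope="module")
def inputs():
    return trial_inputs(64.0, 4.0)


DT = 1.0 / 64.0


class TestSpec:
    def test_param_count(self, space):
        spec = space.model(1)
        # 10 free A + (6 core + 1 return) B + 1 C + 4 gains
        assert spec.n_params == 10 + 7 + 1 + 4

    def test_pack_unpack_roundtrip(self, space, rng):
        spec = space.model(5)
        theta = rng.standard_normal(spec.n_params)
        A, B, C, g = spec.unpack(theta)
        np.testing.assert_allclose(spec.pack(A, B, C, g), theta)
        assert np.all(np.diag(A) == -1.0)

    def test_json_roundtrip(self, space):
        spec = space.model(12)
        back = dcm_core.DCMSpec.from_json(spec.to_json())
        np.testing.assert_array_equal(back.a_mask, spec.a_mask)
        np.testing.assert_array_equal(back.b_mask, spec.b_mask)
        np.testing.assert_array_equal(back.c_mask, spec.c_mask)
        assert back.b_prior_sd == spec.b_prior_sd

    def test_forbidden_masks_rejected(self):
        a = np.ones((4, 4), bool)
        np.fill_diagonal(a, False)
        c = np.array([1, 0, 0, 0], bool)
        with pytest.raises(ShapeError):
            dcm_core.DCMSpec(a_mask=a, b_mask=np.zeros((4, 4)), c_mask=c)

    def test_c_mask_must_be_single_input(self, space):
        a = space.model(1).a_mask
        b = space.model(1).b_mask
        with pytest.raises(ShapeError):
            dcm_core.DCMSpec(a_mask=a, b_mask=b, c_mask=np.array([0, 0, 1, 0], bool))


class TestIntegrate:
    def test_zero_params_zero_output(self, space, inputs):
        spec = space.model(1)
        theta = np.zeros(spec.n_params)  # C=0, gains=0
        y = dcm_core.integrate(spec, theta, inputs, DT)
        np.testing.assert_array_equal(y, 0.0)

    def test_matches_shared_integrator(self, space, inputs, rng):
        spec = space.model(3)
        theta = spec.prior_mean() + 0.1 * rng.standard_normal(spec.n_params)
        theta[-4:] = 1.0
        A, B, C, _ = spec.unpack(theta)
        net = sd.GroundTruthNetwork(
            A=A, B={"task": B}, C=C, input_region="PMC"
        )
        x = sd.simulate_network_dynamics(
            net, inputs["drive"], {"task": inputs["mod"]}, DT
        )
        y = dcm_core.integrate(spec, theta, inputs, DT)
        np.testing.assert_array_equal(y, x)  # bit-for-bit shared contract

    def test_euler_first_order(self, space, inputs, rng):
        spec = space.model(2)
        theta = spec.prior_mean() + 0.05 * rng.standard_normal(spec.n_params)
        exact = dcm_core.integrate(spec, theta, inputs, DT)
        e1 = dcm_core.integrate(spec, theta, inputs, DT, method="euler")
        fine = {
            "drive": np.repeat(inputs["drive"], 2),
            "mod": np.repeat(inputs["mod"], 2),
        }
        e2 = dcm_core.integrate(spec, theta, fine, DT / 2, method="euler")[:, ::2]
        err1 = np.abs(e1 - exact).max()
        err2 = np.abs(e2 - exact).max()
        assert err2 < 0.75 * err1

    def test_batch_matches_single(self, space, inputs, rng):
        spec = space.model(7)
        thetas = spec.prior_mean()[None] + 0.1 * rng.standard_normal((5, spec.n_params))
        batch = dcm_core._integrate_batch(spec, thetas, inputs, DT)
        for p in range(5):
            np.testing.assert_allclose(
                batch[p], dcm_core.integrate(spec, thetas[p], inputs, DT), atol=1e-12
            )


class TestFreeEnergy:
    def test_linear_gaussian_matches_closed_form(self, rng):
        N, K = 50, 4
        X = rng.standard_normal((N, K))
        v0 = np.full(K, 0.3)
        mu0 = rng.standard_normal(K)
        sigma2 = 0.5
        y = X @ rng.standard_normal(K) + rng.normal(0, np.sqrt(sigma2), N)
        res = dcm_core.variational_laplace(
            lambda th: X @ th, y, mu0, v0,
            noise_precision=1 / sigma2, tol=1e-12, max_iter=200,
        )
        exact = multivariate_normal.logpdf(
            y, mean=X @ mu0, cov=X @ np.diag(v0) @ X.T + sigma2 * np.eye(N)
        )
        assert res["free_energy"] == pytest.approx(exact, abs=1e-3)

    def test_posterior_matches_ridge_closed_form(self, rng):
        N, K = 30, 3
        X = rng.standard_normal((N, K))
        v0 = np.full(K, 0.4)
        mu0 = np.zeros(K)
        lam = 4.0
        y = rng.standard_normal(N)
        res = dcm_core.variational_laplace(
            lambda th: X @ th, y, mu0, v0, noise_precision=lam, tol=1e-12, max_iter=200
        )
        H = lam * X.T @ X + np.diag(1 / v0)
        expected = np.linalg.solve(H, lam * X.T @ y)
        np.testing.assert_allclose(res["posterior_mean"], expected, atol=1e-6)
        np.testing.assert_allclose(res["posterior_cov"], np.linalg.inv(H), atol=1e-6)

    def test_occam_prefers_smaller_nested_model(self, rng):
        wins = 0
        for _ in range(100):
            N = 40
            X_small = rng.standard_normal((N, 2))
            X_large = np.hstack([X_small, rng.standard_normal((N, 2))])
            theta = rng.standard_normal(2)
            y = X_small @ theta + rng.normal(0, 0.5, N)
            f_small = dcm_core.variational_laplace(
                lambda th: X_small @ th, y, np.zeros(2), np.ones(2),
                noise_precision=4.0, tol=1e-9,
            )["free_energy"]
            f_large = dcm_core.variational_laplace(
                lambda th: X_large @ th, y, np.zeros(4), np.ones(4),
                noise_precision=4.0, tol=1e-9,
            )["free_energy"]
            wins += f_small > f_large
        assert wins >= 90

    def test_delta_prior_is_loglik_at_prior_mean(self, rng):
        N = 20
        X = rng.standard_normal((N, 2))
        mu0 = np.array([0.3, -0.2])
        lam = 2.0
        y = rng.standard_normal(N)
        res = dcm_core.variational_laplace(
            lambda th: X @ th, y, mu0, np.zeros(2), noise_precision=lam
        )
        r = y - X @ mu0
        expected = -0.5 * lam * r @ r + 0.5 * N * (np.log(lam) - np.log(2 * np.pi))
        assert res["free_energy"] == pytest.approx(expected, abs=1e-10)


class TestInvert:
    def test_self_consistent_fixed_point(self, space, inputs):
        spec = space.model(1)
        y = dcm_core.integrate(spec, spec.prior_mean(), inputs, DT)
        fit = dcm_core.invert(spec, y, inputs, DT)
        assert np.linalg.norm(fit.posterior_mean - spec.prior_mean()) < 1e-3

    def test_posterior_cov_positive_definite(self, space, inputs, rng):
        spec = space.model(4)
        theta = spec.prior_mean().copy()
        theta[spec.param_names.index("C:PMC")] = 1.0
        y = dcm_core.integrate(spec, theta, inputs, DT)
        y = y + 0.05 * rng.standard_normal(y.shape)
        fit = dcm_core.invert(spec, y, inputs, DT)
        ev = np.linalg.eigvalsh(fit.posterior_cov)
        assert ev.min() > 0

    def test_recovers_known_coupling(self, space, inputs):
        spec = space.model(2)
        rng0 = np.random.default_rng(7)
        na = len(spec._a_idx[0])
        nb = len(spec._b_idx[0])
        theta = spec.prior_mean().copy()
        theta[:na] = rng0.uniform(-0.2, 0.2, na)
        theta[na : na + nb] = 0.2
        bi = spec.param_names.index("B:SMA<-PMC")
        theta[bi] = 0.3
        theta[na + nb] = 1.0
        y_clean = dcm_core.integrate(spec, theta, inputs, DT)
        y = y_clean + np.random.default_rng(8).normal(
            0, 0.1 * y_clean.std(), y_clean.shape
        )
        fit = dcm_core.invert(spec, y, inputs, DT)
        assert fit.converged
        assert abs(fit.posterior_mean[bi] - 0.3) < 0.15

    def test_coverage_of_credible_interval(self, space, inputs):
        """true B(SMA<-PMC)=0.3 inside its 95% CI in >= 18/20 replicate fits."""
        spec = space.model(2)
        rng0 = np.random.default_rng(7)
        na = len(spec._a_idx[0])
        nb = len(spec._b_idx[0])
        theta = spec.prior_mean().copy()
        theta[:na] = rng0.uniform(-0.2, 0.2, na)
        theta[na : na + nb] = 0.2
        bi = spec.param_names.index("B:SMA<-PMC")
        theta[bi] = 0.3
        theta[na + nb] = 1.0
        y_clean = dcm_core.integrate(spec, theta, inputs, DT)
        noise_sd = 0.1 * y_clean.std()
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(1000 + rep)
            y = y_clean + rng.normal(0, noise_sd, y_clean.shape)
            fit = dcm_core.invert(spec, y, inputs, DT)
            lo, hi = fit.credible_interval(bi)
            hits += lo <= 0.3 <= hi
        assert hits >= 18

    def test_permutation_invariance(self, inputs, rng):
        """Permuting node order (and masks/data alike) leaves F unchanged."""
        space = bms.build_model_space()
        spec = space.model(2)
        perm = [1, 0, 2, 3]  # swap PMC and SMA
        nodes_p = tuple(dcm_core.NODES[i] for i in perm)
        P = np.eye(4)[perm]
        spec_p = dcm_core.DCMSpec(
            a_mask=P @ spec.a_mask @ P.T,
            b_mask=P @ spec.b_mask @ P.T,
            c_mask=P @ spec.c_mask,
            nodes=nodes_p,
        )
        theta = spec.prior_mean().copy()
        theta[spec.param_names.index("C:PMC")] = 1.0
        y = dcm_core.integrate(spec, theta, inputs, DT)
        y = y + 0.05 * rng.standard_normal(y.shape)
        fit = dcm_core.invert(spec, y, inputs, DT, tol=1e-6)
        fit_p = dcm_core.invert(spec_p, y[perm], inputs, DT, tol=1e-6)
        assert fit_p.free_energy == pytest.approx(fit.free_energy, abs=1e-4)
        B = fit.posterior_b_matrix(spec)
        B_p = fit_p.posterior_b_matrix(spec_p)
        np.testing.assert_allclose(P @ B @ P.T, B_p, atol=1e-4)

    def test_misaligned_inputs_rejected(self, space, rng):
        spec = space.model(1)
        with pytest.raises(ShapeError):
            dcm_core.invert(
                spec,
                rng.standard_normal((4, 100)),
                {"drive": np.zeros(50), "mod": np.zeros(50)},
                DT,
            )
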