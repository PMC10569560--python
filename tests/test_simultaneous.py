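import numpy as np
import pytest
from scipy.special import logsumexp

from spiketypes import (
    ClusterModel,
    GLMParams,
    ModelShape,
    e_step,
    estimate_latents,
    fit_simultaneous,
    joint_logdensity,
    m_step,
)
from spiketypes.glm_core import build_design, log_likelihood
from spiketypes.simultaneous import PosteriorApprox, _laplace_for_pair


def random_omega(rng, K, T_self, lambda_stim=1e-3) -> ClusterModel:
    pi = rng.random(K) + 0.5
    return ClusterModel(
        pi=pi / pi.sum(),
        mu_self=rng.standard_normal((K, T_self)),
        sigma_self=0.3 + rng.random((K, T_self)),
        lambda_stim=lambda_stim,
    )


class TestJointLogDensity:
    def test_additive_decomposition(self, rng, tiny_dataset):
        from scipy.stats import norm

        cfg, ds, _, _ = tiny_dataset
        shape = cfg.shape
        omega = random_omega(rng, 2, shape.T_self)
        n = ds[0]
        X = build_design(n.stimulus, n.spikes, shape)
        beta = GLMParams.from_flat(0.1 * rng.standard_normal(shape.dim), shape)
        for k in range(2):
            lp = joint_logdensity(k, beta, n, omega, shape, design=X)
            expected = (
                log_likelihood(beta, X, n.spikes.astype(float))
                + norm.logpdf(beta.beta_stim, 0.0, 1.0 / np.sqrt(omega.lambda_stim)).sum()
                + norm.logpdf(
                    beta.beta_self, omega.mu_self[k], np.sqrt(omega.sigma_self[k])
                ).sum()
                + np.log(omega.pi[k])
            )
            assert lp == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self, rng, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        shape = cfg.shape
        omega = random_omega(rng, 2, shape.T_self)
        n = ds[1]
        X = build_design(n.stimulus, n.spikes, shape)
        b0 = 0.05 * rng.standard_normal(shape.dim)
        f = lambda b: joint_logdensity(0, b, n, omega, shape, design=X)
        eps = 1e-6
        for j in rng.choice(shape.dim, size=6, replace=False):
            e = np.zeros(shape.dim)
            e[j] = eps
            fd = (f(b0 + e) - f(b0 - e)) / (2 * eps)
            # analytic gradient: likelihood part + prior part
            _, g_ll = log_likelihood(b0, X, n.spikes.astype(float), gradient=True)
            prec = np.concatenate(
                [
                    np.full(shape.T_stim, omega.lambda_stim),
                    1.0 / omega.sigma_self[0],
                    [0.0],
                ]
            )
            mean = np.concatenate([np.zeros(shape.T_stim), omega.mu_self[0], [0.0]])
            g = g_ll - prec * (b0 - mean)
            assert abs(fd - g[j]) <= 1e-5 * max(1.0, abs(g[j]))

    def test_zero_weight_cluster_gives_minus_inf(self, rng, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        omega = random_omega(rng, 2, cfg.shape.T_self)
        omega.pi = np.array([1.0, 0.0])
        beta = GLMParams.from_flat(np.zeros(cfg.shape.dim), cfg.shape)
        assert joint_logdensity(1, beta, ds[0], omega, cfg.shape) == -np.inf


class TestLaplace:
    def test_exact_on_gaussian_integrand(self, rng):
        """With a constant likelihood term the weighted Gaussian is exact:
        log Z must equal the closed-form Gaussian integral."""
        d, T = 6, 10
        X = np.zeros((T, d))  # linear predictor 0 -> Poisson term is a constant
        y = np.zeros(T)
        prec = 0.5 + rng.random(d)
        mean = rng.standard_normal(d)
        log_norm = 0.5 * np.sum(np.log(prec / (2 * np.pi)))
        log_pi = np.log(0.3)
        m, c, logZ, _ = _laplace_for_pair(
            X, X * X, X.T @ y, y, 0.0, prec, mean, log_norm, log_pi, mean * 0, 1e-10
        )
        np.testing.assert_allclose(m, mean, atol=1e-8)
        np.testing.assert_allclose(c, 1.0 / prec, rtol=1e-12)
        # integral of exp(-T) * N(beta; mean, 1/prec) * pi over beta
        assert logZ == pytest.approx(-T + log_pi, abs=1e-8)

    def test_modes_shrink_to_prior_mean_in_tight_prior_limit(self, rng, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        shape = cfg.shape
        omega = random_omega(rng, 2, shape.T_self)
        omega.sigma_self = np.full_like(omega.sigma_self, 1e-8)
        post = e_step(ds.subset([0]), omega, shape)
        for k in range(2):
            sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
            np.testing.assert_allclose(post.m[0, k, sl], omega.mu_self[k], atol=1e-3)

    def test_ztilde_rows_normalized(self, rng, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        omega = random_omega(rng, 3, cfg.shape.T_self)
        post = e_step(ds, omega, cfg.shape)
        np.testing.assert_allclose(post.Ztilde.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(post.c > 0)

    def test_mode_is_stationary_point_of_joint(self, rng, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        shape = cfg.shape
        omega = random_omega(rng, 2, shape.T_self)
        post = e_step(ds.subset([0]), omega, shape, gtol=1e-8)
        n = ds[0]
        X = build_design(n.stimulus, n.spikes, shape)
        f = lambda b: joint_logdensity(0, b, n, omega, shape, design=X)
        m = post.m[0, 0]
        eps = 1e-5
        for j in range(0, shape.dim, 7):
            e = np.zeros(shape.dim)
            e[j] = eps
            assert abs(f(m + e) - f(m - e)) / (2 * eps) < 1e-3


class TestMStep:
    def _post(self, rng, N, K, d):
        logZ = rng.standard_normal((N, K))
        Zt = np.exp(logZ - logsumexp(logZ, axis=1, keepdims=True))
        return PosteriorApprox(
            logZ=logZ,
            Ztilde=Zt,
            m=rng.standard_normal((N, K, d)),
            c=0.1 + rng.random((N, K, d)),
        )

    def test_matches_direct_summation_oracle(self, rng):
        shape = ModelShape(T_stim=2, T_self=3, d_stim=1)
        K, N, d = 3, 12, shape.dim
        post = self._post(rng, N, K, d)
        omega0 = random_omega(rng, K, shape.T_self)
        new = m_step(post, omega0, shape)
        sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
        for k in range(K):
            w = post.Ztilde[:, k]
            pi_k = sum(w) / N
            mu_k = np.zeros(shape.T_self)
            for i in range(N):
                mu_k += w[i] * post.m[i, k, sl]
            mu_k /= w.sum()
            var_k = np.zeros(shape.T_self)
            for i in range(N):
                var_k += w[i] * (post.c[i, k, sl] + post.m[i, k, sl] ** 2)
            var_k = var_k / w.sum() - mu_k**2
            assert new.pi[k] == pytest.approx(pi_k, abs=1e-12)
            np.testing.assert_allclose(new.mu_self[k], mu_k, atol=1e-12)
            np.testing.assert_allclose(new.sigma_self[k], var_k, atol=1e-12)

    def test_single_cluster_unweighted_closed_form(self, rng):
        shape = ModelShape(T_stim=2, T_self=3, d_stim=1)
        N, d = 8, shape.dim
        post = PosteriorApprox(
            logZ=np.zeros((N, 1)),
            Ztilde=np.ones((N, 1)),
            m=rng.standard_normal((N, 1, d)),
            c=0.1 + rng.random((N, 1, d)),
        )
        omega0 = random_omega(rng, 1, shape.T_self)
        new = m_step(post, omega0, shape)
        sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
        ms = post.m[:, 0, sl]
        cs = post.c[:, 0, sl]
        np.testing.assert_allclose(new.mu_self[0], ms.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            new.sigma_self[0], (cs + ms**2).mean(axis=0) - ms.mean(axis=0) ** 2, atol=1e-12
        )

    def test_degenerate_curvature_limit_is_weighted_gmm_update(self, rng):
        shape = ModelShape(T_stim=2, T_self=3, d_stim=1)
        K, N, d = 2, 10, shape.dim
        post = self._post(rng, N, K, d)
        post.c = np.full_like(post.c, 1e-300)
        omega0 = random_omega(rng, K, shape.T_self)
        new = m_step(post, omega0, shape)
        sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
        for k in range(K):
            w = post.Ztilde[:, k] / post.Ztilde[:, k].sum()
            mu = w @ post.m[:, k, sl]
            var = w @ post.m[:, k, sl] ** 2 - mu**2
            np.testing.assert_allclose(new.mu_self[k], mu, atol=1e-10)
            np.testing.assert_allclose(
                new.sigma_self[k], np.maximum(var, 1e-8), atol=1e-10
            )


class TestEstimateLatents:
    def test_argmax_and_mode_selection(self):
        logZ = np.log(np.array([[0.1, 0.9], [0.7, 0.3]]))
        m = np.arange(2 * 2 * 3, dtype=float).reshape(2, 2, 3)
        post = PosteriorApprox(
            logZ=logZ, Ztilde=np.exp(logZ), m=m, c=np.ones_like(m)
        )
        labels, betas = estimate_latents(post)
        assert labels.tolist() == [1, 0]
        assert betas[0] is not m  # value check below
        np.testing.assert_array_equal(betas[0], m[0, 1])
        np.testing.assert_array_equal(betas[1], m[1, 0])

    def test_exact_tie_goes_to_lowest_cluster(self):
        logZ = np.zeros((1, 3))
        post = PosteriorApprox(
            logZ=logZ, Ztilde=np.full((1, 3), 1 / 3), m=np.zeros((1, 3, 2)), c=np.ones((1, 3, 2))
        )
        labels, _ = estimate_latents(post)
        assert labels[0] == 0


class TestFitSimultaneous:
    def test_single_cluster_labels_and_consistency(self, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        fit = fit_simultaneous(ds, cfg.shape, K=1, lambda_stim=1e-4, n_restarts=1, seed=0, max_iter=30)
        assert np.all(fit.labels == 0)
        assert len(fit.betas) == ds.N
        assert np.all(np.isfinite(fit.ll_per_neuron))

    def test_deterministic_given_seed(self, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        kw = dict(K=2, lambda_stim=1e-4, n_restarts=1, seed=5, max_iter=15)
        a = fit_simultaneous(ds, cfg.shape, **kw)
        b = fit_simultaneous(ds, cfg.shape, **kw)
        assert np.array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.omega.mu_self, b.omega.mu_self)

    def test_label_permutation_equivariance(self, rng, tiny_dataset):
        """Permuting cluster indices permutes labels and leaves LL unchanged."""
        cfg, ds, _, _ = tiny_dataset
        shape = cfg.shape
        omega = random_omega(rng, 3, shape.T_self)
        post = e_step(ds, omega, shape)
        perm = np.array([2, 0, 1])
        omega_p = omega.reorder(perm)
        post_p = e_step(ds, omega_p, shape)
        np.testing.assert_allclose(
            post.ll_per_neuron, post_p.ll_per_neuron, atol=1e-8
        )
        labels, _ = estimate_latents(post)
        labels_p, _ = estimate_latents(post_p)
        inverse = np.empty(3, dtype=int)
        inverse[perm] = np.arange(3)
        assert np.array_equal(inverse[labels], labels_p)

    def test_beta_equals_stored_mode(self, tiny_dataset):
        cfg, ds, _, _ = tiny_dataset
        fit = fit_simultaneous(ds, cfg.shape, K=2, lambda_stim=1e-4, n_restarts=1, seed=1, max_iter=10)
        # recovered parameter vectors are finite and the winning restart is recorded
        assert all(np.all(np.isfinite(b.flat)) for b in fit.betas)
        assert len(fit.restart_scores) == 1
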