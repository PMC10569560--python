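import numpy as np
import pytest

from spiketypes import ModelShape, RegWeights, build_design, fit_glm, log_likelihood, select_lambdas
from spiketypes.data_model import NeuronRecord, SpikeDataset
from spiketypes.glm_core import fit_map


def brute_force_design(x, y, shape):
    """Direct loop-summation oracle for every design-matrix entry."""
    T = len(x)
    X = np.zeros((T, shape.dim))
    get = lambda arr, t: arr[t - 1] if t >= 1 else 0.0  # 1-based with zero padding
    for t in range(1, T + 1):
        for tau in range(shape.T_stim):
            X[t - 1, tau] = sum(
                get(x, t - tau * shape.d_stim - s) for s in range(shape.d_stim)
            )
        for tau in range(1, shape.T_self + 1):
            X[t - 1, shape.T_stim + tau - 1] = get(y, t - tau)
        X[t - 1, -1] = 1.0
    return X


class TestDesign:
    def test_matches_brute_force_oracle(self, rng):
        shape = ModelShape(T_stim=3, T_self=2, d_stim=2)
        x = rng.standard_normal(50)
        y = rng.poisson(0.5, 50)
        np.testing.assert_allclose(
            build_design(x, y, shape), brute_force_design(x, y, shape), atol=1e-12
        )

    def test_first_row_history_is_zero_padded(self, rng, small_shape):
        x = rng.standard_normal(30)
        y = rng.poisson(1.0, 30)
        row0 = build_design(x, y, small_shape)[0]
        # only the tau=0 stimulus tap (x~(1) = x(1)) and the constant survive
        assert row0[0] == pytest.approx(x[0])
        assert np.all(row0[1:-1] == 0) and row0[-1] == 1.0

    def test_constant_stimulus_prefilter_sums(self, small_shape):
        x = np.full(20, 3.0)
        X = build_design(x, np.zeros(20, dtype=int), small_shape)
        d = small_shape.d_stim
        assert np.all(X[d - 1 :, 0] == 3.0 * d)

    def test_length_mismatch_rejected(self, small_shape):
        with pytest.raises(ValueError):
            build_design(np.zeros(5), np.zeros(4), small_shape)


class TestLogLikelihood:
    def test_zero_beta_zero_spikes_value(self, small_shape):
        T = 10
        X = build_design(np.zeros(T), np.zeros(T, dtype=int), small_shape)
        beta = np.zeros(small_shape.dim)
        assert log_likelihood(beta, X, np.zeros(T)) == pytest.approx(-10.0)

    def test_gradient_matches_finite_differences(self, rng, small_shape):
        T = 40
        x = rng.standard_normal(T)
        y = rng.poisson(0.4, T)
        X = build_design(x, y, small_shape)
        beta = 0.1 * rng.standard_normal(small_shape.dim)
        _, grad = log_likelihood(beta, X, y, gradient=True)
        eps = 1e-6
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = eps
            fd = (log_likelihood(beta + e, X, y) - log_likelihood(beta - e, X, y)) / (2 * eps)
            assert abs(fd - grad[j]) <= 1e-5 * max(1.0, abs(grad[j]))

    def test_hessian_matches_finite_differences(self, rng, small_shape):
        T = 30
        x = rng.standard_normal(T)
        y = rng.poisson(0.4, T)
        X = build_design(x, y, small_shape)
        beta = 0.1 * rng.standard_normal(small_shape.dim)
        _, _, H = log_likelihood(beta, X, y, gradient=True, hessian=True)
        eps = 1e-6
        for j in range(len(beta)):
            e = np.zeros_like(beta)
            e[j] = eps
            _, gp = log_likelihood(beta + e, X, y, gradient=True)
            _, gm = log_likelihood(beta - e, X, y, gradient=True)
            fd = (gp - gm) / (2 * eps)
            np.testing.assert_allclose(fd, H[:, j], rtol=1e-4, atol=1e-6)


class TestFitGLM:
    def test_huge_penalty_recovers_intercept_mle(self, rng, small_shape):
        T = 400
        x = rng.standard_normal(T)
        y = rng.poisson(0.5, T)
        beta = fit_glm(x, y, small_shape, RegWeights(1e6, 1e6))
        assert np.all(np.abs(beta.beta_stim) < 1e-3)
        assert np.all(np.abs(beta.beta_self) < 1e-3)
        assert beta.beta0 == pytest.approx(np.log(y.mean()), abs=1e-2)

    def test_two_starts_reach_same_optimum(self, rng, small_shape):
        T = 200
        x = rng.standard_normal(T)
        y = rng.poisson(0.3, T)
        X = build_design(x, y, small_shape)
        reg = RegWeights(1e-3, 1e-3)
        b1 = fit_glm(x, y, small_shape, reg, design=X, x0=rng.standard_normal(small_shape.dim))
        b2 = fit_glm(x, y, small_shape, reg, design=X, x0=rng.standard_normal(small_shape.dim))
        np.testing.assert_allclose(b1.flat, b2.flat, atol=1e-6)

    def test_parameter_recovery_long_series(self):
        # simulate from a known GLM and refit at T=200,000
        from spiketypes import GLMParams, gen_pink_noise, simulate_spikes

        shape = ModelShape(T_stim=3, T_self=4, d_stim=2)
        true = GLMParams(
            beta_stim=[0.3, -0.2, 0.1], beta_self=[-2.0, -0.8, -0.3, 0.2], beta0=-3.0
        )
        T = 200_000
        x = gen_pink_noise(T, seed=5)
        y, degenerate = simulate_spikes(true, x, shape, seed=6)
        assert not degenerate
        est = fit_glm(x, y, shape, RegWeights(1e-7, 1e-7))
        err = est.flat - true.flat
        keep = true.flat >= -4
        assert np.sqrt(np.mean(err[keep] ** 2)) < 0.1

    def test_zero_spike_neuron_stays_finite(self, small_shape):
        beta = fit_glm(np.zeros(200), np.zeros(200, dtype=int), small_shape, RegWeights(1e-3, 1e-3))
        assert np.all(np.isfinite(beta.flat)) and beta.beta0 >= -30

    def test_fit_map_with_informative_prior_shrinks_to_mean(self, rng, small_shape):
        T = 50
        x = rng.standard_normal(T)
        y = rng.poisson(0.2, T)
        X = build_design(x, y, small_shape)
        mean = rng.standard_normal(small_shape.dim)
        prec = np.full(small_shape.dim, 1e8)
        b, info = fit_map(X, y, prec, mean, ll_scale=1.0)
        assert info["converged"]
        np.testing.assert_allclose(b, mean, atol=1e-4)


class TestSelectLambdas:
    def _ds(self, rng, n=2, T=300):
        neurons = []
        for i in range(n):
            x = rng.standard_normal(T)
            y = rng.poisson(0.3, T)
            neurons.append(
                NeuronRecord(f"n{i}", x, y, partitions=[(0, T // 2), (T // 2, T)])
            )
        return SpikeDataset(neurons=neurons)

    def test_singleton_grid_returned(self, rng, small_shape):
        ds = self._ds(rng)
        reg = select_lambdas(ds, small_shape, grid=np.array([1e-3]))
        assert reg.lambda_stim == 1e-3 and reg.lambda_self == 1e-3

    def test_matches_exhaustive_grid_evaluation(self, rng, small_shape):
        """Self-filter-driven data: exhaustive scoring picks small lambda_self."""
        from spiketypes import GLMParams, simulate_spikes

        true = GLMParams(beta_stim=[0.0, 0.0, 0.0], beta_self=[-3.0, 0.5, 0.2, -0.2], beta0=-2.2)
        neurons = []
        for i in range(3):
            x = rng.standard_normal(4000)  # stimulus is irrelevant to the truth
            y, degenerate = simulate_spikes(true, x, small_shape, seed=100 + i)
            assert not degenerate
            neurons.append(NeuronRecord(f"n{i}", x, y, partitions=[(0, 2000), (2000, 4000)]))
        ds = SpikeDataset(neurons=neurons)
        grid = np.array([1e-6, 1e-2, 1.0])
        reg = select_lambdas(ds, small_shape, grid=grid)
        assert reg.lambda_self == 1e-6
        assert reg.lambda_stim >= 1e-2

    def test_requires_two_partitions(self, rng, small_shape):
        n = NeuronRecord("n0", rng.standard_normal(50), rng.poisson(0.3, 50))
        with pytest.raises(ValueError):
            select_lambdas(SpikeDataset(neurons=[n]), small_shape, grid=np.array([1e-3]))
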