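"""Simultaneous method: hierarchical EM over cell types and GLM parameters.

The generative model draws, for each neuron, a cluster label
``k ~ Categorical(pi)``, a self-interaction filter
``beta_self ~ N(mu_k, Sigma_k)`` (diagonal Sigma_k), a stimulus filter
``beta_stim ~ N(0, I/lambda_stim)`` shared across types, an offset with a
flat prior, and finally the spike train from the Poisson GLM.  The mixture
parameters Omega_K = {pi_k, mu_k, Sigma_k} are estimated by EM:

* E-step: for every (neuron, cluster) pair, the joint density over beta is
  approximated by a weighted Gaussian (Laplace) at its mode m_{i,k} with
  diagonal curvature c_{i,k}; the evidence weight Z_{i,k} integrates the
  approximation, and the normalized weights Ztilde_{i,k} play the role of
  responsibilities.
* M-step: closed-form updates of pi, mu_k and Sigma_k from the weighted
  modes and curvatures.

Because the E-step is approximate, the marginal-likelihood surrogate
``sum_i log sum_k Z_{i,k}`` is not guaranteed to be exactly monotone;
decreases beyond a small tolerance are logged, not fatal.

All evidence computations run in the log domain: Z_{i,k} spans hundreds of
log-units across clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .data_model import GLMParams, ModelShape, NeuronRecord, SpikeDataset
from .glm_core import RegWeights, build_design, fit_glm, log_likelihood
from .sequential import VARIANCE_FLOOR, ClusterModel, FitResult, fit_gmm

__all__ = [
    "PosteriorApprox",
    "joint_logdensity",
    "e_step",
    "m_step",
    "estimate_latents",
    "fit_simultaneous",
]

logger = logging.getLogger(__name__)

# l2 ridge on beta_self used only for the per-neuron warm-start fits (the
# hierarchical model itself has no self-filter penalty).
_INIT_SELF_RIDGE = 1e-4


@dataclass
class PosteriorApprox:
    """Per-(neuron, cluster) Laplace triples and normalized evidence weights."""

    logZ: np.ndarray  # (N, K)
    Ztilde: np.ndarray  # (N, K), rows sum to 1
    m: np.ndarray  # (N, K, dim) posterior modes
    c: np.ndarray  # (N, K, dim) diagonal covariances, strictly positive

    @property
    def ll_per_neuron(self) -> np.ndarray:
        """Approximate marginal log-likelihood LL_i = log sum_k Z_{i,k}."""
        return logsumexp(self.logZ, axis=1)

    def reorder(self, order: np.ndarray) -> "PosteriorApprox":
        return PosteriorApprox(
            logZ=self.logZ[:, order],
            Ztilde=self.Ztilde[:, order],
            m=self.m[:, order],
            c=self.c[:, order],
        )


def _prior_terms(omega: ClusterModel, shape: ModelShape, k: int):
    """Per-coordinate prior precision/mean for cluster k, plus log-normalizer.

    The offset coordinate carries a flat prior (zero precision, no
    normalizer); the stimulus block carries the shared isotropic
    N(0, I/lambda_stim) prior.
    """
    prec = np.concatenate(
        [
            np.full(shape.T_stim, omega.lambda_stim),
            1.0 / omega.sigma_self[k],
            [0.0],
        ]
    )
    mean = np.concatenate([np.zeros(shape.T_stim), omega.mu_self[k], [0.0]])
    log_norm = 0.5 * shape.T_stim * (np.log(omega.lambda_stim) - np.log(2 * np.pi))
    log_norm -= 0.5 * np.sum(np.log(2 * np.pi * omega.sigma_self[k]))
    return prec, mean, log_norm


def joint_logdensity(
    k: int,
    beta: GLMParams | np.ndarray,
    neuron: NeuronRecord,
    omega: ClusterModel,
    shape: ModelShape,
    design: np.ndarray | None = None,
) -> float:
    """log P_joint(k, beta, y | x; Omega_K) for one neuron and cluster.

    Sum of the Poisson GLM log-likelihood, the shared stimulus-filter prior,
    the cluster's self-filter prior, and log pi_k; the offset contributes no
    prior term.  Returns -inf when pi_k = 0.
    """
    if omega.pi[k] <= 0:
        return -np.inf
    b = beta.flat if isinstance(beta, GLMParams) else np.asarray(beta, float)
    X = design if design is not None else build_design(neuron.stimulus, neuron.spikes, shape)
    prec, mean, log_norm = _prior_terms(omega, shape, k)
    ll = log_likelihood(b, X, neuron.spikes.astype(float))
    dev = b - mean
    return float(ll + log_norm - 0.5 * prec @ dev**2 + np.log(omega.pi[k]))


def _mode_newton(X, X2, Xty, y, prec, mean, x0, gtol, G_cache=None, maxiter=200):
    """Newton ascent to the unique mode of the concave joint log-density.

    Convergence is declared either on the raw gradient norm (``gtol``) or on
    a curvature-scaled Newton decrement (sum of grad^2 over the diagonal
    curvature): with near-degenerate prior variances the precision can reach
    1e8, where a fixed gradient-norm target is meaningless although the mode
    is located to within float resolution.

    ``G_cache`` may hold the likelihood Hessian GEMM ``X^T diag(rate) X``
    from an earlier call: because convergence is judged on the exact
    gradient and steps are line-searched on the exact objective, a stale
    positive-definite curvature only changes the iteration count, never the
    answer.  The cache is refreshed whenever progress stalls and the
    (possibly refreshed) matrix is returned for reuse.
    """
    from scipy.linalg import cho_factor, cho_solve

    from .glm_core import ETA_CEILING

    d = X.shape[1]
    b = np.asarray(x0, dtype=float).copy()
    eta = X @ b

    def value(eta_v, b_v):
        dev = b_v - mean
        return float(
            np.sum(y * eta_v) - np.sum(np.exp(np.minimum(eta_v, ETA_CEILING)))
        ) - 0.5 * float(prec @ dev**2)

    f = value(eta, b)
    G = G_cache
    fresh = False
    stalls = 0
    prev_dec = None
    for _ in range(maxiter):
        rate = np.exp(np.minimum(eta, ETA_CEILING))
        grad = Xty - X.T @ rate - prec * (b - mean)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < gtol:
            return b, eta, rate, G, True
        # diagonal-preconditioned decrement: ~2x the objective suboptimality
        curv = rate @ X2 + prec
        dec_diag = float(np.sum(grad**2 / np.maximum(curv, 1e-300)))
        if dec_diag < 1e-9:
            return b, eta, rate, G, True
        # a stale curvature buys cheap steps but only linear convergence:
        # refresh whenever the decrement stops falling at Newton-like rate
        slow = prev_dec is not None and dec_diag > 0.25 * prev_dec
        if G is None or stalls >= 2 or slow:
            G = (X.T * rate) @ X
            fresh = True
            stalls = 0
        prev_dec = dec_diag
        H = G.copy()
        H[np.diag_indices(d)] += prec
        try:
            cf = cho_factor(H, lower=True)
        except np.linalg.LinAlgError:
            H[np.diag_indices(d)] += 1e-8 * max(np.trace(H) / d, 1.0)
            cf = cho_factor(H, lower=True)
        step = cho_solve(cf, grad)
        t = 1.0
        gs = float(grad @ step)
        accepted = False
        for _ in range(60):
            b_new = b + t * step
            eta_new = X @ b_new
            f_new = value(eta_new, b_new)
            if f_new >= f + 1e-4 * t * gs:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            if fresh:
                # line search at float resolution: accept if the (exact-
                # Hessian) decrement shows we are essentially at the mode
                return b, eta, rate, G, gs < 1e-4 or gnorm < 1e-3
            stalls = 2  # force a fresh curvature and retry
            continue
        if t < 0.5 and not fresh:
            stalls += 1
        b, eta, f = b_new, eta_new, f_new
        fresh = False
    rate = np.exp(np.minimum(eta, ETA_CEILING))
    grad = Xty - X.T @ rate - prec * (b - mean)
    return b, eta, rate, G, float(np.linalg.norm(grad)) < 1e-3


def _laplace_for_pair(X, X2, Xty, y, gl_sum, prec, mean, log_norm, log_pi, x0, gtol, G_cache=None):
    """Mode, diagonal covariance and log evidence for one (neuron, cluster).

    ``X2`` is the elementwise square of the design, cached per neuron so the
    diagonal curvature at the mode costs O(T d) rather than a full Hessian
    build.
    """
    m, eta, rate, G, ok = _mode_newton(X, X2, Xty, y, prec, mean, x0, gtol, G_cache=G_cache)
    if not ok:
        raise RuntimeError("mode search did not converge")
    # negative diagonal curvature of log P_joint at the mode (exact)
    curv = rate @ X2 + prec
    c = 1.0 / curv
    ll = float(np.sum(y * eta - rate)) - gl_sum
    dev = m - mean
    lp = ll + log_norm - 0.5 * float(prec @ dev**2) + log_pi
    logZ = lp + 0.5 * len(m) * np.log(2 * np.pi) + 0.5 * float(np.sum(np.log(c)))
    return m, c, logZ, G


def e_step(
    ds: SpikeDataset,
    omega: ClusterModel,
    shape: ModelShape,
    warm_starts: np.ndarray | None = None,
    designs: list[np.ndarray] | None = None,
    gtol: float = 1e-6,
    cache: dict | None = None,
) -> PosteriorApprox:
    """Laplace E-step over all (neuron, cluster) pairs.

    ``warm_starts`` may be an (N, K, dim) array of previous modes or an
    (N, dim) array of per-neuron parameter fits; mode searches start there
    (the objective is concave, so warm starts change speed, not the answer).
    ``cache`` is an opaque dict persisted across EM iterations that stores
    per-neuron design products and per-pair curvature matrices.
    """
    N, K, d = ds.N, omega.K, shape.dim
    if designs is None:
        designs = [build_design(n.stimulus, n.spikes, shape) for n in ds]
    if cache is None:
        cache = {}
    logZ = np.empty((N, K))
    m = np.empty((N, K, d))
    c = np.empty((N, K, d))
    priors = [_prior_terms(omega, shape, k) for k in range(K)]
    with np.errstate(divide="ignore"):
        log_pi = np.log(omega.pi)
    for i, n in enumerate(ds):
        X = designs[i]
        if ("neuron", i) not in cache:
            y = n.spikes.astype(float)
            cache[("neuron", i)] = (
                X * X,
                X.T @ y,
                y,
                float(np.sum(gammaln(y + 1.0))),
            )
        X2, Xty, y, gl_sum = cache[("neuron", i)]
        for k in range(K):
            prec, mean, log_norm = priors[k]
            if warm_starts is None:
                x0 = None
            elif warm_starts.ndim == 3:
                x0 = warm_starts[i, k]
            else:
                x0 = warm_starts[i]
            if x0 is None:
                x0 = np.zeros(d)
                x0[-1] = max(np.log(max(y.mean(), 1e-12)), -30.0)
            starts = [x0, mean, np.zeros(d)]
            last_err: Exception | None = None
            for si, s in enumerate(starts):
                try:
                    G0 = cache.get(("pair", i, k)) if si == 0 else None
                    m[i, k], c[i, k], logZ[i, k], G = _laplace_for_pair(
                        X, X2, Xty, y, gl_sum, prec, mean, log_norm, log_pi[k], s, gtol,
                        G_cache=G0,
                    )
                    cache[("pair", i, k)] = G
                    last_err = None
                    break
                except (RuntimeError, np.linalg.LinAlgError) as exc:
                    last_err = exc
            if last_err is not None:
                raise RuntimeError(
                    f"E-step mode search failed for neuron {n.neuron_id}, "
                    f"cluster {k}: {last_err}"
                )
    Ztilde = np.exp(logZ - logsumexp(logZ, axis=1, keepdims=True))
    return PosteriorApprox(logZ=logZ, Ztilde=Ztilde, m=m, c=c)


def m_step(post: PosteriorApprox, omega: ClusterModel, shape: ModelShape) -> ClusterModel:
    """Closed-form mixture updates from the weighted Laplace triples.

    pi_k is the mean responsibility; mu_k the responsibility-weighted mean
    of the self-filter modes; Sigma_k the weighted second moment
    ``E[c + m*m] - mu*mu``, floored.  A cluster whose total responsibility
    vanishes is re-seeded at the mode of the worst-explained neuron.
    """
    N, K, _ = post.m.shape
    sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
    Zt = post.Ztilde
    weight = Zt.sum(axis=0)  # (K,)
    pi = weight / N
    mu = np.empty((K, shape.T_self))
    sigma = np.empty((K, shape.T_self))
    ll = post.ll_per_neuron
    for k in range(K):
        if weight[k] < 1e-8:
            worst = int(np.argmin(ll))
            logger.warning(
                "cluster %d lost all responsibility; re-seeding at neuron index %d", k, worst
            )
            best_k = int(np.argmax(post.logZ[worst]))
            mu[k] = post.m[worst, best_k, sl]
            others = [j for j in range(K) if weight[j] >= 1e-8]
            sigma[k] = (
                omega.sigma_self[others].mean(axis=0) if others else np.ones(shape.T_self)
            )
            pi[k] = 1.0 / N
            continue
        w = Zt[:, k] / weight[k]
        ms = post.m[:, k, sl]
        cs = post.c[:, k, sl]
        mu[k] = w @ ms
        sigma[k] = w @ (cs + ms**2) - mu[k] ** 2
    pi = pi / pi.sum()
    sigma = np.maximum(sigma, VARIANCE_FLOOR)
    return ClusterModel(pi=pi, mu_self=mu, sigma_self=sigma, lambda_stim=omega.lambda_stim)


def estimate_latents(post: PosteriorApprox) -> tuple[np.ndarray, np.ndarray]:
    """Point estimates: k_hat_i = argmax_k Z_{i,k} (ties to lowest k), and
    beta_hat_i = m_{i, k_hat_i}."""
    labels = np.argmax(post.logZ, axis=1)
    betas = post.m[np.arange(post.m.shape[0]), labels]
    return labels, betas


def _omega_vec(omega: ClusterModel) -> np.ndarray:
    """Flatten the mixture into an unconstrained vector (log pi, mu, log sigma)."""
    return np.concatenate(
        [np.log(np.maximum(omega.pi, 1e-300)), omega.mu_self.ravel(), np.log(omega.sigma_self).ravel()]
    )


def _vec_omega(vec: np.ndarray, K: int, T_self: int, lambda_stim: float) -> ClusterModel:
    pi = np.exp(vec[:K] - np.max(vec[:K]))
    pi = pi / pi.sum()
    mu = vec[K : K + K * T_self].reshape(K, T_self)
    sigma = np.exp(np.minimum(vec[K + K * T_self :], 50.0)).reshape(K, T_self)
    return ClusterModel(
        pi=pi, mu_self=mu, sigma_self=np.maximum(sigma, VARIANCE_FLOOR), lambda_stim=lambda_stim
    )


def _run_em(ds, shape, omega, betas0, designs, cache, max_iter, tol, accelerate):
    """One EM run from a given initialization; returns the final state.

    ``accelerate`` enables a squared-extrapolation (SQUAREM-style) scheme:
    after two plain E/M sweeps the parameter change is extrapolated along
    its own trajectory, and the candidate is kept only if it does not lower
    the marginal-likelihood surrogate.  The fixed points are those of the
    plain iteration; only the number of sweeps to reach them changes.  This
    matters because the within-cluster variances approach their optimum
    along a notoriously slow EM crawl.  Iterations are counted in E-steps.
    """

    def step(om, warm):
        post = e_step(ds, om, shape, warm_starts=warm, designs=designs, cache=cache)
        return post, float(np.sum(post.ll_per_neuron))

    post, obj = step(omega, betas0)
    n_e = 1
    converged = False
    tol_abs = lambda o: tol * max(1.0, abs(o))
    while n_e < max_iter and not converged:
        omega1 = m_step(post, omega, shape)
        post1, obj1 = step(omega1, post.m)
        n_e += 1
        if obj1 < obj - tol_abs(obj):
            logger.info("surrogate decreased by %.3g (approximate E-step)", obj - obj1)
        if abs(obj1 - obj) <= tol_abs(obj1):
            omega, post, obj = omega1, post1, obj1
            converged = True
            break
        if not accelerate or n_e + 2 > max_iter:
            omega, post, obj = omega1, post1, obj1
            continue
        omega2 = m_step(post1, omega1, shape)
        post2, obj2 = step(omega2, post1.m)
        n_e += 1
        r_vec = _omega_vec(omega1) - _omega_vec(omega)
        v_vec = (_omega_vec(omega2) - _omega_vec(omega1)) - r_vec
        v_norm = float(np.linalg.norm(v_vec))
        if v_norm < 1e-14:
            omega, post, obj = omega2, post2, obj2
            continue
        alpha = min(-1.0, -float(np.linalg.norm(r_vec)) / v_norm)
        cand_vec = _omega_vec(omega) - 2 * alpha * r_vec + alpha * alpha * v_vec
        omega_acc = _vec_omega(cand_vec, omega.K, shape.T_self, omega.lambda_stim)
        try:
            post_acc, obj_acc = step(omega_acc, post2.m)
            n_e += 1
        except RuntimeError:
            obj_acc = -np.inf
        if obj_acc >= obj2:
            omega, post, obj = omega_acc, post_acc, obj_acc
        else:
            omega, post, obj = omega2, post2, obj2
    return omega, post, obj, n_e, converged


def fit_simultaneous(
    ds: SpikeDataset,
    shape: ModelShape,
    K: int,
    lambda_stim: float,
    n_restarts: int = 20,
    seed: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-6,
    gmm_n_init: int = 10,
    accelerate: bool = True,
    init_betas: np.ndarray | None = None,
) -> FitResult:
    """Fit the hierarchical model by restarted EM; return the best restart.

    Each restart initializes Omega_K with a diagonal GMM fit to per-neuron
    GLM estimates (a small fixed ridge on the self filter keeps those
    warm-start fits well-posed), then alternates Laplace E-steps and
    closed-form M-steps until the marginal-likelihood surrogate changes by
    less than ``tol`` (relative) or ``max_iter`` E-step sweeps.
    ``accelerate`` turns on safeguarded extrapolation of the sweep sequence
    (see ``_run_em``); ``init_betas`` supplies precomputed per-neuron fits
    (flat, one row per neuron) so grid searches can share them.
    """
    if ds.N < K:
        raise ValueError(f"cannot fit K={K} clusters to N={ds.N} neurons")
    if lambda_stim <= 0:
        raise ValueError("lambda_stim must be positive")
    designs = [build_design(n.stimulus, n.spikes, shape) for n in ds]
    if init_betas is not None:
        betas0 = np.asarray(init_betas, dtype=float)
    else:
        init_reg = RegWeights(lambda_stim, _INIT_SELF_RIDGE)
        betas0 = np.stack(
            [
                fit_glm(n.stimulus, n.spikes, shape, init_reg, design=X).flat
                for n, X in zip(ds, designs)
            ]
        )
    sl = slice(shape.T_stim, shape.T_stim + shape.T_self)
    restart_seeds = np.random.SeedSequence(seed).generate_state(n_restarts) % (2**31)

    best: dict | None = None
    restart_scores: list[float] = []
    failures: list[str] = []
    base_cache: dict = {}
    for r in range(n_restarts):
        try:
            omega = fit_gmm(betas0[:, sl], K, n_init=gmm_n_init, seed=int(restart_seeds[r]))
            omega.lambda_stim = lambda_stim
            cache = dict(base_cache)  # share per-neuron products across restarts
            omega, post, obj, n_e, converged = _run_em(
                ds, shape, omega, betas0, designs, cache, max_iter, tol, accelerate
            )
            if not base_cache:
                base_cache = {k: v for k, v in cache.items() if k[0] == "neuron"}
            restart_scores.append(obj)
            if best is None or obj > best["score"]:
                best = {
                    "score": obj,
                    "omega": omega,
                    "post": post,
                    "n_iters": n_e,
                    "converged": converged,
                    "restart": r,
                }
        except RuntimeError as exc:
            logger.warning("restart %d failed: %s", r, exc)
            failures.append(f"restart {r}: {exc}")
            restart_scores.append(-np.inf)
    if best is None:
        raise RuntimeError("all EM restarts failed: " + "; ".join(failures))
    logger.info("best restart: %d (score %.6g)", best["restart"], best["score"])

    omega, post = best["omega"], best["post"]
    order = np.argsort(-omega.mu_self.sum(axis=1), kind="stable")
    omega = omega.reorder(order)
    post = post.reorder(order)
    labels, beta_mat = estimate_latents(post)
    betas = [GLMParams.from_flat(beta_mat[i], shape) for i in range(ds.N)]
    return FitResult(
        method="simultaneous",
        omega=omega,
        labels=labels,
        betas=betas,
        ll_per_neuron=post.ll_per_neuron,
        shape=shape,
        reg=None,
        n_em_iters=best["n_iters"],
        converged=best["converged"],
        restart_scores=restart_scores,
    )
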