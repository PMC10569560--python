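"""Single-cell Poisson GLM: design construction, likelihood, MAP fitting.

The model for one neuron is

    y(t) ~ Poisson(exp[ sum_tau beta_stim(tau+1) * x~(t - tau*d_stim)
                        + sum_tau beta_self(tau) * y(t - tau) + beta0 ])

where ``x~`` is the stimulus box-prefiltered over ``d_stim`` bins (an
effective downsampling of the slowly-varying injected current) and both
series are zero-padded for indices before the recording start.  The
log-likelihood is concave in the parameters, so the l2-regularized MAP
problem has a unique optimum; it is solved with a damped trust-region
Newton scheme using exact gradients and Hessians.

Regularization weights (lambda_stim, lambda_self) are selected by
cross-validation over the per-neuron trial partitions, maximizing the
held-out log-likelihood pooled over all neurons on a log-spaced grid in
[1e-7, 1] per axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import gammaln

from .data_model import GLMParams, ModelShape, SpikeDataset

__all__ = [
    "RegWeights",
    "build_design",
    "log_likelihood",
    "fit_glm",
    "fit_map",
    "select_lambdas",
    "ETA_CEILING",
    "BETA0_BOUND",
]

logger = logging.getLogger(__name__)

# Linear-predictor ceiling inside exp() during optimization; exp(30) ~ 1e13
# keeps the objective finite without affecting any realistic optimum.
ETA_CEILING = 30.0
# Box guard on the offset: the unregularized intercept MLE of a zero-spike
# neuron diverges, so beta0 is clipped into this range after fitting.
BETA0_BOUND = 30.0


@dataclass(frozen=True)
class RegWeights:
    """l2 penalty weights for the stimulus and self filters (offset is free)."""

    lambda_stim: float
    lambda_self: float

    def __post_init__(self) -> None:
        if self.lambda_stim < 0 or self.lambda_self < 0:
            raise ValueError("regularization weights must be nonnegative")


def build_design(x: np.ndarray, y: np.ndarray, shape: ModelShape) -> np.ndarray:
    """Design matrix with column blocks [stimulus history | spike history | 1].

    Row ``t`` (0-based) contains ``x~(t - tau*d_stim)`` for
    ``tau = 0..T_stim-1``, then ``y(t - tau)`` for ``tau = 1..T_self``, then
    a constant 1.  Entries referring to times before the recording start are
    zero (zero-padding).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    T = len(x)
    # box-prefiltered stimulus: x~(t) = sum_{s=0}^{d-1} x(t-s), zero-padded
    c = np.concatenate([[0.0], np.cumsum(x)])
    xt = c[1:] - c[np.maximum(np.arange(T) + 1 - shape.d_stim, 0)]
    X = np.zeros((T, shape.dim))
    for tau in range(shape.T_stim):
        lag = tau * shape.d_stim
        X[lag:, tau] = xt[: T - lag] if lag < T else 0.0
    for tau in range(1, shape.T_self + 1):
        if tau < T:
            X[tau:, shape.T_stim + tau - 1] = y[: T - tau]
    X[:, -1] = 1.0
    return X


def _linear_predictor(beta_flat: np.ndarray, X: np.ndarray) -> np.ndarray:
    return X @ beta_flat


def log_likelihood(
    beta: GLMParams | np.ndarray,
    design: np.ndarray,
    y: np.ndarray,
    gradient: bool = False,
    hessian: bool = False,
    clamp_eta: float | None = None,
):
    """Poisson log-likelihood sum_t [y(t) eta(t) - exp(eta(t)) - log y(t)!].

    With ``gradient``/``hessian`` requested, returns a tuple
    ``(ll[, grad][, hess])`` where ``grad = X^T (y - exp(eta))`` and
    ``hess = -X^T diag(exp(eta)) X``.  ``clamp_eta`` caps the linear
    predictor inside ``exp`` (used during optimization to avoid overflow);
    a clamped evaluation is flagged via a log record.
    """
    beta_flat = beta.flat if isinstance(beta, GLMParams) else np.asarray(beta, float)
    y = np.asarray(y, dtype=float)
    eta = _linear_predictor(beta_flat, design)
    if clamp_eta is not None and np.any(eta > clamp_eta):
        logger.debug("linear predictor clamped at %.1f", clamp_eta)
        eta_e = np.minimum(eta, clamp_eta)
    else:
        eta_e = eta
    rate = np.exp(eta_e)
    ll = float(np.sum(y * eta - rate) - np.sum(gammaln(y + 1.0)))
    if not gradient and not hessian:
        return ll
    out = [ll]
    resid = y - rate
    if gradient:
        out.append(design.T @ resid)
    if hessian:
        out.append(-(design.T * rate) @ design)
    return tuple(out)


def fit_map(
    X: np.ndarray,
    y: np.ndarray,
    prior_prec: np.ndarray,
    prior_mean: np.ndarray,
    ll_scale: float = 1.0,
    x0: np.ndarray | None = None,
    gtol: float = 1e-6,
    maxiter: int = 500,
) -> tuple[np.ndarray, dict]:
    """Maximize ``ll_scale * loglik(beta) - 0.5 sum_j prec_j (beta_j - mean_j)^2``.

    The workhorse behind both the l2-regularized per-neuron fit and the
    per-(neuron, cluster) posterior mode searches of the simultaneous
    method.  The objective is concave, so a trust-region Newton scheme with
    exact Hessians (Cholesky-solved at this small dimension, with
    backtracking and Levenberg damping as the trust-region safeguard)
    converges to the unique optimum from any start.  Constant ``log y!``
    terms are dropped during optimization.
    """
    y = np.asarray(y, dtype=float)
    prior_prec = np.asarray(prior_prec, dtype=float)
    prior_mean = np.asarray(prior_mean, dtype=float)
    d = X.shape[1]
    if x0 is None:
        x0 = np.zeros(d)
        with np.errstate(divide="ignore"):
            x0[-1] = max(np.log(max(y.mean(), 1e-12)), -BETA0_BOUND)

    def value(eta, b):
        dev = b - prior_mean
        return ll_scale * float(np.sum(y * eta) - np.sum(np.exp(np.minimum(eta, ETA_CEILING)))) - 0.5 * float(prior_prec @ dev**2)

    b = np.asarray(x0, dtype=float).copy()
    eta = X @ b
    f = value(eta, b)
    n_iter = 0
    Xty = X.T @ y
    while True:
        rate = np.exp(np.minimum(eta, ETA_CEILING))
        grad = ll_scale * (Xty - X.T @ rate) - prior_prec * (b - prior_mean)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < gtol or n_iter >= maxiter:
            break
        n_iter += 1
        H = ll_scale * ((X.T * rate) @ X)
        H[np.diag_indices(d)] += prior_prec
        # Levenberg damping as fallback for an ill-conditioned Hessian
        damp = 0.0
        for _ in range(40):
            try:
                cf = cho_factor(
                    H if damp == 0.0 else H + damp * np.eye(d), lower=True
                )
                step = cho_solve(cf, grad)
                break
            except np.linalg.LinAlgError:
                damp = max(10 * damp, 1e-10 * max(np.trace(H) / d, 1.0))
        else:  # pragma: no cover - H is PSD by construction
            raise RuntimeError("Hessian factorization failed")
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
            break  # no ascent possible beyond floating-point resolution
        b, eta, f = b_new, eta_new, f_new
    info = {
        "converged": gnorm < max(10 * gtol, 1e-5),
        "grad_norm": gnorm,
        "n_iter": n_iter,
        "eta": eta,
        "rate": rate,
    }
    if not info["converged"] and gnorm > 1e-3:
        raise RuntimeError(
            f"MAP fit did not converge: |grad|={gnorm:.2e} after {n_iter} iterations"
        )
    return b, info


def fit_glm(
    x: np.ndarray,
    y: np.ndarray,
    shape: ModelShape,
    reg: RegWeights,
    normalize_by: int | None = None,
    design: np.ndarray | None = None,
    x0: np.ndarray | None = None,
) -> GLMParams:
    """l2-regularized maximum-likelihood fit of the single-cell GLM.

    Maximizes ``(1/T_train) loglik - (lambda_stim/2)||beta_stim||^2 -
    (lambda_self/2)||beta_self||^2`` (offset unpenalized).  ``normalize_by``
    overrides the training-bin count ``T_train`` (used by cross-validation
    where the design has more rows than the training fold).
    """
    X = design if design is not None else build_design(x, y, shape)
    y = np.asarray(y, dtype=float)
    T_train = normalize_by if normalize_by is not None else len(y)
    prec = np.concatenate(
        [
            np.full(shape.T_stim, reg.lambda_stim),
            np.full(shape.T_self, reg.lambda_self),
            [0.0],
        ]
    )
    beta, info = fit_map(X, y, prec, np.zeros(shape.dim), ll_scale=1.0 / T_train, x0=x0)
    if abs(beta[-1]) > BETA0_BOUND:
        logger.warning("offset hit guard bound +-%.0f; clipping", BETA0_BOUND)
        beta = beta.copy()
        beta[-1] = float(np.clip(beta[-1], -BETA0_BOUND, BETA0_BOUND))
    return GLMParams.from_flat(beta, shape)


def lambda_grid(grid_size: int = 8) -> np.ndarray:
    """Log-spaced grid over [1e-7, 1] used for both penalty axes."""
    return np.logspace(-7, 0, grid_size)


def select_lambdas(
    ds: SpikeDataset,
    shape: ModelShape,
    grid_size: int = 8,
    grid: np.ndarray | None = None,
) -> RegWeights:
    """Select (lambda_stim, lambda_self) by pooled cross-validation.

    For every grid point, each neuron is refit on all partitions but one and
    scored on the held-out partition; the criterion is the held-out
    log-likelihood averaged over all data points of all neurons,

        V_ALL = sum_i (1/(N T_i)) sum_l log P_SC(fold l | fit on others).

    Returns the maximizing grid point; ties break toward larger lambdas.
    """
    for n in ds:
        if n.L < 2:
            raise ValueError(f"neuron {n.neuron_id} has fewer than 2 partitions")
    g = np.asarray(grid) if grid is not None else lambda_grid(grid_size)
    designs = [build_design(n.stimulus, n.spikes, shape) for n in ds]
    best = None
    best_score = -np.inf
    for lam_stim in g:
        for lam_self in g:
            reg = RegWeights(lam_stim, lam_self)
            score = 0.0
            ok = True
            for n, X in zip(ds, designs):
                yf = n.spikes.astype(float)
                warm = None
                for start, end in n.partitions:
                    mask = np.ones(n.T, dtype=bool)
                    mask[start:end] = False
                    try:
                        beta = fit_glm(
                            n.stimulus[mask],
                            n.spikes[mask],
                            shape,
                            reg,
                            normalize_by=int(mask.sum()),
                            design=X[mask],
                            x0=warm,
                        )
                    except RuntimeError as exc:  # pragma: no cover - rare
                        logger.warning(
                            "inner CV fit failed at (%.2e, %.2e): %s", lam_stim, lam_self, exc
                        )
                        ok = False
                        break
                    warm = beta.flat
                    score += (
                        log_likelihood(beta, X[start:end], yf[start:end]) / (ds.N * n.T)
                    )
                if not ok:
                    break
            if not ok:
                score = -np.inf
            # scanning in increasing lambda order with >= breaks ties upward
            if score >= best_score:
                best_score = score
                best = reg
    assert best is not None
    return best
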