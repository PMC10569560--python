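"""Sequential method: fit each neuron's GLM, then cluster the self-filters.

Step 1 fits every neuron's Poisson GLM independently with cross-validated
(or caller-supplied "oracle") l2 penalties.  Step 2 fits a
diagonal-covariance Gaussian mixture to the fitted self-interaction filters
(the features that define functional cell types) and assigns each neuron to
the mixture component with the highest weighted density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.mixture import GaussianMixture

from .data_model import GLMParams, ModelShape, SpikeDataset
from .glm_core import RegWeights, build_design, fit_glm, select_lambdas

__all__ = ["ClusterModel", "FitResult", "fit_gmm", "assign_types", "run_sequential", "VARIANCE_FLOOR"]

logger = logging.getLogger(__name__)

# Floor on every diagonal covariance entry; prevents evidence blow-up when a
# component collapses onto few neurons.  Shared with the simultaneous method.
VARIANCE_FLOOR = 1e-8


@dataclass
class ClusterModel:
    """Mixture over self-interaction filters: Omega_K = {pi_k, mu_k, Sigma_k}.

    ``sigma_self`` stores the diagonal of each component covariance.
    ``lambda_stim`` is the shared stimulus prior precision; it is carried
    here because the simultaneous method's generative model owns it, while
    the sequential method leaves it at 0 (unused).
    """

    pi: np.ndarray
    mu_self: np.ndarray  # (K, T_self)
    sigma_self: np.ndarray  # (K, T_self) diagonal covariances
    lambda_stim: float = 0.0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.mu_self = np.atleast_2d(np.asarray(self.mu_self, dtype=float))
        self.sigma_self = np.atleast_2d(np.asarray(self.sigma_self, dtype=float))
        if abs(self.pi.sum() - 1.0) > 1e-12:
            raise ValueError("mixture weights must sum to 1")
        if np.any(self.sigma_self < VARIANCE_FLOOR * (1 - 1e-12)):
            raise ValueError("component variances below the variance floor")

    @property
    def K(self) -> int:
        return len(self.pi)

    def log_component_density(self, betas_self: np.ndarray) -> np.ndarray:
        """(N, K) matrix of log [pi_k N(beta_i; mu_k, Sigma_k)]."""
        b = np.atleast_2d(betas_self)
        dev = b[:, None, :] - self.mu_self[None, :, :]  # (N, K, D)
        quad = np.sum(dev**2 / self.sigma_self[None, :, :], axis=2)
        logdet = np.sum(np.log(self.sigma_self), axis=1)
        d = self.mu_self.shape[1]
        with np.errstate(divide="ignore"):
            logpi = np.log(self.pi)
        return logpi[None, :] - 0.5 * (d * np.log(2 * np.pi) + logdet[None, :] + quad)

    def reorder(self, order: np.ndarray) -> "ClusterModel":
        return ClusterModel(
            pi=self.pi[order],
            mu_self=self.mu_self[order],
            sigma_self=self.sigma_self[order],
            lambda_stim=self.lambda_stim,
        )


@dataclass
class FitResult:
    """Outcome of either clustering method on one dataset."""

    method: str
    omega: ClusterModel
    labels: np.ndarray  # k_hat_i in {0, .., K-1}
    betas: list[GLMParams]
    ll_per_neuron: np.ndarray
    shape: ModelShape
    reg: RegWeights | None = None
    n_em_iters: int = 0
    converged: bool = True
    restart_scores: list[float] = field(default_factory=list)

    @property
    def total_ll(self) -> float:
        return float(np.sum(self.ll_per_neuron))


def fit_gmm(
    betas_self: np.ndarray, K: int, n_init: int = 20, seed: int | None = None
) -> ClusterModel:
    """Best-of-``n_init`` diagonal GMM fit (k-means initialized) to the filters."""
    B = np.atleast_2d(np.asarray(betas_self, dtype=float))
    if B.shape[0] < K:
        raise ValueError(f"cannot fit K={K} components to N={B.shape[0]} points")
    gm = GaussianMixture(
        n_components=K,
        covariance_type="diag",
        init_params="kmeans",
        n_init=n_init,
        reg_covar=VARIANCE_FLOOR,
        random_state=None if seed is None else int(seed) % (2**31),
    )
    gm.fit(B)
    if not gm.converged_:
        logger.warning("GMM EM did not fully converge; using best iterate")
    return ClusterModel(
        pi=gm.weights_ / gm.weights_.sum(),
        mu_self=gm.means_,
        sigma_self=np.maximum(gm.covariances_, VARIANCE_FLOOR),
    )


def assign_types(betas_self: np.ndarray, model: ClusterModel) -> np.ndarray:
    """MLE cell type per neuron: argmax_k pi_k N(beta_i; mu_k, Sigma_k).

    Ties break to the lowest cluster index.
    """
    scores = model.log_component_density(betas_self)
    return np.argmax(scores, axis=1)


def _order_by_filter_mean(model: ClusterModel, labels: np.ndarray):
    """Relabel clusters by descending sum of their mean self-filter."""
    order = np.argsort(-model.mu_self.sum(axis=1), kind="stable")
    inverse = np.empty_like(order)
    inverse[order] = np.arange(len(order))
    return model.reorder(order), inverse[labels]


def run_sequential(
    ds: SpikeDataset,
    shape: ModelShape,
    K: int,
    grid_size: int = 8,
    seed: int | None = None,
    reg: RegWeights | None = None,
    n_init: int = 20,
) -> FitResult:
    """Full sequential pipeline on one dataset.

    ``reg`` bypasses cross-validated lambda selection (the "oracle
    hyperparameters" used in simulation studies); otherwise the lambdas are
    chosen by pooled CV over the per-neuron partitions.
    """
    if reg is None:
        reg = select_lambdas(ds, shape, grid_size=grid_size)
    betas = []
    for n in ds:
        X = build_design(n.stimulus, n.spikes, shape)
        betas.append(fit_glm(n.stimulus, n.spikes, shape, reg, design=X))
    B = np.stack([b.beta_self for b in betas])
    model = fit_gmm(B, K, n_init=n_init, seed=seed)
    labels = assign_types(B, model)
    model, labels = _order_by_filter_mean(model, labels)
    ll_per_neuron = logsumexp(model.log_component_density(B), axis=1)
    return FitResult(
        method="sequential",
        omega=model,
        labels=labels,
        betas=betas,
        ll_per_neuron=ll_per_neuron,
        shape=shape,
        reg=reg,
    )
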