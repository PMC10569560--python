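"""Model selection: BIC over K (and lambda_stim), plus held-out-neuron CVLL.

The BIC heuristic penalizes the sum of per-neuron (approximate marginal or
GMM) log-likelihoods by half the mixture's parameter count times log N,
where N counts neurons:

    BIC = sum_i LL_i - dof(Omega_K)/2 * log N,
    dof = (K-1) + K*T_self + K*T_self = K*(2*T_self + 1) - 1.

Larger is better; grids over K (and lambda_stim for the simultaneous
method) are searched exhaustively.  BIC values are not comparable between
the two methods, whose LL_i are defined on different quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data_model import ModelShape, SpikeDataset
from .glm_core import RegWeights, build_design, fit_glm
from .sequential import FitResult, run_sequential
from .simultaneous import e_step, fit_simultaneous

__all__ = ["SelectionReport", "dof", "bic", "select_model", "cvll_heldout"]

logger = logging.getLogger(__name__)


def dof(K: int, T_self: int) -> int:
    """Degrees of freedom of the mixture: K*(2*T_self + 1) - 1.

    K-1 free weights plus K means and K diagonal covariances of length
    T_self each.
    """
    if K < 1 or T_self < 1:
        raise ValueError("K and T_self must be positive")
    return K * (2 * T_self + 1) - 1


def bic(ll_per_neuron: np.ndarray, K: int, T_self: int, N: int | None = None) -> float:
    """sum_i LL_i - dof/2 * log N (larger is better)."""
    ll = np.asarray(ll_per_neuron, dtype=float)
    n = N if N is not None else len(ll)
    if n < 1:
        raise ValueError("need at least one neuron")
    return float(ll.sum() - 0.5 * dof(K, T_self) * np.log(n))


@dataclass
class SelectionReport:
    """Exhaustive grid search result over (K, lambda_stim)."""

    grid: list[tuple[int, float]]
    bic: list[float]
    ll_sum: list[float]
    dof: list[int]
    chosen: tuple[int, float]
    fits: dict[tuple[int, float], FitResult] = field(default_factory=dict)
    per_restart_scores: list[list[float]] = field(default_factory=list)

    @property
    def chosen_fit(self) -> FitResult:
        return self.fits[self.chosen]


def select_model(
    ds: SpikeDataset,
    shape: ModelShape,
    K_grid,
    lambda_grid,
    method: str = "simultaneous",
    seed: int | None = None,
    **fit_kwargs,
) -> SelectionReport:
    """Fit every (K, lambda_stim) grid point and score it with BIC.

    For the sequential method the lambda grid is ignored beyond its first
    entry (its regularization is chosen separately by cross-validation or
    supplied as ``reg``), so each K is fit once.  Ties break to the
    smallest K, then the largest lambda_stim.
    """
    K_grid = list(K_grid)
    lambda_grid = list(lambda_grid)
    if not K_grid or not lambda_grid:
        raise ValueError("grids must be nonempty")
    if method == "sequential":
        lambda_grid = lambda_grid[:1]
    seeds = np.random.SeedSequence(seed).generate_state(len(K_grid) * len(lambda_grid)) % (2**31)
    grid, bics, lls, dofs, restart_scores = [], [], [], [], []
    fits: dict[tuple[int, float], FitResult] = {}
    init_betas: dict[float, np.ndarray] = {}
    if method == "simultaneous":
        # per-neuron warm-start fits depend only on lambda_stim: share them
        # across the K grid
        from .glm_core import fit_glm as _fit_glm
        from .simultaneous import _INIT_SELF_RIDGE

        for lam in lambda_grid:
            reg = RegWeights(lam, _INIT_SELF_RIDGE)
            init_betas[lam] = np.stack(
                [
                    _fit_glm(
                        n.stimulus, n.spikes, shape, reg,
                        design=build_design(n.stimulus, n.spikes, shape),
                    ).flat
                    for n in ds
                ]
            )
    idx = 0
    for K in K_grid:
        for lam in lambda_grid:
            point_seed = int(seeds[idx])
            idx += 1
            try:
                if method == "simultaneous":
                    fit = fit_simultaneous(
                        ds, shape, K, lambda_stim=lam, seed=point_seed,
                        init_betas=init_betas[lam], **fit_kwargs
                    )
                elif method == "sequential":
                    fit = run_sequential(ds, shape, K, seed=point_seed, **fit_kwargs)
                else:
                    raise ValueError(f"unknown method {method!r}")
                score = bic(fit.ll_per_neuron, K, shape.T_self, ds.N)
                fits[(K, lam)] = fit
                restart_scores.append(list(fit.restart_scores))
                lls.append(fit.total_ll)
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning("grid point (K=%d, lam=%.3g) failed: %s", K, lam, exc)
                score = -np.inf
                lls.append(-np.inf)
                restart_scores.append([])
            grid.append((K, lam))
            bics.append(score)
            dofs.append(dof(K, shape.T_self))
    # ties: smallest K first, then largest lambda; scan order guarantees the
    # first strict maximum encountered per K, so prefer larger lambda within K
    best_idx = 0
    for j in range(1, len(grid)):
        better = bics[j] > bics[best_idx]
        tie = bics[j] == bics[best_idx]
        same_K_larger_lam = tie and grid[j][0] == grid[best_idx][0] and grid[j][1] > grid[best_idx][1]
        if better or same_K_larger_lam:
            best_idx = j
    return SelectionReport(
        grid=grid,
        bic=bics,
        ll_sum=lls,
        dof=dofs,
        chosen=grid[best_idx],
        fits=fits,
        per_restart_scores=restart_scores,
    )


def cvll_heldout(
    train: SpikeDataset,
    heldout: SpikeDataset,
    fitted: FitResult,
    method: str | None = None,
) -> float:
    """Mean held-out-neuron log-likelihood under a model fit on ``train``.

    Simultaneous: one Laplace E-step of the held-out neurons against the
    fitted mixture, scoring log sum_k Z_{i,k}.  Sequential: each held-out
    neuron's GLM is fit individually (with the training regularization) and
    its self-filter scored under the fitted GMM.
    """
    if heldout.N == 0:
        raise ValueError("empty held-out set")
    method = method or fitted.method
    if method == "simultaneous":
        post = e_step(heldout, fitted.omega, fitted.shape)
        return float(np.mean(post.ll_per_neuron))
    if method == "sequential":
        reg = fitted.reg if fitted.reg is not None else RegWeights(1e-4, 1e-4)
        vals = []
        for n in heldout:
            X = build_design(n.stimulus, n.spikes, fitted.shape)
            beta = fit_glm(n.stimulus, n.spikes, fitted.shape, reg, design=X)
            scores = fitted.omega.log_component_density(beta.beta_self[None, :])
            vals.append(float(logsumexp(scores, axis=1)[0]))
        return float(np.mean(vals))
    raise ValueError(f"unknown method {method!r}")
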