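"""Evaluation statistics for fitted models and clusterings.

* adjusted Rand score (ARS) between two labelings, from the contingency
  table (1 = identical partitions, 0 = chance agreement);
* root-mean-squared filter error against ground truth, excluding
  coefficients whose true value is below -4 (their magnitude barely moves
  the Poisson likelihood);
* average negative log-likelihood (ANLL) per test bin;
* PSTH smoothing (10 ms Gaussian kernel) and the explained-variance
  statistic EV, plus the EV ratio comparing the model-predicted PSTH with
  the trial-averaged PSTH on repeated stimulus presentations;
* the metadata enrichment z-score comparing each cluster's share of an
  attribute's carriers against its share of the whole population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.special import comb

from .data_model import GLMParams, ModelShape
from .glm_core import build_design, log_likelihood
from .simulate import simulate_spikes

__all__ = [
    "PSTH",
    "ars",
    "rms_filter",
    "anll",
    "smooth_psth",
    "ev",
    "ev_ratio",
    "metadata_zscore",
]


def ars(labels_a, labels_b) -> float:
    """Adjusted Rand score between two labelings of the same items.

    Computed from the pair-counting contingency table:
    (sum_ij C(n_ij,2) - E) / (max - E), with E the chance expectation.
    Symmetric; 1 iff the labelings agree up to renaming; 0 at chance.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be 1-D and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least two items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    cont = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(cont, (ai, bi), 1)
    sum_cells = comb(cont, 2).sum()
    sum_rows = comb(cont.sum(axis=1), 2).sum()
    sum_cols = comb(cont.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total
    max_index = 0.5 * (sum_rows + sum_cols)
    if max_index == expected:  # both labelings put everything in one class
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def rms_filter(true_beta: np.ndarray, est_beta: np.ndarray, exclude_below: float = -4.0) -> float:
    """RMS error over coefficients whose true value is at least ``exclude_below``."""
    t = np.asarray(true_beta, dtype=float)
    e = np.asarray(est_beta, dtype=float)
    if t.shape != e.shape:
        raise ValueError("filters must have equal length")
    keep = t >= exclude_below
    if not np.any(keep):
        raise ValueError("all coefficients excluded by the threshold")
    return float(np.sqrt(np.mean((t[keep] - e[keep]) ** 2)))


def anll(beta: GLMParams, x_test: np.ndarray, y_test: np.ndarray, shape: ModelShape) -> float:
    """Average negative log-likelihood per test bin (lower is better)."""
    X = build_design(x_test, y_test, shape)
    return -log_likelihood(beta, X, np.asarray(y_test, dtype=float)) / len(y_test)


@dataclass
class PSTH:
    """A spike train smoothed with a unit-mass Gaussian kernel."""

    values: np.ndarray
    kernel_sd: float = 0.010  # seconds

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("PSTH values must be nonnegative")


def smooth_psth(spikes: np.ndarray, bin_width: float, kernel_sd: float = 0.010) -> PSTH:
    """Gaussian smoothing of a spike-count series (reflecting boundaries).

    The kernel standard deviation is given in seconds and converted to bins
    via the bin width; total spike mass is conserved away from edges, and
    the reflecting edge policy preserves it near them too.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sd_bins = kernel_sd / bin_width
    vals = gaussian_filter1d(np.asarray(spikes, dtype=float), sigma=sd_bins, mode="reflect")
    return PSTH(values=np.maximum(vals, 0.0), kernel_sd=kernel_sd)


def _as_values(p) -> np.ndarray:
    return p.values if isinstance(p, PSTH) else np.asarray(p, dtype=float)


def ev(psth1, psth2) -> float:
    """Explained variance between two PSTHs:

        EV = [var(p1) + var(p2) - var(p1 - p2)] / [var(p1) + var(p2)],

    with population variances over time bins.  Equals 1 for identical
    traces, 0 in expectation for independent ones.
    """
    p1 = _as_values(psth1)
    p2 = _as_values(psth2)
    if p1.shape != p2.shape:
        raise ValueError("PSTHs must have equal length")
    v1 = np.var(p1)
    v2 = np.var(p2)
    if v1 + v2 == 0:
        raise ValueError("EV undefined: both traces are constant")
    return float((v1 + v2 - np.var(p1 - p2)) / (v1 + v2))


def ev_ratio(
    beta: GLMParams,
    test_trials: np.ndarray,
    x_test: np.ndarray,
    shape: ModelShape,
    n_sim: int = 3000,
    seed: int | None = None,
    bin_width: float = 0.002,
    kernel_sd: float = 0.010,
    count_cap: int = 50,
    neuron_id: str = "?",
) -> float:
    """Explained-variance ratio on repeated presentations of one stimulus.

    Simulates ``n_sim`` GLM responses to the test stimulus, averages them
    and smooths the average (the model PSTH); smooths each recorded trial
    (stPSTH_j) and averages those (the data PSTH); returns

        sum_j EV(stPSTH_j, PSTH_model) / sum_j EV(stPSTH_j, PSTH_data).

    Per-bin simulated counts are truncated at ``count_cap``; a simulation
    flagged as runaway raises, naming the neuron.
    """
    trials = np.atleast_2d(np.asarray(test_trials, dtype=float))
    if trials.shape[0] < 2:
        raise ValueError("EV ratio needs at least 2 repeated presentations")
    if trials.shape[1] != len(x_test):
        raise ValueError("trial length must match the test stimulus")
    sims, degenerate = simulate_spikes(
        beta, x_test, shape, seed=seed, n_series=n_sim, count_cap=count_cap
    )
    if degenerate:
        raise RuntimeError(f"runaway simulated rate for neuron {neuron_id}")
    psth_m = smooth_psth(sims.mean(axis=0), bin_width, kernel_sd)
    st = [smooth_psth(tr, bin_width, kernel_sd) for tr in trials]
    psth_d = PSTH(values=np.mean([p.values for p in st], axis=0), kernel_sd=kernel_sd)
    num = sum(ev(p, psth_m) for p in st)
    den = sum(ev(p, psth_d) for p in st)
    return float(num / den)


def metadata_zscore(labels, attribute_values) -> pd.DataFrame:
    """Per-(cluster, attribute-value) enrichment z-scores.

    For cluster i and attribute value a, with p_i the overall fraction of
    neurons in cluster i, p_i^(a) the fraction among carriers of a, N the
    population size and N^(a) the carrier count:

        Z = (p_i^(a) - p_i) / sqrt(p_i^(a)(1-p_i^(a))/N^(a) + p_i(1-p_i)/N).

    Neurons whose attribute is missing (None/NaN) are excluded from the
    carrier counts but kept in the population.  A zero denominator (both
    fractions in {0, 1}) yields Z = 0.
    """
    labels = np.asarray(labels)
    attrs = pd.Series(attribute_values)
    if len(labels) != len(attrs):
        raise ValueError("labels and attribute values must cover the same neurons")
    N = len(labels)
    clusters = np.unique(labels)
    values = sorted(v for v in attrs.dropna().unique())
    rows = {}
    for i in clusters:
        in_i = labels == i
        p_i = in_i.mean()
        row = {}
        for a in values:
            has_a = (attrs == a).to_numpy()
            N_a = int(has_a.sum())
            p_ia = (in_i & has_a).sum() / N_a
            var = p_ia * (1 - p_ia) / N_a + p_i * (1 - p_i) / N
            row[a] = 0.0 if var == 0 else float((p_ia - p_i) / np.sqrt(var))
        rows[i] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=values)
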