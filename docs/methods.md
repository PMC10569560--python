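# Methods

## The model

Each neuron's spiking response to an injected current is modeled as a
Poisson GLM over 2 ms bins,

    y_i(t) ~ Poisson( exp[ Σ_τ β_i^stim(τ+1) x̃_i(t − τ·d^stim)
                           + Σ_τ β_i^self(τ) y_i(t − τ) + β_i^0 ] ),

where `x̃` is the stimulus summed over a box of `d^stim` bins (the injected
current varies far more slowly than spiking, so its filter taps are spaced
`d^stim` bins apart) and both series are zero-padded before the recording
start.  Defaults: 10 stimulus taps spaced 5 bins apart (100 ms of stimulus
history), 20 self-interaction taps (40 ms of spiking history), one offset —
31 parameters per neuron.  The log-likelihood is strictly concave in the
parameters.

Functional cell types are clusters in the space of self-interaction
filters.  Two estimators are provided:

**Sequential.**  Fit every neuron's GLM independently with l2 penalties on
both filters (offset free), the objective being the per-bin-normalized
log-likelihood minus `(λ/2)‖β‖²` per block.  The penalty pair is selected by
cross-validation over the per-neuron trial partitions, maximizing the
held-out log-likelihood pooled over all neurons and time bins on a
log-spaced grid in [1e−7, 1] per axis (8 points per axis by default).  The
fitted self-filters are then clustered with a diagonal-covariance Gaussian
mixture (k-means initialized, best of 20 restarts), and each neuron is
assigned the component maximizing `π_k · N(β̂_i^self; μ_k, Σ_k)`.

**Simultaneous.**  A hierarchical generative model: cluster label
`k_i ~ Categorical(π)`; self-filter `β_i^self ~ N(μ_k, Σ_k)` with diagonal
Σ_k; stimulus filter `β_i^stim ~ N(0, I/λ^stim)` shared across types; flat
prior on the offset; then the GLM likelihood.  The mixture parameters
Ω_K = {π_k, μ_k, Σ_k} are maximum-likelihood estimates obtained by EM in
which each E-step builds, for every (neuron, cluster) pair, a weighted
Gaussian (Laplace) approximation of the joint density over β: its mode
m_{i,k}, the inverse diagonal of the Hessian c_{i,k} at the mode, and an
evidence weight Z_{i,k} from the Gaussian integral.  The normalized weights
Z̃_{i,k} act as responsibilities in closed-form M-step updates of π, μ, Σ.
Point estimates afterwards: `k̂_i = argmax_k Z_{i,k}` (marginal over β, so
small-variance clusters are not spuriously favored) and `β̂_i = m_{i,k̂_i}`.
Per-neuron approximate marginal log-likelihoods `LL_i = log Σ_k Z_{i,k}`
feed model selection.

There is no self-filter ridge in the hierarchical model — the cluster prior
itself regularizes — which is exactly how estimates "borrow strength": each
neuron's posterior pools the data of its whole cluster.

## Model selection

BIC over K (and λ^stim for the simultaneous method):
`BIC = Σ_i LL_i − dof/2 · log N` with `dof = K(2·T^self + 1) − 1`
(K−1 free weights, K means, K diagonal covariances), N counting neurons.
Larger is better; ties go to smaller K, then larger λ^stim.  BIC values are
not comparable between the two methods because their LL_i are defined on
different quantities (marginal spike-train evidence vs GMM density of point
estimates).  A basic held-out-neuron CVLL is also provided: one Laplace
E-step of the held-out neurons against the fitted mixture (simultaneous),
or the GMM log-density of their individually fitted filters (sequential).

## Evaluation metrics

* **ARS** — adjusted Rand score from the pair-counting contingency table;
  implemented here directly, with scikit-learn's implementation used only
  as a cross-check in tests.
* **Filter RMS** — root-mean-squared error against ground truth, excluding
  coefficients whose true value is below −4: at rates around e^−5 per bin,
  the likelihood is essentially flat in how negative such a coefficient is.
* **ANLL** — negative log-likelihood per test bin (with the log y! terms).
* **EV / EV ratio** — PSTHs are spike trains smoothed with a unit-mass
  Gaussian kernel of 10 ms standard deviation (reflecting boundaries, which
  conserve spike mass at the edges; the choice of edge policy is ours).
  `EV(p1,p2) = [var p1 + var p2 − var(p1−p2)] / [var p1 + var p2]` with
  population variances over time bins.  The EV ratio simulates 3000
  responses of the fitted GLM to the test stimulus, averages them, then
  smooths (in that order), and divides the summed EV between single-trial
  PSTHs and the model PSTH by the summed EV between single-trial PSTHs and
  the trial-averaged PSTH.  Simulated rollouts cap counts at 50 per bin and
  raise if the rollout runs away.
* **Metadata z-score** — for cluster i and attribute value a,
  `Z = (p̂_i^(a) − p̂_i) / sqrt(p̂_i^(a)(1−p̂_i^(a))/N^(a) + p̂_i(1−p̂_i)/N)`,
  comparing the attribute carriers' cluster distribution with the
  population's.

## Synthetic data

The simulator reproduces the simulation-study design: every neuron shares a
fixed stimulus filter and offset β0 = −5; self-filters are drawn from a
K-component isotropic mixture with equal weights, `β^self ~ N(μ_k, σ²I)`,
with σ defaulting to 1e−2 (the small end of the studied range
[1e−2, 10^(−5/6)]); each neuron receives repeated presentations (default 3)
of one pink-noise current waveform; spikes are sampled bin by bin because
the rate at t depends on the sampled history.

Choices the study design leaves open, fixed here once:

* **Stimulus waveform** — exact 1/f-spectrum noise over the full band from
  1/T to Nyquist (complex-Gaussian spectral coefficients), standardized,
  scaled by a gain of 0.5 so that the stimulus drive has a standard
  deviation near 1.5 log-units.  Mean rates land near 0.02 spikes/bin
  (≈10 Hz at 2 ms bins) — quiet but responsive, in the range of cortical
  cells under noise injections.
* **True stimulus filter** — a smooth biphasic profile (fast excitation,
  slower suppression) of length 10.
* **True cluster means** — up to five profiles sharing a deep early
  refractory dip (below −4, mirroring the exclusion rule above) and
  differing in the likelihood-informative region at lags 3–14: recovery
  timescale, a mild subcritical late rebound, a delayed secondary
  suppression, or a shallow slow decay.  Concentrating the differences at
  moderate-magnitude lags makes the types distinguishable from their spike
  trains, not merely as parameter vectors.
* **Bins per presentation** — default 6600 × 3 trials ≈ 20,000 bins per
  neuron, a deliberate reduction of the original recordings' length chosen
  to keep a full study replicate tractable on one CPU; consequences are
  discussed under Limitations.
* **Degeneracy** — a run whose mean rate over any 1000-bin window exceeds
  5 spikes/bin is flagged as runaway self-excitation; datasets containing
  one are rejected, and study harnesses skip and log such replicates.

What the simulator does not emulate: slow drift and adaptation, coupling
between neurons, trial-to-trial gain changes, and the exact band and
amplitude of experimental current waveforms.  Passing tests on these data
show correct recovery of the generative model's structure, not performance
on any real recording.

## Numerical choices

* All MAP problems (per-neuron fits, E-step mode searches) are strictly
  concave and solved by damped Newton with exact Hessians, Cholesky solves,
  and Armijo backtracking; gradient tolerance 1e−6, with a
  curvature-scaled Newton-decrement criterion as well — when a cluster
  variance sits at its floor the prior precision reaches 1e8 and a fixed
  gradient-norm target is not meaningful even though the mode is located to
  float resolution.
* The linear predictor is capped at 30 inside `exp` during optimization;
  reported likelihoods are computed uncapped.  Offsets are clipped to
  ±30 (the intercept MLE of a zero-spike neuron diverges) and flagged.
* E-step bookkeeping: the likelihood Hessian `X^T diag(rate) X` for each
  (neuron, cluster) pair is cached across EM sweeps and refreshed whenever
  Newton progress stalls or after three uses; the line search on the exact
  objective and the exact-gradient stopping rule make the cached matrix a
  speed device only.  The Laplace curvature at the accepted mode is always
  computed exactly.  Evidence weights are handled in the log domain
  throughout (they span hundreds of log-units across clusters).
* EM runs until the relative change of `Σ_i LL_i` falls below 1e−6 or 200
  E-step sweeps.  Because the within-cluster variances approach their
  optimum along a very slow, nearly-harmonic EM crawl, sweeps are
  extrapolated in SQUAREM fashion (two plain sweeps, then a squared
  extrapolation in (log π, μ, log Σ) space, kept only if it does not lower
  the surrogate).  The accelerated iteration has the same fixed points as
  the plain one; without it the variance estimates — and everything
  downstream of them, including BIC's evidence gaps — sit far from
  convergence at any affordable sweep budget.
* Variance floor 1e−8 on every diagonal covariance entry (both methods).
  A cluster whose total responsibility falls below 1e−8 is re-seeded at the
  mode of the worst-explained neuron with averaged variances; logged.
* Because the E-step is an approximation, the surrogate `Σ_i log Σ_k Z_{i,k}`
  is not theoretically guaranteed monotone; decreases beyond 1e−6
  (relative) are logged, not fatal.  In practice the trace is nondecreasing.
* Ties: cluster assignment argmaxes break to the lowest index; final
  cluster indices are ordered by descending `Σ_t μ_k^self(t)`.
* Restart seeds derive from one master seed via `SeedSequence`; the winning
  restart index is logged.  Reruns with the same seed are bit-identical.

## Scaled-down study protocol

Replicating the simulation study on one CPU uses reduced problem sizes,
chosen as the package's working defaults:

* Oracle hyperparameters (the λ values that best recover the true filters
  by RMS) are selected on 3 held-out oracle datasets with 4 neurons per
  cluster, scoring per-neuron GLM fits on a coarse λ grid
  {1e−6, 1e−4, 1e−2, 1}; the simultaneous method takes its λ^stim from the
  same scoring.  Running full EM per grid point would dominate the study's
  cost, and the held-out score surface is flat near its optimum.
* The method-comparison harness (`replicate-sim-study`) runs at "small"
  scale: 8 neurons per cluster, 2 × 1500 bins per neuron, 1 EM restart.
* K-recovery uses BIC over K ∈ {1..5} on datasets of 13 neurons per
  cluster at 2 × 3,000 bins each; both the neuron count and the recording
  length matter here (see Limitations).
* The pooling-effect measurement uses the study's population size (3 × 40
  neurons, σ = 1e−2) at 2 × 10,000 bins per neuron, 1 EM restart, and
  "spread" means the mean diagonal covariance entry — the within-cluster
  variance.  Pooling n spike trains shrinks the posterior variance of a
  cluster member's filter about n-fold, so the fold-ratio of saturating
  spreads between the two methods is expected near the per-cluster count.

## Known limitations

* The per-neuron estimation noise s² scales as 1/T. Quantities that compare
  s² against σ² — most visibly the saturating-spread fold-ratio, which is
  about `s²_seq / max(σ², converged Σ̂_sim)` — therefore depend on the
  recording length, and a reduced-length replicate need not reproduce the
  fold-ratio seen at full recording length even though the direction of
  every comparison is preserved.
* BIC-based K recovery is likewise scale-sensitive: the marginal-evidence
  gain from splitting two nearby clusters grows with recording length and
  scales linearly with the neuron count, while the penalty grows only
  logarithmically.  On strongly reduced data BIC genuinely — and correctly
  — prefers fewer clusters than the generator used, even when the
  fixed-K fit recovers the true labels almost perfectly.
* The variance-component MLE of a cluster coordinate whose true σ² is far
  below s²/n sits at (or crawls toward) the floor; the "saturating" spread
  of the simultaneous method is then governed by sampling fluctuations of
  the observed scatter, not by σ itself.
* The Laplace approximation is a single-mode Gaussian; for neurons with
  very few spikes the posterior over deep refractory coefficients is skewed
  and the diagonal-curvature variance understates it.
* `cvll_heldout` implements the basic held-out-neuron score only (no
  refitting protocol); it is labeled "basic" deliberately.
* Only the self-interaction filters define cell types; clustering stimulus
  filters or offsets is out of scope, as are coupling filters between
  neurons and alternative link functions or basis parameterizations.
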