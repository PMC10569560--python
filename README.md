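# spiketypes

Discovering **functional cell types** from spike-train data: neurons are
grouped by the parameters of a predictive model of their spiking, rather
than by morphology or transcriptome, so that the discovered types are by
construction the ones that matter for predicting responses.

Each neuron's response to an injected current is a Poisson GLM over 2 ms
bins,

    y_i(t) ~ Poisson( exp[ β_i^stim · x̃_i(t) + β_i^self · y_i(t−1:t−20) + β_i^0 ] ),

with a downsampled stimulus filter (100 ms), a self-interaction filter
(40 ms of spike history — the feature that defines a cell type), and an
offset.  Two estimators of the type structure are provided:

* **Sequential** — fit every neuron's GLM independently (l2-regularized,
  penalties chosen by cross-validation), then cluster the fitted
  self-interaction filters with a diagonal-covariance Gaussian mixture.
* **Simultaneous** — a hierarchical model in which the cluster label and
  the GLM parameters of every neuron are latent, fitted by EM with a
  per-(neuron, cluster) weighted-Gaussian (Laplace) approximation.  Each
  neuron's parameter estimate borrows strength from the rest of its
  cluster, which sharpens both the single-cell fits and the clustering.

Also included: BIC model selection over the number of types K (and the
stimulus prior precision λ^stim), held-out-neuron scores, evaluation
statistics (adjusted Rand score, filter RMS with the deep-coefficient
exclusion rule, per-bin negative log-likelihood, explained-variance ratio
on repeated stimulus presentations, metadata enrichment z-scores), and a
synthetic-data generator that emulates the simulation study: pink-noise
currents, mixture-sampled self-filters, generative Poisson rollouts with
runaway detection.

See `docs/methods.md` for the model, algorithms and numerical choices.

## Worked example

```python
import numpy as np
from spiketypes import (SimulationConfig, make_dataset, run_sequential,
                        fit_simultaneous, RegWeights, ars)

cfg = SimulationConfig(K=3, n_per_cluster=8, sigma=1e-2, T=3000, n_trials=2, seed=7)
ds, true_labels, true_params = make_dataset(cfg)   # 24 neurons, 6000 bins each

seq = run_sequential(ds, cfg.shape, K=3, seed=1, reg=RegWeights(1e-4, 1e-4))
sim = fit_simultaneous(ds, cfg.shape, K=3, lambda_stim=1e-4, n_restarts=1, seed=1)

print("sequential   ARS %.2f  spread %.4f" % (ars(seq.labels, true_labels),
                                              seq.omega.sigma_self.mean()))
print("simultaneous ARS %.2f  spread %.4f" % (ars(sim.labels, true_labels),
                                              sim.omega.sigma_self.mean()))
```

prints

```
sequential   ARS 0.49  spread 0.1018
simultaneous ARS 0.54  spread 0.0195
```

The adjusted Rand score (1 = perfect recovery of the generating clusters,
0 = chance) is higher for the simultaneous method, and its estimated
within-cluster variance ("spread", mean diagonal covariance entry) is
several-fold tighter: at this small within-cluster sd (σ = 0.01) the
sequential spread mostly reflects per-neuron estimation noise, which the
simultaneous method suppresses by pooling the spike trains of each cluster.

The same pipelines are available from a shell:

```bash
spiketypes simulate --K 3 --sigma 0.01 --seed 1 --out run/
spiketypes fit-simultaneous --data run/dataset --K 3 --seed 2 --out run/fit
spiketypes evaluate --fit run/fit --data run/dataset --seed 3 --out run/eval
spiketypes replicate-sim-study --reps 10 --scale small --seed 4 --out run/study
```

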