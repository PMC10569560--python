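import numpy as np
import pytest

from spiketypes import ModelShape, NeuronRecord, SimulationConfig, SpikeDataset, make_dataset


@pytest.fixture(scope="session")
def small_shape() -> ModelShape:
    """Reduced filter dimensions for fast unit tests."""
    return ModelShape(T_stim=3, T_self=4, d_stim=2)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 6-neuron, 2-cluster simulated dataset with ground truth (session-cached)."""
    cfg = SimulationConfig(K=2, n_per_cluster=3, sigma=1e-2, T=1200, n_trials=2, seed=42)
    ds, labels, params = make_dataset(cfg)
    return cfg, ds, labels, params


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_neuron(rng, T=60, neuron_id="n0", L=2, rate=0.2) -> NeuronRecord:
    edges = np.linspace(0, T, L + 1, dtype=int)
    return NeuronRecord(
        neuron_id=neuron_id,
        stimulus=rng.standard_normal(T),
        spikes=rng.poisson(rate, T),
        partitions=list(zip(edges[:-1], edges[1:])),
    )


@pytest.fixture
def toy_dataset(rng) -> SpikeDataset:
    return SpikeDataset(neurons=[make_neuron(rng, neuron_id=f"n{i}") for i in range(4)])
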