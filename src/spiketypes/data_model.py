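"""Core containers for spike-train datasets and fitted single-cell models.

A :class:`SpikeDataset` holds, for each neuron, a paired time series of
injected stimulus current ``x_i(t)`` and binned spike counts ``y_i(t)``
(2 ms bins by default), the trial/partition boundaries used for
cross-validation, and optional categorical metadata (e.g. transgenic line,
cortical layer).  All downstream fitting and evaluation code consumes only
these containers, never files.

Time indices are 1-based in the documentation (``t ∈ {1, …, T_i}``) and
0-based internally; partition ranges are stored as half-open
``[start, end)`` 0-based index pairs.  The conversion is owned entirely by
this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModelShape",
    "GLMParams",
    "NeuronRecord",
    "SpikeDataset",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "split_neuron_folds",
]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


@dataclass(frozen=True)
class ModelShape:
    """Dimensions of the single-cell GLM covariates.

    ``T_stim`` stimulus-filter taps (spaced ``d_stim`` bins apart on the
    box-prefiltered stimulus), ``T_self`` spike-history taps (one per bin),
    plus one offset.  Defaults correspond to filtering the last 100 ms of
    stimulus and 40 ms of spiking history at 2 ms bins.
    """

    T_stim: int = 10
    T_self: int = 20
    d_stim: int = 5

    def __post_init__(self) -> None:
        if self.T_stim < 1 or self.T_self < 1 or self.d_stim < 1:
            raise ValidationError("ModelShape dimensions must be positive")

    @property
    def dim(self) -> int:
        """Total parameter dimension ``T_stim + T_self + 1``."""
        return self.T_stim + self.T_self + 1


@dataclass(frozen=True)
class GLMParams:
    """One neuron's GLM parameter vector ``(beta_stim, beta_self, beta0)``.

    The flat concatenation order is ``[beta_stim, beta_self, beta0]``.
    """

    beta_stim: np.ndarray
    beta_self: np.ndarray
    beta0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_stim", np.asarray(self.beta_stim, dtype=float))
        object.__setattr__(self, "beta_self", np.asarray(self.beta_self, dtype=float))
        object.__setattr__(self, "beta0", float(self.beta0))
        if not (
            np.all(np.isfinite(self.beta_stim))
            and np.all(np.isfinite(self.beta_self))
            and np.isfinite(self.beta0)
        ):
            raise ValidationError("GLMParams entries must be finite")

    @property
    def flat(self) -> np.ndarray:
        return np.concatenate([self.beta_stim, self.beta_self, [self.beta0]])

    @classmethod
    def from_flat(cls, vec: np.ndarray, shape: ModelShape) -> "GLMParams":
        vec = np.asarray(vec, dtype=float)
        if vec.size != shape.dim:
            raise ValidationError(
                f"flat vector has length {vec.size}, expected {shape.dim}"
            )
        return cls(
            beta_stim=vec[: shape.T_stim],
            beta_self=vec[shape.T_stim : shape.T_stim + shape.T_self],
            beta0=float(vec[-1]),
        )


@dataclass
class NeuronRecord:
    """Stimulus/spike time series for one neuron.

    ``partitions`` lists ``L >= 1`` half-open ``[start, end)`` 0-based index
    ranges that are disjoint, ordered, contiguous and cover ``[0, T)``; they
    delimit trials (repeated stimulus presentations) and double as the
    cross-validation folds over time bins.
    """

    neuron_id: str
    stimulus: np.ndarray
    spikes: np.ndarray
    partitions: list[tuple[int, int]] = field(default_factory=list)
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stimulus = np.asarray(self.stimulus, dtype=float)
        self.spikes = np.asarray(self.spikes)
        if not self.partitions:
            self.partitions = [(0, len(self.spikes))]
        self.partitions = [(int(a), int(b)) for a, b in self.partitions]
        self.validate()
        self.spikes = self.spikes.astype(np.int64)

    @property
    def T(self) -> int:
        return len(self.spikes)

    @property
    def L(self) -> int:
        return len(self.partitions)

    def validate(self) -> None:
        nid = self.neuron_id
        if self.stimulus.ndim != 1 or self.spikes.ndim != 1:
            raise ValidationError(f"neuron {nid}: stimulus and spikes must be 1-D")
        if len(self.stimulus) != len(self.spikes):
            raise ValidationError(
                f"neuron {nid}: stimulus length {len(self.stimulus)} != "
                f"spikes length {len(self.spikes)}"
            )
        if len(self.spikes) < 1:
            raise ValidationError(f"neuron {nid}: empty time series")
        if not np.all(np.isfinite(self.stimulus)):
            raise ValidationError(f"neuron {nid}: non-finite stimulus values")
        spk = np.asarray(self.spikes, dtype=float)
        if np.any(spk < 0) or np.any(spk != np.round(spk)):
            raise ValidationError(f"neuron {nid}: spike counts must be nonnegative integers")
        if len(self.partitions) < 1:
            raise ValidationError(f"neuron {nid}: needs at least one partition")
        cursor = 0
        for start, end in self.partitions:
            if start != cursor or end <= start:
                raise ValidationError(
                    f"neuron {nid}: partitions must be ordered, disjoint and "
                    f"contiguous; got range [{start}, {end}) after index {cursor}"
                )
            cursor = end
        if cursor != self.T:
            raise ValidationError(
                f"neuron {nid}: partitions cover [0, {cursor}) but T={self.T}"
            )


@dataclass
class SpikeDataset:
    """A population of neurons recorded with a common bin width (seconds)."""

    neurons: list[NeuronRecord]
    bin_width: float = 0.002
    name: str = "dataset"

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValidationError("bin_width must be positive")
        ids = [n.neuron_id for n in self.neurons]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate neuron_id in dataset")

    @property
    def N(self) -> int:
        return len(self.neurons)

    def __iter__(self):
        return iter(self.neurons)

    def __getitem__(self, i: int) -> NeuronRecord:
        return self.neurons[i]

    def subset(self, indices, name: str | None = None) -> "SpikeDataset":
        """Dataset restricted to the given neuron positions (order preserved)."""
        return SpikeDataset(
            neurons=[self.neurons[i] for i in indices],
            bin_width=self.bin_width,
            name=name or self.name,
        )


# ---------------------------------------------------------------------------
# On-disk container: directory with one .npz per neuron (stimulus, spikes,
# partition boundaries), metadata.tsv in long format, and manifest.json with
# bin_width and neuron ordering.
# ---------------------------------------------------------------------------

def write_dataset(ds: SpikeDataset, path: str | Path) -> None:
    """Write a dataset to the documented directory container."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "name": ds.name,
        "bin_width": ds.bin_width,
        "neurons": [n.neuron_id for n in ds.neurons],
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    rows = []
    for n in ds.neurons:
        np.savez(
            path / f"{n.neuron_id}.npz",
            stimulus=n.stimulus,
            spikes=n.spikes,
            partitions=np.asarray(n.partitions, dtype=np.int64).reshape(-1, 2),
        )
        for attr, value in n.metadata.items():
            rows.append((n.neuron_id, attr, value))
    meta = pd.DataFrame(rows, columns=["neuron_id", "attribute", "value"])
    meta.to_csv(path / "metadata.tsv", sep="\t", index=False)


def read_dataset(path: str | Path) -> SpikeDataset:
    """Read and validate a dataset from the documented directory container."""
    path = Path(path)
    manifest_file = path / "manifest.json"
    if not manifest_file.exists():
        raise ValidationError(f"no manifest.json under {path}")
    manifest = json.loads(manifest_file.read_text())
    meta_file = path / "metadata.tsv"
    metadata: dict[str, dict[str, str]] = {}
    if meta_file.exists():
        meta = pd.read_csv(meta_file, sep="\t", dtype=str)
        for _, row in meta.iterrows():
            metadata.setdefault(row["neuron_id"], {})[row["attribute"]] = row["value"]
    neurons = []
    for nid in manifest["neurons"]:
        npz_file = path / f"{nid}.npz"
        if not npz_file.exists():
            raise ValidationError(f"missing array file for neuron {nid}")
        with np.load(npz_file) as arrs:
            for key in ("stimulus", "spikes", "partitions"):
                if key not in arrs:
                    raise ValidationError(f"neuron {nid}: missing array '{key}'")
            neurons.append(
                NeuronRecord(
                    neuron_id=nid,
                    stimulus=arrs["stimulus"],
                    spikes=arrs["spikes"],
                    partitions=[tuple(p) for p in arrs["partitions"]],
                    metadata=metadata.get(nid, {}),
                )
            )
    return SpikeDataset(neurons=neurons, bin_width=manifest["bin_width"], name=manifest["name"])


def split_neuron_folds(
    ds: SpikeDataset, n_folds: int, seed: int
) -> list[tuple[SpikeDataset, SpikeDataset]]:
    """Partition neurons into folds for held-out-neuron evaluation.

    Returns one ``(train, heldout)`` pair per fold.  Folds are disjoint,
    cover all neurons, have sizes differing by at most one, and are
    deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > ds.N:
        raise ValueError(f"n_folds={n_folds} exceeds N={ds.N}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(ds.N)
    folds = [sorted(order[f::n_folds].tolist()) for f in range(n_folds)]
    out = []
    for f, heldout_idx in enumerate(folds):
        train_idx = sorted(set(range(ds.N)) - set(heldout_idx))
        out.append(
            (
                ds.subset(train_idx, name=f"{ds.name}-fold{f}-train"),
                ds.subset(heldout_idx, name=f"{ds.name}-fold{f}-heldout"),
            )
        )
    return out
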