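"""The group block and the six-layer GroupNet architectures.

The group block is the architectural unit: L consecutive grouped 1-D
convolution layers — layer i's kernels split into N_i independent
partition units — followed by j pointwise (1x1) "cluster" convolution
layers that remix the feature maps across groups. A block is parameterised
as (L, N_1..N_L, j); the configuration written {2, 2, 2, 1} means two
grouped layers with 2 partitions each and one cluster layer.

For two consecutive layers with m and n kernels and an even G-way split,
the grouped second layer holds G * (m/G) * (n/G) * k weights against
m * n * k ungrouped — a reduction by exactly 1/G.

The full network has six layers: input (1 x 62) -> group block ->
max-pooling -> dropout -> fully-connected -> softmax. The LP variant ends
in a single 8-class softmax over label combinations; the BR variant is
three structurally identical subnetworks with disjoint parameters, one
2-class softmax head per disease.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .cohort import N_FEATURES, N_LABELS, N_LP_CLASSES
from .exceptions import ConfigError, ValidationError
from .losses import softmax
from .nnet import (
    Activation,
    Conv1d,
    Dense,
    Dropout,
    Flatten,
    MaxPool1d,
    Sequential,
)

VARIANTS = ("LP", "BR")


@dataclass
class GroupBlockSpec:
    """(L, N_i, j) parameterisation plus kernel counts and kernel size."""

    partitions: tuple[int, ...] = (2, 2)
    kernels_per_layer: tuple[int, ...] = (32, 32)
    cluster_layers: int = 1
    cluster_channels: int = 32
    kernel_size: int = 3

    def __post_init__(self) -> None:
        self.partitions = tuple(int(v) for v in self.partitions)
        self.kernels_per_layer = tuple(int(v) for v in self.kernels_per_layer)
        if len(self.partitions) < 1:
            raise ConfigError("group block needs at least one grouped layer")
        if len(self.kernels_per_layer) != len(self.partitions):
            raise ConfigError("kernels_per_layer must match partitions in length")
        if any(n < 1 for n in self.partitions):
            raise ConfigError("partition counts must be >= 1")
        if self.cluster_layers < 0:
            raise ConfigError("cluster_layers must be >= 0")
        if self.kernel_size % 2 != 1 or self.kernel_size < 1:
            raise ConfigError("kernel_size must be a positive odd integer")
        for i, (n_parts, channels) in enumerate(
            zip(self.partitions, self.kernels_per_layer), start=1
        ):
            if channels % n_parts != 0:
                raise ConfigError(
                    f"grouped layer {i}: {channels} kernels not divisible "
                    f"into {n_parts} partitions"
                )

    @property
    def L(self) -> int:
        """Number of consecutive grouped convolution layers."""
        return len(self.partitions)

    def describe(self) -> str:
        """The ``{L, N_1..N_L, j}`` notation for this block."""
        inner = ", ".join(str(v) for v in (self.L, *self.partitions, self.cluster_layers))
        return "{" + inner + "}"

    def to_dict(self) -> dict:
        return {
            "partitions": list(self.partitions),
            "kernels_per_layer": list(self.kernels_per_layer),
            "cluster_layers": self.cluster_layers,
            "cluster_channels": self.cluster_channels,
            "kernel_size": self.kernel_size,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroupBlockSpec":
        return cls(**d)


@dataclass
class NetworkSpec:
    """Architecture of one GroupNet: variant, block, and the tail layers."""

    variant: str = "BR"
    block: GroupBlockSpec = field(default_factory=GroupBlockSpec)
    pool_size: int = 2
    dropout_rate: float = 0.5
    fc_units: int = 64
    activation: str = "tanh"
    input_length: int = N_FEATURES

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigError(f"variant must be one of {VARIANTS}")
        if not 0 <= self.dropout_rate < 1:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.pool_size < 1:
            raise ConfigError("pool_size must be >= 1")
        if self.fc_units < 1:
            raise ConfigError("fc_units must be >= 1")
        if self.input_length // self.pool_size < 1:
            raise ConfigError("pooled length < 1: pool_size too large")

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "block": self.block.to_dict(),
            "pool_size": self.pool_size,
            "dropout_rate": self.dropout_rate,
            "fc_units": self.fc_units,
            "activation": self.activation,
            "input_length": self.input_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        d = dict(d)
        if "block" in d and isinstance(d["block"], dict):
            d["block"] = GroupBlockSpec.from_dict(d["block"])
        return cls(**d)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# parameter counting (convolution weights only, biases excluded)


def grouped_weight_count(m: int, n: int, kernel_size: int, groups: int) -> int:
    """Weights of the second of two consecutive layers under a G-way split.

    Each of the G partitions convolves m/G incoming channels with n/G
    kernels: G * (m/G) * (n/G) * kernel_size weights.
    """
    if m % groups or n % groups:
        raise ConfigError(f"kernel counts {m}, {n} not divisible by {groups} groups")
    return groups * (m // groups) * (n // groups) * kernel_size


def ungrouped_weight_count(m: int, n: int, kernel_size: int) -> int:
    """Weights of the same layer without grouping: m * n * kernel_size."""
    return m * n * kernel_size


def count_conv_params(spec: GroupBlockSpec, input_channels: int = 1) -> list[int]:
    """Per-layer convolution weight counts of a built block, biases excluded.

    A grouped layer on a single input channel cannot split channels, so
    its count is unaffected by its partition number; from the second layer
    on, each partition sees only its 1/N_i share of the channels.
    """
    counts = []
    in_ch = input_channels
    for n_parts, out_ch in zip(spec.partitions, spec.kernels_per_layer):
        group_in = in_ch if in_ch == 1 else in_ch // n_parts
        if in_ch > 1 and in_ch % n_parts != 0:
            raise ConfigError(f"{in_ch} channels not divisible into {n_parts} groups")
        counts.append(out_ch * group_in * spec.kernel_size)
        in_ch = out_ch
    for _ in range(spec.cluster_layers):
        counts.append(spec.cluster_channels * in_ch)
        in_ch = spec.cluster_channels
    return counts


# ---------------------------------------------------------------------------
# construction


def build_group_block(
    spec: GroupBlockSpec,
    input_channels: int = 1,
    activation: str = "tanh",
    rng: np.random.Generator | None = None,
) -> list:
    """Layer list of one group block: grouped convs then 1x1 cluster convs.

    Every convolution uses 'same' padding and stride 1, with the
    activation applied after it, so the sequence preserves length.
    """
    rng = rng or np.random.default_rng()
    layers: list = []
    in_ch = input_channels
    for i, (n_parts, out_ch) in enumerate(
        zip(spec.partitions, spec.kernels_per_layer), start=1
    ):
        layers.append(
            Conv1d(
                in_ch,
                out_ch,
                spec.kernel_size,
                groups=n_parts,
                rng=rng,
                name=f"grouped conv layer {i}",
            )
        )
        layers.append(Activation(activation))
        in_ch = out_ch
    for i in range(spec.cluster_layers):
        layers.append(
            Conv1d(in_ch, spec.cluster_channels, 1, groups=1, rng=rng,
                   name=f"cluster conv layer {i + 1}")
        )
        layers.append(Activation(activation))
        in_ch = spec.cluster_channels
    return layers


def _build_tail(
    spec: NetworkSpec, channels: int, n_out: int, rng: np.random.Generator
) -> list:
    pooled = spec.input_length // spec.pool_size
    return [
        MaxPool1d(spec.pool_size),
        Dropout(spec.dropout_rate, rng=rng),
        Flatten(),
        Dense(channels * pooled, spec.fc_units, rng=rng),
        Activation(spec.activation),
        Dense(spec.fc_units, n_out, rng=rng),
    ]


class GroupNetwork:
    """A built GroupNet: one softmax stack (LP) or three disjoint heads (BR).

    Holds the raw :class:`~groupnet.nnet.Sequential` stacks; prediction
    applies the softmax. Training lives in :mod:`groupnet.model`.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0) -> None:
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        block = spec.block
        out_ch = (
            block.cluster_channels if block.cluster_layers else block.kernels_per_layer[-1]
        )
        n_heads = 1 if spec.variant == "LP" else N_LABELS
        n_out = N_LP_CLASSES if spec.variant == "LP" else 2
        self.nets: list[Sequential] = []
        for _ in range(n_heads):
            layers = build_group_block(block, 1, spec.activation, rng)
            layers += _build_tail(spec, out_ch, n_out, rng)
            self.nets.append(Sequential(layers))

    # -- bookkeeping --------------------------------------------------

    @property
    def variant(self) -> str:
        return self.spec.variant

    def parameter_count(self) -> int:
        return sum(net.parameter_count() for net in self.nets)

    def config_hash(self) -> str:
        return self.spec.config_hash()

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        """Point every dropout layer at one shared generator (training)."""
        for net in self.nets:
            for layer in net.layers:
                if isinstance(layer, Dropout):
                    layer.rng = rng

    def summary(self) -> str:
        lines = [
            f"GroupNet {self.spec.variant} variant, "
            f"group block {self.spec.block.describe()}",
            f"kernels per grouped layer: {self.spec.block.kernels_per_layer}, "
            f"kernel size 1x{self.spec.block.kernel_size}",
            f"pool {self.spec.pool_size}, dropout {self.spec.dropout_rate}, "
            f"fc {self.spec.fc_units}, activation {self.spec.activation}",
            f"heads: {len(self.nets)}, total parameters: {self.parameter_count()}",
        ]
        return "\n".join(lines)

    # -- forward ------------------------------------------------------

    def _check_features(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2 or features.shape[1] != self.spec.input_length:
            raise ValidationError(
                f"expected (n, {self.spec.input_length}) features, "
                f"got {features.shape}"
            )
        return features

    def forward_logits(
        self, features: np.ndarray, train: bool = False
    ) -> list[np.ndarray]:
        """Per-head logits for a feature batch; (batch, 1, length) internally."""
        x = self._check_features(features)[:, None, :]
        return [net.forward(x, train=train) for net in self.nets]

    def predict(self, features: np.ndarray, batch_size: int = 2048) -> np.ndarray:
        """Class probabilities in inference mode (dropout off), batched.

        LP: (n, 8) softmax over label combinations. BR: (n, 3) per-disease
        positive-class probabilities (second unit of each 2-way softmax).
        """
        features = self._check_features(features)
        chunks = []
        for start in range(0, features.shape[0], batch_size):
            batch = features[start : start + batch_size]
            logits = self.forward_logits(batch, train=False)
            if self.spec.variant == "LP":
                chunks.append(softmax(logits[0]))
            else:
                chunks.append(
                    np.column_stack([softmax(lg)[:, 1] for lg in logits])
                )
        return np.concatenate(chunks, axis=0)

    # -- serialisation ------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for h, net in enumerate(self.nets):
            for k, v in net.state_arrays().items():
                out[f"net{h}.{k}"] = v
        return out

    def weights_checksum(self) -> str:
        digest = hashlib.sha256()
        arrays = self.state_arrays()
        for k in sorted(arrays):
            digest.update(k.encode())
            digest.update(np.ascontiguousarray(arrays[k]).tobytes())
        return digest.hexdigest()

    def save_weights(self, path) -> None:
        """Single-file weight dump with embedded config hash and checksum."""
        arrays = self.state_arrays()
        meta = {
            "config_hash": self.config_hash(),
            "checksum": self.weights_checksum(),
            "spec": self.spec.to_dict(),
        }
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        ), **arrays)

    @classmethod
    def load_weights(cls, path, expected_spec: NetworkSpec | None = None):
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        spec = NetworkSpec.from_dict(meta["spec"])
        if expected_spec is not None and expected_spec.config_hash() != spec.config_hash():
            raise ConfigError(
                "config-hash mismatch between weights file and network spec"
            )
        model = cls(spec, seed=0)
        for h, net in enumerate(model.nets):
            net.load_state_arrays(
                {k[len(f"net{h}.") :]: v for k, v in arrays.items()
                 if k.startswith(f"net{h}.")}
            )
        if model.weights_checksum() != meta["checksum"]:
            raise ConfigError("weights checksum mismatch: file corrupted or tampered")
        return model


def build_groupnet(spec: NetworkSpec, seed: int = 0) -> GroupNetwork:
    """Construct a GroupNet with seeded fan-in-uniform initial weights."""
    return GroupNetwork(spec, seed=seed)
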