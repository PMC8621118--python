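"""The seven 1D-CNN/GRU classifier variants for score prediction.

Two reusable heads feed a shared dense meta-learner:

* a 1D-CNN head — one convolution (64 filters, ReLU, same padding,
  stride 1), max-pool of size 2, flatten;
* a time-distributed GRU head — one GRU layer (64 units) emitting its
  state at every timestep, flattened, so long inputs are not compressed
  into a single fixed vector.

The meta-learner is a dense layer of 100 units, 50% dropout, and a
5-way softmax. Variants (by abbreviation):

====  =========================================================
C     single 1D-CNN head (kernel 3)
G     single GRU head
DC    double-head 1D-CNN (kernels 1 and 3)
TC    triple-head 1D-CNN (kernels 1, 3 and 5)
C-G   sequential: convolution + pool, then GRU over the pooled
      sequence (one graph, not two stages)
C+G   1D-CNN head and GRU head in parallel
DC+G  double-head 1D-CNN plus GRU head in parallel
====  =========================================================

All heads see the raw multichannel input (parallel variants) and the whole
graph — heads plus meta-learner — trains end-to-end under a single loss,
which is what the stacking-ensemble wiring amounts to here; there is no
out-of-fold meta-training stage. The GRU consumes the full 72-channel
sequence directly with hidden size 64 (no input projection).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    GRU,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    Network,
    ParallelConcat,
    Sequential,
)

__all__ = [
    "HeadSpec",
    "ModelSpec",
    "VARIANTS",
    "list_variants",
    "get_variant",
    "build_model",
    "feature_length",
    "count_parameters",
    "describe",
]


@dataclass(frozen=True)
class HeadSpec:
    """One feature-extraction head."""

    kind: str  # "conv" | "gru"
    kernel_size: int | None = None
    filters: int = 64
    units: int = 64
    pool_size: int = 2

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "gru"):
            raise ValueError(f"unknown head kind {self.kind!r}")
        if self.kind == "conv" and not self.kernel_size:
            raise ValueError("conv heads require kernel_size")


@dataclass(frozen=True)
class ModelSpec:
    """A full classifier: heads, wiring, and the dense meta-learner."""

    variant: str
    heads: tuple[HeadSpec, ...]
    sequential: bool = False  # True only for C-G (conv feeding the GRU)
    meta_dense_units: int = 100
    dropout_rate: float = 0.5
    output_units: int = 5

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        d["heads"] = tuple(HeadSpec(**h) for h in d["heads"])
        return cls(**d)


def _conv(k: int) -> HeadSpec:
    return HeadSpec(kind="conv", kernel_size=k)


_GRU = HeadSpec(kind="gru")

VARIANTS: dict[str, ModelSpec] = {
    "C": ModelSpec("C", (_conv(3),)),
    "G": ModelSpec("G", (_GRU,)),
    "DC": ModelSpec("DC", (_conv(1), _conv(3))),
    "TC": ModelSpec("TC", (_conv(1), _conv(3), _conv(5))),
    "C-G": ModelSpec("C-G", (_conv(3), _GRU), sequential=True),
    "C+G": ModelSpec("C+G", (_conv(3), _GRU)),
    "DC+G": ModelSpec("DC+G", (_conv(1), _conv(3), _GRU)),
}


def list_variants() -> list[ModelSpec]:
    """All seven catalogued variants, each buildable."""
    return list(VARIANTS.values())


def get_variant(name: str) -> ModelSpec:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
        ) from None


def _head_feature_length(head: HeadSpec, t: int) -> int:
    if head.kind == "conv":
        return (t // head.pool_size) * head.filters
    return t * head.units


def feature_length(spec: ModelSpec, input_shape: tuple[int, int]) -> int:
    """Length of the concatenated feature vector entering the meta-learner."""
    t, _ = input_shape
    if spec.sequential:
        conv, gru = spec.heads
        return (t // conv.pool_size) * gru.units
    return sum(_head_feature_length(h, t) for h in spec.heads)


def count_parameters(spec: ModelSpec, input_shape: tuple[int, int]) -> int:
    """Closed-form trainable-parameter count.

    Conventions: conv ``k*in*filters + filters``; GRU (single bias)
    ``3*(in*units + units^2 + units)``; dense ``in*out + out``.
    """
    t, channels = input_shape
    total = 0
    if spec.sequential:
        conv, gru = spec.heads
        total += conv.kernel_size * channels * conv.filters + conv.filters
        total += 3 * (conv.filters * gru.units + gru.units**2 + gru.units)
    else:
        for h in spec.heads:
            if h.kind == "conv":
                total += h.kernel_size * channels * h.filters + h.filters
            else:
                total += 3 * (channels * h.units + h.units**2 + h.units)
    feat = feature_length(spec, input_shape)
    total += feat * spec.meta_dense_units + spec.meta_dense_units
    total += spec.meta_dense_units * spec.output_units + spec.output_units
    return total


def build_model(
    spec: ModelSpec, input_shape: tuple[int, int], seed: int = 0
) -> Network:
    """Assemble a trainable network for inputs of ``(time, channels)``."""
    t, channels = input_shape
    for h in spec.heads:
        if h.kind == "conv" and t < h.pool_size:
            raise ValueError(f"time length {t} shorter than pool size {h.pool_size}")
    rng = np.random.default_rng(seed)

    def head_layers(h: HeadSpec, in_ch: int) -> list:
        if h.kind == "conv":
            return [Conv1D(in_ch, h.filters, h.kernel_size, rng), MaxPool1D(h.pool_size)]
        return [GRU(in_ch, h.units, rng)]

    if spec.sequential:
        conv, gru = spec.heads
        body: list = head_layers(conv, channels) + head_layers(gru, conv.filters) + [Flatten()]
        trunk_layers: list = body
    else:
        branches = [
            Sequential(head_layers(h, channels) + [Flatten()]) for h in spec.heads
        ]
        trunk_layers = [ParallelConcat(branches)]

    feat = feature_length(spec, input_shape)
    trunk_layers += [
        Dense(feat, spec.meta_dense_units, "relu", rng),
        Dropout(spec.dropout_rate, np.random.default_rng(rng.integers(2**31))),
        Dense(spec.meta_dense_units, spec.output_units, None, rng),
    ]
    return Network(Sequential(trunk_layers), spec.output_units)


def describe(spec: ModelSpec, input_shape: tuple[int, int]) -> str:
    """Human-readable summary: head shapes, feature length, parameter count."""
    t, channels = input_shape
    lines = [f"variant {spec.variant}  input ({t} x {channels})"]
    if spec.sequential:
        conv, gru = spec.heads
        lines.append(
            f"  conv k={conv.kernel_size} -> ({t} x {conv.filters}), "
            f"pool -> ({t // conv.pool_size} x {conv.filters}), "
            f"gru -> ({t // conv.pool_size} x {gru.units})"
        )
    else:
        for h in spec.heads:
            if h.kind == "conv":
                lines.append(
                    f"  conv head k={h.kernel_size}: ({t} x {h.filters}) "
                    f"-> pool ({t // h.pool_size} x {h.filters}) "
                    f"-> flat {_head_feature_length(h, t)}"
                )
            else:
                lines.append(
                    f"  gru head: ({t} x {h.units}) -> flat {_head_feature_length(h, t)}"
                )
    lines.append(f"  concat features: {feature_length(spec, input_shape):,}")
    lines.append(
        f"  meta: dense({spec.meta_dense_units}, relu) -> dropout({spec.dropout_rate}) "
        f"-> softmax({spec.output_units})"
    )
    lines.append(f"  trainable parameters: {count_parameters(spec, input_shape):,}")
    return "\n".join(lines)
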