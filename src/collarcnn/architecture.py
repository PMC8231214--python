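"""Declarative CNN architecture and exact complexity accounting.

The classifier is a stack of convolutional blocks (convolution with bias ->
dropout -> batch normalisation -> ReLU), a kernel-1 "expansion" block that
widens the feature map (64 -> 512 channels in the reference network),
adaptive average pooling to one value per channel, and a fully connected
head to the three behaviour classes.

Parameter counting convention (it reproduces the reference network's
170,563 / 11,923 / 1,063 totals exactly): conv weight + conv bias + two
trainable batch-norm parameters per channel (scale and shift; running
statistics excluded) per block, plus head weight + bias.

Operation counting reports multiply-accumulates (MACCs) for one forward
pass: per conv block, out_length x in_channels x kernel x out_channels, plus
in x out for the head; batch-norm, ReLU and pooling arithmetic excluded by
default. MACC totals depend on the stride/padding convention, which is
configurable and always reported alongside the count.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Sequence

import yaml

__all__ = [
    "ConvBlockSpec",
    "ArchitectureSpec",
    "Precision",
    "ComplexityReport",
    "build_model",
    "count_params",
    "count_macc",
    "memory_kb",
    "format_kb",
    "compression",
    "format_compression",
]


class SpecError(ValueError):
    """Architecture specification is internally inconsistent."""


class Precision(enum.Enum):
    """Storage precision for deployment accounting (bytes per parameter)."""

    FP32 = 4
    FP16 = 2

    @property
    def bytes_per_param(self) -> int:
        return self.value


@dataclass(frozen=True)
class ConvBlockSpec:
    out_channels: int
    kernel_size: int
    stride: int = 1

    def __post_init__(self):
        if min(self.out_channels, self.kernel_size, self.stride) < 1:
            raise SpecError("channels, kernel and stride must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    """The network as data: everything counting and pruning operate on."""

    conv_blocks: tuple[ConvBlockSpec, ...]
    in_channels: int = 3
    n_classes: int = 3
    dropout_p: float = 0.25

    def __post_init__(self):
        if not self.conv_blocks:
            raise SpecError("at least one conv block required")
        if not 0.0 <= self.dropout_p < 1.0:
            raise SpecError("dropout_p must be in [0, 1)")
        if self.in_channels < 1 or self.n_classes < 1:
            raise SpecError("in_channels and n_classes must be >= 1")

    @classmethod
    def default(
        cls,
        n_filters: int = 64,
        expansion: int = 512,
        n_feature_blocks: int = 3,
        kernel_size: int = 16,
        stride: int = 2,
        dropout_p: float = 0.25,
        n_classes: int = 3,
    ) -> "ArchitectureSpec":
        """Reference architecture: ``n_feature_blocks`` kernel-16 blocks of
        ``n_filters`` filters followed by a kernel-1 expansion block; the
        head input always equals the expansion width."""
        blocks = tuple(
            ConvBlockSpec(n_filters, kernel_size, stride) for _ in range(n_feature_blocks)
        ) + (ConvBlockSpec(expansion, 1, 1),)
        return cls(conv_blocks=blocks, dropout_p=dropout_p, n_classes=n_classes)

    @property
    def head_in_features(self) -> int:
        return self.conv_blocks[-1].out_channels

    def channel_chain(self) -> list[int]:
        return [self.in_channels] + [b.out_channels for b in self.conv_blocks]

    def with_filters(self, remaining: Sequence[int]) -> "ArchitectureSpec":
        """Same topology with new per-block channel counts (after pruning)."""
        if len(remaining) != len(self.conv_blocks):
            raise SpecError("one channel count per conv block required")
        blocks = tuple(
            replace(b, out_channels=int(c)) for b, c in zip(self.conv_blocks, remaining)
        )
        return replace(self, conv_blocks=blocks)

    def receptive_field(self) -> int:
        """Minimum input length accepted by the stacked valid convolutions."""
        length = 1
        for b in reversed(self.conv_blocks):
            length = (length - 1) * b.stride + b.kernel_size
        return length

    # -- YAML round trip -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "in_channels": self.in_channels,
            "n_classes": self.n_classes,
            "dropout_p": self.dropout_p,
            "conv_blocks": [
                {"out_channels": b.out_channels, "kernel_size": b.kernel_size, "stride": b.stride}
                for b in self.conv_blocks
            ],
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=False)

    @classmethod
    def from_dict(cls, data: dict) -> "ArchitectureSpec":
        return cls(
            conv_blocks=tuple(ConvBlockSpec(**b) for b in data["conv_blocks"]),
            in_channels=data.get("in_channels", 3),
            n_classes=data.get("n_classes", 3),
            dropout_p=data.get("dropout_p", 0.25),
        )

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureSpec":
        with open(path) as handle:
            return cls.from_dict(yaml.safe_load(handle))


def count_params(spec: ArchitectureSpec) -> int:
    """Trainable parameters: conv (in*out*k + out bias + 2*out batch-norm)
    per block, plus head (in*out + out bias)."""
    total = 0
    c_in = spec.in_channels
    for b in spec.conv_blocks:
        total += c_in * b.out_channels * b.kernel_size + b.out_channels  # conv w + b
        total += 2 * b.out_channels  # batch-norm scale + shift
        c_in = b.out_channels
    total += spec.head_in_features * spec.n_classes + spec.n_classes
    return total


def count_macc(
    spec: ArchitectureSpec, input_length: int, include_elementwise: bool = False
) -> int:
    """Multiply-accumulates for one forward pass at ``input_length`` samples.

    Valid padding, block strides as specified. With ``include_elementwise``
    the per-element batch-norm multiply and the pooling accumulation are
    added; the default counts conv and head MACCs only.
    """
    if input_length < spec.receptive_field():
        raise ValueError(
            f"input length {input_length} below receptive field {spec.receptive_field()}"
        )
    total = 0
    c_in = spec.in_channels
    length = input_length
    for b in spec.conv_blocks:
        length = (length - b.kernel_size) // b.stride + 1
        total += length * c_in * b.kernel_size * b.out_channels
        if include_elementwise:
            total += length * b.out_channels * 2  # batch-norm scale/shift
        c_in = b.out_channels
    if include_elementwise:
        total += length * c_in  # pooling accumulation
    total += spec.head_in_features * spec.n_classes
    return total


def memory_kb(n_params: int, precision: Precision) -> float:
    """Model size in KiB at ``bytes_per_param`` per parameter (exact float;
    use :func:`format_kb` for a 1-decimal display)."""
    if n_params < 0:
        raise ValueError("n_params must be >= 0")
    return n_params * precision.bytes_per_param / 1024.0


def format_kb(kb: float) -> float:
    """One-decimal display of a memory figure."""
    return round(kb, 1)


def compression(reference_params: int, pruned_params: int) -> float:
    """Parameter-count ratio of the reference to the reduced network."""
    if pruned_params <= 0:
        raise ValueError("pruned_params must be > 0")
    return reference_params / pruned_params


def format_compression(ratio: float) -> float:
    """Two-decimal display, truncating (14.305 -> 14.30)."""
    import math

    return math.floor(ratio * 100.0 + 1e-9) / 100.0


@dataclass
class ComplexityReport:
    """One deployment-table row for a spec, relative to a reference spec."""

    n_params: int
    n_macc: int
    memory_kb_fp32: float
    memory_kb_fp16: float
    compression: float | None = None
    speedup: float | None = None
    input_length: int | None = None

    @classmethod
    def for_spec(
        cls,
        spec: ArchitectureSpec,
        input_length: int,
        reference: ArchitectureSpec | None = None,
    ) -> "ComplexityReport":
        n = count_params(spec)
        macc = count_macc(spec, input_length)
        comp = speed = None
        if reference is not None:
            comp = compression(count_params(reference), n)
            speed = count_macc(reference, input_length) / macc
        return cls(
            n_params=n,
            n_macc=macc,
            memory_kb_fp32=memory_kb(n, Precision.FP32),
            memory_kb_fp16=memory_kb(n, Precision.FP16),
            compression=comp,
            speedup=speed,
            input_length=input_length,
        )

    def row(self) -> dict:
        return {
            "params": self.n_params,
            "compression": None if self.compression is None else format_compression(self.compression),
            "operations": self.n_macc,
            "speedup": None if self.speedup is None else round(self.speedup, 1),
            "memory_kb_fp32": format_kb(self.memory_kb_fp32),
            "memory_kb_fp16": format_kb(self.memory_kb_fp16),
            "input_length": self.input_length,
        }


def build_model(spec: ArchitectureSpec, seed: int = 0, dtype=None):
    """Instantiate the network for a spec with seeded fan-in uniform init.

    Block order: convolution -> dropout -> batch normalisation -> ReLU;
    then global average pooling and the linear head.
    """
    import numpy as np

    from .nn import BatchNorm1d, Conv1d, ConvNet, Dropout, GlobalAvgPool, Linear, ReLU

    dtype = dtype or np.float32
    rng = np.random.default_rng(seed)
    layers = []
    c_in = spec.in_channels
    for b in spec.conv_blocks:
        layers.append(Conv1d(c_in, b.out_channels, b.kernel_size, b.stride, rng=rng, dtype=dtype))
        layers.append(Dropout(spec.dropout_p))
        layers.append(BatchNorm1d(b.out_channels, dtype=dtype))
        layers.append(ReLU())
        c_in = b.out_channels
    layers.append(GlobalAvgPool())
    layers.append(Linear(spec.head_in_features, spec.n_classes, rng=rng, dtype=dtype))
    net = ConvNet(layers)
    net.spec = spec
    return net
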