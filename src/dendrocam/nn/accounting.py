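"""Analytic receptive-field and convolution parameter/cost accounting.

The receptive field after layer ``k`` of a stack of convolutions and
poolings grows as

    l_k = l_{k-1} + (f_k - 1) * prod_{i=1}^{k-1} s_i,     l_0 = 1

with kernel/pool size ``f_k`` and strides ``s_i``.  The parameter and
multiply-accumulate budgets of a standard convolution (kernel ``D_k``,
``M`` input channels, ``N_out`` output channels, feature map ``D_f``) are

    params = D_k^2 M N_out            cost = D_k^2 M N_out D_f^2

while the depthwise-separable substitute (one spatial filter per channel
followed by a 1x1 pointwise mix) needs

    params = D_k^2 M + M N_out        cost = (D_k^2 M + M N_out) D_f^2

i.e. a cost ratio of 1/N_out + 1/D_k^2 — the MobileNet compression
identity.  With D_k=3 and M=N_out=32 the per-block parameter count drops
from 9216 to 1312.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = [
    "ConvLayerSpec",
    "ConvAccounting",
    "receptive_field",
    "standard_conv_params",
    "separable_conv_params",
    "standard_conv_cost",
    "separable_conv_cost",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """One layer of a conv/pool stack: kernel (or pool) size and stride."""

    kernel_size: int
    stride: int = 1
    layer_kind: Literal["conv", "pool"] = "conv"

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError(
                f"kernel_size and stride must be >= 1, got "
                f"{self.kernel_size}, {self.stride}"
            )
        if self.layer_kind not in ("conv", "pool"):
            raise ValueError(f"layer_kind must be conv or pool, got {self.layer_kind}")


@dataclass(frozen=True)
class ConvAccounting:
    """Shape bookkeeping for one convolution: kernel D_k, channels M -> N_out,
    square feature map D_f."""

    kernel_size: int
    in_channels: int
    out_channels: int
    feature_map_size: int = 1

    def __post_init__(self) -> None:
        for name in ("kernel_size", "in_channels", "out_channels", "feature_map_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")


def receptive_field(layers: Sequence[ConvLayerSpec]) -> list[int]:
    """Cumulative receptive-field size after each layer of a stack.

    Returns one entry per layer; the stride product for layer ``k`` runs
    over layers ``1 .. k-1`` (the jump of one output pixel in input
    coordinates *before* layer k is applied).
    """
    if len(layers) == 0:
        raise ValueError("layer stack must be non-empty")
    sizes: list[int] = []
    l = 1
    jump = 1  # product of strides of all previous layers
    for spec in layers:
        l = l + (spec.kernel_size - 1) * jump
        sizes.append(l)
        jump *= spec.stride
    return sizes


def standard_conv_params(acc: ConvAccounting) -> int:
    """Trainable weights of a standard convolution, ``D_k^2 M N_out``."""
    return acc.kernel_size * acc.kernel_size * acc.in_channels * acc.out_channels


def separable_conv_params(acc: ConvAccounting) -> int:
    """Trainable weights of a depthwise-separable convolution,
    ``D_k^2 M + M N_out`` (depthwise plus 1x1 pointwise)."""
    dk, m, n = acc.kernel_size, acc.in_channels, acc.out_channels
    return dk * dk * m + m * n


def standard_conv_cost(acc: ConvAccounting) -> int:
    """Multiply-accumulates of a standard convolution over a D_f x D_f map."""
    return standard_conv_params(acc) * acc.feature_map_size**2


def separable_conv_cost(acc: ConvAccounting) -> int:
    """Multiply-accumulates of a separable convolution over a D_f x D_f map."""
    dk, m, n, df = (
        acc.kernel_size,
        acc.in_channels,
        acc.out_channels,
        acc.feature_map_size,
    )
    return dk * dk * m * df * df + m * n * df * df
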