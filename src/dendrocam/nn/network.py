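"""The lightweight attention U-net trunk segmenter.

Architecture: a U-net-like encoder/decoder in which every convolution is
depthwise-separable.  The contracting path repeats (separable 3x3 conv ->
ReLU -> 2x2 max-pool); a spatial attention module re-weights the feature
map after the third pooling stage (configurable), exploiting the
operating convention that the measured trunk sits in the middle of the
frame.  The expansive path mirrors it: nearest-neighbour 2x up-sampling,
an up-convolution, concatenation with the matching contracting feature
map, then two separable 3x3 convolutions with ReLU.  A final 1x1
convolution maps features to a single trunk-probability channel.

Channel schedule defaults to a constant 32 channels in and out of every
block — the compression setting M = N = 32 — with classic per-level
doubling available via ``double_channels``.

The network is fully convolutional: once built it accepts any input
whose spatial dimensions are divisible by ``pool_kernel ** levels``.
Images are expected as float RGB in [0, 1]; they are centred by
subtracting 0.5 before the first convolution.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np

from ..mask import SegmentationMask
from .accounting import ConvAccounting, separable_conv_params, standard_conv_params
from .layers import (
    MaxPool2x2,
    Parameter,
    PointwiseConv,
    ReLU,
    SeparableConv2d,
    SpatialAttention,
    UpsampleNearest2x,
    sigmoid,
)

__all__ = ["NetworkConfig", "TrunkSegmenter", "build_network", "predict_mask"]


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-parameters of the segmenter.

    ``attention_stage`` is the (1-based) pooling stage after which the
    spatial attention module is applied; the default 3 places it at the
    bottleneck of a 3-level network.
    """

    input_size: Tuple[int, int] = (128, 128)
    levels: int = 3
    channels: int = 32
    attention_stage: int = 3
    conv_kernel: int = 3
    pool_kernel: int = 2
    in_channels: int = 3
    attention_kernel: int = 7
    double_channels: bool = False
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.levels < 3:
            raise ValueError(f"levels must be >= 3, got {self.levels}")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        if self.pool_kernel != 2:
            raise ValueError("only 2x2 pooling is supported")
        if not (1 <= self.attention_stage <= self.levels):
            raise ValueError(
                f"attention_stage must be in [1, levels], got {self.attention_stage}"
            )
        factor = self.pool_kernel**self.levels
        h, w = self.input_size
        if h % factor or w % factor:
            raise ValueError(
                f"input size {h}x{w} not divisible by "
                f"pool_kernel**levels = {factor}"
            )

    def level_channels(self) -> List[int]:
        if self.double_channels:
            return [self.channels * 2**i for i in range(self.levels)]
        return [self.channels] * self.levels


class TrunkSegmenter:
    """Separable-convolution attention U-net over NHWC float32 arrays."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        ch = cfg.level_channels()
        L = cfg.levels
        k = cfg.conv_kernel

        self.enc_conv: List[SeparableConv2d] = []
        self.enc_relu: List[ReLU] = []
        self.pools: List[MaxPool2x2] = []
        prev = cfg.in_channels
        for i in range(L):
            self.enc_conv.append(SeparableConv2d(prev, ch[i], k, rng))
            self.enc_relu.append(ReLU())
            self.pools.append(MaxPool2x2())
            prev = ch[i]

        self.attention = SpatialAttention(cfg.attention_kernel, rng)

        self.ups: List[UpsampleNearest2x] = []
        self.up_conv: List[SeparableConv2d] = []
        self.up_relu: List[ReLU] = []
        self.dec_conv1: List[SeparableConv2d] = []
        self.dec_relu1: List[ReLU] = []
        self.dec_conv2: List[SeparableConv2d] = []
        self.dec_relu2: List[ReLU] = []
        for j in range(L):  # j indexes the level the decoder block restores
            below = ch[j + 1] if j + 1 < L else ch[L - 1]
            self.ups.append(UpsampleNearest2x())
            self.up_conv.append(SeparableConv2d(below, ch[j], k, rng))
            self.up_relu.append(ReLU())
            self.dec_conv1.append(SeparableConv2d(2 * ch[j], ch[j], k, rng))
            self.dec_relu1.append(ReLU())
            self.dec_conv2.append(SeparableConv2d(ch[j], ch[j], k, rng))
            self.dec_relu2.append(ReLU())

        self.final = PointwiseConv(ch[0], 1, rng, bias=True)
        self._skip_channels = ch

    # ---------------------------------------------------------------- params

    def parameters(self) -> List[Parameter]:
        params: List[Parameter] = []
        for i in range(self.cfg.levels):
            params += self.enc_conv[i].parameters()
        params += self.attention.parameters()
        for j in range(self.cfg.levels):
            params += self.up_conv[j].parameters()
            params += self.dec_conv1[j].parameters()
            params += self.dec_conv2[j].parameters()
        params += self.final.parameters()
        return params

    def count_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def expected_parameter_count(self) -> int:
        """Analytic parameter audit from the convolution accounting
        formulas: sum of separable-block counts plus the attention
        convolution and the final 1x1 classifier (the only two layers
        with bias terms)."""
        cfg = self.cfg
        ch = cfg.level_channels()
        k = cfg.conv_kernel
        L = cfg.levels

        def sep(m: int, n: int) -> int:
            return separable_conv_params(ConvAccounting(k, m, n))

        total = 0
        prev = cfg.in_channels
        for i in range(L):
            total += sep(prev, ch[i])
            prev = ch[i]
        total += standard_conv_params(ConvAccounting(cfg.attention_kernel, 2, 1)) + 1
        for j in range(L):
            below = ch[j + 1] if j + 1 < L else ch[L - 1]
            total += sep(below, ch[j]) + sep(2 * ch[j], ch[j]) + sep(ch[j], ch[j])
        total += standard_conv_params(ConvAccounting(1, ch[0], 1)) + 1
        return total

    # --------------------------------------------------------------- forward

    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[3] != self.cfg.in_channels:
            raise ValueError(
                f"expected NHWC input with {self.cfg.in_channels} channels, "
                f"got shape {x.shape}"
            )
        factor = self.cfg.pool_kernel**self.cfg.levels
        if x.shape[1] % factor or x.shape[2] % factor:
            raise ValueError(
                f"input spatial dims {x.shape[1]}x{x.shape[2]} not divisible "
                f"by {factor}"
            )

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logit map (N, H, W, 1) for a batch of [0,1] RGB images."""
        self._check_input(x)
        cur = np.ascontiguousarray(x, dtype=np.float32) - np.float32(0.5)
        L = self.cfg.levels
        self._skips: List[np.ndarray] = []
        for i in range(L):
            cur = self.enc_relu[i].forward(self.enc_conv[i].forward(cur, train), train)
            self._skips.append(cur)
            cur = self.pools[i].forward(cur, train)
            if i + 1 == self.cfg.attention_stage:
                cur = self.attention.forward(cur, train)
        for j in reversed(range(L)):
            cur = self.ups[j].forward(cur, train)
            cur = self.up_relu[j].forward(self.up_conv[j].forward(cur, train), train)
            cur = np.concatenate([cur, self._skips[j]], axis=3)
            cur = self.dec_relu1[j].forward(self.dec_conv1[j].forward(cur, train), train)
            cur = self.dec_relu2[j].forward(self.dec_conv2[j].forward(cur, train), train)
        out = self.final.forward(cur, train)
        if not train:
            self._skips = []
        return out

    def backward(self, grad: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(logits)."""
        L = self.cfg.levels
        ch = self._skip_channels
        cur = self.final.backward(grad)
        skip_grads: List[Optional[np.ndarray]] = [None] * L
        for j in range(L):
            cur = self.dec_conv2[j].backward(self.dec_relu2[j].backward(cur))
            cur = self.dec_conv1[j].backward(self.dec_relu1[j].backward(cur))
            skip_grads[j] = cur[..., ch[j] :]
            cur = self.up_conv[j].backward(self.up_relu[j].backward(cur[..., : ch[j]]))
            cur = self.ups[j].backward(cur)
        for i in reversed(range(L)):
            if i + 1 == self.cfg.attention_stage:
                cur = self.attention.backward(cur)
            cur = self.pools[i].backward(cur)
            cur = cur + skip_grads[i]
            cur = self.enc_conv[i].backward(self.enc_relu[i].backward(cur))
        self._skips = []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # ------------------------------------------------------------- inference

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Trunk probability map (H, W) for one [0,1] RGB image (H, W, 3)."""
        if image.ndim != 3:
            raise ValueError(f"expected one HWC image, got shape {image.shape}")
        logits = self.forward_logits(image[None], train=False)
        return sigmoid(logits[0, :, :, 0]).astype(np.float64)

    def predict_mask(
        self, image: np.ndarray, threshold: Optional[float] = None
    ) -> SegmentationMask:
        thr = self.cfg.threshold if threshold is None else threshold
        return SegmentationMask.from_probability(self.predict_proba(image), thr)

    # ----------------------------------------------------------- persistence

    def save(self, path: Union[str, Path]) -> None:
        """Checkpoint weights + config as a compressed npz."""
        arrays = {f"param_{i}": p.value for i, p in enumerate(self.parameters())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.cfg)).encode(), dtype=np.uint8
        )
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrunkSegmenter":
        with np.load(path) as data:
            cfg_dict = json.loads(bytes(data["config_json"].tobytes()).decode())
            cfg_dict["input_size"] = tuple(cfg_dict["input_size"])
            model = cls(NetworkConfig(**cfg_dict))
            for i, p in enumerate(model.parameters()):
                loaded = data[f"param_{i}"]
                if loaded.shape != p.value.shape:
                    raise ValueError(f"checkpoint shape mismatch at param {i}")
                p.value[...] = loaded
        return model


def build_network(cfg: NetworkConfig, seed: int = 0) -> TrunkSegmenter:
    """Construct the segmenter with seeded weight initialisation."""
    return TrunkSegmenter(cfg, seed=seed)


def predict_mask(
    model: TrunkSegmenter, image: np.ndarray, threshold: Optional[float] = None
) -> SegmentationMask:
    """Functional alias for :meth:`TrunkSegmenter.predict_mask`."""
    return model.predict_mask(image, threshold)
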