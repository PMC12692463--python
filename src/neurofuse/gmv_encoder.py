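"""Structural-pathway encoder: a 3-D residual CNN over gray-matter volumes.

Stem convolution, four cascaded stages of basic residual blocks (two 3×3×3
convolutions with batch norm, identity or projection shortcut), stride-2
downsampling at stages 2–4, global average pooling, and a linear projection
to the embedding z_gm.  No softmax is applied to the representation — the
embedding feeds a residual fusion stage and linear classifier heads that
need its unconstrained geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .nn import BatchNorm3d, Conv3d, Linear, Module

__all__ = ["GMVEncoderParams", "GMVEncoder", "BasicBlock3d",
           "expected_parameter_count"]


@dataclass
class GMVEncoderParams:
    """Channel schedule and depth of the four-stage 3-D ResNet.

    The compact default is sized for desk-scale volumes (16×20×16); the
    ``resnet18_3d`` preset ([2,2,2,2] blocks, [64,128,256,512] channels)
    targets full-size 121×145×121 images.
    """

    channels: tuple[int, ...] = (16, 32, 64, 128)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1, 1)
    d_out: int = 128
    stem_channels: int | None = None  # default: channels[0]
    stem_stride: int = 1

    def __post_init__(self):
        if len(self.channels) != 4 or len(self.blocks_per_stage) != 4:
            raise ValueError("the residual trunk has exactly four stages")
        if self.stem_channels is None:
            self.stem_channels = self.channels[0]

    @classmethod
    def resnet18_3d(cls, d_out: int = 128) -> "GMVEncoderParams":
        return cls(channels=(64, 128, 256, 512),
                   blocks_per_stage=(2, 2, 2, 2), d_out=d_out, stem_stride=2)


class BasicBlock3d(Module):
    """Two 3×3×3 conv + BN units with a shortcut connection.

    When the residual branch weights are zero the block reduces exactly to
    ReLU(shortcut(x)).
    """

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv3d(c_in, c_out, 3, rng, stride=stride, padding=1,
                            bias=False)
        self.bn1 = BatchNorm3d(c_out)
        self.conv2 = Conv3d(c_out, c_out, 3, rng, stride=1, padding=1,
                            bias=False)
        self.bn2 = BatchNorm3d(c_out)
        if stride != 1 or c_in != c_out:
            self.shortcut_conv = Conv3d(c_in, c_out, 1, rng, stride=stride,
                                        padding=0, bias=False)
            self.shortcut_bn = BatchNorm3d(c_out)
        else:
            self.shortcut_conv = None
            self.shortcut_bn = None

    def shortcut(self, x: Tensor) -> Tensor:
        if self.shortcut_conv is None:
            return x
        return self.shortcut_bn(self.shortcut_conv(x))

    def forward(self, x: Tensor) -> Tensor:
        r = self.bn1(self.conv1(x)).relu()
        r = self.bn2(self.conv2(r))
        return (r + self.shortcut(x)).relu()


class GMVEncoder(Module):
    def __init__(self, params: GMVEncoderParams, rng: np.random.Generator):
        super().__init__()
        self.params = params
        self.stem = Conv3d(1, params.stem_channels, 3, rng,
                           stride=params.stem_stride, padding=1, bias=False)
        self.stem_bn = BatchNorm3d(params.stem_channels)
        self.stages: list[list[BasicBlock3d]] = []
        c_in = params.stem_channels
        for stage_idx, (c_out, n_blocks) in enumerate(
                zip(params.channels, params.blocks_per_stage)):
            stride = 1 if stage_idx == 0 else 2
            blocks = []
            for b in range(n_blocks):
                blocks.append(BasicBlock3d(c_in, c_out,
                                           stride if b == 0 else 1, rng))
                c_in = c_out
            self.stages.append(blocks)
        self.proj = Linear(params.channels[-1], params.d_out, rng)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        if x.ndim != 5:
            raise ValueError(
                f"expected input of rank 5 (B,1,D,H,W), got rank {x.ndim}")
        h = self.stem_bn(self.stem(x)).relu()
        for blocks in self.stages:
            for block in blocks:
                h = block(h)
        pooled = h.mean(axis=(2, 3, 4))  # global adaptive average pool
        return self.proj(pooled)


def expected_parameter_count(params: GMVEncoderParams) -> int:
    """Closed-form parameter count for a configured encoder.

    Independent of the module tree: counts stem, per-block convolutions,
    batch-norm affine pairs, projection shortcuts, and the output head.
    """
    def conv(cin, cout, k):
        return cin * cout * k ** 3

    def bn(c):
        return 2 * c

    total = conv(1, params.stem_channels, 3) + bn(params.stem_channels)
    c_in = params.stem_channels
    for stage_idx, (c_out, n_blocks) in enumerate(
            zip(params.channels, params.blocks_per_stage)):
        stride = 1 if stage_idx == 0 else 2
        for b in range(n_blocks):
            s = stride if b == 0 else 1
            total += conv(c_in, c_out, 3) + bn(c_out)
            total += conv(c_out, c_out, 3) + bn(c_out)
            if s != 1 or c_in != c_out:
                total += conv(c_in, c_out, 1) + bn(c_out)
            c_in = c_out
    total += params.channels[-1] * params.d_out + params.d_out
    return total
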