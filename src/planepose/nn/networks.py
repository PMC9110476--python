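"""Backbone factories for the 9-parameter pose-regression head.

Two backbones are provided:

* ``smallconv`` — four conv/batchnorm/pool blocks feeding *separate*
  translation and rotation branches.  Small enough to train from scratch
  on a CPU.  The spatial layout is kept (flatten, not global pooling)
  because translation regression needs it, and the branches are split
  because with λ ≪ 1 the translation term contributes only a tiny share
  of the shared-trunk gradient: a dedicated branch lets the translation
  readout train at full adaptive rate from the shared conv features.
* ``resnet18`` — an 18-layer residual network (eight two-conv residual
  blocks between a stem conv and the fully connected output).

Both map ``(N, C, S, S)`` image batches to ``(N, 9)`` outputs
``(t1, t2, t3, r1..r6)``.  Final layers are initialised with shrunk
weights and (for the rotation part) an identity bias so an untrained
network starts at the neutral pose.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm2d,
    Conv2d,
    Flatten,
    GlobalAvgPool2d,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    ResidualBlock,
    Sequential,
)

__all__ = ["build_network", "BACKBONES", "IDENTITY_HEAD_BIAS", "TwoHeadNet"]

BACKBONES = ("smallconv", "resnet18")

#: Head bias for the neutral pose: zero translation, identity 6D rotation.
IDENTITY_HEAD_BIAS = np.array([0, 0, 0, 1, 0, 0, 0, 1, 0], dtype=np.float32)


class TwoHeadNet(Layer):
    """Shared trunk with separate translation (3) and rotation (6) branches."""

    def __init__(self, trunk: Layer, head_t: Layer, head_r: Layer):
        self.trunk, self.head_t, self.head_r = trunk, head_t, head_r

    def children(self) -> list[Layer]:
        return [self.trunk, self.head_t, self.head_r]

    def parameters(self):
        return (self.trunk.parameters() + self.head_t.parameters()
                + self.head_r.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.trunk.forward(x, train=train)
        t = self.head_t.forward(f, train=train)
        r = self.head_r.forward(f, train=train)
        return np.concatenate([t, r], axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        df = self.head_t.backward(dout[:, :3]) + self.head_r.backward(dout[:, 3:])
        return self.trunk.backward(df)


def _head_linear(nin: int, rng: np.random.Generator) -> Linear:
    head = Linear(nin, 9, rng=rng)
    head.w.value *= 0.1
    head.b.value[:] = IDENTITY_HEAD_BIAS
    return head


def _smallconv(image_size: int, in_channels: int, rng: np.random.Generator) -> TwoHeadNet:
    if image_size % 16 != 0:
        raise ValueError(f"smallconv needs image_size divisible by 16, got {image_size}")
    s = image_size // 16
    trunk = Sequential(
        Conv2d(in_channels, 24, rng=rng, bias=False), BatchNorm2d(24), ReLU(), MaxPool2d(),
        Conv2d(24, 48, rng=rng, bias=False), BatchNorm2d(48), ReLU(), MaxPool2d(),
        Conv2d(48, 96, rng=rng, bias=False), BatchNorm2d(96), ReLU(), MaxPool2d(),
        Conv2d(96, 192, rng=rng, bias=False), BatchNorm2d(192), ReLU(), MaxPool2d(),
        Flatten(),
    )
    nfeat = 192 * s * s
    t_out = Linear(256, 3, rng=rng)
    t_out.w.value *= 0.1
    head_t = Sequential(Linear(nfeat, 256, rng=rng), ReLU(), t_out)
    r_out = Linear(384, 6, rng=rng)
    r_out.w.value *= 0.1
    r_out.b.value[:] = IDENTITY_HEAD_BIAS[3:]
    head_r = Sequential(Linear(nfeat, 384, rng=rng), ReLU(), r_out)
    return TwoHeadNet(trunk, head_t, head_r)


def _resnet18(image_size: int, in_channels: int, rng: np.random.Generator) -> Sequential:
    if image_size % 16 != 0:
        raise ValueError(f"resnet18 needs image_size divisible by 16, got {image_size}")
    return Sequential(
        Conv2d(in_channels, 64, k=7, stride=2, pad=3, rng=rng, bias=False),
        BatchNorm2d(64), ReLU(), MaxPool2d(),
        ResidualBlock(64, 64, rng=rng), ResidualBlock(64, 64, rng=rng),
        ResidualBlock(64, 128, stride=2, rng=rng), ResidualBlock(128, 128, rng=rng),
        ResidualBlock(128, 256, stride=2, rng=rng), ResidualBlock(256, 256, rng=rng),
        ResidualBlock(256, 512, stride=2, rng=rng), ResidualBlock(512, 512, rng=rng),
        GlobalAvgPool2d(),
        _head_linear(512, rng),
    )


def build_network(
    backbone: str,
    image_size: int,
    in_channels: int = 1,
    rng: np.random.Generator | None = None,
) -> Layer:
    """Construct a backbone mapping image batches to 9-parameter outputs."""
    rng = rng or np.random.default_rng(0)
    if backbone == "smallconv":
        return _smallconv(image_size, in_channels, rng)
    if backbone == "resnet18":
        return _resnet18(image_size, in_channels, rng)
    raise ValueError(f"unknown backbone {backbone!r}; choose from {BACKBONES}")
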