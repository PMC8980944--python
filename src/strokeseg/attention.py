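"""Cross-spatial and channel attention modules used on the skip paths.

The cross-spatial attention module (CSAM) replaces a plain skip
connection: each side (encoder feature ``Fe``, decoder feature ``Fd``)
produces a spatial attention map from channel-wise average/max pooling,
a 3x3 convolution and a sigmoid; the maps then gate the *opposite*
feature, the original feature is added back as a residual, and the two
branches are concatenated along channels:

    M(F)       = sigmoid(conv3x3([avgpool_c(F); maxpool_c(F)]))
    Ss(Fe, Fd) = [ M(Fe) * Fd + Fd ; M(Fd) * Fe + Fe ]

The channel attention module (CAM) then gates the mixed feature channel
by channel, CBAM-style: global average and max pooling give two channel
descriptors, a shared two-layer perceptron maps both, and the sigmoid of
their sum rescales each channel:

    M(Ss) = sigmoid(MLP(avgpool(Ss)) + MLP(maxpool(Ss)));   Sc = M(Ss) * Ss

All operations accept a single ``C x H x W`` feature map or a batched
``N x C x H x W`` tensor.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, concat, relu, sigmoid

__all__ = [
    "SpatialGate", "CrossSpatialAttention", "ChannelAttention",
    "spatial_attention_map", "cross_spatial_attention",
    "channel_attention_weights", "channel_attention_apply",
]


def _batched(f):
    """Allow unbatched CxHxW arguments on batched NCHW modules."""
    def wrapper(self, *xs):
        xs = [as_tensor(x) for x in xs]
        unbatched = xs[0].ndim == 3
        if unbatched:
            xs = [x.reshape(1, *x.shape) for x in xs]
        out = f(self, *xs)
        if unbatched:
            out = out.reshape(*out.shape[1:])
        return out
    return wrapper


class SpatialGate(nn.Module):
    """Spatial attention map: channel pooling -> 3x3 conv -> sigmoid."""

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, 3, padding=1, bias=True, rng=rng)

    @_batched
    def forward(self, f: Tensor) -> Tensor:
        avg = f.mean(axis=1, keepdims=True)
        mx = f.max(axis=1, keepdims=True)
        return sigmoid(self.conv(concat([avg, mx], axis=1)))


class CrossSpatialAttention(nn.Module):
    """CSAM: each branch's map gates the other branch, with residuals.

    The two 3x3 attention convolutions are independent (encoder and
    decoder feature statistics differ), one per branch.
    """

    def __init__(self, rng: np.random.Generator):
        super().__init__()
        self.gate_enc = SpatialGate(rng)
        self.gate_dec = SpatialGate(rng)

    @_batched
    def forward(self, fe: Tensor, fd: Tensor) -> Tensor:
        if fe.shape != fd.shape:
            raise ValueError(
                f"cross_spatial_attention needs equal shapes, got {fe.shape} vs {fd.shape}")
        m_e = self.gate_enc(fe)
        m_d = self.gate_dec(fd)
        return concat([m_e * fd + fd, m_d * fe + fe], axis=1)


class ChannelAttention(nn.Module):
    """CAM: shared two-layer MLP over global avg/max descriptors."""

    def __init__(self, channels: int, reduction: int = 16, *,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 4)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(relu(self.fc1(v)))

    @_batched
    def weights(self, ss: Tensor) -> Tensor:
        avg = ss.mean(axis=(2, 3))
        mx = ss.max(axis=(2, 3))
        return sigmoid(self._mlp(avg) + self._mlp(mx))

    @_batched
    def forward(self, ss: Tensor) -> Tensor:
        w = self.weights(ss)
        n, c = ss.shape[0], ss.shape[1]
        return ss * w.reshape(n, c, 1, 1)


# ---------------------------------------------------------------------
# functional surface (used directly by tests and docs)
# ---------------------------------------------------------------------

def spatial_attention_map(f, gate: SpatialGate) -> Tensor:
    """Attention map of a single feature map under a given gate."""
    return gate(as_tensor(f))


def cross_spatial_attention(fe, fd, csam: CrossSpatialAttention) -> Tensor:
    return csam(as_tensor(fe), as_tensor(fd))


def channel_attention_weights(ss, cam: ChannelAttention) -> Tensor:
    return cam.weights(as_tensor(ss))


def channel_attention_apply(ss, w) -> Tensor:
    """Scale each channel of ``ss`` by its weight in ``w``."""
    ss, w = as_tensor(ss), as_tensor(w)
    unbatched = ss.ndim == 3
    if unbatched:
        ss = ss.reshape(1, *ss.shape)
    if w.ndim == 1:
        w = w.reshape(1, *w.shape)
    if w.shape[-1] != ss.shape[1]:
        raise ValueError(
            f"weight length {w.shape[-1]} != channel count {ss.shape[1]}")
    out = ss * w.reshape(w.shape[0], w.shape[-1], 1, 1)
    return out.reshape(*out.shape[1:]) if unbatched else out
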