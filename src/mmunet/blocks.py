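"""Computational building blocks of the segmentation network.

Three components recur throughout the architecture:

* :class:`ResidualConv` -- two 3x3 conv/BN/ReLU layers learning a residual,
  plus a 1x1 convolution aligning the input channel count for the
  element-wise addition.
* :class:`HybridAttention` -- a channel mask and a spatial mask, each built
  from average, max and *range* (max minus min) pooling and squashed through
  a sigmoid, multiplied onto the feature map one after the other.
* :class:`DilatedConvBlock` -- five parallel channel-preserving branches
  (1x1 conv; 3x3 convs at dilation rates 1, 3 and 2-stacked-twice; global
  average pooling broadcast back over the plane) concatenated and reduced
  by a final 1x1 convolution, so the output shape equals the input shape.

All blocks preserve spatial dimensions exactly; convolution padding is
chosen accordingly.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm2d, Conv2d, Linear, Module

HAB_ORDERS = ("channel_first", "spatial_first", "parallel")


class ResidualConv(Module):
    """conv3x3-BN-ReLU -> conv3x3-BN-ReLU, added to a 1x1-projected shortcut."""

    def __init__(self, in_ch: int, out_ch: int, *, rng: np.random.Generator, name: str = "rc"):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv1 = Conv2d(in_ch, out_ch, 3, pad=1, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(out_ch, name=f"{name}.bn1")
        self.conv2 = Conv2d(out_ch, out_ch, 3, pad=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_ch, name=f"{name}.bn2")
        self.shortcut = Conv2d(in_ch, out_ch, 1, pad=0, rng=rng, name=f"{name}.shortcut")

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        h = ad.relu(self.bn2(self.conv2(h)))
        return h + self.shortcut(x)


class PlainDoubleConv(Module):
    """conv3x3-BN-ReLU twice, no shortcut (decoder stages and bottleneck)."""

    def __init__(
        self, in_ch: int, mid_ch: int, out_ch: int, *, rng: np.random.Generator, name: str = "dc"
    ):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.conv1 = Conv2d(in_ch, mid_ch, 3, pad=1, rng=rng, name=f"{name}.conv1")
        self.bn1 = BatchNorm2d(mid_ch, name=f"{name}.bn1")
        self.conv2 = Conv2d(mid_ch, out_ch, 3, pad=1, rng=rng, name=f"{name}.conv2")
        self.bn2 = BatchNorm2d(out_ch, name=f"{name}.bn2")

    def __call__(self, x: Tensor) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x)))
        return ad.relu(self.bn2(self.conv2(h)))


def _channel_pools(f: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Per-channel average, max and range over the spatial plane -> (N, C)."""
    gap = f.mean(axis=(2, 3))
    gmp = f.max(axis=(2, 3))
    grp = gmp - f.min(axis=(2, 3))
    return gap, gmp, grp


def _spatial_pools(f: Tensor) -> Tensor:
    """Per-pixel average, max and range across channels -> (N, 3, H, W)."""
    gap = f.mean(axis=1, keepdims=True)
    gmp = f.max(axis=1, keepdims=True)
    grp = gmp - f.min(axis=1, keepdims=True)
    return ad.concat([gap, gmp, grp], axis=1)


class HybridAttention(Module):
    """Channel-space hybrid attention.

    The channel mask is ``sigmoid(MLP(GAP) + MLP(GMP) + MLP(GRP))`` with a
    single MLP (two linear layers around a ReLU, hidden width C/r) shared by
    the three pooled vectors.  The spatial mask concatenates the three
    per-pixel pooled maps and passes them through one 7x7 convolution and a
    sigmoid.  ``order`` selects how the two masks are applied:

    - ``channel_first`` (default): the spatial mask is computed on the
      channel-refined map and applied to it;
    - ``spatial_first``: the symmetric opposite;
    - ``parallel``: both masks are computed from the raw input and applied
      jointly.
    """

    def __init__(
        self,
        ch: int,
        *,
        reduction: int = 1,
        order: str = "channel_first",
        rng: np.random.Generator,
        name: str = "hab",
    ):
        if order not in HAB_ORDERS:
            raise ValueError(f"unknown attention order {order!r}; expected one of {HAB_ORDERS}")
        if ch % reduction:
            raise ValueError(f"channels {ch} not divisible by reduction {reduction}")
        self.ch = ch
        self.order = order
        hidden = ch // reduction
        self.fc1 = Linear(ch, hidden, rng=rng, name=f"{name}.fc1")
        self.fc2 = Linear(hidden, ch, rng=rng, name=f"{name}.fc2")
        self.spatial_conv = Conv2d(3, 1, 7, pad=3, rng=rng, name=f"{name}.spatial")

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(ad.relu(self.fc1(v)))

    def channel_mask(self, f: Tensor) -> Tensor:
        """(N, C) mask in (0, 1)."""
        gap, gmp, grp = _channel_pools(f)
        return ad.sigmoid(self._mlp(gap) + self._mlp(gmp) + self._mlp(grp))

    def spatial_mask(self, f: Tensor) -> Tensor:
        """(N, 1, H, W) mask in (0, 1)."""
        return ad.sigmoid(self.spatial_conv(_spatial_pools(f)))

    def _apply_channel(self, f: Tensor) -> Tensor:
        n, c = f.shape[0], f.shape[1]
        return f * self.channel_mask(f).reshape(n, c, 1, 1)

    def __call__(self, f: Tensor) -> Tensor:
        if self.order == "channel_first":
            g = self._apply_channel(f)
            return g * self.spatial_mask(g)
        if self.order == "spatial_first":
            g = f * self.spatial_mask(f)
            return self._apply_channel(g)
        # parallel: both masks from the raw input, applied jointly
        n, c = f.shape[0], f.shape[1]
        return f * self.channel_mask(f).reshape(n, c, 1, 1) * self.spatial_mask(f)


class DilatedConvBlock(Module):
    """Multi-rate dilated convolution block (channel- and shape-preserving).

    Branches (each C -> C, spatial size unchanged): 1x1 conv; 3x3 conv at
    dilation 1; 3x3 conv at dilation 3 (padding 3); two stacked 3x3 convs at
    dilation 2 (padding 2 each); global average pooling broadcast back over
    the plane.  The concatenated 5C channels are reduced to C by a final
    1x1 convolution.  The block is purely convolutional (no normalization
    or activation inside); the surrounding stages supply nonlinearity.
    """

    def __init__(self, ch: int, *, rng: np.random.Generator, name: str = "dcb"):
        self.ch = ch
        self.branch1 = Conv2d(ch, ch, 1, pad=0, rng=rng, name=f"{name}.b1")
        self.branch2 = Conv2d(ch, ch, 3, pad=1, dilation=1, rng=rng, name=f"{name}.b2")
        self.branch3 = Conv2d(ch, ch, 3, pad=3, dilation=3, rng=rng, name=f"{name}.b3")
        self.branch4a = Conv2d(ch, ch, 3, pad=2, dilation=2, rng=rng, name=f"{name}.b4a")
        self.branch4b = Conv2d(ch, ch, 3, pad=2, dilation=2, rng=rng, name=f"{name}.b4b")
        self.reduce = Conv2d(5 * ch, ch, 1, pad=0, rng=rng, name=f"{name}.reduce")

    def __call__(self, f: Tensor) -> Tensor:
        n, c, h, w = f.shape
        gap = f.mean(axis=(2, 3), keepdims=True).broadcast_to((n, c, h, w))
        branches = [
            self.branch1(f),
            self.branch2(f),
            self.branch3(f),
            self.branch4b(self.branch4a(f)),
            gap,
        ]
        return self.reduce(ad.concat(branches, axis=1))
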