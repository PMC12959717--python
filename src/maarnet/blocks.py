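"""Attention building blocks of the segmentation network.

Three components:

* :class:`DSCAM` — depthwise-separable channel attention.  The input is
  adaptively average-pooled to ``C x 2 x 2`` (rather than globally pooled,
  so a little spatial structure survives the squeeze), collapsed to
  ``C x 1 x 1`` by a per-channel 2x2 convolution, mixed across channels by a
  1x1 convolution (the depthwise step sees each channel in isolation, so
  this restores cross-channel correlation), batch-normalized and passed
  through a sigmoid.  The resulting per-channel weights in (0, 1) rescale
  the input.

* :class:`EnhancedBasicBlock` — a ResNet basic block whose main (two-conv)
  branch output is gated by DSCAM before the residual addition.  With an
  identity shortcut this is the stride-1, equal-width form; with a
  projection shortcut it downsamples and/or changes width.

* :class:`DSCBAM` — skip-connection attention running a channel branch
  (the DSCAM pipeline up to its pre-sigmoid logits) and a spatial branch
  (depthwise 3x3 -> pointwise to one channel -> BN) in parallel.  The two
  logit maps are broadcast-summed point-to-point and squashed by a single
  sigmoid, so the combined multiplier stays in (0, 1); no channel
  concatenation is involved.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor


def _check_spatial(x: Tensor) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected (N, C, H, W) input, got shape {x.shape}")
    _, _, h, w = x.shape
    if h < 2 or w < 2:
        raise ValueError(
            f"attention pooling needs height and width >= 2, got {h}x{w}")


class DSCAM(nn.Module):
    """Depthwise-separable channel attention (pool -> dw 2x2 -> pw 1x1 -> BN -> sigmoid)."""

    def __init__(self, channels: int, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.dw = nn.Conv2d(channels, channels, 2, groups=channels, bias=bias,
                            rng=rng)
        self.pw = nn.Conv2d(channels, channels, 1, bias=bias, rng=rng)
        self.bn = nn.BatchNorm2d(channels)

    def channel_logits(self, x: Tensor) -> Tensor:
        """Pre-sigmoid per-channel logits of shape (N, C, 1, 1)."""
        _check_spatial(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        squeezed = nn.adaptive_avg_pool2d(x, 2)      # (N, C, 2, 2)
        vec = self.dw(squeezed)                      # (N, C, 1, 1)
        vec = self.pw(vec)
        return self.bn(vec)

    def forward(self, x: Tensor) -> Tensor:
        weights = self.channel_logits(x).sigmoid()
        return x * weights


class EnhancedBasicBlock(nn.Module):
    """Residual basic block with channel attention on the main branch.

    ``stride == 1 and in_channels == out_channels`` gives the identity-shortcut
    form; any downsampling or width change switches to a 1x1 projection
    shortcut with matching stride.  ``attention=False`` reduces the block to
    the plain ResNet basic block.
    """

    def __init__(self, in_channels: int, out_channels: int, stride: int = 1,
                 attention: bool = True, bias: bool = False,
                 attention_bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = stride
        self.conv1 = nn.Conv2d(in_channels, out_channels, 3, stride=stride,
                               padding=1, bias=bias, rng=rng)
        self.bn1 = nn.BatchNorm2d(out_channels)
        self.conv2 = nn.Conv2d(out_channels, out_channels, 3, padding=1,
                               bias=bias, rng=rng)
        self.bn2 = nn.BatchNorm2d(out_channels)
        self.attention = DSCAM(out_channels, bias=attention_bias,
                               rng=rng) if attention else None
        self.projects = stride != 1 or in_channels != out_channels
        if self.projects:
            self.shortcut_conv = nn.Conv2d(in_channels, out_channels, 1,
                                           stride=stride, bias=bias, rng=rng)
            self.shortcut_bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}")
        main = nn.relu(self.bn1(self.conv1(x)))
        main = self.bn2(self.conv2(main))
        if self.attention is not None:
            main = self.attention(main)
        shortcut = self.shortcut_bn(self.shortcut_conv(x)) if self.projects else x
        return nn.relu(main + shortcut)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        return (self.out_channels, h // self.stride, w // self.stride)


class DSCBAM(nn.Module):
    """Parallel channel + spatial attention for skip connections."""

    def __init__(self, channels: int, spatial_kernel: int = 3,
                 bias: bool = False, rng: np.random.Generator | None = None):
        super().__init__()
        if spatial_kernel % 2 != 1:
            raise ValueError("spatial kernel size must be odd")
        self.channels = channels
        self.channel_branch = DSCAM(channels, bias=bias, rng=rng)
        self.spatial_dw = nn.Conv2d(channels, channels, spatial_kernel,
                                    padding=spatial_kernel // 2,
                                    groups=channels, bias=bias, rng=rng)
        self.spatial_pw = nn.Conv2d(channels, 1, 1, bias=bias, rng=rng)
        self.spatial_bn = nn.BatchNorm2d(1)

    def forward(self, x: Tensor) -> Tensor:
        _check_spatial(x)
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        channel_logits = self.channel_branch.channel_logits(x)  # (N, C, 1, 1)
        spatial = self.spatial_pw(self.spatial_dw(x))            # (N, 1, H, W)
        spatial_logits = self.spatial_bn(spatial)
        # point-to-point sum of the two logit maps, one sigmoid at the end:
        # the combined multiplier stays strictly inside (0, 1)
        weights = (channel_logits + spatial_logits).sigmoid()
        return x * weights
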