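"""Classic 4-level U-Net baseline, used as a profiling reference.

Encoder widths 64-1024, two 3x3 conv + BN + ReLU per level, 2x2 max-pool
downsampling, transposed-conv (k=2, s=2) upsampling with channel
concatenation, and a single-channel 1x1 output head for the binary
vessel-vs-background task.  All convolutions carry biases.

The baseline exists to anchor the parameter/MAC accounting against a
universally known architecture; it is profiled and cross-checked, not
trained, in this package.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .autograd import Tensor, concat


class _DoubleConv(nn.Module):
    def __init__(self, cin: int, cout: int, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, padding=1, bias=True, rng=rng)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, padding=1, bias=True, rng=rng)
        self.bn2 = nn.BatchNorm2d(cout)

    def forward(self, x: Tensor) -> Tensor:
        x = nn.relu(self.bn1(self.conv1(x)))
        return nn.relu(self.bn2(self.conv2(x)))


class UNet(nn.Module):
    """The standard U-Net with widths (64, 128, 256, 512, 1024)."""

    def __init__(self, in_channels: int = 3, out_channels: int = 1,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        widths = [64, 128, 256, 512, 1024]
        self.inc = _DoubleConv(in_channels, widths[0], rng)
        self.pool = nn.MaxPool2d(2)
        self.down1 = _DoubleConv(widths[0], widths[1], rng)
        self.down2 = _DoubleConv(widths[1], widths[2], rng)
        self.down3 = _DoubleConv(widths[2], widths[3], rng)
        self.down4 = _DoubleConv(widths[3], widths[4], rng)
        self.up1 = nn.ConvTranspose2d(widths[4], widths[3], 2, stride=2, rng=rng)
        self.dec1 = _DoubleConv(widths[4], widths[3], rng)
        self.up2 = nn.ConvTranspose2d(widths[3], widths[2], 2, stride=2, rng=rng)
        self.dec2 = _DoubleConv(widths[3], widths[2], rng)
        self.up3 = nn.ConvTranspose2d(widths[2], widths[1], 2, stride=2, rng=rng)
        self.dec3 = _DoubleConv(widths[2], widths[1], rng)
        self.up4 = nn.ConvTranspose2d(widths[1], widths[0], 2, stride=2, rng=rng)
        self.dec4 = _DoubleConv(widths[1], widths[0], rng)
        self.head = nn.Conv2d(widths[0], out_channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x1 = self.inc(x)
        x2 = self.down1(self.pool(x1))
        x3 = self.down2(self.pool(x2))
        x4 = self.down3(self.pool(x3))
        x5 = self.down4(self.pool(x4))
        y = self.dec1(concat([self.up1(x5), x4], axis=1))
        y = self.dec2(concat([self.up2(y), x3], axis=1))
        y = self.dec3(concat([self.up3(y), x2], axis=1))
        y = self.dec4(concat([self.up4(y), x1], axis=1))
        return self.head(y)
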