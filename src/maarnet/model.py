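"""Assembly of the attention-assisted residual segmentation network.

The network is a U-shaped encoder-decoder:

* **Encoder** — a 3x3 stride-2 stem followed by four stages of residual
  basic blocks with channel attention, producing feature maps at 1/2, 1/4,
  1/8 and 1/16 of the input resolution (widths 64/128/256/512).
* **High-semantic layer** (optional) — one projection block downsamples to
  1/32 at width ``high_semantic_width``; global average pooling of that map
  yields a context vector which, passed through a two-layer 1x1 bottleneck,
  is broadcast-added back onto the map to enlarge the effective receptive
  field.  When disabled, a parameter-free 2x2 max-pool provides the 1/32
  pyramid entry.
* **Skip attention** (optional) — parallel channel+spatial attention
  (:class:`~maarnet.blocks.DSCBAM`) gates every skip-bound map.
* **Decoder** — repeated bilinear 2x upsampling, 1x1 channel-matching
  convolution, elementwise **addition** with the attended skip map, and a
  3x3 refinement convolution.  No transposed convolutions are used.
* **Auxiliary branch** (training only) — the five pyramid maps plus the
  final decoder feature map are resized to input resolution, concatenated,
  and compressed to class logits by one 1x1 convolution; it contributes an
  extra loss term during training and nothing at inference.

The default :class:`NetworkConfig` is the reference configuration whose
parameter and multiply-accumulate budgets the profiling module reproduces;
its widths (including the decoder refinement widths and the context
bottleneck) are calibrated against those budgets and should be treated as
part of the model definition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .autograd import Tensor, concat
from .blocks import DSCBAM, EnhancedBasicBlock

STRIDES = (2, 4, 8, 16, 32)


@dataclass
class NetworkConfig:
    """Structural hyperparameters of the segmentation network."""

    input_channels: int = 3
    num_classes: int = 2
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    stage_blocks: tuple[int, ...] = (2, 3, 2, 2)
    high_semantic_width: int = 896
    context_width: int = 344          # bottleneck of the global-context head
    decoder_widths: tuple[int, ...] = (69, 262, 198, 69)  # refine widths at 1/16..1/2
    final_width: int = 64             # full-resolution refinement width
    spatial_kernel: int = 3           # DSCBAM spatial-branch kernel
    enable_high_semantic: bool = True
    enable_skip_attention: bool = True
    enable_aux: bool = True

    def __post_init__(self):
        self.stage_widths = tuple(self.stage_widths)
        self.stage_blocks = tuple(self.stage_blocks)
        self.decoder_widths = tuple(self.decoder_widths)
        if len(self.stage_widths) != 4 or len(self.stage_blocks) != 4:
            raise ValueError("expected 4 encoder stages (scales 1/2 .. 1/16)")
        if len(self.decoder_widths) != 4:
            raise ValueError("expected 4 decoder refine widths (1/16 .. 1/2)")
        if any(w <= 0 for w in self.stage_widths + self.decoder_widths):
            raise ValueError("widths must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("stage_widths", "stage_blocks", "decoder_widths"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Feature maps at output strides 2..32 plus the pooled context vector."""

    maps: dict[int, Tensor]
    global_context: Tensor | None = None

    def __getitem__(self, stride: int) -> Tensor:
        return self.maps[stride]


@dataclass
class SegmentationOutput:
    logits: Tensor
    aux_logits: Tensor | None = None


class _ConvBNReLU(nn.Module):
    def __init__(self, cin, cout, k, stride=1, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, padding=k // 2,
                              bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def forward(self, x):
        return nn.relu(self.bn(self.conv(x)))


class _ContextHead(nn.Module):
    """Global-context enrichment: GAP -> 1x1 reduce -> ReLU -> 1x1 expand."""

    def __init__(self, channels: int, hidden: int, rng=None):
        super().__init__()
        self.reduce = nn.Conv2d(channels, hidden, 1, bias=False, rng=rng)
        self.expand = nn.Conv2d(hidden, channels, 1, bias=False, rng=rng)

    def forward(self, pooled: Tensor) -> Tensor:
        return self.expand(nn.relu(self.reduce(pooled)))


class MAARNet(nn.Module):
    """Multiscale attention-assisted residual segmentation network."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = cfg = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        w1, w2, w3, w4 = cfg.stage_widths
        b1, b2, b3, b4 = cfg.stage_blocks

        self.stem = _ConvBNReLU(cfg.input_channels, w1, 3, stride=2, rng=rng)
        def stage(cin, cout, nblocks, downsample):
            blocks = []
            for i in range(nblocks):
                stride = 2 if (downsample and i == 0) else 1
                blocks.append(EnhancedBasicBlock(
                    cin if i == 0 else cout, cout, stride=stride, rng=rng))
            return nn.Sequential(*blocks)
        self.stage1 = stage(w1, w1, b1, downsample=False)   # 1/2
        self.stage2 = stage(w1, w2, b2, downsample=True)    # 1/4
        self.stage3 = stage(w2, w3, b3, downsample=True)    # 1/8
        self.stage4 = stage(w3, w4, b4, downsample=True)    # 1/16

        if cfg.enable_high_semantic:
            whs = cfg.high_semantic_width
            self.high_semantic = EnhancedBasicBlock(w4, whs, stride=2, rng=rng)
            self.context = _ContextHead(whs, cfg.context_width, rng=rng)
            deep_width = whs
        else:
            self.reduce32 = nn.MaxPool2d(2)
            deep_width = w4

        if cfg.enable_skip_attention:
            self.att2 = DSCBAM(w1, cfg.spatial_kernel, rng=rng)
            self.att4 = DSCBAM(w2, cfg.spatial_kernel, rng=rng)
            self.att8 = DSCBAM(w3, cfg.spatial_kernel, rng=rng)
            self.att16 = DSCBAM(w4, cfg.spatial_kernel, rng=rng)
            if cfg.enable_high_semantic:
                self.att32 = DSCBAM(deep_width, cfg.spatial_kernel, rng=rng)

        d16, d8, d4, d2 = cfg.decoder_widths
        if cfg.enable_high_semantic:
            # deepest decoder level: 1/32 -> 1/16 (projection + refinement)
            self.proj16 = _ConvBNReLU(deep_width, w4, 1, rng=rng)
            self.refine16 = _ConvBNReLU(w4, d16, 3, rng=rng)
            prev = d16
        else:
            prev = w4  # parameter-free fusion of the pooled 1/32 map
        self.proj8 = _ConvBNReLU(prev, w3, 1, rng=rng)
        self.refine8 = _ConvBNReLU(w3, d8, 3, rng=rng)
        self.proj4 = _ConvBNReLU(d8, w2, 1, rng=rng)
        self.refine4 = _ConvBNReLU(w2, d4, 3, rng=rng)
        self.proj2 = _ConvBNReLU(d4, w1, 1, rng=rng)
        self.refine2 = _ConvBNReLU(w1, d2, 3, rng=rng)
        self.final_refine = _ConvBNReLU(d2, cfg.final_width, 3, rng=rng)
        self.head = nn.Conv2d(cfg.final_width, cfg.num_classes, 1, bias=True,
                              rng=rng)

        if cfg.enable_aux:
            aux_in = w1 + w2 + w3 + w4 + deep_width + cfg.final_width
            self.aux_head = nn.Conv2d(aux_in, cfg.num_classes, 1, bias=True,
                                      rng=rng)

    # -- stages -----------------------------------------------------------
    @staticmethod
    def _check_input(x: Tensor) -> None:
        _, _, h, w = x.shape
        if h % 32 or w % 32:
            pad_h, pad_w = (-h) % 32, (-w) % 32
            raise ValueError(
                f"input {h}x{w} not divisible by 32; pad by ({pad_h}, {pad_w})")

    def encode(self, x: Tensor) -> FeaturePyramid:
        self._check_input(x)
        p2 = self.stage1(self.stem(x))
        p4 = self.stage2(p2)
        p8 = self.stage3(p4)
        p16 = self.stage4(p8)
        if self.config.enable_high_semantic:
            p32 = self.high_semantic(p16)
            pooled = nn.adaptive_avg_pool2d(p32, 1)        # (N, whs, 1, 1)
            p32 = p32 + self.context(pooled)               # broadcast enrichment
            context = pooled
        else:
            p32 = self.reduce32(p16)
            context = nn.adaptive_avg_pool2d(p32, 1)
        return FeaturePyramid(maps={2: p2, 4: p4, 8: p8, 16: p16, 32: p32},
                              global_context=context)

    def attend_skips(self, pyramid: FeaturePyramid) -> FeaturePyramid:
        if not self.config.enable_skip_attention:
            return pyramid
        maps = {
            2: self.att2(pyramid[2]),
            4: self.att4(pyramid[4]),
            8: self.att8(pyramid[8]),
            16: self.att16(pyramid[16]),
            32: self.att32(pyramid[32]) if self.config.enable_high_semantic
                else pyramid[32],
        }
        return FeaturePyramid(maps=maps, global_context=pyramid.global_context)

    @staticmethod
    def _up2(x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return nn.bilinear_resize(x, (2 * h, 2 * w))

    def decode(self, pyramid: FeaturePyramid,
               return_features: bool = False):
        for s in STRIDES:
            if s not in pyramid.maps:
                raise ValueError(f"pyramid is missing the stride-{s} map")
        if self.config.enable_high_semantic:
            x = self.proj16(self._up2(pyramid[32])) + pyramid[16]
            x = self.refine16(x)
        else:
            x = self._up2(pyramid[32]) + pyramid[16]
        x = self.refine8(self.proj8(self._up2(x)) + pyramid[8])
        x = self.refine4(self.proj4(self._up2(x)) + pyramid[4])
        x = self.refine2(self.proj2(self._up2(x)) + pyramid[2])
        feats = self.final_refine(self._up2(x))
        logits = self.head(feats)
        return (logits, feats) if return_features else logits

    def aux_branch(self, pyramid: FeaturePyramid,
                   final_features: Tensor) -> Tensor:
        if not self.training:
            raise RuntimeError("auxiliary branch is a training-only head")
        if not self.config.enable_aux:
            raise RuntimeError("auxiliary branch is disabled in this config")
        _, _, h, w = final_features.shape
        stack = [nn.bilinear_resize(pyramid[s], (h, w)) for s in STRIDES]
        stack.append(final_features)
        return self.aux_head(concat(stack, axis=1))

    def forward(self, x: Tensor) -> SegmentationOutput:
        pyramid = self.attend_skips(self.encode(x))
        logits, feats = self.decode(pyramid, return_features=True)
        aux = None
        if self.training and self.config.enable_aux:
            aux = self.aux_branch(pyramid, feats)
        return SegmentationOutput(logits=logits, aux_logits=aux)
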