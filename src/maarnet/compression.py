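"""Model compression: structured channel pruning, conv-BN fusion, INT8 PTQ.

Pruning
-------
Whole output channels are removed from selected convolutions (a dense
rebuild, not masking), ranked per layer by the L2 norm of each filter
slice.  Layers are chosen deepest-first — feature layers farthest from the
input influence the output least, so they are pruned with priority — and
only layers whose width is structurally free are touched: the first 3x3
convolution inside each residual block (its output feeds only the block's
own BN and second convolution) and the decoder refinement convolutions
(consumed only by the next projection).  Channels tied across residual
additions or skip fusions are never pruned.

Fusion and quantization
-----------------------
For deployment, each conv+BN pair is folded into a single biased
convolution (``W' = W * g / sqrt(var + eps)``, ``b' = (b - mu) * g /
sqrt(var + eps) + beta``), then post-training static quantization converts
the compute-bearing convolutions to INT8: weights symmetric per output
channel (``scale_c = max|w_c| / 127``), activations per-tensor affine with
a zero point, calibrated from min/max statistics recorded on a calibration
set (drawn from the training data).  At inference each quantized convolution
quantizes its input, accumulates in integer arithmetic and dequantizes its
output; the operations between convolutions (attention gates, resizing,
additions) stay in floating point.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .autograd import Tensor
from .blocks import DSCAM, DSCBAM, EnhancedBasicBlock
from .model import MAARNet, _ContextHead, _ConvBNReLU

__all__ = [
    "channel_importance_l2", "PruningPlan", "build_prune_plan", "apply_prune",
    "fuse_conv_bn", "fuse_model", "QuantSpec", "quantize_array",
    "dequantize_array", "QuantizedConv2d", "calibrate_and_quantize",
    "conv_weight_bytes",
]


# ---------------------------------------------------------------------------
# structured pruning
# ---------------------------------------------------------------------------

def channel_importance_l2(conv_weights: np.ndarray) -> np.ndarray:
    """Output-channel indices sorted by descending filter L2 norm.

    Ties break toward the lower index (stable sort on the negated norms).
    """
    w = np.asarray(conv_weights)
    if w.ndim != 4:
        raise ValueError("expected (C_out, C_in/g, kh, kw) weights")
    norms = np.sqrt((w.astype(np.float64) ** 2).sum(axis=(1, 2, 3)))
    return np.argsort(-norms, kind="stable")


@dataclass
class PruningPlan:
    """Per-layer kept-channel indices, deepest layer first."""

    keep_ratio: float
    entries: list[tuple[str, np.ndarray]] = field(default_factory=list)

    def layer_names(self) -> list[str]:
        return [name for name, _ in self.entries]


def _prunable_sites(model: MAARNet) -> list[dict]:
    """Structurally free conv sites in topological (input-to-output) order.

    Each site: the pruned conv, its BN, and the consumer convs whose input
    channels must be remapped.
    """
    sites: list[dict] = []

    def block_sites(prefix: str, seq: nn.Sequential):
        for i, blk in enumerate(seq.mods):
            sites.append({
                "name": f"{prefix}.{i}.conv1",
                "conv": blk.conv1, "bn": blk.bn1, "consumers": [blk.conv2],
            })

    block_sites("stage1", model.stage1)
    block_sites("stage2", model.stage2)
    block_sites("stage3", model.stage3)
    block_sites("stage4", model.stage4)
    cfg = model.config
    if cfg.enable_high_semantic:
        hs = model.high_semantic
        sites.append({"name": "high_semantic.conv1", "conv": hs.conv1,
                      "bn": hs.bn1, "consumers": [hs.conv2]})
        sites.append({"name": "refine16", "conv": model.refine16.conv,
                      "bn": model.refine16.bn, "consumers": [model.proj8.conv]})
    sites.append({"name": "refine8", "conv": model.refine8.conv,
                  "bn": model.refine8.bn, "consumers": [model.proj4.conv]})
    sites.append({"name": "refine4", "conv": model.refine4.conv,
                  "bn": model.refine4.bn, "consumers": [model.proj2.conv]})
    sites.append({"name": "refine2", "conv": model.refine2.conv,
                  "bn": model.refine2.bn, "consumers": [model.final_refine.conv]})
    return sites


def build_prune_plan(model: MAARNet, keep_ratio: float,
                     n_layers: int) -> PruningPlan:
    """Plan pruning of the ``n_layers`` deepest structurally free convs."""
    if not 0.0 < keep_ratio <= 1.0:
        raise ValueError("keep_ratio must be in (0, 1]")
    sites = _prunable_sites(model)
    selected = list(reversed(sites))[:n_layers]   # deepest first
    plan = PruningPlan(keep_ratio=keep_ratio)
    for site in selected:
        conv = site["conv"]
        c = conv.out_channels
        if c < 2:
            raise ValueError(f"layer {site['name']} has fewer than 2 channels")
        n_keep = math.ceil(keep_ratio * c)
        order = channel_importance_l2(conv.weight.data)
        kept = np.sort(order[:n_keep])
        plan.entries.append((site["name"], kept))
    return plan


def apply_prune(model: MAARNet, plan: PruningPlan) -> MAARNet:
    """Dense rebuild of ``model`` with the planned channels removed.

    The input model is left untouched; the returned model is runnable and
    strictly smaller whenever ``keep_ratio < 1``.
    """
    pruned = copy.deepcopy(model)
    sites = {s["name"]: s for s in _prunable_sites(pruned)}
    for name, kept in plan.entries:
        if name not in sites:
            raise KeyError(f"unknown prunable layer '{name}'")
        site = sites[name]
        conv, bn = site["conv"], site["bn"]
        kept = np.asarray(kept)
        if kept.size == 0 or kept.max() >= conv.out_channels:
            raise ValueError(f"invalid kept indices for {name}")
        conv.weight.data = conv.weight.data[kept]
        if conv.bias is not None:
            conv.bias.data = conv.bias.data[kept]
        conv.out_channels = len(kept)
        bn.weight.data = bn.weight.data[kept]
        bn.bias.data = bn.bias.data[kept]
        bn.register_buffer("running_mean", bn.running_mean[kept])
        bn.register_buffer("running_var", bn.running_var[kept])
        bn.num_features = len(kept)
        for consumer in site["consumers"]:
            if consumer.groups != 1:
                raise ValueError("cannot remap grouped consumer")
            consumer.weight.data = consumer.weight.data[:, kept]
            consumer.in_channels = len(kept)
    return pruned


# ---------------------------------------------------------------------------
# conv-BN fusion
# ---------------------------------------------------------------------------

_FUSE_PAIRS: dict[type, list[tuple[str, str]]] = {
    _ConvBNReLU: [("conv", "bn")],
    EnhancedBasicBlock: [("conv1", "bn1"), ("conv2", "bn2"),
                         ("shortcut_conv", "shortcut_bn")],
    DSCAM: [("pw", "bn")],
    DSCBAM: [("spatial_pw", "spatial_bn")],
}


def fuse_conv_bn(conv: nn.Conv2d, bn: nn.BatchNorm2d) -> nn.Conv2d:
    """Fold a BN layer into the preceding convolution (inference only)."""
    fused = nn.Conv2d(conv.in_channels, conv.out_channels, conv.kernel_size,
                      stride=conv.stride, padding=conv.padding,
                      groups=conv.groups, bias=True)
    scale = bn.weight.data / np.sqrt(bn.running_var + bn.eps)
    fused.weight.data = conv.weight.data * scale[:, None, None, None]
    base = conv.bias.data if conv.bias is not None else 0.0
    fused.bias.data = (base - bn.running_mean) * scale + bn.bias.data
    return fused


def fuse_model(model: nn.Module) -> nn.Module:
    """Return a copy of ``model`` with every known conv+BN pair folded."""
    fused = copy.deepcopy(model)
    for _, mod in fused.named_modules():
        pairs = _FUSE_PAIRS.get(type(mod), [])
        for conv_name, bn_name in pairs:
            if conv_name not in mod._modules or bn_name not in mod._modules:
                continue  # e.g. a basic block without projection shortcut
            conv = getattr(mod, conv_name)
            bn = getattr(mod, bn_name)
            setattr(mod, conv_name, fuse_conv_bn(conv, bn))
            setattr(mod, bn_name, nn.Identity())
    return fused


# ---------------------------------------------------------------------------
# INT8 post-training static quantization
# ---------------------------------------------------------------------------

QMIN, QMAX = -128, 127


@dataclass(frozen=True)
class QuantSpec:
    """Per-tensor affine quantization parameters with calibration range."""

    scale: float
    zero_point: int
    range_min: float
    range_max: float

    def __post_init__(self):
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        if not QMIN <= self.zero_point <= QMAX:
            raise ValueError("zero point outside int8 range")

    @classmethod
    def from_range(cls, lo: float, hi: float) -> "QuantSpec":
        lo, hi = min(lo, 0.0), max(hi, 0.0)  # keep 0 exactly representable
        span = hi - lo
        if span < 1e-12:  # constant activation: guarded minimum scale
            scale = max(abs(hi), 1e-8) / QMAX if hi != 0 else 1e-8
            return cls(scale=scale, zero_point=0, range_min=lo, range_max=hi)
        scale = span / (QMAX - QMIN)
        zp = int(np.clip(round(QMIN - lo / scale), QMIN, QMAX))
        return cls(scale=scale, zero_point=zp, range_min=lo, range_max=hi)

    @classmethod
    def symmetric(cls, values: np.ndarray) -> "QuantSpec":
        amax = float(np.abs(values).max())
        scale = max(amax, 1e-12) / QMAX
        return cls(scale=scale, zero_point=0,
                   range_min=-amax, range_max=amax)


def quantize_array(values: np.ndarray, spec: QuantSpec) -> np.ndarray:
    q = np.round(values / spec.scale) + spec.zero_point
    return np.clip(q, QMIN, QMAX).astype(np.int8)


def dequantize_array(q: np.ndarray, spec: QuantSpec) -> np.ndarray:
    return (q.astype(np.float64) - spec.zero_point) * spec.scale


class _ObservedConv(nn.Module):
    """Wraps a conv during calibration, recording its input range."""

    def __init__(self, conv: nn.Conv2d):
        super().__init__()
        self.conv = conv
        self.lo = math.inf
        self.hi = -math.inf

    def forward(self, x):
        self.lo = min(self.lo, float(x.data.min()))
        self.hi = max(self.hi, float(x.data.max()))
        return self.conv(x)


class QuantizedConv2d(nn.Module):
    """INT8 convolution: quantize input, integer accumulate, dequantize.

    Weights are quantized symmetrically per output channel (the standard
    deployment choice for convolutions: one scale per filter), activations
    per tensor with an affine zero point from calibration.
    """

    def __init__(self, conv: nn.Conv2d, input_spec: QuantSpec):
        super().__init__()
        self.in_channels = conv.in_channels
        self.out_channels = conv.out_channels
        self.kernel_size = conv.kernel_size
        self.stride = conv.stride
        self.padding = conv.padding
        self.groups = conv.groups
        self.input_spec = input_spec
        w = conv.weight.data
        amax = np.abs(w).max(axis=(1, 2, 3))
        self.weight_scales = np.maximum(amax, 1e-12) / QMAX   # (C_out,)
        wq = np.round(w / self.weight_scales[:, None, None, None])
        self.weight_q = np.clip(wq, QMIN, QMAX).astype(np.int8)
        self.bias = None if conv.bias is None else conv.bias.data.copy()

    def forward(self, x: Tensor) -> Tensor:
        xq = quantize_array(x.data, self.input_spec).astype(np.int64)
        xq -= self.input_spec.zero_point        # centred integers
        n, cin, h, w = xq.shape
        k = self.kernel_size
        cols, ho, wo = nn._im2col(xq, k, k, self.stride, self.padding)
        g = self.groups
        kk = (cin // g) * k * k
        cols_g = cols.reshape(n, g, kk, ho * wo)
        w_g = self.weight_q.astype(np.int64).reshape(g, self.out_channels // g, kk)
        acc = np.matmul(w_g, cols_g)                     # integer domain
        acc = acc.reshape(n, self.out_channels, ho, wo)
        out = acc.astype(np.float64) * (
            self.input_spec.scale * self.weight_scales[None, :, None, None])
        if self.bias is not None:
            out += self.bias.reshape(1, -1, 1, 1)
        return Tensor(out)


def _conv_children(model: nn.Module):
    for _, mod in model.named_modules():
        for name, child in list(mod._modules.items()):
            if type(child) is nn.Conv2d:
                yield mod, name, child


# attention gates and the global-context head are control logic with a
# negligible share of the compute; they stay in float by default
_GATE_MODULES = (DSCAM, DSCBAM, _ContextHead)


def calibrate_and_quantize(model: nn.Module,
                           calibration_batches: list[np.ndarray],
                           quantize_gates: bool = False) -> nn.Module:
    """Fuse conv-BN chains, calibrate activation ranges, quantize to INT8.

    ``calibration_batches``: arrays of shape (N, C, H, W) in model input
    scale, typically preprocessed training tiles.  With the default
    ``quantize_gates=False`` the convolutions inside attention gates and
    the context head keep float weights (mixed-precision deployment
    style); pass True to quantize every convolution.
    """
    if not calibration_batches:
        raise ValueError("calibration set must not be empty")
    fused = fuse_model(model)
    fused.eval()
    for parent, name, conv in list(_conv_children(fused)):
        if not quantize_gates and isinstance(parent, _GATE_MODULES):
            continue
        setattr(parent, name, _ObservedConv(conv))
    from .autograd import no_grad
    with no_grad():
        for batch in calibration_batches:
            fused(Tensor(batch))
    for _, mod in fused.named_modules():
        for name, child in list(mod._modules.items()):
            if isinstance(child, _ObservedConv):
                if not math.isfinite(child.lo):
                    # never executed during calibration (e.g. the training-only
                    # auxiliary head): keep it in float
                    setattr(mod, name, child.conv)
                    continue
                spec = QuantSpec.from_range(child.lo, child.hi)
                setattr(mod, name, QuantizedConv2d(child.conv, spec))
    return fused


def conv_weight_bytes(model: nn.Module) -> int:
    """Bytes needed to store conv weights (int8 for quantized layers,
    float32 otherwise) — the quantity the ~4x size reduction refers to."""
    total = 0
    for _, mod in model.named_modules():
        if isinstance(mod, QuantizedConv2d):
            total += mod.weight_q.size  # 1 byte each
        elif isinstance(mod, (nn.Conv2d, nn.ConvTranspose2d)):
            total += mod.weight.data.size * 4
    return total
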