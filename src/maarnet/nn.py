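"""Neural-network layers on top of the autograd engine.

Implements exactly the operator set the segmentation network needs:
grouped/depthwise 2-D convolution (im2col + BLAS matmul), transposed
convolution, batch normalization, pooling, bilinear resizing and the usual
activations, plus ``Module`` bookkeeping (parameter traversal, train/eval
mode) and an Adam optimizer.

Convolution weights follow the ``(out_channels, in_channels/groups, kh, kw)``
layout; feature maps are ``(N, C, H, W)``.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, is_grad_enabled

__all__ = [
    "Module", "Sequential", "Parameter", "Conv2d", "ConvTranspose2d",
    "BatchNorm2d", "ReLU", "Sigmoid", "MaxPool2d", "AdaptiveAvgPool2d",
    "bilinear_resize", "adaptive_avg_pool2d", "relu", "cross_entropy",
    "Adam", "trace_ops",
]


# ---------------------------------------------------------------------------
# op tracing (drives the analytic profiler)
# ---------------------------------------------------------------------------

_TRACE: list | None = None
_SHAPES_ONLY = False


class trace_ops:
    """Context manager recording every traced op executed inside it.

    Each entry is a dict with ``kind``, a human-readable ``label``, the
    parameter count, the multiply-accumulate count and the parameter object
    ids (so shared parameters can be de-duplicated by the consumer).

    With ``shapes_only=True`` the traced ops skip their arithmetic and
    propagate zero arrays of the correct output shape, which makes
    profiling large inputs essentially free.  Forward code must therefore
    never branch on activation values (ours does not).
    """

    def __init__(self, shapes_only: bool = False):
        self._shapes_only = shapes_only

    def __enter__(self):
        global _TRACE, _SHAPES_ONLY
        self._prev = (_TRACE, _SHAPES_ONLY)
        _TRACE = []
        _SHAPES_ONLY = self._shapes_only
        self.entries = _TRACE
        return self

    def __exit__(self, *exc):
        global _TRACE, _SHAPES_ONLY
        _TRACE, _SHAPES_ONLY = self._prev
        return False


def _record(kind: str, label: str, params: int, macs: int,
            param_ids: tuple[int, ...] = ()) -> None:
    if _TRACE is not None:
        _TRACE.append({"kind": kind, "label": label, "params": params,
                       "macs": macs, "param_ids": param_ids})


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # even inside no_grad contexts


# ---------------------------------------------------------------------------
# module base
# ---------------------------------------------------------------------------

class Module:
    def __init__(self):
        self._modules: dict[str, Module] = {}
        self._params: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def modules(self):
        for _, m in self.named_modules():
            yield m

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def astype(self, dtype):
        """Cast all parameters and buffers (e.g. to float32 for speed)."""
        for p in self.parameters():
            p.data = p.data.astype(dtype)
        for mod in self.modules():
            for name in list(mod._buffers):
                mod.register_buffer(name, getattr(mod, name).astype(dtype))
        return self

    # -- flat state dict of numpy arrays ----------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, p in self.named_parameters():
            state[name] = p.data.copy()
        for mod_name, mod in self.named_modules():
            for buf_name, _ in mod._buffers.items():
                key = f"{mod_name}.{buf_name}" if mod_name else buf_name
                state[key] = getattr(mod, buf_name).copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {}
        for mod_name, mod in self.named_modules():
            for buf_name in mod._buffers:
                key = f"{mod_name}.{buf_name}" if mod_name else buf_name
                buffers[key] = (mod, buf_name)
        for key, value in state.items():
            if key in params:
                if params[key].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                params[key].data = value.copy()
            elif key in buffers:
                mod, buf_name = buffers[key]
                mod.register_buffer(buf_name, value.copy())
            else:
                raise KeyError(f"unexpected key {key}")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


# ---------------------------------------------------------------------------
# im2col convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]          # (n, c, ho, wo, kh, kw)
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    x = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            x[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, i, j]
    if pad:
        x = x[:, :, pad:-pad, pad:-pad]
    return x


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """Grouped 2-D convolution; depthwise when ``groups == in_channels``."""
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"input has {cin} channels but weight expects {cin_g * groups}")
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    if _TRACE is not None:
        n_params = weight.data.size + (0 if bias is None else bias.data.size)
        macs = cout * ho * wo * cin_g * kh * kw + (0 if bias is None else cout * ho * wo)
        ids = (id(weight),) if bias is None else (id(weight), id(bias))
        _record("conv", f"conv{kh}x{kw} {cin}->{cout} s{stride} g{groups} @{ho}x{wo}",
                n_params, n * macs, ids)
        if _SHAPES_ONLY:
            return Tensor(np.zeros((n, cout, ho, wo)))
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    k = cin_g * kh * kw
    if groups == 1:
        out = np.matmul(weight.data.reshape(cout, k), cols)
    else:
        cols_g = cols.reshape(n, groups, k, ho * wo)
        w_g = weight.data.reshape(groups, cout // groups, k)
        out = np.matmul(w_g, cols_g)
    out = out.reshape(n, cout, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        if groups == 1:
            g2 = g.reshape(n, cout, ho * wo)
            gw = np.matmul(g2, cols.transpose(0, 2, 1)).sum(axis=0)
            gcols = np.matmul(weight.data.reshape(cout, k).T, g2)
        else:
            cols_g = cols.reshape(n, groups, k, ho * wo)
            w_g = weight.data.reshape(groups, cout // groups, k)
            g_g = g.reshape(n, groups, cout // groups, ho * wo)
            gw = np.matmul(g_g, cols_g.transpose(0, 1, 3, 2)).sum(axis=0)
            gcols = np.matmul(w_g.transpose(0, 2, 1), g_g)
        gw = gw.reshape(weight.data.shape)
        gcols = gcols.reshape(n, cin * kh * kw, ho * wo)
        gx = _col2im(gcols, (n, cin, h, w), kh, kw, stride, padding)
        if bias is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    return Tensor._make(out, parents, backward)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng()
        fan_in = in_channels // groups * kernel_size ** 2
        # He initialization, appropriate for the ReLU-dominated network
        std = math.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding,
                      self.groups)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        ho = (h + 2 * self.padding - self.kernel_size) // self.stride + 1
        wo = (w + 2 * self.padding - self.kernel_size) // self.stride + 1
        return (self.out_channels, ho, wo)


class ConvTranspose2d(Module):
    """Stride-``s`` transposed convolution (used by the U-Net baseline).

    Forward only: the baseline exists for architecture profiling and
    reference computations, not for training in this package.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        rng = rng or np.random.default_rng()
        std = math.sqrt(1.0 / (in_channels * kernel_size ** 2))
        self.weight = Parameter(rng.normal(
            0.0, std, (in_channels, out_channels, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        n, cin, h, w = x.shape
        k, s = self.kernel_size, self.stride
        ho, wo = (h - 1) * s + k, (w - 1) * s + k
        if _TRACE is not None:
            n_params = self.weight.data.size + (
                0 if self.bias is None else self.bias.data.size)
            macs = self.out_channels * ho * wo * cin * k * k + (
                0 if self.bias is None else self.out_channels * ho * wo)
            ids = (id(self.weight),) if self.bias is None else (
                id(self.weight), id(self.bias))
            _record("conv_transpose",
                    f"tconv{k}x{k} {cin}->{self.out_channels} s{s} @{ho}x{wo}",
                    n_params, n * macs, ids)
            if _SHAPES_ONLY:
                return Tensor(np.zeros((n, self.out_channels, ho, wo)))
        out = np.zeros((n, self.out_channels, ho, wo))
        # scatter each input pixel's k x k contribution
        contrib = np.einsum("nihw,iokl->nohwkl", x.data, self.weight.data,
                            optimize=True)
        for i in range(k):
            for j in range(k):
                out[:, :, i:i + s * h:s, j:j + s * w:s] += contrib[:, :, :, :, i, j]
        if self.bias is not None:
            out += self.bias.data.reshape(1, -1, 1, 1)
        return Tensor(out)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        return (self.out_channels,
                (h - 1) * self.stride + self.kernel_size,
                (w - 1) * self.stride + self.kernel_size)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_features))
        self.bias = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = self.num_features
        if _TRACE is not None:
            n, _, h, w = x.shape
            _record("batchnorm", f"bn {c} @{h}x{w}", 2 * c, 2 * n * c * h * w,
                    (id(self.weight), id(self.bias)))
            if _SHAPES_ONLY:
                return x
        if self.training:
            # batch statistics as graph nodes: autograd differentiates
            # through mean and variance exactly
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            unbiased = var.data.reshape(c) * (n / max(n - 1, 1))
            m = self.momentum
            self.register_buffer(
                "running_mean",
                (1 - m) * self.running_mean + m * mu.data.reshape(c))
            self.register_buffer(
                "running_var", (1 - m) * self.running_var + m * unbiased)
            x_hat = (x - mu) * ((var + self.eps) ** -0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            x_hat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return x_hat * self.weight.reshape(1, c, 1, 1) \
            + self.bias.reshape(1, c, 1, 1)


def relu(x: Tensor) -> Tensor:
    """ReLU; traced at one op per element when profiling."""
    if _TRACE is not None:
        _record("relu", f"relu @{'x'.join(map(str, x.shape[1:]))}",
                0, int(np.prod(x.shape)))
        if _SHAPES_ONLY:
            return x
    return x.relu()


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int = 2, stride: int | None = None):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size

    def forward(self, x: Tensor) -> Tensor:
        k = self.kernel_size
        if k != self.stride:
            raise NotImplementedError("only kernel_size == stride pooling")
        if _TRACE is not None:
            _record("maxpool", f"maxpool{k}x{k}", 0, 0)  # excluded by convention
            if _SHAPES_ONLY:
                n, c, h, w = x.shape
                return Tensor(np.zeros((n, c, h // k, w // k)))
        n, c, h, w = x.shape
        if h % k or w % k:
            raise ValueError(f"spatial dims {h}x{w} not divisible by {k}")
        windows = x.data.reshape(n, c, h // k, k, w // k, k)
        windows = windows.transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h // k, w // k, k * k)
        idx = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            gwin = np.zeros_like(windows)
            np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
            gx = gwin.reshape(n, c, h // k, w // k, k, k)
            gx = gx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
            return (gx,)

        return Tensor._make(out, (x,), backward)

    def output_shape(self, in_shape):
        c, h, w = in_shape
        return (c, h // self.stride, w // self.stride)


# ---------------------------------------------------------------------------
# resampling as separable linear maps
# ---------------------------------------------------------------------------

def _adaptive_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Averaging matrix of adaptive average pooling along one axis."""
    mat = np.zeros((n_out, n_in))
    for i in range(n_out):
        start = (i * n_in) // n_out
        end = -(-((i + 1) * n_in) // n_out)  # ceil
        mat[i, start:end] = 1.0 / (end - start)
    return mat


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Interpolation matrix for corner-excluding (half-pixel) bilinear resize."""
    mat = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1)
        lo = int(math.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        mat[i, lo] += 1.0 - frac
        mat[i, hi] += frac
    return mat


def _separable_resample(x: Tensor, row: np.ndarray, col: np.ndarray) -> Tensor:
    row = row.astype(x.data.dtype, copy=False)
    col = col.astype(x.data.dtype, copy=False)
    if _TRACE is not None:
        _record("resample", f"resample ->{row.shape[0]}x{col.shape[0]}", 0, 0)
        if _SHAPES_ONLY:
            n, c = x.shape[:2]
            return Tensor(np.zeros((n, c, row.shape[0], col.shape[0])))
    # out[n,c] = row @ x[n,c] @ col.T, via two broadcasted BLAS matmuls
    out = np.matmul(np.matmul(row, x.data), col.T)

    def backward(g):
        return (np.matmul(np.matmul(row.T, g), col),)

    return Tensor._make(out, (x,), backward)


def adaptive_avg_pool2d(x: Tensor, output_size: int | tuple[int, int]) -> Tensor:
    oh, ow = (output_size, output_size) if isinstance(output_size, int) \
        else output_size
    _, _, h, w = x.shape
    return _separable_resample(x, _adaptive_matrix(h, oh), _adaptive_matrix(w, ow))


def bilinear_resize(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Bilinear resampling to ``size`` (corner-excluding convention)."""
    oh, ow = size
    _, _, h, w = x.shape
    if (oh, ow) == (h, w):
        return x
    return _separable_resample(x, _bilinear_matrix(h, oh), _bilinear_matrix(w, ow))


class AdaptiveAvgPool2d(Module):
    def __init__(self, output_size: int | tuple[int, int]):
        super().__init__()
        self.output_size = output_size

    def forward(self, x: Tensor) -> Tensor:
        return adaptive_avg_pool2d(x, self.output_size)


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean pixelwise cross-entropy.

    ``logits``: (N, n_classes, H, W); ``target``: integer labels (N, H, W).
    """
    n, ncls, h, w = logits.shape
    shift = logits.data.max(axis=1, keepdims=True)  # constant: stabilises exp
    z = logits - Tensor(shift)
    log_probs = z - z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros(logits.shape, dtype=logits.data.dtype)
    idx0, idx2, idx3 = np.ogrid[:n, :h, :w]
    onehot[idx0, target, idx2, idx3] = 1.0
    return -(log_probs * Tensor(onehot)).sum() * (1.0 / (n * h * w))


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
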