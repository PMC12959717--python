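"""Independent scalar-loop reference implementations.

Everything here is written with explicit Python loops over pixels and
channels, deliberately sharing no code with the package's vectorized
engine, so the two can check each other.
"""

import math

import numpy as np


def conv2d_loops(x, w, b=None, stride=1, padding=1, groups=1):
    """Plain-loop 2-D convolution; x: (C, H, W), w: (O, C/g, kh, kw)."""
    c, h, wd = x.shape
    o, cg, kh, kw = w.shape
    xp = np.zeros((c, h + 2 * padding, wd + 2 * padding))
    xp[:, padding:padding + h, padding:padding + wd] = x
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((o, ho, wo))
    out_per_group = o // groups
    for oc in range(o):
        g = oc // out_per_group
        for i in range(ho):
            for j in range(wo):
                acc = 0.0
                for ic in range(cg):
                    for di in range(kh):
                        for dj in range(kw):
                            acc += (w[oc, ic, di, dj]
                                    * xp[g * cg + ic, i * stride + di,
                                         j * stride + dj])
                out[oc, i, j] = acc + (b[oc] if b is not None else 0.0)
    return out


def adaptive_pool_loops(x, out_size):
    """Adaptive average pooling with the floor/ceil window convention."""
    c, h, w = x.shape
    out = np.zeros((c, out_size, out_size))
    for ch in range(c):
        for i in range(out_size):
            i0, i1 = (i * h) // out_size, -(-((i + 1) * h) // out_size)
            for j in range(out_size):
                j0, j1 = (j * w) // out_size, -(-((j + 1) * w) // out_size)
                acc = 0.0
                for a in range(i0, i1):
                    for bb in range(j0, j1):
                        acc += x[ch, a, bb]
                out[ch, i, j] = acc / ((i1 - i0) * (j1 - j0))
    return out


def bn_eval_loops(x, gamma, beta, mean, var, eps=1e-5):
    out = np.zeros_like(x)
    for ch in range(x.shape[0]):
        s = gamma[ch] / math.sqrt(var[ch] + eps)
        out[ch] = (x[ch] - mean[ch]) * s + beta[ch]
    return out


def sigmoid_scalar(v):
    return 1.0 / (1.0 + math.exp(-v))


def dscam_loops(x, dw_w, pw_w, gamma, beta, mean, var):
    """Full channel-attention pipeline: pool -> dw 2x2 -> pw 1x1 -> BN ->
    sigmoid -> rescale."""
    c = x.shape[0]
    pooled = adaptive_pool_loops(x, 2)                       # (C, 2, 2)
    vec = conv2d_loops(pooled, dw_w, stride=1, padding=0, groups=c)  # (C,1,1)
    vec = conv2d_loops(vec, pw_w, stride=1, padding=0)       # (C, 1, 1)
    vec = bn_eval_loops(vec, gamma, beta, mean, var)
    out = np.zeros_like(x)
    for ch in range(c):
        out[ch] = x[ch] * sigmoid_scalar(vec[ch, 0, 0])
    return out


def dscam_logits_loops(x, dw_w, pw_w, gamma, beta, mean, var):
    c = x.shape[0]
    pooled = adaptive_pool_loops(x, 2)
    vec = conv2d_loops(pooled, dw_w, stride=1, padding=0, groups=c)
    vec = conv2d_loops(vec, pw_w, stride=1, padding=0)
    return bn_eval_loops(vec, gamma, beta, mean, var)        # (C, 1, 1)


def dscbam_loops(x, ch_params, sp_dw_w, sp_pw_w, sp_gamma, sp_beta,
                 sp_mean, sp_var, spatial_kernel=3):
    """Parallel channel+spatial attention with one sigmoid after the sum."""
    c, h, w = x.shape
    ch_logits = dscam_logits_loops(x, *ch_params)            # (C, 1, 1)
    sp = conv2d_loops(x, sp_dw_w, stride=1, padding=spatial_kernel // 2,
                      groups=c)                              # (C, H, W)
    sp = conv2d_loops(sp, sp_pw_w, stride=1, padding=0)      # (1, H, W)
    sp_logits = bn_eval_loops(sp, sp_gamma, sp_beta, sp_mean, sp_var)
    out = np.zeros_like(x)
    for ch in range(c):
        for i in range(h):
            for j in range(w):
                weight = sigmoid_scalar(ch_logits[ch, 0, 0]
                                        + sp_logits[0, i, j])
                out[ch, i, j] = x[ch, i, j] * weight
    return out


def basicblock_loops(x, p, stride=1):
    """Residual block: conv-BN-ReLU-conv-BN -> DSCAM gate -> (+shortcut) -> ReLU.

    ``p`` is a dict of numpy weight arrays keyed like the module attributes.
    """
    main = conv2d_loops(x, p["conv1"], stride=stride, padding=1)
    main = bn_eval_loops(main, *p["bn1"])
    main = np.maximum(main, 0.0)
    main = conv2d_loops(main, p["conv2"], stride=1, padding=1)
    main = bn_eval_loops(main, *p["bn2"])
    if "dscam" in p:
        main = dscam_loops(main, *p["dscam"])
    if "shortcut" in p:
        short = conv2d_loops(x, p["shortcut"], stride=stride, padding=0)
        short = bn_eval_loops(short, *p["shortcut_bn"])
    else:
        short = x
    return np.maximum(main + short, 0.0)


def cross_entropy_loops(logits, target):
    """Mean pixel cross-entropy; logits (K, H, W), target (H, W) ints."""
    k, h, w = logits.shape
    total = 0.0
    for i in range(h):
        for j in range(w):
            z = [logits[c, i, j] for c in range(k)]
            m = max(z)
            logsum = m + math.log(sum(math.exp(v - m) for v in z))
            total += logsum - z[target[i, j]]
    return total / (h * w)
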