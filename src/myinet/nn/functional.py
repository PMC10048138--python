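"""Differentiable operations for the segmentation networks.

Every function takes and returns :class:`~myinet.nn.tensor.Tensor` objects and
registers a hand-derived vector-Jacobian product.  Convolution is im2col +
BLAS matmul with the patch extraction and the col2im scatter both written as
kernel-position slice loops (at most k*k iterations), which keeps the hot path
inside vectorised numpy.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor

__all__ = [
    "add",
    "relu",
    "relu6",
    "concat",
    "conv2d",
    "batch_norm2d",
    "max_pool2d",
    "resize_bilinear",
    "upsample_bilinear",
    "weighted_cross_entropy",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data
    if a.data.shape != b.data.shape:
        raise ValueError(f"add requires equal shapes, got {a.shape} vs {b.shape}")

    def backward(g):
        if a.requires_grad:
            a.accumulate_grad(g)
        if b.requires_grad:
            b.accumulate_grad(g)

    return Tensor.from_op(out_data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    x = _as_tensor(x)
    mask = x.data > 0
    out = Tensor.from_op(np.where(mask, x.data, 0.0), (x,), None)

    def backward(g):
        x.accumulate_grad(g * mask)

    out._backward = backward if out.requires_grad else None
    return out


def relu6(x: Tensor) -> Tensor:
    """Rectifier capped at 6, as used inside the inverted-residual blocks."""
    x = _as_tensor(x)
    mask = (x.data > 0) & (x.data < 6.0)
    out = Tensor.from_op(np.clip(x.data, 0.0, 6.0), (x,), None)

    def backward(g):
        x.accumulate_grad(g * mask)

    out._backward = backward if out.requires_grad else None
    return out


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate_grad(g[tuple(idx)])

    return Tensor.from_op(out_data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def _im2col(xp: np.ndarray, kh: int, kw: int, sh: int, sw: int, dh: int, dw: int,
            ho: int, wo: int) -> np.ndarray:
    """Extract patches from a padded input; returns (N, C, kh, kw, ho, wo)."""
    n, c = xp.shape[:2]
    cols = np.empty((n, c, kh, kw, ho, wo), dtype=xp.dtype)
    for a in range(kh):
        for b in range(kw):
            cols[:, :, a, b] = xp[:, :, a * dh: a * dh + sh * ho: sh,
                                  b * dw: b * dw + sw * wo: sw]
    return cols


def _col2im(gcols: np.ndarray, xp_shape, kh, kw, sh, sw, dh, dw, ho, wo) -> np.ndarray:
    gxp = np.zeros(xp_shape, dtype=gcols.dtype)
    for a in range(kh):
        for b in range(kw):
            gxp[:, :, a * dh: a * dh + sh * ho: sh,
                b * dw: b * dw + sw * wo: sw] += gcols[:, :, a, b]
    return gxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """2-D cross-correlation with stride, zero padding, dilation and groups.

    ``weight`` has shape (C_out, C_in/groups, kh, kw); depthwise convolution is
    ``groups == C_in`` with one input channel per group.
    """
    x, weight = _as_tensor(x), _as_tensor(weight)
    n, c, h, w = x.data.shape
    c_out, c_in_g, kh, kw = weight.data.shape
    if c % groups or c_out % groups or c_in_g != c // groups:
        raise ValueError(
            f"incompatible channels for conv2d: in={c}, out={c_out}, groups={groups}")
    sh = sw = int(stride)
    dh = dw = int(dilation)
    ph = pw = int(padding)
    ho = (h + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    wo = (w + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    if ho < 1 or wo < 1:
        raise ValueError("conv2d output would be empty; input too small for kernel")

    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw, sh, sw, dh, dw, ho, wo)
    g = groups
    og = c_out // g
    cg = c // g
    # (N, g, cg*kh*kw, L) x (g, og, cg*kh*kw) -> (N, g, og, L)
    cols_m = cols.reshape(n, g, cg * kh * kw, ho * wo)
    w_m = weight.data.reshape(g, og, cg * kh * kw)
    out = np.einsum("gok,ngkl->ngol", w_m, cols_m, optimize=True)
    out = out.reshape(n, c_out, ho, wo)
    if bias is not None:
        out = out + bias.data.reshape(1, c_out, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(gout):
        gm = gout.reshape(n, g, og, ho * wo)
        if weight.requires_grad:
            gw = np.einsum("ngol,ngkl->gok", gm, cols_m, optimize=True)
            weight.accumulate_grad(gw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate_grad(gout.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.einsum("gok,ngol->ngkl", w_m, gm, optimize=True)
            gcols = gcols.reshape(n, c, kh, kw, ho, wo)
            gxp = _col2im(gcols, xp.shape, kh, kw, sh, sw, dh, dw, ho, wo)
            if ph or pw:
                gxp = gxp[:, :, ph:ph + h, pw:pw + w]
            x.accumulate_grad(gxp)

    return Tensor.from_op(out, parents, backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, *,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Per-channel batch normalisation over (N, H, W).

    In training mode batch statistics are used and the supplied running
    buffers are updated in place; in inference mode the running buffers are
    used directly.
    """
    x = _as_tensor(x)
    c = x.data.shape[1]
    axes = (0, 2, 3)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size / c
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        # unbiased variance for the running estimate, as is conventional
        running_var += momentum * var * (m / max(m - 1.0, 1.0))
    else:
        mean = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * inv_std.reshape(1, c, 1, 1)
    out = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma.accumulate_grad((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta.accumulate_grad(g.sum(axis=axes))
        if x.requires_grad:
            gam_inv = (gamma.data * inv_std).reshape(1, c, 1, 1)
            if training:
                m = x.data.size / c
                gsum = g.sum(axis=axes).reshape(1, c, 1, 1)
                gx_sum = (g * xhat).sum(axis=axes).reshape(1, c, 1, 1)
                gx = gam_inv * (g - gsum / m - xhat * gx_sum / m)
            else:
                gx = gam_inv * g
            x.accumulate_grad(gx)

    return Tensor.from_op(out, (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling and resampling
# ---------------------------------------------------------------------------


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    k, s, p = int(kernel), int(stride), int(padding)
    ho = (h + 2 * p - k) // s + 1
    wo = (w + 2 * p - k) // s + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)),
                constant_values=-np.inf)
    cols = _im2col(xp, k, k, s, s, 1, 1, ho, wo)  # (N, C, k, k, ho, wo)
    cols = cols.reshape(n, c, k * k, ho, wo)
    amax = cols.argmax(axis=2)
    out = np.take_along_axis(cols, amax[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        gcols = np.zeros_like(cols)
        np.put_along_axis(gcols, amax[:, :, None], g[:, :, None], axis=2)
        gxp = _col2im(gcols.reshape(n, c, k, k, ho, wo), xp.shape,
                      k, k, s, s, 1, 1, ho, wo)
        x.accumulate_grad(gxp[:, :, p:p + h, p:p + w])

    return Tensor.from_op(out, (x,), backward)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_out, n_in), half-pixel centers."""
    a = np.zeros((n_out, n_in))
    if n_in == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w1 = src - i0
    a[np.arange(n_out), i0] += 1.0 - w1
    a[np.arange(n_out), i1] += w1
    return a


def resize_bilinear(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Bilinear resampling to an arbitrary spatial size (half-pixel alignment)."""
    x = _as_tensor(x)
    h, w = x.data.shape[-2:]
    ho, wo = int(out_hw[0]), int(out_hw[1])
    if (ho, wo) == (h, w):
        out = x.data.copy()

        def backward_id(g):
            x.accumulate_grad(g)

        return Tensor.from_op(out, (x,), backward_id)
    ah = _interp_matrix(ho, h)
    aw = _interp_matrix(wo, w)
    out = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def backward(g):
        gx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
        x.accumulate_grad(gx)

    return Tensor.from_op(out, (x,), backward)


def upsample_bilinear(x: Tensor, scale: int) -> Tensor:
    h, w = x.data.shape[-2:]
    return resize_bilinear(x, (h * scale, w * scale))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------


def weighted_cross_entropy(scores: Tensor, labels: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Class-weighted softmax cross-entropy averaged over all pixels.

    ``scores`` is (N, C, H, W); ``labels`` integer (N, H, W); ``weights`` a
    length-C vector.  The mean is over the pixel count, not the weight sum, so
    the loss scale tracks the weight scale.
    """
    scores = _as_tensor(scores)
    if not np.all(np.isfinite(scores.data)):
        raise ValueError("non-finite values in class scores")
    labels = np.asarray(labels)
    n, c, h, w = scores.data.shape
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (c,):
        raise ValueError(f"expected {c} class weights, got shape {weights.shape}")
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} does not match scores {(n, h, w)}")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError("labels outside [0, n_classes)")

    shifted = scores.data - scores.data.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    logp = shifted - logz  # (N, C, H, W)
    w_pix = weights[labels]  # (N, H, W)
    logp_true = np.take_along_axis(logp, labels[:, None], axis=1)[:, 0]
    n_pix = n * h * w
    loss = -(w_pix * logp_true).sum() / n_pix

    def backward(g):
        softmax = np.exp(logp)
        onehot = np.zeros_like(softmax)
        np.put_along_axis(onehot, labels[:, None], 1.0, axis=1)
        gx = (softmax - onehot) * w_pix[:, None] / n_pix
        scores.accumulate_grad(gx * g)

    return Tensor.from_op(loss, (scores,), backward)
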