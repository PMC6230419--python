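"""Layer primitives of the encoder-decoder network, with hand-written gradients.

All tensors are rank-4 ``(batch, channels, height, width)``.  Convolutions are
3x3, stride 1, "same" zero padding, implemented as im2col + one GEMM so the
heavy lifting runs in BLAS; max pooling is 2x2 non-overlapping and memorizes
per-window argmax positions (flat indices into the input plane) that the
matching max-unpool consumes.  Every forward has a matching ``*_backward``
used by the training loop's backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConvParams:
    """3x3 convolution weights ``(out_ch, in_ch, 3, 3)`` and per-channel bias."""

    kernels: np.ndarray
    bias: np.ndarray

    def __post_init__(self):
        if self.kernels.ndim != 4 or self.kernels.shape[2:] != (3, 3):
            raise ValueError(f"kernels must be (out,in,3,3), got {self.kernels.shape}")

    @property
    def n_params(self) -> int:
        return self.kernels.size + self.bias.size


@dataclass
class BNParams:
    """Batch-norm scale/shift plus running statistics for inference."""

    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5
    momentum: float = 0.1  # running <- (1-momentum)*running + momentum*batch
    n_batches_tracked: int = 0

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size


@dataclass
class PoolIndices:
    """Flat argmax positions (into the H*W input plane) of one 2x2 max pool."""

    indices: np.ndarray  # (N, C, H/2, W/2) int64
    input_shape: tuple   # (N, C, H, W)


def _check_4d(x: np.ndarray) -> None:
    if x.ndim != 4:
        raise ValueError(f"expected a (batch, channel, height, width) tensor, got shape {x.shape}")


def _shift_cols(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N, 9*C, H*W): the 9 shifted copies of the zero-padded
    input stacked channel-blockwise, offset-major (so block k = offset
    (k//3, k%3)).  Pure contiguous slice copies — the GEMM's cheap feed."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = np.empty((n, 9 * c, h, w), dtype=x.dtype)
    for k in range(9):
        di, dj = divmod(k, 3)
        cols[:, k * c:(k + 1) * c] = xp[:, :, di:di + h, dj:dj + w]
    return cols.reshape(n, 9 * c, h * w)


def _kernels_flat(kernels: np.ndarray) -> np.ndarray:
    """(O,C,3,3) -> (O, 9*C) in the offset-major order of :func:`_shift_cols`."""
    o, c = kernels.shape[:2]
    return np.ascontiguousarray(kernels.transpose(0, 2, 3, 1)).reshape(o, 9 * c)


def conv2d_3x3_same(x: np.ndarray, p: ConvParams) -> np.ndarray:
    """Same-padding 3x3 cross-correlation (the CNN convention of "convolution")."""
    _check_4d(x)
    n, c, h, w = x.shape
    out_ch, in_ch = p.kernels.shape[:2]
    if in_ch != c:
        raise ValueError(f"channel mismatch: input has {c}, kernels expect {in_ch}")
    cols = _shift_cols(x)
    out = np.matmul(_kernels_flat(p.kernels), cols)  # (n, O, H*W)
    out += p.bias.astype(x.dtype)[:, None]
    return out.reshape(n, out_ch, h, w)


def _adjoint_kernels(kernels: np.ndarray) -> np.ndarray:
    """Kernels of the adjoint (transposed) convolution: channels swapped and
    both spatial axes flipped.  conv(x, K)^T dout == conv(dout, adjoint(K))."""
    return np.ascontiguousarray(kernels.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])


def conv2d_3x3_same_backward(
    x: np.ndarray, p: ConvParams, dout: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dkernels, dbias); shifted columns are recomputed, not
    cached, and dx is the adjoint convolution of dout."""
    n, c, h, w = x.shape
    out_ch = p.kernels.shape[0]
    dout_flat = dout.reshape(n, out_ch, h * w)
    cols = _shift_cols(x)  # (n, 9c, hw)
    # dW[o, (k,c)] = sum_n dout[n,o,:] . cols[n,(k,c),:]
    dk_flat = np.matmul(dout_flat, cols.transpose(0, 2, 1)).sum(axis=0)  # (O, 9c)
    dkernels = dk_flat.reshape(out_ch, 3, 3, c).transpose(0, 3, 1, 2)
    dbias = dout_flat.sum(axis=(0, 2))
    dx = conv2d_3x3_same(
        dout, ConvParams(kernels=_adjoint_kernels(p.kernels),
                         bias=np.zeros(c, dtype=x.dtype))
    )
    return dx, np.ascontiguousarray(dkernels), dbias


def batch_norm(
    x: np.ndarray, p: BNParams, mode: str = "train"
) -> tuple[np.ndarray, dict]:
    """Per-channel batch normalization.

    In ``train`` mode the batch statistics over (batch, height, width) are
    used and the running statistics are updated in place by an exponential
    moving average; in ``infer`` mode the running statistics are used and
    nothing mutates.  Returns the output and a cache for the backward pass.
    """
    _check_4d(x)
    c = x.shape[1]
    if p.gamma.shape[0] != c:
        raise ValueError(f"channel mismatch: input has {c}, BN has {p.gamma.shape[0]}")
    if mode == "train":
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))  # biased (population) variance
        p.running_mean *= 1.0 - p.momentum
        p.running_mean += p.momentum * mean
        p.running_var *= 1.0 - p.momentum
        p.running_var += p.momentum * var
        p.n_batches_tracked += 1
    elif mode == "infer":
        if p.n_batches_tracked == 0:
            raise RuntimeError(
                "batch_norm in infer mode before any running statistics exist; "
                "train first or load a checkpoint"
            )
        mean, var = p.running_mean, p.running_var
    else:
        raise ValueError(f"mode must be 'train' or 'infer', got {mode!r}")

    inv_std = 1.0 / np.sqrt(var + p.eps)
    xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
    out = p.gamma[None, :, None, None] * xhat + p.beta[None, :, None, None]
    cache = {"xhat": xhat, "inv_std": inv_std, "mode": mode}
    return out, cache


def batch_norm_backward(
    dout: np.ndarray, p: BNParams, cache: dict
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients (dx, dgamma, dbeta).

    In train mode the gradient flows through the batch mean and variance as
    well (the full normalization Jacobian); in infer mode the statistics are
    constants and the map is affine.
    """
    xhat, inv_std = cache["xhat"], cache["inv_std"]
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * p.gamma[None, :, None, None]
    if cache["mode"] == "infer":
        return dxhat * inv_std[None, :, None, None], dgamma, dbeta
    n, _, h, w = dout.shape
    m = n * h * w
    s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
    s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
    dx = (inv_std[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
    return dx, dgamma, dbeta


def relu(x: np.ndarray) -> np.ndarray:
    """f(x) = max(0, x), elementwise."""
    return np.maximum(x, 0.0)


def relu_backward(dout: np.ndarray, x: np.ndarray) -> np.ndarray:
    return dout * (x > 0)


def maxpool2x2_with_indices(x: np.ndarray) -> tuple[np.ndarray, PoolIndices]:
    """2x2 stride-2 max pooling; ties go to the first (row-major) maximum."""
    _check_4d(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"spatial dims must be even for 2x2 pooling, got {h}x{w}")
    ho, wo = h // 2, w // 2
    # (N,C,Ho,2,Wo,2) -> (N,C,Ho,Wo,2,2) -> windows flattened row-major
    win = x.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    local = win.argmax(axis=-1)  # argmax returns the first maximum
    vals = np.take_along_axis(win, local[..., None], axis=-1)[..., 0]
    rows = 2 * np.arange(ho)[None, None, :, None] + local // 2
    cols = 2 * np.arange(wo)[None, None, None, :] + local % 2
    flat = (rows * w + cols).astype(np.int64)
    return vals, PoolIndices(indices=flat, input_shape=(n, c, h, w))


def maxunpool2x2(x: np.ndarray, idx: PoolIndices, out_shape: tuple | None = None) -> np.ndarray:
    """Scatter pooled values back to their memorized positions; zeros elsewhere."""
    _check_4d(x)
    if out_shape is None:
        out_shape = idx.input_shape
    n, c, h, w = out_shape
    if x.shape != idx.indices.shape:
        raise ValueError(
            f"pooled tensor shape {x.shape} inconsistent with indices {idx.indices.shape}"
        )
    if (n, c) != x.shape[:2] or h != 2 * x.shape[2] or w != 2 * x.shape[3]:
        raise ValueError(f"out_shape {out_shape} inconsistent with pooled shape {x.shape}")
    out = np.zeros((n, c, h * w), dtype=x.dtype)
    np.put_along_axis(out, idx.indices.reshape(n, c, -1), x.reshape(n, c, -1), axis=2)
    return out.reshape(n, c, h, w)


def maxpool2x2_backward(dout: np.ndarray, idx: PoolIndices) -> np.ndarray:
    """Route each pooled gradient back to its argmax position (= unpool of dout)."""
    return maxunpool2x2(dout, idx)


def maxunpool2x2_backward(dout: np.ndarray, idx: PoolIndices) -> np.ndarray:
    """Gather the gradient from each memorized position."""
    n, c, h, w = idx.input_shape
    gathered = np.take_along_axis(
        dout.reshape(n, c, h * w), idx.indices.reshape(n, c, -1), axis=2
    )
    return gathered.reshape(idx.indices.shape)


def softmax_pixelwise(x: np.ndarray) -> np.ndarray:
    """Channel softmax per pixel, computed with max-subtraction for stability."""
    _check_4d(x)
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_pixelwise_backward(dout: np.ndarray, probs: np.ndarray) -> np.ndarray:
    inner = (dout * probs).sum(axis=1, keepdims=True)
    return probs * (dout - inner)
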