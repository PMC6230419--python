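"""Assembly of the 31-layer simplified-SegNet architecture.

Two encoder blocks (conv-BN-ReLU twice, then 2x2 max pool) are mirrored by
two decoder blocks (max unpool, then conv-BN-ReLU twice); pooling indices
memorized by encoder1/encoder2 are consumed by decoder1/decoder2
respectively, so upsampling is a sparse scatter rather than interpolation.
The final convolution has 4 output channels — background, CSF, GM, WM — and
a pixel-wise softmax turns them into class probabilities.  The stack at the
default filter width of 64 has 225,420 trainable scalars.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from .layers import (
    BNParams,
    ConvParams,
    batch_norm,
    batch_norm_backward,
    conv2d_3x3_same,
    conv2d_3x3_same_backward,
    maxpool2x2_with_indices,
    maxpool2x2_backward,
    maxunpool2x2,
    maxunpool2x2_backward,
    relu,
    relu_backward,
    softmax_pixelwise,
)

N_CLASSES = 4
CLASS_NAMES = ("background", "CSF", "GM", "WM")


@dataclass(frozen=True)
class LayerSpec:
    name: str
    type: str  # input | conv | bn | relu | pool | unpool | softmax | pixelclass
    in_channels: int = 0
    out_channels: int = 0
    pair: str = ""  # pool/unpool pairing key


@dataclass(frozen=True)
class ArchitectureSpec:
    """The ordered 31-layer stack plus the encoder-decoder pool pairings."""

    layers: tuple
    filter_width: int

    def hash(self) -> str:
        blob = json.dumps(
            [(l.name, l.type, l.in_channels, l.out_channels, l.pair) for l in self.layers]
        ).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_architecture(filter_width: int = 64) -> ArchitectureSpec:
    """Build the layer list: 1 input, 7 width-`filter_width` convs, one
    4-channel head conv, 8 batch norms, 7 ReLUs, 2 pool/unpool pairs,
    softmax and the pixel-classification (loss) layer — 31 layers."""
    if filter_width < 1:
        raise ValueError("filter_width must be >= 1")
    w = filter_width
    L = LayerSpec
    layers = (
        L("input", "input"),
        L("encoder1_conv1", "conv", 1, w),
        L("encoder1_bn_1", "bn", w, w),
        L("encoder1_relu_1", "relu"),
        L("encoder1_conv2", "conv", w, w),
        L("encoder1_bn_2", "bn", w, w),
        L("encoder1_relu_2", "relu"),
        L("encoder1_maxpool", "pool", pair="1"),
        L("encoder2_conv1", "conv", w, w),
        L("encoder2_bn_1", "bn", w, w),
        L("encoder2_relu_1", "relu"),
        L("encoder2_conv2", "conv", w, w),
        L("encoder2_bn_2", "bn", w, w),
        L("encoder2_relu_2", "relu"),
        L("encoder2_maxpool", "pool", pair="2"),
        L("decoder2_unpool", "unpool", pair="2"),
        L("decoder2_conv2", "conv", w, w),
        L("decoder2_bn_2", "bn", w, w),
        L("decoder2_relu_2", "relu"),
        L("decoder2_conv1", "conv", w, w),
        L("decoder2_bn_1", "bn", w, w),
        L("decoder2_relu_1", "relu"),
        L("decoder1_unpool", "unpool", pair="1"),
        L("decoder1_conv2", "conv", w, w),
        L("decoder1_bn_2", "bn", w, w),
        L("decoder1_relu_2", "relu"),
        L("decoder1_conv1", "conv", w, N_CLASSES),
        L("decoder1_bn_1", "bn", N_CLASSES, N_CLASSES),
        L("decoder1_relu_1", "relu"),
        L("softmax", "softmax"),
        L("pixel_classify", "pixelclass"),
    )
    assert len(layers) == 31
    return ArchitectureSpec(layers=layers, filter_width=w)


def init_params(
    arch: ArchitectureSpec,
    rng: np.random.Generator | int | None = None,
    dtype=np.float32,
) -> dict:
    """He (fan-in scaled) initialization: kernels ~ N(0, 2/fan_in), biases 0,
    BN gamma 1 / beta 0, running stats (0, 1).  Deterministic given the rng."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    params: dict = {}
    for layer in arch.layers:
        if layer.type == "conv":
            fan_in = 9 * layer.in_channels
            std = np.sqrt(2.0 / fan_in)
            params[layer.name] = ConvParams(
                kernels=rng.normal(0.0, std, (layer.out_channels, layer.in_channels, 3, 3)).astype(dtype),
                bias=np.zeros(layer.out_channels, dtype=dtype),
            )
        elif layer.type == "bn":
            c = layer.out_channels
            params[layer.name] = BNParams(
                gamma=np.ones(c, dtype=dtype),
                beta=np.zeros(c, dtype=dtype),
                running_mean=np.zeros(c, dtype=dtype),
                running_var=np.ones(c, dtype=dtype),
            )
    return params


def count_parameters(params: dict) -> int:
    """Total trainable scalars (conv kernels + biases, BN gamma + beta)."""
    return sum(p.n_params for p in params.values())


def forward(
    params: dict,
    x: np.ndarray,
    mode: str = "infer",
    arch: ArchitectureSpec | None = None,
    keep_cache: bool = True,
) -> tuple[np.ndarray, dict]:
    """Run the full stack; returns (probabilities, cache).

    ``x`` is (batch, 1, H, W) with H and W divisible by 4.  The cache holds
    every intermediate needed by :func:`backward` plus the two PoolIndices.
    """
    if arch is None:
        arch = _infer_arch(params)
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError(f"input must be (batch, 1, H, W), got {x.shape}")
    if x.shape[2] % 4 or x.shape[3] % 4:
        raise ValueError(
            f"spatial dims must be divisible by 4 (two 2x poolings), got {x.shape[2]}x{x.shape[3]}"
        )
    records = []
    pool_indices: dict = {}
    out = x
    for layer in arch.layers:
        if layer.type in ("input", "pixelclass"):
            continue
        if layer.type == "conv":
            rec = {"x": out} if keep_cache else {}
            out = conv2d_3x3_same(out, params[layer.name])
        elif layer.type == "bn":
            out, bn_cache = batch_norm(out, params[layer.name], mode=mode)
            rec = {"bn": bn_cache} if keep_cache else {}
        elif layer.type == "relu":
            rec = {"x": out} if keep_cache else {}
            out = relu(out)
        elif layer.type == "pool":
            out, idx = maxpool2x2_with_indices(out)
            pool_indices[layer.pair] = idx
            rec = {"idx": idx}
        elif layer.type == "unpool":
            idx = pool_indices[layer.pair]
            out = maxunpool2x2(out, idx)
            rec = {"idx": idx}
        elif layer.type == "softmax":
            out = softmax_pixelwise(out)
            rec = {"probs": out}
        else:  # pragma: no cover
            raise ValueError(f"unknown layer type {layer.type}")
        if keep_cache:
            records.append((layer, rec))
    cache = {"records": records, "pool_indices": pool_indices, "arch": arch}
    return out, cache


def backward(params: dict, cache: dict, dlogits: np.ndarray) -> dict:
    """Backpropagate from the softmax *input* (the loss gradient is usually
    fused with the softmax) down to every trainable parameter.

    Returns a dict keyed like ``params`` with ``(dkernels, dbias)`` for conv
    layers and ``(dgamma, dbeta)`` for batch norms.
    """
    grads: dict = {}
    d = dlogits
    for layer, rec in reversed(cache["records"]):
        if layer.type == "softmax":
            continue  # caller supplies the gradient at the softmax input
        if layer.type == "conv":
            d, dk, db = conv2d_3x3_same_backward(rec["x"], params[layer.name], d)
            grads[layer.name] = (dk, db)
        elif layer.type == "bn":
            d, dg, db = batch_norm_backward(d, params[layer.name], rec["bn"])
            grads[layer.name] = (dg, db)
        elif layer.type == "relu":
            d = relu_backward(d, rec["x"])
        elif layer.type == "pool":
            d = maxpool2x2_backward(d, rec["idx"])
        elif layer.type == "unpool":
            d = maxunpool2x2_backward(d, rec["idx"])
    return grads


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Per-pixel argmax over the 4 channels; ties go to the lowest class."""
    if probs.ndim != 4 or probs.shape[1] != N_CLASSES:
        raise ValueError(f"expected (batch, {N_CLASSES}, H, W), got {probs.shape}")
    return probs.argmax(axis=1).astype(np.uint8)


def _infer_arch(params: dict) -> ArchitectureSpec:
    return build_architecture(filter_width=params["encoder1_conv1"].kernels.shape[0])


# ---------------------------------------------------------------------------
# Checkpoint I/O: a single .npz mapping layer-name.field -> array plus a JSON
# header (architecture hash, class names, normalization note).

FORMAT_VERSION = 1


def save_checkpoint(path, params: dict, arch: ArchitectureSpec, extra: dict | None = None) -> None:
    header = {
        "format_version": FORMAT_VERSION,
        "architecture_hash": arch.hash(),
        "filter_width": arch.filter_width,
        "class_names": list(CLASS_NAMES),
        "normalization": "zero-center per slice",
        "bn_state": {},
    }
    if extra:
        header.update(extra)
    arrays = {}
    for name, p in params.items():
        if isinstance(p, ConvParams):
            arrays[f"{name}.kernels"] = p.kernels
            arrays[f"{name}.bias"] = p.bias
        else:
            arrays[f"{name}.gamma"] = p.gamma
            arrays[f"{name}.beta"] = p.beta
            arrays[f"{name}.running_mean"] = p.running_mean
            arrays[f"{name}.running_var"] = p.running_var
            header["bn_state"][name] = {
                "eps": p.eps,
                "momentum": p.momentum,
                "n_batches_tracked": p.n_batches_tracked,
            }
    arrays["__header__"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[dict, ArchitectureSpec, dict]:
    """Load a checkpoint; rejects files whose architecture hash does not match
    the stack rebuilt from the stored filter width."""
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    header = json.loads(bytes(arrays.pop("__header__")).decode())
    arch = build_architecture(filter_width=header["filter_width"])
    if header["architecture_hash"] != arch.hash():
        raise ValueError(
            f"checkpoint architecture hash {header['architecture_hash']} does not match "
            f"this package's {arch.hash()} (incompatible checkpoint)"
        )
    params: dict = {}
    for layer in arch.layers:
        if layer.type == "conv":
            params[layer.name] = ConvParams(
                kernels=arrays[f"{layer.name}.kernels"],
                bias=arrays[f"{layer.name}.bias"],
            )
        elif layer.type == "bn":
            st = header["bn_state"][layer.name]
            params[layer.name] = BNParams(
                gamma=arrays[f"{layer.name}.gamma"],
                beta=arrays[f"{layer.name}.beta"],
                running_mean=arrays[f"{layer.name}.running_mean"],
                running_var=arrays[f"{layer.name}.running_var"],
                eps=st["eps"],
                momentum=st["momentum"],
                n_batches_tracked=st["n_batches_tracked"],
            )
    return params, arch, header
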