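"""Training environment: class weighting, weighted cross-entropy, augmentation,
SGD with momentum, and the minibatch loop.

The recipe follows the usual practice for small encoder-decoder segmentation
nets on imbalanced pixel classes: median-frequency class weights, on-the-fly
augmentation (random horizontal reflection and rotation within ±10°), SGDM
with learning rate 1e-3 / momentum 0.9 / minibatch 8, batch-norm in train
mode, and the best-by-training-loss parameters returned at the end.
"""

from __future__ import annotations

import copy
import time
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_data import SlicePair, zero_center
from .layers import BNParams, ConvParams
from .network import (
    ArchitectureSpec,
    backward,
    build_architecture,
    forward,
    init_params,
    predict_labels,
)

N_CLASSES = 4
LOG_EPS = 1e-12  # probability floor inside the log


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 8
    max_epochs: int = 40
    seed: int = 0
    augment: bool = True
    rotation_range: float = 10.0  # degrees, uniform in ±range
    class_weight: str = "median-frequency"  # or "uniform"
    filter_width: int = 64
    dtype: str = "float32"
    early_stop_tol: float = 1e-4
    early_stop_patience: int = 10

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not (0.0 <= self.momentum < 1.0):
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.class_weight not in ("median-frequency", "uniform"):
            raise ValueError(f"unknown class_weight scheme {self.class_weight!r}")


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    epochs: list = field(default_factory=list)

    def append(self, **record) -> None:
        self.epochs.append(record)

    def __len__(self) -> int:
        return len(self.epochs)


def compute_class_weights(labels_list, scheme: str = "median-frequency") -> np.ndarray:
    """Median-frequency balancing: weight_c = median(freq) / freq_c.

    Frequencies are pixel counts over the whole collection.  Every class
    must occur at least once, otherwise its weight is undefined.
    """
    counts = np.zeros(N_CLASSES, dtype=np.int64)
    for labels in labels_list:
        counts += np.bincount(np.asarray(labels).ravel(), minlength=N_CLASSES)[:N_CLASSES]
    if (counts == 0).any():
        missing = [c for c in range(N_CLASSES) if counts[c] == 0]
        raise ValueError(f"class(es) {missing} absent from the dataset; weights undefined")
    if scheme == "uniform":
        return np.ones(N_CLASSES)
    if scheme != "median-frequency":
        raise ValueError(f"unknown class_weight scheme {scheme!r}")
    freq = counts / counts.sum()
    return np.median(freq) / freq


def weighted_cross_entropy(probs: np.ndarray, truth: np.ndarray, w: np.ndarray) -> float:
    """Mean over pixels of -w[y] * log p_y, with p floored at 1e-12."""
    truth = np.asarray(truth)
    if probs.shape[0] != truth.shape[0] or probs.shape[2:] != truth.shape[1:]:
        raise ValueError(f"probs shape {probs.shape} incompatible with truth {truth.shape}")
    p_true = np.take_along_axis(probs, truth[:, None].astype(np.int64), axis=1)[:, 0]
    wpix = np.asarray(w)[truth]
    return float(-(wpix * np.log(np.maximum(p_true, LOG_EPS))).sum() / truth.size)


def loss_gradients(
    params: dict,
    batch: tuple[np.ndarray, np.ndarray],
    w: np.ndarray,
    arch: ArchitectureSpec | None = None,
    mode: str = "train",
):
    """Forward + backward on one minibatch.

    Returns ``(loss, probs, grads)`` where grads is keyed like ``params``.
    The softmax and the weighted cross-entropy are fused: the gradient at
    the softmax input is w[y]/N * (p - onehot(y)).
    """
    x, y = batch
    probs, cache = forward(params, x, mode=mode, arch=arch)
    loss = weighted_cross_entropy(probs, y, w)
    n_pix = y.size
    y64 = np.asarray(y, dtype=np.int64)
    dlogits = probs.copy()
    np.put_along_axis(
        dlogits, y64[:, None], np.take_along_axis(dlogits, y64[:, None], axis=1) - 1.0, axis=1
    )
    wpix = np.asarray(w, dtype=probs.dtype)[y64][:, None]
    dlogits *= wpix / n_pix
    grads = backward(params, cache, dlogits.astype(probs.dtype))
    return loss, probs, grads


def augment_pair(pair: SlicePair, rng: np.random.Generator, rotation_range: float = 10.0) -> SlicePair:
    """Random horizontal (X-axis) reflection with probability 1/2, then a
    rotation by an angle uniform in ±rotation_range about the image center.

    The image is interpolated bilinearly, labels by nearest neighbour, and
    out-of-canvas regions are filled with background (0); shapes never change.
    """
    flip = rng.random() < 0.5
    angle = float(rng.uniform(-rotation_range, rotation_range)) if rotation_range > 0 else 0.0
    image, labels = pair.image, pair.labels
    if flip:
        image = image[:, ::-1].copy()
        labels = labels[:, ::-1].copy()
    if angle != 0.0:
        image = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant", cval=0.0)
        labels = ndimage.rotate(
            labels, angle, reshape=False, order=0, mode="constant", cval=0
        ).astype(labels.dtype)
    return SlicePair(image=image, labels=labels, identifier=pair.identifier,
                     zero_centered=pair.zero_centered)


def init_optimizer_state(params: dict) -> dict:
    """Zero velocity arrays congruent to every trainable parameter."""
    state = {}
    for name, p in params.items():
        if isinstance(p, ConvParams):
            state[name] = (np.zeros_like(p.kernels), np.zeros_like(p.bias))
        elif isinstance(p, BNParams):
            state[name] = (np.zeros_like(p.gamma), np.zeros_like(p.beta))
    return state


def sgdm_step(params: dict, grads: dict, state: dict, lr: float, momentum: float) -> None:
    """v <- momentum*v - lr*g;  theta <- theta + v  (in place)."""
    for name, g in grads.items():
        p = params[name]
        v = state[name]
        if isinstance(p, ConvParams):
            targets = (p.kernels, p.bias)
        else:
            targets = (p.gamma, p.beta)
        for arr, vel, grad in zip(targets, v, g):
            vel *= momentum
            vel -= lr * grad.astype(vel.dtype)
            arr += vel


def _as_slice_pair(item) -> SlicePair:
    if isinstance(item, SlicePair):
        return item
    # duck-type PhantomPair and (image, labels) tuples
    if hasattr(item, "image") and hasattr(item, "labels"):
        return SlicePair(image=item.image, labels=item.labels)
    image, labels = item
    return SlicePair(image=np.asarray(image), labels=np.asarray(labels))


def _batch_tensors(pairs, dtype) -> tuple[np.ndarray, np.ndarray]:
    """Zero-center each slice (unless already centered) and stack to (B,1,H,W)."""
    imgs = []
    labs = []
    for p in pairs:
        img = p.image if p.zero_centered else zero_center(p.image)
        imgs.append(np.asarray(img, dtype=dtype))
        labs.append(np.asarray(p.labels, dtype=np.int64))
    return np.stack(imgs)[:, None], np.stack(labs)


def train(
    dataset,
    cfg: TrainConfig,
    val_dataset=None,
    log=None,
) -> tuple[dict, TrainHistory]:
    """Train the network on a dataset of image/label pairs.

    Each epoch shuffles the items, applies augmentation on the fly, and
    steps SGDM per minibatch with batch norm in train mode.  Returns the
    best-by-training-loss parameters (a deep copy, including running
    statistics) and the full history.  Deterministic given ``cfg.seed``.
    """
    cfg.validate()
    pairs = [_as_slice_pair(p) for p in dataset]
    if not pairs:
        raise ValueError("dataset is empty")
    weights = compute_class_weights([p.labels for p in pairs], cfg.class_weight)

    dtype = np.dtype(cfg.dtype).type
    rng = np.random.default_rng(cfg.seed)
    arch = build_architecture(cfg.filter_width)
    params = init_params(arch, rng, dtype=dtype)
    state = init_optimizer_state(params)

    history = TrainHistory()
    best_loss = np.inf
    best_params = copy.deepcopy(params)
    stall = 0

    for epoch in range(cfg.max_epochs):
        t0 = time.perf_counter()
        order = rng.permutation(len(pairs))
        losses = []
        correct = 0
        total = 0
        for start in range(0, len(pairs), cfg.batch_size):
            chunk = [pairs[i] for i in order[start:start + cfg.batch_size]]
            if cfg.augment:
                chunk = [augment_pair(p, rng, cfg.rotation_range) for p in chunk]
            x, y = _batch_tensors(chunk, dtype)
            loss, probs, grads = loss_gradients(params, (x, y), weights, arch, mode="train")
            sgdm_step(params, grads, state, cfg.learning_rate, cfg.momentum)
            losses.append(loss)
            correct += int((predict_labels(probs) == y).sum())
            total += y.size

        record = {
            "epoch": epoch + 1,
            "loss": float(np.mean(losses)),
            "train_accuracy": correct / total,
            "wall_time_s": time.perf_counter() - t0,
        }
        if val_dataset:
            record["val_accuracy"] = _global_accuracy(params, val_dataset, arch, dtype)
        history.append(**record)
        if log is not None:
            log(record)

        if record["loss"] < best_loss - cfg.early_stop_tol:
            best_loss = record["loss"]
            best_params = copy.deepcopy(params)
            stall = 0
        else:
            if record["loss"] < best_loss:
                best_loss = record["loss"]
                best_params = copy.deepcopy(params)
            stall += 1
            if stall >= cfg.early_stop_patience:
                break

    return best_params, history


def _global_accuracy(params, dataset, arch, dtype) -> float:
    correct = 0
    total = 0
    for item in dataset:
        p = _as_slice_pair(item)
        x, y = _batch_tensors([p], dtype)
        probs, _ = forward(params, x, mode="infer", arch=arch, keep_cache=False)
        correct += int((predict_labels(probs) == y).sum())
        total += y.size
    return correct / total


def predict_pairs(params: dict, images, arch: ArchitectureSpec | None = None,
                  dtype=np.float32) -> list[np.ndarray]:
    """Segment a list of raw 2D slices with a trained network (infer mode)."""
    out = []
    for img in images:
        x = np.asarray(zero_center(np.asarray(img)), dtype=dtype)[None, None]
        probs, _ = forward(params, x, mode="infer", arch=arch, keep_cache=False)
        out.append(predict_labels(probs)[0])
    return out
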