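"""Scikit-learn-style estimator wrapping the full segmentation pipeline.

``SegNetSegmenter`` is a pixel classifier: ``fit`` takes a stack of 2D
slices with matching label maps, ``predict`` returns label maps, and
``predict_proba`` per-pixel class probabilities.  It composes with sklearn
model selection (``get_params``/``set_params``/``clone`` all behave), while
the functional modules (:mod:`segbrain.network`, :mod:`segbrain.training`,
:mod:`segbrain.metrics`) remain usable on their own.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .io_data import SlicePair
from .network import (
    build_architecture,
    count_parameters,
    forward,
    load_checkpoint,
    predict_labels,
    save_checkpoint,
)
from .training import TrainConfig, train, compute_class_weights
from .io_data import zero_center


class SegNetSegmenter(BaseEstimator):
    """4-class (background/CSF/GM/WM) encoder-decoder pixel classifier.

    Parameters mirror :class:`segbrain.training.TrainConfig`; the default
    configuration is the full-width (64-filter) network trained by SGDM
    with learning rate 1e-3, momentum 0.9 and minibatch 8.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict
        Trained network parameters (best-by-training-loss).
    arch_ : ArchitectureSpec
        The 31-layer architecture actually built.
    history_ : TrainHistory
        Per-epoch loss / accuracy / wall-time records.
    class_weights_ : ndarray
        The class weights used by the loss.
    n_parameters_ : int
        Trainable scalar count (225,420 at filter width 64).
    """

    def __init__(
        self,
        filter_width: int = 64,
        learning_rate: float = 0.001,
        momentum: float = 0.9,
        batch_size: int = 8,
        max_epochs: int = 40,
        augment: bool = True,
        rotation_range: float = 10.0,
        class_weight: str = "median-frequency",
        seed: int = 0,
        dtype: str = "float32",
        early_stop_tol: float = 1e-4,
        early_stop_patience: int = 10,
    ):
        self.filter_width = filter_width
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.augment = augment
        self.rotation_range = rotation_range
        self.class_weight = class_weight
        self.seed = seed
        self.dtype = dtype
        self.early_stop_tol = early_stop_tol
        self.early_stop_patience = early_stop_patience

    # -- sklearn plumbing ---------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate,
            momentum=self.momentum,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            seed=self.seed,
            augment=self.augment,
            rotation_range=self.rotation_range,
            class_weight=self.class_weight,
            filter_width=self.filter_width,
            dtype=self.dtype,
            early_stop_tol=self.early_stop_tol,
            early_stop_patience=self.early_stop_patience,
        )

    @staticmethod
    def _validate_xy(X, y=None):
        X = [np.asarray(x) for x in X]
        if not X:
            raise ValueError("X is empty")
        for x in X:
            if x.ndim != 2:
                raise ValueError(f"each slice must be 2D, got shape {x.shape}")
            if x.shape[0] % 4 or x.shape[1] % 4:
                raise ValueError(
                    f"slice dims must be divisible by 4, got {x.shape}; "
                    "pad with segbrain.io_data.pad_to_multiple first"
                )
        if y is None:
            return X, None
        y = [np.asarray(m) for m in y]
        if len(y) != len(X):
            raise ValueError(f"X has {len(X)} slices but y has {len(y)} label maps")
        return X, y

    # -- core API -----------------------------------------------------------
    def fit(self, X, y, log=None):
        """Train on slices ``X`` (iterable of 2D arrays or an (n,H,W) array)
        with label maps ``y`` over {0,1,2,3}."""
        X, y = self._validate_xy(X, y)
        pairs = [SlicePair(image=img, labels=lab) for img, lab in zip(X, y)]
        cfg = self._config()
        self.class_weights_ = compute_class_weights([p.labels for p in pairs], cfg.class_weight)
        self.params_, self.history_ = train(pairs, cfg, log=log)
        self.arch_ = build_architecture(cfg.filter_width)
        self.n_parameters_ = count_parameters(self.params_)
        self.classes_ = np.arange(4)
        return self

    def predict_proba(self, X) -> list[np.ndarray]:
        """Per-slice (4, H, W) class-probability maps (inference mode)."""
        self._check_fitted()
        X, _ = self._validate_xy(X)
        out = []
        dtype = np.dtype(self.dtype).type
        for img in X:
            xin = np.asarray(zero_center(img), dtype=dtype)[None, None]
            probs, _ = forward(self.params_, xin, mode="infer", arch=self.arch_, keep_cache=False)
            out.append(probs[0])
        return out

    def predict(self, X) -> list[np.ndarray]:
        """Per-slice label maps (argmax of :meth:`predict_proba`)."""
        return [predict_labels(p[None])[0] for p in self.predict_proba(X)]

    def score(self, X, y) -> float:
        """Global pixel accuracy over the given slices."""
        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        correct = sum(int((p == t).sum()) for p, t in zip(preds, y))
        total = sum(t.size for t in y)
        return correct / total

    def evaluate(self, X, y, bf_tolerance=None) -> dict:
        """Full :mod:`segbrain.metrics` report over a test set."""
        X, y = self._validate_xy(X, y)
        preds = self.predict(X)
        return metrics.evaluate_set(list(zip(preds, y)), bf_tolerance=bf_tolerance)

    # -- persistence ----------------------------------------------------------
    def save(self, path, extra: dict | None = None) -> None:
        self._check_fitted()
        header_extra = {"seed": self.seed}
        if extra:
            header_extra.update(extra)
        save_checkpoint(path, self.params_, self.arch_, extra=header_extra)

    @classmethod
    def load(cls, path) -> "SegNetSegmenter":
        params, arch, header = load_checkpoint(path)
        est = cls(filter_width=arch.filter_width, seed=header.get("seed", 0))
        est.params_ = params
        est.arch_ = arch
        est.n_parameters_ = count_parameters(params)
        est.classes_ = np.arange(4)
        return est

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise RuntimeError("this SegNetSegmenter is not fitted yet; call fit() or load()")
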