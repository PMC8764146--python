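"""Scikit-learn-style estimator facade over the training engine.

``SemiSupervisedSegmenter`` follows the sklearn semi-supervised
convention: samples whose mask is entirely -1 are treated as unlabeled,
so the estimator composes with sklearn model selection utilities while
the heavy lifting stays in :mod:`msstgan.engine`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .data import SyntheticSample
from .engine import TrainConfig, images_to_batch, train_on_samples
from .metrics import binarize, evaluate_set
from .networks import segment

__all__ = ["SemiSupervisedSegmenter"]


class SemiSupervisedSegmenter(BaseEstimator):
    """Adversarially trained lesion segmenter (fit/predict interface).

    Parameters mirror :class:`msstgan.engine.TrainConfig`. ``fit`` expects
    ``X`` of shape (n_samples, H, W, 3) with uint8 RGB values and ``y`` of
    shape (n_samples, H, W) holding binary masks, with unlabeled samples
    marked by an all ``-1`` mask (sklearn's unlabeled sentinel).

    Attributes
    ----------
    segmentor_ : the trained segmentation network
    discriminator_ : the trained patch discriminator
    record_ : per-epoch loss history and validation metrics
    """

    def __init__(self, learning_rate: float = 0.0005, weight_decay: float = 0.0001,
                 batch_size: int = 4, epochs: int = 100, mode: str = "semi",
                 seed: int = 0, image_size: int = 512, encoder_scale: str = "full",
                 threshold: float = 0.5, augment: bool = True,
                 val_fraction: float = 0.25):
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.mode = mode
        self.seed = seed
        self.image_size = image_size
        self.encoder_scale = encoder_scale
        self.threshold = threshold
        self.augment = augment
        self.val_fraction = val_fraction

    def _config(self) -> TrainConfig:
        return TrainConfig(learning_rate=self.learning_rate,
                           weight_decay=self.weight_decay,
                           batch_size=self.batch_size, epochs=self.epochs,
                           mode=self.mode, seed=self.seed,
                           image_size=self.image_size,
                           encoder_scale=self.encoder_scale,
                           threshold=self.threshold, augment=self.augment,
                           val_fraction=self.val_fraction)

    @staticmethod
    def _split(X, y):
        X = np.asarray(X)
        if X.ndim != 4 or X.shape[-1] != 3:
            raise ValueError(f"X must be (n, H, W, 3) RGB, got {X.shape}")
        if y is None:
            raise ValueError("y is required; mark unlabeled samples with all -1")
        y = np.asarray(y)
        if y.shape != X.shape[:3]:
            raise ValueError(f"y shape {y.shape} does not match X {X.shape[:3]}")
        labeled, unlabeled = [], []
        for img, mask in zip(X, y):
            if (mask == -1).all():
                unlabeled.append(SyntheticSample(image=img.astype(np.uint8),
                                                 mask=None, phenotype="point_like",
                                                 seed=-1))
            else:
                if not np.isin(mask, (0, 1)).all():
                    raise ValueError("labeled masks must be binary (or all -1)")
                labeled.append(SyntheticSample(image=img.astype(np.uint8),
                                               mask=mask.astype(np.uint8),
                                               phenotype="flaky", seed=-1))
        return labeled, unlabeled

    def fit(self, X, y):
        labeled, unlabeled = self._split(X, y)
        cfg = self._config()
        if cfg.mode == "semi" and not unlabeled:
            raise ValueError("mode='semi' but y contains no unlabeled (-1) samples")
        g, d, record = train_on_samples(labeled, unlabeled, cfg)
        self.segmentor_ = g
        self.discriminator_ = d
        self.record_ = record
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel lesion probabilities, shape (n, H, W)."""
        check_is_fitted(self, "segmentor_")
        X = np.asarray(X)
        probs = segment(self.segmentor_, images_to_batch(X))
        return probs[:, 0]

    def predict(self, X) -> np.ndarray:
        """Binary lesion masks, shape (n, H, W)."""
        return binarize(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean Dice coefficient over the given labeled set."""
        probs = self.predict_proba(X)
        report = evaluate_set(list(probs), [np.asarray(m) for m in y],
                              threshold=self.threshold)
        return report.mean("dsc")
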