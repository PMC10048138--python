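"""Median-frequency class balancing and the weighted pixel loss.

Severely imbalanced segmentation data (background dominates, scar is rare)
biases an unweighted learner towards the majority class.  Median-frequency
balancing sets each class weight to

    W_i = median(F) / F_i

where F_i is the relative pixel frequency of class i, so the class at the
median frequency gets weight 1, rarer classes are boosted and the dominant
class is attenuated.  For an even number of classes the median is the mean
of the two middle order statistics, which makes the harmonic mean of the two
straddling weights exactly 1 -- a useful self-check on any published weight
vector.

The weights enter training through a class-weighted softmax cross-entropy
averaged over the pixel count (not the weight sum, so learning-rate semantics
do not depend on the weight scale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor
from .nn import functional as F

__all__ = ["ClassWeights", "median_frequency_weights", "weighted_pixel_loss"]


@dataclass
class ClassWeights:
    """Strictly positive per-class loss weights."""

    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.weights.ndim != 1 or self.weights.size < 2:
            raise ValueError("weights must be a vector of >= 2 classes")
        if not np.all(self.weights > 0):
            raise ValueError("all class weights must be strictly positive")

    def __len__(self):
        return self.weights.size

    @classmethod
    def uniform(cls, n_classes: int) -> "ClassWeights":
        return cls(np.ones(n_classes))


def median_frequency_weights(frequencies) -> ClassWeights:
    """W_i = median(F) / F_i for a vector of relative class frequencies.

    Raises if any frequency is zero: a class with no pixels has no finite
    weight -- drop the class or floor its frequency before calling.
    """
    f = np.asarray(frequencies, dtype=np.float64)
    if np.any(f == 0):
        raise ZeroDivisionError(
            "zero class frequency: drop the class or floor its frequency "
            "before computing median-frequency weights")
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    return ClassWeights(np.median(f) / f)


def weighted_pixel_loss(class_scores, labels, weights: ClassWeights) -> Tensor:
    """Weight-scaled softmax cross-entropy averaged over pixels.

    ``class_scores`` may be a (H, W, C) array/Tensor for one image or a
    (N, C, H, W) batch; ``labels`` the matching integer grid(s).  Returns a
    scalar Tensor; call ``.backward()`` for gradients with respect to the
    scores, or ``.item()`` for the value.
    """
    scores = class_scores if isinstance(class_scores, Tensor) else Tensor(class_scores)
    labels = np.asarray(labels)
    if scores.data.ndim == 3:  # (H, W, C) -> (1, C, H, W)
        scores = _hwc_to_nchw(scores)
        labels = labels[None]
    w = weights.weights if isinstance(weights, ClassWeights) else np.asarray(weights)
    return F.weighted_cross_entropy(scores, labels, w)


def _hwc_to_nchw(scores: Tensor) -> Tensor:
    data = np.transpose(scores.data, (2, 0, 1))[None]

    def backward(g):
        scores.accumulate_grad(np.transpose(g[0], (1, 2, 0)))

    return Tensor.from_op(data, (scores,), backward)
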