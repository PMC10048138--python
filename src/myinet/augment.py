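"""Training-time geometric augmentation.

Two joint transforms are applied on the fly to training images only:
uniform random rotation over [0, 360) degrees and uniform random scaling
in [0.9, 1.1].  Pixels are interpolated bilinearly; label masks use
nearest-neighbour so class codes are preserved.  Regions exposed by the
transform are filled with the image's own background intensity (median of
its background-labelled pixels) and label 0.  Exact multiples of 90 degrees
take a lossless grid-rotation path.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import rescale, rotate

from .phantom import LabeledImage

__all__ = ["rotate_labeled", "scale_labeled", "random_rotation", "random_scale",
           "augment_pair"]


def _background_fill(li: LabeledImage) -> float:
    bg = li.pixels[li.labels == 0]
    return float(np.median(bg)) if bg.size else 0.0


def rotate_labeled(li: LabeledImage, angle: float) -> LabeledImage:
    """Rotate pixels and labels jointly by ``angle`` degrees (CCW)."""
    angle = float(angle) % 360.0
    if angle == 0.0:
        return LabeledImage(li.pixels.copy(), li.labels.copy(),
                            li.patient_id, li.slice_index)
    if angle % 90.0 == 0.0 and li.pixels.shape[0] == li.pixels.shape[1]:
        k = int(angle // 90)
        return LabeledImage(np.rot90(li.pixels, k).copy(),
                            np.rot90(li.labels, k).copy(),
                            li.patient_id, li.slice_index)
    fill = _background_fill(li)
    pixels = rotate(li.pixels, angle, order=1, cval=fill, preserve_range=True)
    labels = rotate(li.labels.astype(float), angle, order=0, cval=0.0,
                    preserve_range=True).astype(np.int64)
    return LabeledImage(np.clip(pixels, 0.0, 1.0), labels,
                        li.patient_id, li.slice_index)


def scale_labeled(li: LabeledImage, factor: float) -> LabeledImage:
    """Scale about the image centre, then crop/pad back to the input size."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    if factor == 1.0:
        return LabeledImage(li.pixels.copy(), li.labels.copy(),
                            li.patient_id, li.slice_index)
    h, w = li.pixels.shape
    fill = _background_fill(li)
    pixels = rescale(li.pixels, factor, order=1, preserve_range=True)
    labels = rescale(li.labels.astype(float), factor, order=0,
                     preserve_range=True).astype(np.int64)

    def fit(arr, cval):
        ah, aw = arr.shape
        out = np.full((h, w), cval, dtype=arr.dtype)
        if ah >= h:  # centre crop
            top, left = (ah - h) // 2, (aw - w) // 2
            out[...] = arr[top:top + h, left:left + w]
        else:  # centre pad
            top, left = (h - ah) // 2, (w - aw) // 2
            out[top:top + ah, left:left + aw] = arr
        return out

    return LabeledImage(np.clip(fit(pixels, fill), 0.0, 1.0),
                        fit(labels, np.int64(0)),
                        li.patient_id, li.slice_index)


def random_rotation(li: LabeledImage, rng: np.random.Generator) -> LabeledImage:
    """Rotation by an angle drawn uniformly from [0, 360)."""
    return rotate_labeled(li, rng.uniform(0.0, 360.0))


def random_scale(li: LabeledImage, rng: np.random.Generator) -> LabeledImage:
    """Scaling by a factor drawn uniformly from [0.9, 1.1]."""
    return scale_labeled(li, rng.uniform(0.9, 1.1))


def augment_pair(li: LabeledImage, rng: np.random.Generator,
                 rotation: bool = True, scaling: bool = True) -> LabeledImage:
    """The training-time augmentation chain: rotation then scaling."""
    if rotation:
        li = random_rotation(li, rng)
    if scaling:
        li = random_scale(li, rng)
    return li
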