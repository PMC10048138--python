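"""Full segmentation model: backbone + ASPP + decoder.

The pipeline follows the encoder/context/decoder flow:

1. a backbone feature extractor produces low-level (H/4) and high-level
   (H/16) feature grids;
2. atrous spatial pyramid pooling fuses multi-rate context on the high-level
   grid;
3. the decoder up-samples the context features x4 bilinearly, concatenates
   them with 1x1-projected low-level features, refines with two 3x3
   convolutions and projects to per-class scores;
4. a final x4 bilinear up-sampling restores the input resolution, yielding an
   H x W x n_classes score map.

Three named variants are constructible: ``MI-ResNet50-AC``, ``MI-ResNet18-AC``
and ``MI-MobileNet-AC``.  Decoder widths (48-channel low-level projection,
256-channel refinement, both thinned by the width multiplier) follow common
encoder-decoder practice.
"""

from __future__ import annotations

import numpy as np

from .aspp import Aspp, AsppSpec
from .backbones import ModelSpec, build_backbone
from .nn import BatchNorm2d, Conv2d, Module, ReLU, Sequential, Tensor
from .nn import functional as F

__all__ = ["SegmentationModel", "VARIANTS", "build_myinet", "build_variant",
           "segment"]

#: Published variant name -> backbone identifier.
VARIANTS = {
    "MI-ResNet50-AC": "mi-resnet50",
    "MI-ResNet18-AC": "mi-resnet18",
    "MI-MobileNet-AC": "mi-mobilenetv2",
}


class SegmentationModel(Module):
    def __init__(self, spec: ModelSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        seed_pool = rng.integers(0, 2**31 - 1, size=4)
        self.backbone = build_backbone(spec, int(seed_pool[0]))
        aspp_spec = AsppSpec(in_channels=self.backbone.high_level_channels,
                             branch_channels=spec.channels(spec.aspp_channels),
                             base_rate=spec.atrous_base_rate)
        self.aspp = Aspp(aspp_spec, np.random.default_rng(int(seed_pool[1])))

        rng_dec = np.random.default_rng(int(seed_pool[2]))
        c_low = spec.channels(48)
        c_ref = spec.channels(256)
        self.low_proj = Sequential(
            Conv2d(self.backbone.low_level_channels, c_low, 1, rng_dec),
            BatchNorm2d(c_low), ReLU())
        self.refine = Sequential(
            Conv2d(aspp_spec.branch_channels + c_low, c_ref, 3, rng_dec, padding=1),
            BatchNorm2d(c_ref), ReLU(),
            Conv2d(c_ref, c_ref, 3, rng_dec, padding=1),
            BatchNorm2d(c_ref), ReLU())
        rng_cls = np.random.default_rng(int(seed_pool[3]))
        self.classifier = Conv2d(c_ref, spec.n_classes, 1, rng_cls, bias=True)

    def forward(self, x) -> Tensor:
        """Batch (N, 1, H, W) -> per-class scores (N, n_classes, H, W)."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, _, h, w = x.data.shape
        if h % self.spec.output_stride or w % self.spec.output_stride:
            raise ValueError(
                f"input size {h}x{w} must be divisible by the output stride "
                f"{self.spec.output_stride}")
        low, high = self.backbone(x)
        ctx = self.aspp(high)
        ctx = F.resize_bilinear(ctx, low.data.shape[-2:])
        fused = F.concat([ctx, self.low_proj(low)], axis=1)
        scores = self.classifier(self.refine(fused))
        return F.resize_bilinear(scores, (h, w))

    def predict_scores(self, image: np.ndarray) -> np.ndarray:
        """(H, W) image -> (H, W, n_classes) scores, in inference mode."""
        image = np.asarray(image, dtype=np.float64)
        if image.ndim != 2:
            raise ValueError("expected a single 2-D grayscale image")
        was_training = self.training
        self.eval()
        try:
            out = self.forward(image[None, None])
        finally:
            self.train(was_training)
        return np.transpose(out.data[0], (1, 2, 0))


def build_myinet(spec: ModelSpec, seed: int = 0) -> SegmentationModel:
    """Assemble the full model from an architecture spec with seeded init."""
    return SegmentationModel(spec, np.random.default_rng(seed))


def build_variant(name: str, seed: int = 0, **overrides) -> SegmentationModel:
    """Build one of the named variants (see :data:`VARIANTS`)."""
    if name not in VARIANTS:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")
    return build_myinet(ModelSpec(backbone=VARIANTS[name], **overrides), seed)


def segment(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax labels for one image; ties go to the lowest class."""
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("non-finite intensities in input image")
    scores = model.predict_scores(image)
    return np.argmax(scores, axis=-1).astype(np.int64)
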