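"""Cardiac LGE-CMR semantic segmentation toolkit.

An end-to-end pipeline for four-class segmentation of short-axis
late-gadolinium-enhancement cardiac MRI slices (background / blood pool /
myocardium / LGE scar): residual and MobileNet-style feature extractors with
atrous spatial pyramid pooling and an up-sampling decoder, median-frequency
class balancing, a momentum-SGD training loop with step decay and early
stopping, a boundary-aware evaluation suite, and a synthetic cardiac phantom
generator that stands in for clinical data.
"""

from . import aspp, augment, backbones, io, metrics, model, nn, phantom, training, weighting
from .backbones import ModelSpec, dsc_cost
from .metrics import evaluate_dataset
from .model import VARIANTS, build_myinet, build_variant, segment
from .phantom import (Cohort, LabeledImage, PhantomParams, class_frequencies,
                      generate_cohort, generate_phantom)
from .training import TrainConfig, TrainHistory, lr_schedule, train
from .weighting import ClassWeights, median_frequency_weights, weighted_pixel_loss

__version__ = "0.1.0"

__all__ = [
    "ModelSpec", "dsc_cost", "evaluate_dataset", "VARIANTS", "build_myinet",
    "build_variant", "segment", "Cohort", "LabeledImage", "PhantomParams",
    "class_frequencies", "generate_cohort", "generate_phantom", "TrainConfig",
    "TrainHistory", "lr_schedule", "train", "ClassWeights",
    "median_frequency_weights", "weighted_pixel_loss",
    "aspp", "augment", "backbones", "io", "metrics", "model", "nn", "phantom",
    "training", "weighting",
]
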