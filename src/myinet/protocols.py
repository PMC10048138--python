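"""Frozen desk-scale study protocols.

These are the package's reference experiments at laptop scale: small phantom
cohorts, reduced network width, the standard optimisation regimen.  They are
used by the regression tests and by ``scripts/acceptance.py`` so that both
always run the identical protocol.

The desk-scale learning protocol trains a width-halved MI-ResNet18-AC on a
60-slice phantom cohort (20 patients x 3 slices at 64x64, split 48 train /
12 validation by patient) for at most 30 epochs under the standard regimen
(initial rate 1e-3, factor-1/3 drop every 10 epochs, batch 10, momentum 0.9,
patience 4), once with median-frequency class weights and once unweighted.
The unweighted run is the global-accuracy reference -- plain cross-entropy
optimises exactly that metric -- while the weighted run trades global
accuracy for recall on the rare LGE class; comparing the two quantifies what
the class weighting buys.
"""

from __future__ import annotations

import numpy as np

from .metrics import confusion_matrix, evaluate_dataset
from .model import build_variant, segment
from .phantom import PhantomParams, generate_cohort
from .training import TrainConfig, train

__all__ = ["DESK_COHORT", "desk_scale_learning"]

#: Conditions of the desk-scale learning protocol.
DESK_COHORT = dict(n_patients=20, slices_per_patient=3, image_size=64,
                   fractions=(0.8, 0.2, 0.0), width_multiplier=0.5,
                   max_epochs=30)


def desk_scale_learning(seed: int = 11, max_epochs: int | None = None) -> dict:
    """Run the desk-scale learning protocol; returns a result dictionary.

    Keys: ``gacc_unweighted``, ``gacc_weighted`` (validation global
    accuracy of the best-validation model), ``lge_recall_unweighted``,
    ``lge_recall_weighted``, ``wiou_unweighted``, ``bfscore_unweighted``,
    ``epochs_{un,}weighted``, ``history_{un,}weighted``.
    """
    p = DESK_COHORT
    cohort = generate_cohort(
        p["n_patients"], p["slices_per_patient"],
        PhantomParams.default(p["image_size"]), seed=seed,
        fractions=p["fractions"])
    val = cohort.split("validation")
    out: dict = {}
    for tag, balance in (("unweighted", "none"), ("weighted", "median_frequency")):
        model = build_variant("MI-ResNet18-AC", seed=seed,
                              width_multiplier=p["width_multiplier"])
        cfg = TrainConfig(max_epochs=max_epochs or p["max_epochs"], seed=seed,
                          balance=balance)
        model, history = train(model, cohort, cfg)
        preds = [segment(model, im.pixels) for im in val]
        gts = [im.labels for im in val]
        cm = confusion_matrix(gts, preds)
        report = evaluate_dataset(list(zip(gts, preds)))
        lge_recall = (cm.counts[3, 3] / cm.true_totals[3]
                      if cm.true_totals[3] else float("nan"))
        out[f"gacc_{tag}"] = report.global_accuracy
        out[f"wiou_{tag}"] = report.weighted_iou
        out[f"bfscore_{tag}"] = report.dataset_bfscore
        out[f"lge_recall_{tag}"] = float(lge_recall)
        out[f"epochs_{tag}"] = len(history)
        out[f"history_{tag}"] = history
    return out
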