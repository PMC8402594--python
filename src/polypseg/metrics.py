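"""Pixel-wise evaluation of predicted polyp masks.

All metrics derive from the per-image confusion counts between a predicted
binary mask and its expert ground truth: TP are polyp pixels predicted as
polyp, FP background pixels predicted as polyp, TN background predicted
background, FN polyp predicted background.

Two aggregation modes are provided. ``per_image_mean`` (the default)
averages each metric over images, keeping every image equally weighted;
``dataset_aggregate`` sums the confusion counts over the whole set first, so
the class IoUs are those of the pooled pixel population and mean IoU is
exactly the arithmetic mean of the two class IoUs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_from_masks",
    "compute_metrics",
    "aggregate_per_image",
    "aggregate_counts",
    "bin_accuracies",
    "ACCURACY_BIN_EDGES",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "iou_polyp", "iou_background", "mean_iou", "dice", "f2")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    iou_polyp: float
    iou_background: float
    mean_iou: float
    dice: float
    f2: float
    aggregation_mode: str = "single_image"
    degenerate_flags: List[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        d = {name: getattr(self, name) for name in METRIC_NAMES}
        d["aggregation_mode"] = self.aggregation_mode
        if self.degenerate_flags:
            d["degenerate_flags"] = list(self.degenerate_flags)
        return d


def _check_binary(arr: np.ndarray, what: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{what} mask must be strictly binary (0/1)")
    return arr.astype(bool)


def confusion_from_masks(predicted: np.ndarray,
                         truth: np.ndarray) -> ConfusionCounts:
    """Pixel tally of TP/FP/TN/FN between two binary masks."""
    pred = _check_binary(predicted, "predicted")
    true = _check_binary(truth, "truth")
    if pred.shape != true.shape:
        raise ValueError(
            f"resolution mismatch: {pred.shape} vs {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    tn = int(np.count_nonzero(~pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, vacuous_ok: bool,
           flags: List[str], name: str) -> float:
    """num/den with the zero-denominator convention: 1.0 when the condition
    the metric tests is vacuously satisfied, else 0.0."""
    if den > 0:
        return num / den
    flags.append(name)
    return 1.0 if vacuous_ok else 0.0


def compute_metrics(counts: ConfusionCounts,
                    aggregation_mode: str = "single_image") -> MetricReport:
    """The full metric suite from one set of confusion counts.

    accuracy=(TP+TN)/total, sensitivity=TP/(TP+FN), specificity=TN/(TN+FP),
    precision=TP/(TP+FP), IoU_polyp=TP/(TP+FP+FN),
    IoU_background=TN/(TN+FP+FN), dice=2TP/(2TP+FP+FN) and
    F2 = 5*precision*sensitivity / (4*precision + sensitivity)
    (the F-beta measure at beta=2, weighting recall over precision).

    Zero denominators (an image with no polyp pixels, say) return 1.0 when
    the metric's condition holds vacuously and there are no contradicting
    errors, else 0.0; such cases are listed in ``degenerate_flags`` so
    per-image averages remain total.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    if counts.total == 0:
        raise ValueError("empty confusion counts")
    flags: List[str] = []
    accuracy = (tp + tn) / counts.total
    sensitivity = _ratio(tp, tp + fn, fp == 0, flags, "sensitivity")
    specificity = _ratio(tn, tn + fp, fn == 0, flags, "specificity")
    precision = _ratio(tp, tp + fp, fn == 0, flags, "precision")
    iou_polyp = _ratio(tp, tp + fp + fn, True, flags, "iou_polyp")
    iou_background = _ratio(tn, tn + fp + fn, True, flags, "iou_background")
    dice = _ratio(2 * tp, 2 * tp + fp + fn, True, flags, "dice")
    if 4 * precision + sensitivity > 0:
        f2 = 5 * precision * sensitivity / (4 * precision + sensitivity)
    else:
        flags.append("f2")
        f2 = 1.0 if tp + fp + fn == 0 else 0.0
    return MetricReport(accuracy=accuracy, sensitivity=sensitivity,
                        specificity=specificity, precision=precision,
                        iou_polyp=iou_polyp, iou_background=iou_background,
                        mean_iou=(iou_polyp + iou_background) / 2.0,
                        dice=dice, f2=f2, aggregation_mode=aggregation_mode,
                        degenerate_flags=flags)


def aggregate_per_image(reports: Sequence[MetricReport]) -> MetricReport:
    """Arithmetic mean of each metric over images (``per_image_mean``)."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    means = {name: float(np.mean([getattr(r, name) for r in reports]))
             for name in METRIC_NAMES}
    flags = sorted({f for r in reports for f in r.degenerate_flags})
    return MetricReport(**means, aggregation_mode="per_image_mean",
                        degenerate_flags=flags)


def aggregate_counts(counts: Iterable[ConfusionCounts]) -> MetricReport:
    """Pool confusion counts over the dataset, then compute the metrics
    (``dataset_aggregate``): mean IoU is the mean of the pooled class IoUs."""
    total = None
    for c in counts:
        total = c if total is None else total + c
    if total is None:
        raise ValueError("cannot aggregate an empty count list")
    return compute_metrics(total, aggregation_mode="dataset_aggregate")


#: lower bin edges of the per-image accuracy histogram, best range first
ACCURACY_BIN_EDGES = (0.90, 0.80, 0.70, 0.60, 0.50, 0.0)


def bin_accuracies(per_image_accuracies: Sequence[float]) -> Tuple[int, ...]:
    """Histogram of per-image accuracies over the six standard ranges
    ([0.9, 1], [0.8, 0.9), ..., [0.5, 0.6), [0, 0.5)); counts sum to the
    number of images."""
    acc = np.asarray(per_image_accuracies, dtype=float)
    if acc.size and (acc.min() < 0.0 or acc.max() > 1.0):
        raise ValueError("accuracies must lie in [0, 1]")
    bins = [0] * len(ACCURACY_BIN_EDGES)
    for a in np.atleast_1d(acc):
        for i, lo in enumerate(ACCURACY_BIN_EDGES):
            if a >= lo:
                bins[i] += 1
                break
    return tuple(bins)
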