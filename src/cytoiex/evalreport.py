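"""Classification metrics and annotated reporting.

Positive class is malignant throughout: precision measures how many flagged
cells are truly malignant, recall how many malignant cells were found.  The
reject option ("unclassified") is counted as a negative (normal) prediction by
default — a conservative policy for a screening tool — or excluded entirely.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from skimage.segmentation import find_boundaries

from .iextreme import UNCLASSIFIED

POSITIVE = "malignant"
NEGATIVE = "normal"

_COLORS = {
    "malignant": (220, 30, 30),
    "normal": (30, 180, 30),
    UNCLASSIFIED: (240, 200, 30),
}


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int
    n_unclassified: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    zero_denominator: bool = False

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def confusion(
    labels, predictions, unclassified_policy: str = "as-normal"
) -> ConfusionCounts:
    """Tally confusion counts with malignant as the positive class.

    ``unclassified_policy`` is either ``"as-normal"`` (rejections score as
    negative predictions) or ``"exclude"`` (rejections are dropped from the
    scored set); either way they are tallied in ``n_unclassified``.
    """
    labels = list(labels)
    predictions = list(predictions)
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions must have equal length")
    if unclassified_policy not in ("as-normal", "exclude"):
        raise ValueError(f"unknown unclassified_policy {unclassified_policy!r}")
    tp = tn = fp = fn = n_unc = 0
    for truth, pred in zip(labels, predictions):
        if truth not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown label value {truth!r}")
        if pred == UNCLASSIFIED:
            n_unc += 1
            if unclassified_policy == "exclude":
                continue
            pred = NEGATIVE
        elif pred not in (POSITIVE, NEGATIVE):
            raise ValueError(f"unknown prediction value {pred!r}")
        if truth == POSITIVE:
            tp += pred == POSITIVE
            fn += pred == NEGATIVE
        else:
            fp += pred == POSITIVE
            tn += pred == NEGATIVE
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn, n_unclassified=n_unc)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator precision or recall is reported as 0 with a flag rather
    than raising.
    """
    if counts.total < 1:
        raise ValueError("no scored cells")
    accuracy = (counts.tp + counts.tn) / counts.total
    zero = False
    if counts.tp + counts.fp > 0:
        precision = counts.tp / (counts.tp + counts.fp)
    else:
        precision, zero = 0.0, True
    if counts.tp + counts.fn > 0:
        recall = counts.tp / (counts.tp + counts.fn)
    else:
        recall, zero = 0.0, True
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return MetricsReport(
        accuracy=accuracy, precision=precision, recall=recall, f1=f1,
        counts=counts, zero_denominator=zero,
    )


def evaluate(labels, predictions, unclassified_policy: str = "as-normal") -> MetricsReport:
    """Convenience: confusion counts plus metrics in one call."""
    return metrics(confusion(labels, predictions, unclassified_policy))


def annotate(
    image: np.ndarray,
    masks: list[np.ndarray],
    predictions,
    memberships: np.ndarray | None = None,
    class_order: list[str] | None = None,
    lesion_fraction: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Color-coded contour overlay plus a structured per-cell report.

    Contours: red = malignant, green = normal, yellow = unclassified.  The
    report lists each cell's decision and (when supplied) its per-class
    membership values, plus aggregate counts and the lesion fraction.
    """
    image = np.asarray(image)
    overlay = image.copy() if image.ndim == 3 else np.stack([image] * 3, axis=-1).copy()
    predictions = list(predictions)
    cells = []
    class_counts: dict[str, int] = {}
    for i, (mask, pred) in enumerate(zip(masks, predictions)):
        color = _COLORS.get(pred, (128, 128, 128))
        boundary = find_boundaries(np.asarray(mask, dtype=bool), mode="inner")
        overlay[boundary] = color
        record: dict = {"id": i, "decision": str(pred)}
        if memberships is not None and class_order is not None:
            for j, c in enumerate(class_order):
                record[f"mu_{c}"] = float(memberships[i, j])
        cells.append(record)
        class_counts[str(pred)] = class_counts.get(str(pred), 0) + 1
    report = {"cells": cells, "counts": class_counts}
    if lesion_fraction is not None:
        report["lesion_fraction"] = float(lesion_fraction)
    return overlay, report
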