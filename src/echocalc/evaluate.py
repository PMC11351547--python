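"""Detection matching, classification metrics and dataset-split utilities.

Detection quality is scored by greedy one-to-one matching of predictions to
ground-truth boxes in descending confidence order: a prediction is a true positive
iff it can claim an unmatched truth with IoU >= the threshold (default 0.5); leftover
predictions are false positives and leftover truths false negatives.  Precision,
recall and F1 are derived from unrounded counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotations import BoundingBox
from .errors import LengthError
from .manifest import DatasetManifest

__all__ = [
    "MetricsReport",
    "iou",
    "match_detections",
    "classification_metrics",
    "split_manifest",
    "kfold",
]


@dataclass
class MetricsReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int | None = None  # absent for detection

    @property
    def precision(self) -> float | None:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) > 0 else None

    @property
    def recall(self) -> float | None:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) > 0 else None

    @property
    def f1(self) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    @property
    def accuracy(self) -> float | None:
        if self.tn is None:
            return None
        total = self.tp + self.fp + self.fn + self.tn
        return (self.tp + self.tn) / total if total else None

    def asdict(self) -> dict:
        out = {"tp": self.tp, "fp": self.fp, "fn": self.fn}
        if self.tn is not None:
            out["tn"] = self.tn
            out["accuracy"] = self.accuracy
        out["precision"] = self.precision
        out["recall"] = self.recall
        out["f1"] = self.f1
        return out


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open pixel boxes."""
    ix = max(0, min(a.x_max, b.x_max) - max(a.x_min, b.x_min))
    iy = max(0, min(a.y_max, b.y_max) - max(a.y_min, b.y_min))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def match_detections(
    predictions: dict[str, list],
    truths: dict[str, list[BoundingBox]],
    iou_threshold: float = 0.5,
) -> MetricsReport:
    """Greedy confidence-ordered matching of per-image predictions to truth boxes.

    ``predictions`` maps image id to a list of :class:`~echocalc.models.DetectionResult`
    (or plain ``(confidence, box)`` pairs); every key must exist in ``truths``.
    """
    report = MetricsReport()
    for image_id, preds in predictions.items():
        truth_boxes = truths[image_id]  # KeyError on id mismatch is intentional
        entries = []
        for p in preds:
            if isinstance(p, tuple):
                conf, box = p
            else:
                conf, box = p.confidence, p.box
            entries.append((conf, box))
        order = sorted(range(len(entries)), key=lambda i: -entries[i][0])
        unmatched = list(range(len(truth_boxes)))
        for i in order:
            _, box = entries[i]
            best_j, best_iou = None, 0.0
            for j in unmatched:
                v = iou(box, truth_boxes[j])
                if v > best_iou:
                    best_j, best_iou = j, v
            if best_j is not None and best_iou >= iou_threshold and iou_threshold > 0:
                unmatched.remove(best_j)
                report.tp += 1
            elif iou_threshold == 0 and best_j is not None and best_iou > 0:
                unmatched.remove(best_j)
                report.tp += 1
            else:
                report.fp += 1
        report.fn += len(unmatched)
    # images with truths but no prediction entry at all
    for image_id, boxes in truths.items():
        if image_id not in predictions:
            report.fn += len(boxes)
    return report


def classification_metrics(labels, preds) -> MetricsReport:
    """Confusion counts and derived metrics for binary labels/predictions."""
    labels = [bool(v) for v in labels]
    preds = [bool(v) for v in preds]
    if len(labels) != len(preds):
        raise LengthError(f"labels ({len(labels)}) and predictions ({len(preds)}) differ")
    report = MetricsReport(tn=0)
    for y, p in zip(labels, preds):
        if y and p:
            report.tp += 1
        elif not y and p:
            report.fp += 1
        elif y and not p:
            report.fn += 1
        else:
            report.tn += 1
    return report


def split_manifest(
    manifest: DatasetManifest,
    fractions: tuple[float, ...],
    seed: int,
    names: tuple[str, ...] | None = None,
    group_aware: bool = False,
) -> list[DatasetManifest]:
    """Seeded shuffle then contiguous partition by ``fractions`` (must sum to 1).

    Sizes are floors of ``fraction * n`` with the remainder assigned to the first
    (training) split.  With ``group_aware=True`` the shuffle-and-partition happens on
    group ids instead, so an original stays with its augmented/duplicated variants;
    split sizes then depend on group sizes.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if names is None:
        names = ("train", "val", "test")[: len(fractions)]
        if len(names) < len(fractions):
            names = tuple(f"split{i}" for i in range(len(fractions)))
    rng = np.random.default_rng(seed)

    if group_aware:
        groups = list(dict.fromkeys(s.group for s in manifest))
        order = rng.permutation(len(groups))
        units = [groups[i] for i in order]
    else:
        order = rng.permutation(len(manifest))
        units = [manifest[int(i)] for i in order]

    n = len(units)
    sizes = [int(f * n) for f in fractions]
    sizes[0] += n - sum(sizes)

    parts, start = [], 0
    for size, name in zip(sizes, names):
        chunk = units[start : start + size]
        start += size
        if group_aware:
            selected = set(chunk)
            part = manifest.subset(lambda s, sel=selected: s.group in sel)
        else:
            part = DatasetManifest(list(chunk))
        parts.append(part.with_split(name))
    return parts


def kfold(manifest: DatasetManifest, k: int, seed: int) -> list[DatasetManifest]:
    """Seeded shuffle into k disjoint folds with balanced sizes (remainder spread
    over the first folds): 61 samples with k=5 gives folds of 13,12,12,12,12."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(manifest)
    if k > n:
        raise ValueError(f"k={k} exceeds the manifest size {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        idx = order[start : start + size]
        start += size
        folds.append(DatasetManifest([manifest[int(j)] for j in idx]).with_split(f"fold{i}"))
    return folds
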