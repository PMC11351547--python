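"""Bounding-box data model, CSV persistence, ROI cropping and detector-format export.

Coordinates are 0-based, half-open pixel intervals: a box covers the pixel grid
``[x_min, x_max) x [y_min, y_max)`` so ``width = x_max - x_min`` with no off-by-one
ambiguity.  The annotation CSV schema is ``image_id,x_min,y_min,x_max,y_max`` with a
header row; one row per valve box.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import BoundsError, SchemaError

#: Single object class: the aortic valve.
AORTIC_VALVE_CLASS = 0

CSV_COLUMNS = ("image_id", "x_min", "y_min", "x_max", "y_max")


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle in pixel coordinates, half-open on both axes."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (0 <= self.x_min < self.x_max and 0 <= self.y_min < self.y_max):
            raise ValueError(
                f"invalid box: need 0 <= x_min < x_max and 0 <= y_min < y_max, "
                f"got ({self.x_min}, {self.y_min}, {self.x_max}, {self.y_max})"
            )

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    @property
    def area(self) -> int:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2.0, (self.y_min + self.y_max) / 2.0)

    def shifted(self, dx: int, dy: int) -> "BoundingBox":
        return BoundingBox(self.x_min + dx, self.y_min + dy, self.x_max + dx, self.y_max + dy)

    def clipped(self, width: int, height: int) -> "BoundingBox | None":
        """Intersect with the image extent; ``None`` if the intersection is empty."""
        x0, y0 = max(self.x_min, 0), max(self.y_min, 0)
        x1, y1 = min(self.x_max, width), min(self.y_max, height)
        if x0 >= x1 or y0 >= y1:
            return None
        return BoundingBox(x0, y0, x1, y1)

    def astuple(self) -> tuple[int, int, int, int]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)


@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    box: BoundingBox
    label: int = AORTIC_VALVE_CLASS


def write_annotations_csv(records: list[AnnotationRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow([rec.image_id, *rec.box.astuple()])


def read_annotations_csv(path: str | Path) -> list[AnnotationRecord]:
    """Read annotation records; raises :class:`SchemaError` on a bad header and
    ``ValueError`` on inverted/degenerate coordinates."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected header {','.join(CSV_COLUMNS)}")
        missing = [c for c in CSV_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing columns {missing}")
        records = []
        for row in reader:
            box = BoundingBox(
                int(row["x_min"]), int(row["y_min"]), int(row["x_max"]), int(row["y_max"])
            )
            records.append(AnnotationRecord(image_id=row["image_id"], box=box))
    return records


def crop_roi(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Crop the region of interest (the valve area) delimited by ``box``.

    Output pixel (0, 0) is input pixel (x_min, y_min); the output extent is
    (height, width) = (y_max - y_min, x_max - x_min).
    """
    h, w = image.shape[:2]
    if box.x_max > w or box.y_max > h:
        raise BoundsError(f"box {box.astuple()} exceeds image extent {w}x{h}")
    return image[box.y_min : box.y_max, box.x_min : box.x_max].copy()


def to_detector_record(
    box: BoundingBox, image_w: int, image_h: int
) -> tuple[int, float, float, float, float]:
    """Normalized ``(class, cx, cy, w, h)`` record for detector training files."""
    if box.x_max > image_w or box.y_max > image_h:
        raise BoundsError(f"box {box.astuple()} exceeds image extent {image_w}x{image_h}")
    cx = (box.x_min + box.x_max) / (2.0 * image_w)
    cy = (box.y_min + box.y_max) / (2.0 * image_h)
    return (AORTIC_VALVE_CLASS, cx, cy, box.width / image_w, box.height / image_h)


def from_detector_record(
    record: tuple[int, float, float, float, float], image_w: int, image_h: int
) -> BoundingBox:
    """Inverse of :func:`to_detector_record`, exact to within 1 px of quantization."""
    _, cx, cy, w, h = record
    x_min = round(cx * image_w - w * image_w / 2.0)
    y_min = round(cy * image_h - h * image_h / 2.0)
    x_max = round(cx * image_w + w * image_w / 2.0)
    y_max = round(cy * image_h + h * image_h / 2.0)
    return BoundingBox(max(x_min, 0), max(y_min, 0), min(x_max, image_w), min(y_max, image_h))


def write_detector_labels(
    records: list[AnnotationRecord], image_sizes: dict[str, tuple[int, int]], out_dir: str | Path
) -> None:
    """One ``<image_id>.txt`` per image with ``class cx cy w h`` lines."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for rec in records:
        w, h = image_sizes[rec.image_id]
        cls, cx, cy, bw, bh = to_detector_record(rec.box, w, h)
        with open(out_dir / f"{rec.image_id}.txt", "a") as fh:
            fh.write(f"{cls} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}\n")
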