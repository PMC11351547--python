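"""Dataset manifest: ordered collection of labeled samples with split assignments.

A :class:`LabeledSample` carries the image either in memory (``image``) or on disk
(``path``); pipelines generated by :mod:`echocalc.synth` keep both so tests can run
without touching the filesystem.  ``group_id`` ties augmented/duplicated variants back
to their original sample for leakage-aware splitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import numpy as np

from .annotations import AnnotationRecord, BoundingBox, write_annotations_csv


@dataclass
class LabeledSample:
    image_id: str
    image: np.ndarray | None = None
    path: str | None = None
    valve_box: BoundingBox | None = None
    calcified: bool | None = None
    group_id: str | None = None
    duplicate_of: str | None = None
    augmentation: str | None = None  # e.g. "rotation:+10"
    split: str | None = None
    patient_id: str | None = None

    def load_image(self) -> np.ndarray:
        if self.image is not None:
            return self.image
        if self.path is None:
            raise ValueError(f"sample {self.image_id!r} has neither in-memory image nor path")
        return np.asarray(iio.imread(self.path))

    @property
    def group(self) -> str:
        return self.group_id if self.group_id is not None else self.image_id


@dataclass
class DatasetManifest:
    samples: list[LabeledSample] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self) -> Iterator[LabeledSample]:
        return iter(self.samples)

    def __getitem__(self, idx):
        if isinstance(idx, slice):
            return DatasetManifest(self.samples[idx])
        return self.samples[idx]

    def append(self, sample: LabeledSample) -> None:
        self.samples.append(sample)

    def extend(self, samples) -> None:
        self.samples.extend(samples)

    def class_counts(self) -> tuple[int, int]:
        """(n_calcified, n_healthy) over samples with a known label."""
        pos = sum(1 for s in self.samples if s.calcified is True)
        neg = sum(1 for s in self.samples if s.calcified is False)
        return pos, neg

    def annotation_records(self) -> list[AnnotationRecord]:
        return [
            AnnotationRecord(image_id=s.image_id, box=s.valve_box)
            for s in self.samples
            if s.valve_box is not None
        ]

    def subset(self, predicate) -> "DatasetManifest":
        return DatasetManifest([s for s in self.samples if predicate(s)])

    def with_split(self, name: str) -> "DatasetManifest":
        return DatasetManifest([replace(s, split=name) for s in self.samples])

    def write_images(self, out_dir: str | Path) -> None:
        """Write each in-memory image as ``<image_id>.png`` and record its path."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s in self.samples:
            p = out_dir / f"{s.image_id}.png"
            iio.imwrite(p, s.load_image())
            s.path = str(p)

    def write_annotations(self, path: str | Path) -> None:
        write_annotations_csv(self.annotation_records(), path)
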