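"""Box-aware image augmentation and dataset assembly.

Four deterministic operators, each applied with a fixed parameter pair to yield
exactly two variants per original image:

* translation by +/-20% of the image extent (same signed fraction on both axes),
* zoom about the image center with scale 0.5 or 2 (canvas size fixed),
* rotation about the image center by +/-10 degrees (the probe position varies by
  roughly that much between operators),
* gamma contrast with gamma 0.5 or 1.2 (photometric; the box is unchanged).

So a manifest of n images becomes n * (1 + 2*|techniques|) records, and the minority
class can additionally be duplicated cyclically until both classes are equal.
Annotation boxes are co-transformed by the same affine and clipped to the canvas;
an augmentation that pushes a box fully off-canvas raises :class:`BoxLostError`.

Geometric convention: pixel centers sit at integer coordinates, so a half-open pixel
box [x_min, x_max) occupies the continuous interval [x_min - 0.5, x_max - 0.5] and
the canvas center of a WxH image is ((W-1)/2, (H-1)/2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from skimage.transform import AffineTransform, warp

from .annotations import BoundingBox
from .errors import BalanceError, BoxLostError
from .manifest import DatasetManifest

TECHNIQUES = ("translation", "zoom", "rotation", "gamma")

#: The fixed parameter pairs; two variants per technique per image.
DEFAULT_PARAMETERS: dict[str, tuple[float, float]] = {
    "translation": (0.2, -0.2),
    "zoom": (0.5, 2.0),
    "rotation": (10.0, -10.0),
    "gamma": (0.5, 1.2),
}


@dataclass(frozen=True)
class AugmentationSpec:
    technique: str
    parameters: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise ValueError(f"unknown technique {self.technique!r}; one of {TECHNIQUES}")
        if not self.parameters:
            object.__setattr__(self, "parameters", DEFAULT_PARAMETERS[self.technique])


def _canvas_center(image: np.ndarray) -> tuple[float, float]:
    h, w = image.shape[:2]
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def _box_from_continuous(
    x0: float, y0: float, x1: float, y1: float, width: int, height: int
) -> BoundingBox:
    """Convert a continuous region back to a clipped half-open pixel box."""
    bx0 = int(math.floor(x0 + 0.5))
    by0 = int(math.floor(y0 + 0.5))
    bx1 = int(math.ceil(x1 + 0.5))
    by1 = int(math.ceil(y1 + 0.5))
    bx0, by0 = max(bx0, 0), max(by0, 0)
    bx1, by1 = min(bx1, width), min(by1, height)
    if bx0 >= bx1 or by0 >= by1:
        raise BoxLostError("transformed box lies entirely outside the canvas")
    return BoundingBox(bx0, by0, bx1, by1)


def translate(
    image: np.ndarray, box: BoundingBox | None, fraction: float
) -> tuple[np.ndarray, BoundingBox | None]:
    """Shift by round(fraction*W) horizontally and round(fraction*H) vertically."""
    if not -1.0 < fraction < 1.0:
        raise ValueError("|fraction| must be < 1")
    h, w = image.shape[:2]
    dx, dy = round(fraction * w), round(fraction * h)
    out = np.zeros_like(image)
    sx0, sy0 = max(-dx, 0), max(-dy, 0)
    sx1, sy1 = min(w - dx, w), min(h - dy, h)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 + dy : sy1 + dy, sx0 + dx : sx1 + dx] = image[sy0:sy1, sx0:sx1]
    if box is None:
        return out, None
    bx0, by0 = max(box.x_min + dx, 0), max(box.y_min + dy, 0)
    bx1, by1 = min(box.x_max + dx, w), min(box.y_max + dy, h)
    if bx0 >= bx1 or by0 >= by1:
        raise BoxLostError("translated box lies entirely outside the canvas")
    return out, BoundingBox(bx0, by0, bx1, by1)


def _warp_affine(image: np.ndarray, inverse_matrix: np.ndarray) -> np.ndarray:
    """Bilinear warp with zero fill; uint8 in, uint8 out."""
    tform = AffineTransform(matrix=inverse_matrix)
    warped = warp(
        image.astype(float), tform, order=1, mode="constant", cval=0.0, preserve_range=True
    )
    return np.clip(np.rint(warped), 0, 255).astype(np.uint8)


def zoom(
    image: np.ndarray, box: BoundingBox | None, scale: float
) -> tuple[np.ndarray, BoundingBox | None]:
    """Scale about the image center; the canvas stays fixed (shrink pads, enlarge crops)."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    h, w = image.shape[:2]
    cx, cy = _canvas_center(image)
    # warp wants the output->input map: p_in = c + (p_out - c)/scale
    m = np.array(
        [[1 / scale, 0, cx * (1 - 1 / scale)], [0, 1 / scale, cy * (1 - 1 / scale)], [0, 0, 1]]
    )
    out = _warp_affine(image, m)
    if box is None:
        return out, None
    x0 = cx + (box.x_min - 0.5 - cx) * scale
    y0 = cy + (box.y_min - 0.5 - cy) * scale
    x1 = cx + (box.x_max - 0.5 - cx) * scale
    y1 = cy + (box.y_max - 0.5 - cy) * scale
    return out, _box_from_continuous(x0, y0, x1, y1, w, h)


def rotate(
    image: np.ndarray, box: BoundingBox | None, angle: float, max_angle: float = 45.0
) -> tuple[np.ndarray, BoundingBox | None]:
    """Rotate about the image center; the new box is the clipped axis-aligned hull of
    the four rotated corners."""
    if abs(angle) > max_angle:
        raise ValueError(f"|angle| must be <= {max_angle} degrees")
    h, w = image.shape[:2]
    cx, cy = _canvas_center(image)
    th = math.radians(angle)
    c, s = math.cos(th), math.sin(th)
    # forward rotation of content: p_out = c + R(p_in - c); warp wants the inverse
    minv = np.array(
        [
            [c, s, cx - c * cx - s * cy],
            [-s, c, cy + s * cx - c * cy],
            [0, 0, 1],
        ]
    )
    out = _warp_affine(image, minv)
    if box is None:
        return out, None
    corners = np.array(
        [
            [box.x_min - 0.5, box.y_min - 0.5],
            [box.x_max - 0.5, box.y_min - 0.5],
            [box.x_min - 0.5, box.y_max - 0.5],
            [box.x_max - 0.5, box.y_max - 0.5],
        ]
    )
    rel = corners - [cx, cy]
    rot = rel @ np.array([[c, -s], [s, c]]).T + [cx, cy]
    return out, _box_from_continuous(
        rot[:, 0].min(), rot[:, 1].min(), rot[:, 0].max(), rot[:, 1].max(), w, h
    )


def gamma_lut(gamma: float) -> np.ndarray:
    levels = np.arange(256, dtype=float) / 255.0
    return np.rint(255.0 * np.power(levels, gamma)).astype(np.uint8)


def gamma_contrast(
    image: np.ndarray, box: BoundingBox | None, gamma: float
) -> tuple[np.ndarray, BoundingBox | None]:
    """Power-law contrast: out = round(255 * (in/255)**gamma); the box is unchanged."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    return gamma_lut(gamma)[image], box


_OPERATORS = {
    "translation": translate,
    "zoom": zoom,
    "rotation": rotate,
    "gamma": gamma_contrast,
}


def apply_augmentation(
    image: np.ndarray, box: BoundingBox | None, spec: AugmentationSpec
) -> list[tuple[np.ndarray, BoundingBox | None, str]]:
    """All variants of one technique: [(image, box, tag), ...] with one entry per
    parameter value."""
    op = _OPERATORS[spec.technique]
    out = []
    for value in spec.parameters:
        img, bx = op(image, box, value)
        out.append((img, bx, f"{spec.technique}:{value:+g}"))
    return out


def augment_dataset(
    manifest: DatasetManifest,
    techniques: Iterable[str] | Sequence[AugmentationSpec],
    custom: bool = False,
) -> DatasetManifest:
    """Originals plus two variants per technique per image.

    ``|output| = |input| * (1 + 2 * |techniques|)``, reproducing the dataset sizes
    used for detector training (61 -> 183 with one technique, 305 with two, 549 with
    all four).  Box-losing transforms abort with the offending image id.
    """
    if len(manifest) == 0:
        raise ValueError("cannot augment an empty manifest")
    specs = []
    for t in techniques:
        if isinstance(t, AugmentationSpec):
            if not custom and tuple(t.parameters) != DEFAULT_PARAMETERS[t.technique]:
                raise ValueError(
                    f"non-standard parameters {t.parameters} for {t.technique!r}; "
                    "pass custom=True to allow"
                )
            specs.append(t)
        else:
            specs.append(AugmentationSpec(t))
    seen = [s.technique for s in specs]
    if len(set(seen)) != len(seen):
        raise ValueError(f"duplicate techniques in {seen}")

    out = DatasetManifest(list(manifest.samples))
    for sample in manifest:
        image = sample.load_image()
        for spec in specs:
            try:
                variants = apply_augmentation(image, sample.valve_box, spec)
            except BoxLostError as exc:
                raise BoxLostError(str(exc), image_id=sample.image_id) from exc
            for img, bx, tag in variants:
                out.append(
                    replace(
                        sample,
                        image_id=f"{sample.image_id}__{tag.replace(':', '')}",
                        image=img,
                        path=None,
                        valve_box=bx,
                        augmentation=tag,
                        group_id=sample.group,
                    )
                )
    return out


def balance_by_duplication(manifest: DatasetManifest) -> DatasetManifest:
    """Duplicate minority-class samples cyclically until the classes are equal.

    The output has ``2 * majority_count`` records; duplicates carry ``duplicate_of``.
    """
    pos = [s for s in manifest if s.calcified is True]
    neg = [s for s in manifest if s.calcified is False]
    if not pos or not neg:
        raise BalanceError(
            f"both classes must be present to balance (calcified={len(pos)}, healthy={len(neg)})"
        )
    if len(pos) == len(neg):
        return DatasetManifest(list(manifest.samples))
    minority = pos if len(pos) < len(neg) else neg
    deficit = abs(len(pos) - len(neg))
    out = DatasetManifest(list(manifest.samples))
    for k in range(deficit):
        src = minority[k % len(minority)]
        out.append(
            replace(
                src,
                image_id=f"{src.image_id}__dup{k // len(minority)}",
                duplicate_of=src.image_id,
                group_id=src.group,
            )
        )
    return out
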