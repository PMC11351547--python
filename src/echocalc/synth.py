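"""Seeded synthetic echocardiogram generator.

Real parasternal short-axis echocardiograms are private clinical data, so every
downstream stage of the pipeline is exercised on synthetic scenes that reproduce the
features the pipeline actually consumes:

* a dark background with a brighter sector-shaped ultrasound field (the "cone"),
  textured with Gaussian speckle;
* a bright ring (annulus) standing in for the aortic valve, at a known tight
  bounding box — localizable, not anatomically realistic;
* optional near-white calcium blobs rendered as Gaussian-profiled discs whose peak
  intensity is exactly controllable, so threshold-based heuristics can be tested
  against exact ground truth.

All randomness is driven by ``SceneParams.seed`` / the ``seed`` argument: identical
parameters give bit-identical images.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotations import BoundingBox
from .errors import GeometryError
from .manifest import DatasetManifest, LabeledSample

# Default threshold used when counting "bright" blob pixels in the ground truth;
# matches the upper end of the heuristic threshold sweep (190-220).
DEFAULT_BLOB_PIXEL_THRESHOLD = 220


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic echocardiogram scene.

    The cone is the circular sector with apex ``cone_apex`` (near the top edge),
    central axis pointing straight down, half-opening ``cone_half_angle`` degrees and
    radius ``cone_radius`` pixels.  Speckle texture is i.i.d. Gaussian noise with the
    given mean/sd, clipped to ``[0, speckle_max]``; the default ceiling of 200 keeps
    texture strictly below the calcium intensity band so bright pixels are
    attributable to calcium alone (set ``speckle_max=255`` for full-range speckle).
    """

    image_size: int = 800
    cone_apex: tuple[float, float] = (400.0, 20.0)  # (x, y)
    cone_half_angle: float = 35.0  # degrees
    cone_radius: float = 700.0
    background_level: int = 0
    speckle_mean: float = 70.0
    speckle_sd: float = 25.0
    speckle_max: int = 200
    valve_center: tuple[float, float] = (400.0, 420.0)
    valve_outer_radius: float = 80.0
    valve_inner_radius: float = 55.0
    valve_level: int = 160
    ring_jaggedness: float = 2.0  # radial wobble (px) of the ring boundary
    calcium_blobs: tuple[tuple[tuple[float, float], float, int], ...] = ()
    seed: int = 0

    def with_blobs(self, blobs) -> "SceneParams":
        return replace(self, calcium_blobs=tuple(blobs))


@dataclass(frozen=True)
class GroundTruth:
    valve_box: BoundingBox
    calcified: bool
    blob_pixels: int  # pixels strictly above the query threshold


def _sector_distance_angle(params: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel distance from the apex and absolute angle (deg) off the downward axis."""
    n = params.image_size
    ax, ay = params.cone_apex
    yy, xx = np.mgrid[0:n, 0:n]
    dx = xx - ax
    dy = yy - ay
    dist = np.hypot(dx, dy)
    with np.errstate(invalid="ignore"):
        ang = np.degrees(np.abs(np.arctan2(dx, dy)))  # 0 along +y (down)
    ang[dist == 0] = 0.0
    return dist, ang


def sector_mask(params: SceneParams) -> np.ndarray:
    """Analytic boolean raster of the cone sector (the ground-truth cone mask)."""
    dist, ang = _sector_distance_angle(params)
    return (dist <= params.cone_radius) & (ang <= params.cone_half_angle)


def _check_circle_inside_sector(
    params: SceneParams, center: tuple[float, float], radius: float, what: str
) -> None:
    ax, ay = params.cone_apex
    cx, cy = center
    d = math.hypot(cx - ax, cy - ay)
    if d + radius > params.cone_radius:
        raise GeometryError(f"{what} crosses the cone arc (apex distance {d:.1f} + r {radius:.1f} "
                            f"> cone radius {params.cone_radius:.1f})")
    if d <= radius:
        raise GeometryError(f"{what} encloses the cone apex")
    theta = math.degrees(abs(math.atan2(cx - ax, cy - ay)))
    clearance = math.degrees(math.asin(min(radius / d, 1.0)))
    if theta + clearance > params.cone_half_angle:
        raise GeometryError(f"{what} crosses a cone edge (angle {theta:.1f} deg + clearance "
                            f"{clearance:.1f} deg > half-angle {params.cone_half_angle:.1f} deg)")
    n = params.image_size
    if not (radius <= cx <= n - radius and radius <= cy <= n - radius):
        raise GeometryError(f"{what} exceeds the image extent")


def validate_scene(params: SceneParams) -> None:
    """Raise :class:`GeometryError` unless valve ring and all blobs lie inside the cone."""
    if params.valve_inner_radius >= params.valve_outer_radius:
        raise GeometryError("valve inner radius must be smaller than outer radius")
    margin = params.ring_jaggedness
    _check_circle_inside_sector(
        params, params.valve_center, params.valve_outer_radius + margin, "valve ring"
    )
    for center, radius, intensity in params.calcium_blobs:
        if not (0 <= intensity <= 255):
            raise GeometryError(f"blob intensity {intensity} outside [0, 255]")
        _check_circle_inside_sector(params, center, radius, "calcium blob")


def generate_scene(
    params: SceneParams, blob_pixel_threshold: int = DEFAULT_BLOB_PIXEL_THRESHOLD
) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns an (H, W, 3) uint8 image and its exact ground truth.

    The three channels are identical (grayscale ultrasound replicated to RGB).  The
    ground-truth ``valve_box`` is the tight half-open box of the painted ring pixels.
    """
    validate_scene(params)
    rng = np.random.default_rng(params.seed)
    n = params.image_size

    dist, ang = _sector_distance_angle(params)
    cone = (dist <= params.cone_radius) & (ang <= params.cone_half_angle)

    img = np.full((n, n), float(params.background_level))
    speckle = rng.normal(params.speckle_mean, params.speckle_sd, size=(n, n))
    img[cone] = np.clip(speckle[cone], 0, params.speckle_max)

    # Valve ring: annulus with a small seeded radial wobble so the boundary is not a
    # perfect circle (echo structures are not), painted at a flat gray level.
    vx, vy = params.valve_center
    yy, xx = np.mgrid[0:n, 0:n]
    rdist = np.hypot(xx - vx, yy - vy)
    if params.ring_jaggedness > 0:
        phase = np.arctan2(yy - vy, xx - vx)
        harmonics = rng.normal(0, params.ring_jaggedness / 2, size=3)
        phases = rng.uniform(0, 2 * np.pi, size=3)
        wobble = sum(
            h * np.sin((k + 2) * phase + p) for k, (h, p) in enumerate(zip(harmonics, phases))
        )
    else:
        wobble = 0.0
    ring = (rdist >= params.valve_inner_radius + wobble) & (
        rdist <= params.valve_outer_radius + wobble
    )
    img[ring] = params.valve_level

    ys, xs = np.nonzero(ring)
    valve_box = BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)

    # Calcium blobs: Gaussian-profiled discs, sigma = r/2, support cut at 2r; the
    # center pixel is forced to the exact stated peak so thresholds behave exactly.
    for (bx, by), radius, intensity in params.calcium_blobs:
        if intensity <= 0:
            continue
        sigma = max(radius / 2.0, 0.5)
        bdist = np.hypot(xx - bx, yy - by)
        support = bdist <= 2.0 * radius
        profile = intensity * np.exp(-(bdist[support] ** 2) / (2 * sigma**2))
        img[support] = np.maximum(img[support], profile)
        cxi, cyi = int(round(bx)), int(round(by))
        img[cyi, cxi] = intensity

    img8 = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    rgb = np.repeat(img8[:, :, None], 3, axis=2)

    calcified = any(intensity > 0 for _, _, intensity in params.calcium_blobs)
    blob_pixels = int(np.count_nonzero(img8 > blob_pixel_threshold))
    return rgb, GroundTruth(valve_box=valve_box, calcified=calcified, blob_pixels=blob_pixels)


def _jittered_params(base: SceneParams, rng: np.random.Generator, calcified: bool,
                     sample_seed: int) -> SceneParams:
    """Per-sample jitter: valve center uniform within +/-10% of the image size, outer
    radius +/-20% (ring thickness preserved proportionally); calcified samples get
    1-3 near-white blobs inside the ring's inner disc."""
    n = base.image_size
    shift = 0.10 * n
    for _ in range(100):
        cx = base.valve_center[0] + rng.uniform(-shift, shift)
        cy = base.valve_center[1] + rng.uniform(-shift, shift)
        scale = rng.uniform(0.8, 1.2)
        outer = base.valve_outer_radius * scale
        inner = base.valve_inner_radius * scale
        blobs = []
        if calcified:
            for _ in range(rng.integers(1, 4)):
                brad = rng.uniform(3.0, 6.0)
                rmax = max(inner - brad - base.ring_jaggedness - 1.0, 1.0)
                rho = rng.uniform(0, rmax)
                phi = rng.uniform(0, 2 * np.pi)
                blobs.append(((cx + rho * np.cos(phi), cy + rho * np.sin(phi)), brad, 255))
        candidate = replace(
            base,
            valve_center=(cx, cy),
            valve_outer_radius=outer,
            valve_inner_radius=inner,
            calcium_blobs=tuple(blobs),
            seed=sample_seed,
        )
        try:
            validate_scene(candidate)
            return candidate
        except GeometryError:
            continue
    raise GeometryError("could not place a jittered valve inside the cone after 100 tries")


def generate_dataset(
    n_calcified: int,
    n_healthy: int,
    base_params: SceneParams | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> DatasetManifest:
    """Generate a labeled dataset of synthetic scenes.

    Samples are named ``STUDY_000``, ``STUDY_001``, ... (anonymized-style ids).
    Calcified and healthy samples are interleaved deterministically by a seeded
    shuffle so class order carries no information.  When ``out_dir`` is given, PNG
    images plus ``annotations.csv`` (valve boxes) and ``ground_truth.csv``
    (id, calcified, blob count) are written there.
    """
    if n_calcified < 0 or n_healthy < 0:
        raise ValueError("sample counts must be non-negative")
    if base_params is None:
        base_params = SceneParams()
    rng = np.random.default_rng(seed)
    labels = [True] * n_calcified + [False] * n_healthy
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]

    manifest = DatasetManifest()
    truths: list[GroundTruth] = []
    for idx, calcified in enumerate(labels):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        params = _jittered_params(base_params, rng, calcified, sample_seed)
        image, truth = generate_scene(params)
        image_id = f"STUDY_{idx:03d}"
        manifest.append(
            LabeledSample(
                image_id=image_id,
                image=image,
                valve_box=truth.valve_box,
                calcified=truth.calcified,
                group_id=image_id,
            )
        )
        truths.append(truth)

    if out_dir is not None:
        out_dir = Path(out_dir)
        manifest.write_images(out_dir)
        manifest.write_annotations(out_dir / "annotations.csv")
        with open(out_dir / "ground_truth.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image_id", "calcified", "blob_pixels"])
            for sample, truth in zip(manifest, truths):
                writer.writerow([sample.image_id, int(truth.calcified), truth.blob_pixels])
    return manifest
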