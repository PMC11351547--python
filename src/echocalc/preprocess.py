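"""Ultrasound-cone extraction and image standardization.

An echocardiogram frame is a dark canvas with a brighter sector-shaped imaging field
(the "cone") plus vendor overlays.  The pipeline isolates the cone:

1. :func:`detect_cone` — find the two straight sector edges (Hough line voting,
   refined by a least-squares fit to nearby boundary pixels) and the far arc
   (robust max apex distance), then rasterize the sector as a binary mask.  When
   the two-lines-plus-arc template cannot be fit, fall back to the convex hull of
   the largest bright region (flagged on the result).
2. :func:`mask_and_tight_crop` — zero everything outside the mask and crop away
   the empty border.
3. :func:`standardize_crop` — cut a fixed-size window (default 640x640) around the
   cone centroid with NO rescaling, padding with zeros, so the detector input has a
   fixed shape without aspect-ratio distortion.
4. :func:`reduce_noise` — subtract the global minimum pixel value so the darkest
   zones become pure black.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.transform import hough_line, hough_line_peaks

from .annotations import BoundingBox
from .errors import DetectionError, FormatError

FOREGROUND_THRESHOLD = 10  # gray level above which a pixel counts as inside the field
MIN_EDGE_SEPARATION_DEG = 15.0  # two sector edges must differ by at least this much


@dataclass
class ConeMask:
    """Binary sector mask plus the fitted boundary parameters.

    ``apex`` is the sector tip in (x, y); ``edge_angles`` are the directions (degrees,
    measured from the +x axis) of the two straight edges leaving the apex;
    ``radius`` is the arc distance from the apex.  ``fallback`` is True when the
    two-lines-plus-arc fit failed and the mask is a convex hull instead.
    """

    mask: np.ndarray
    apex: tuple[float, float] | None = None
    edge_angles: tuple[float, float] | None = None
    radius: float | None = None
    fallback: bool = False

    @property
    def half_angle(self) -> float | None:
        if self.edge_angles is None:
            return None
        a, b = self.edge_angles
        diff = abs(a - b) % 360.0
        return min(diff, 360.0 - diff) / 2.0

    @property
    def axis_angle(self) -> float | None:
        """Direction (degrees from +x) of the sector's central axis."""
        if self.apex is None or self.edge_angles is None:
            return None
        vecs = [np.array([math.cos(math.radians(a)), math.sin(math.radians(a))])
                for a in self.edge_angles]
        bisector = vecs[0] + vecs[1]
        return math.degrees(math.atan2(bisector[1], bisector[0]))

    def boundary_lines(self) -> dict:
        """The two edge segments and the far arc, as plain coordinate parameters."""
        if self.fallback or self.apex is None:
            return {}
        segs = []
        for a in self.edge_angles:
            end = (self.apex[0] + self.radius * math.cos(math.radians(a)),
                   self.apex[1] + self.radius * math.sin(math.radians(a)))
            segs.append((self.apex, end))
        return {"edges": segs, "arc": {"center": self.apex, "radius": self.radius,
                                       "angles": self.edge_angles}}


def _foreground(image: np.ndarray) -> np.ndarray:
    gray = image[..., 0] if image.ndim == 3 else image
    fg = gray > FOREGROUND_THRESHOLD
    if not fg.any():
        raise DetectionError("no foreground pixels above the background threshold")
    labels = measure.label(fg)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    fg = labels == largest
    return ndi.binary_fill_holes(fg)


def _refine_line(edge_pts: np.ndarray, angle: float, dist: float, tol: float = 2.0):
    """Total-least-squares refit of a Hough line using boundary points within ``tol``.

    Returns the refined (normal_angle, distance) in the Hough (theta, rho)
    parameterization, or the input if too few points support the line.
    """
    xs, ys = edge_pts[:, 1].astype(float), edge_pts[:, 0].astype(float)
    resid = xs * math.cos(angle) + ys * math.sin(angle) - dist
    sel = np.abs(resid) < tol
    if sel.sum() < 10:
        return angle, dist
    x, y = xs[sel], ys[sel]
    mx, my = x.mean(), y.mean()
    cov = np.cov(np.stack([x - mx, y - my]))
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]  # eigenvector of the smaller eigenvalue
    theta = math.atan2(normal[1], normal[0])
    rho = mx * math.cos(theta) + my * math.sin(theta)
    if rho < 0:
        rho, theta = -rho, theta + math.pi
    return theta, rho


def rasterize_sector(shape: tuple[int, int], apex: tuple[float, float],
                     edge_angles: tuple[float, float], radius: float) -> np.ndarray:
    """Boolean raster of the sector with the given apex/edges/arc (any orientation)."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - apex[0], yy - apex[1]
    dist = np.hypot(dx, dy)
    a0, a1 = (math.radians(a) for a in edge_angles)
    v0 = np.array([math.cos(a0), math.sin(a0)])
    v1 = np.array([math.cos(a1), math.sin(a1)])
    bis = v0 + v1
    bis = bis / np.linalg.norm(bis)
    half = math.acos(np.clip(np.dot(v0, bis), -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = (dx * bis[0] + dy * bis[1]) / np.where(dist == 0, 1.0, dist)
    inside_angle = cosang >= math.cos(half)
    inside_angle |= dist == 0
    return inside_angle & (dist <= radius)


def detect_cone(image: np.ndarray) -> ConeMask:
    """Detect the ultrasound sector in an 8-bit frame.

    Raises :class:`DetectionError` if the image has no foreground at all.  On
    failure to fit two straight edges and an arc, returns the convex hull of the
    largest bright region with ``fallback=True``.
    """
    fg = _foreground(image)
    boundary = fg ^ ndi.binary_erosion(fg)
    edge_pts = np.argwhere(boundary)  # (row, col)

    thetas = np.linspace(-np.pi / 2, np.pi / 2, 720, endpoint=False)
    accum, angles, dists = hough_line(boundary, theta=thetas)
    diag = math.hypot(*fg.shape)
    _, peak_angles, peak_dists = hough_line_peaks(
        accum, angles, dists, num_peaks=6, threshold=0.25 * accum.max(),
        min_distance=9, min_angle=10,
    )

    lines = []
    for ang, dist in zip(peak_angles, peak_dists):
        theta, rho = _refine_line(edge_pts, float(ang), float(dist))
        # require meaningful support along the line
        xs, ys = edge_pts[:, 1], edge_pts[:, 0]
        on = np.abs(xs * math.cos(theta) + ys * math.sin(theta) - rho) < 2.0
        if on.sum() >= 0.15 * diag:
            lines.append((theta, rho, on.sum()))

    best_pair = None
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            t0, t1 = lines[i][0], lines[j][0]
            sep = math.degrees(abs(math.atan2(math.sin(t0 - t1), math.cos(t0 - t1))))
            sep = min(sep, 180.0 - sep)
            if sep >= MIN_EDGE_SEPARATION_DEG:
                score = lines[i][2] + lines[j][2]
                if best_pair is None or score > best_pair[0]:
                    best_pair = (score, lines[i], lines[j])

    if best_pair is None:
        hull = morphology.convex_hull_image(fg)
        return ConeMask(mask=hull, fallback=True)

    (_, (th0, r0, _), (th1, r1, _)) = best_pair
    # apex = intersection of the two lines x*cos(t)+y*sin(t)=r
    a = np.array([[math.cos(th0), math.sin(th0)], [math.cos(th1), math.sin(th1)]])
    b = np.array([r0, r1])
    try:
        apex = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        hull = morphology.convex_hull_image(fg)
        return ConeMask(mask=hull, fallback=True)

    fg_pts = np.argwhere(fg)
    dvec = fg_pts[:, ::-1].astype(float) - apex  # (x, y) relative to apex
    dist = np.hypot(dvec[:, 0], dvec[:, 1])
    radius = float(np.percentile(dist, 99.5))

    # Edge directions: each line direction, signed to point from the apex into the mask
    edge_angles = []
    centroid = fg_pts[:, ::-1].mean(axis=0) - apex
    for th in (th0, th1):
        d = np.array([-math.sin(th), math.cos(th)])  # direction along the line
        if np.dot(d, centroid) < 0:
            d = -d
        edge_angles.append(math.degrees(math.atan2(d[1], d[0])))

    mask = rasterize_sector(fg.shape, tuple(apex), tuple(edge_angles), radius)
    if not mask.any():
        hull = morphology.convex_hull_image(fg)
        return ConeMask(mask=hull, fallback=True)
    return ConeMask(mask=mask, apex=(float(apex[0]), float(apex[1])),
                    edge_angles=(edge_angles[0], edge_angles[1]), radius=radius)


def tight_crop_box(mask: np.ndarray) -> BoundingBox:
    """Tight half-open bounding box of the True pixels of a mask."""
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise DetectionError("empty mask")
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def mask_and_tight_crop(image: np.ndarray, mask: ConeMask | np.ndarray) -> np.ndarray:
    """Zero pixels outside the cone mask and crop to the mask's tight bounding box."""
    m = mask.mask if isinstance(mask, ConeMask) else mask
    if m.shape != image.shape[:2]:
        raise ValueError(f"mask shape {m.shape} != image shape {image.shape[:2]}")
    out = image.copy()
    out[~m] = 0
    box = tight_crop_box(m)
    return out[box.y_min : box.y_max, box.x_min : box.x_max]


def standardize_crop(
    image: np.ndarray,
    box_hint: BoundingBox | None = None,
    size: int = 640,
    center: tuple[float, float] | None = None,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Cut a ``size`` x ``size`` window around the content centroid, never rescaling.

    The window is centered on ``box_hint``'s center when given, else on an explicit
    ``center``, else on the centroid of nonzero pixels (the cone).  Areas outside the
    source are zero-padded.  Returns the window and its offset ``(x0, y0)`` in source
    coordinates: output pixel (x, y) shows source pixel (x + x0, y + y0), so a source
    box maps into the window by shifting by (-x0, -y0).
    """
    h, w = image.shape[:2]
    if box_hint is not None:
        cx, cy = box_hint.center
    elif center is not None:
        cx, cy = center
    else:
        gray = image[..., 0] if image.ndim == 3 else image
        ys, xs = np.nonzero(gray)
        if len(xs) == 0:
            cx, cy = w / 2.0, h / 2.0
        else:
            cx, cy = float(xs.mean()), float(ys.mean())

    x0 = int(round(cx - size / 2.0))
    y0 = int(round(cy - size / 2.0))
    shape = (size, size) + image.shape[2:]
    out = np.zeros(shape, dtype=image.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + size, w), min(y0 + size, h)
    if sx0 < sx1 and sy0 < sy1:
        out[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = image[sy0:sy1, sx0:sx1]
    return out, (x0, y0)


def reduce_noise(image: np.ndarray) -> np.ndarray:
    """Subtract the global scalar minimum from every pixel (all channels).

    Turns the darkest zones into pure black; idempotent (the output minimum is 0).
    """
    lo = int(image.min())
    return (image.astype(np.int16) - lo).clip(0, 255).astype(np.uint8)


def anonymized_ids(count: int, start: int = 0, prefix: str = "STUDY") -> list[str]:
    """Sequential anonymized frame ids: STUDY_000, STUDY_001, ..."""
    return [f"{prefix}_{i:03d}" for i in range(start, start + count)]


def extract_dicom_frames(path: str | Path, start_index: int = 0):
    """Extract frames from a DICOM file as 8-bit RGB images with anonymized ids.

    Returns a list of ``(image, anonymized_id)`` pairs; no patient-identifying
    metadata is propagated.  Requires the optional ``pydicom`` dependency.
    """
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError(
            "DICOM support requires the optional dependency 'pydicom' "
            "(pip install pydicom); PNG/JPEG inputs need no extra packages"
        ) from exc

    ds = pydicom.dcmread(str(path))
    if "PixelData" not in ds:
        raise FormatError(f"{path}: DICOM file has no pixel data")
    arr = ds.pixel_array
    if arr.ndim == 2:
        frames = [arr]
    elif arr.ndim == 3 and arr.shape[-1] in (3, 4):
        frames = [arr[..., :3]]
    elif arr.ndim == 3:
        frames = list(arr)
    elif arr.ndim == 4:
        frames = [f[..., :3] for f in arr]
    else:
        raise FormatError(f"{path}: unsupported pixel array shape {arr.shape}")

    out = []
    for frame, fid in zip(frames, anonymized_ids(len(frames), start_index)):
        f = np.asarray(frame, dtype=float)
        if f.max() > 255:
            f = f * (255.0 / f.max())
        f = f.clip(0, 255).astype(np.uint8)
        if f.ndim == 2:
            f = np.repeat(f[:, :, None], 3, axis=2)
        out.append((f, fid))
    return out
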