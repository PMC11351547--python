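"""Valve detector and calcification classifiers.

Three predictors, all behind thin trainable-model contracts:

* **Heuristic classifier** — binarize the valve crop at a gray threshold and call the
  valve calcified iff at least one pixel survives as pure white.  Calcium is strongly
  hyperechoic, so on clean images near-white pixels are calcium; thresholds 190-220
  bracket the useful band.  No trained weights involved.

* **Valve detector** — a trainable sliding-window detector: windows are sampled from
  annotated frames, reduced to small normalized patches, and scored by a logistic
  model trained incrementally (one pass per epoch, with a loss log).  Inference slides
  windows over a letterboxed, downscaled frame at three scales around the training
  median box size, applies non-maximum suppression and returns confidence-ranked
  boxes.  This stands in for a pretrained-CNN detector fine-tuned on the task; the
  contract (config, loss log, seeded determinism, confidence threshold) is the same.

* **Learned classifier** — a frozen convolutional feature extractor (a small stack of
  fixed, seeded random filters standing in for ImageNet-pretrained backbones; several
  "families" of different widths are provided) with a configurable pooling mode over
  the last convolutional map, followed by a trainable dense head with 120 hidden
  units and a sigmoid output.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import SGDClassifier
from sklearn.metrics import log_loss
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .annotations import BoundingBox
from .errors import ConfigError, DataError
from .evaluate import iou
from .manifest import DatasetManifest

# ---------------------------------------------------------------------------
# Heuristic classifier
# ---------------------------------------------------------------------------

HEURISTIC_THRESHOLDS = (190, 200, 210, 220)
DEFAULT_HEURISTIC_THRESHOLD = 220


@dataclass(frozen=True)
class ClassificationResult:
    probability_calcified: float
    label: bool

    @staticmethod
    def from_probability(p: float, cutoff: float = 0.5) -> "ClassificationResult":
        return ClassificationResult(probability_calcified=float(p), label=bool(p >= cutoff))


def heuristic_binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Strict-threshold binarization: a pixel becomes white (255 in every channel)
    iff its minimum channel value is strictly greater than ``threshold``; everything
    else becomes black."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must be in [0, 255]")
    gray = image.min(axis=2) if image.ndim == 3 else image
    white = gray > threshold
    out = np.zeros_like(image)
    out[white] = 255
    return out


def heuristic_classify(
    image: np.ndarray, threshold: int = DEFAULT_HEURISTIC_THRESHOLD
) -> ClassificationResult:
    """Calcified iff any white pixel survives binarization; the reported probability
    is the white-pixel fraction (a convenience score, not a calibrated probability)."""
    binary = heuristic_binarize(image, threshold)
    gray = binary[..., 0] if binary.ndim == 3 else binary
    frac = float(np.count_nonzero(gray) / gray.size)
    return ClassificationResult(probability_calcified=frac, label=frac > 0)


# ---------------------------------------------------------------------------
# Detector
# ---------------------------------------------------------------------------

#: Detector "backbones": window-scoring models of different patch resolutions.
DETECTOR_BACKBONES = {
    "window-s": {"patch": 16, "downscale": 4, "stride": 2, "negatives_per_image": 12},
    "window-m": {"patch": 24, "downscale": 4, "stride": 2, "negatives_per_image": 16},
}


@dataclass
class DetectorConfig:
    input_size: int = 640
    batch_size: int = 32
    epochs: int = 75
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    backbone_id: str = "window-s"
    confidence_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError(f"split must sum to 1, got {self.split}")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.backbone_id not in DETECTOR_BACKBONES:
            raise ConfigError(
                f"unknown detector backbone {self.backbone_id!r}; "
                f"one of {sorted(DETECTOR_BACKBONES)}"
            )


@dataclass(frozen=True)
class DetectionResult:
    box: BoundingBox
    confidence: float
    margin: float | None = None  # raw decision score; used for fine-grained ranking

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must be in [0, 1]")

    @property
    def rank_key(self) -> float:
        return self.margin if self.margin is not None else self.confidence


def letterbox(image: np.ndarray, size: int) -> tuple[np.ndarray, float, tuple[int, int]]:
    """Uniformly rescale the longer side to ``size`` and pad to a square canvas.

    Returns (canvas, scale, (pad_x, pad_y)); a source coordinate maps to
    ``coord * scale + pad``.  Aspect ratio is preserved (no distortion).
    """
    h, w = image.shape[:2]
    scale = size / max(h, w)
    nh, nw = int(round(h * scale)), int(round(w * scale))
    resized = resize(image.astype(float), (nh, nw) + image.shape[2:], order=1,
                     anti_aliasing=scale < 1, preserve_range=True)
    canvas = np.zeros((size, size) + image.shape[2:], dtype=image.dtype)
    pad_y, pad_x = (size - nh) // 2, (size - nw) // 2
    canvas[pad_y : pad_y + nh, pad_x : pad_x + nw] = np.clip(np.rint(resized), 0, 255)
    return canvas, scale, (pad_x, pad_y)


def _to_gray(image: np.ndarray) -> np.ndarray:
    return image[..., 0].astype(float) if image.ndim == 3 else image.astype(float)


def _window_features(gray_small: np.ndarray, box: tuple[int, int, int, int], patch: int) -> np.ndarray:
    """Normalized patch features for one window (x0, y0, x1, y1) of the downscaled frame."""
    x0, y0, x1, y1 = box
    win = gray_small[y0:y1, x0:x1]
    p = resize(win, (patch, patch), order=1, anti_aliasing=False, preserve_range=True)
    mu, sd = p.mean(), p.std()
    p = (p - mu) / (sd + 1e-6)
    return np.concatenate([p.ravel(), [mu / 255.0, sd / 255.0]])


@dataclass
class DetectorModel:
    config: DetectorConfig
    classifier: SGDClassifier
    box_size: tuple[float, float]  # median (w, h) in downscaled coords
    loss_log: list[float] = field(default_factory=list)

    def write_logs(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "detector_loss.csv", "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["epoch", "train_loss"])
            for i, loss in enumerate(self.loss_log):
                writer.writerow([i + 1, f"{loss:.6f}"])


def _prepare_frame(image: np.ndarray, config: DetectorConfig):
    bb = DETECTOR_BACKBONES[config.backbone_id]
    canvas, scale, (px, py) = letterbox(image, config.input_size)
    ds = bb["downscale"]
    gray = _to_gray(canvas)
    small = gray.reshape(gray.shape[0] // ds, ds, gray.shape[1] // ds, ds).mean(axis=(1, 3))
    total = scale / ds  # source px -> downscaled px
    return small, total, (px / ds, py / ds)


def _map_box_to_small(box: BoundingBox, factor: float, pad: tuple[float, float], lim: int):
    x0 = box.x_min * factor + pad[0]
    y0 = box.y_min * factor + pad[1]
    x1 = box.x_max * factor + pad[0]
    y1 = box.y_max * factor + pad[1]
    xi0, yi0 = max(int(round(x0)), 0), max(int(round(y0)), 0)
    xi1, yi1 = min(int(round(x1)), lim), min(int(round(y1)), lim)
    if xi1 - xi0 < 2 or yi1 - yi0 < 2:
        return None
    return (xi0, yi0, xi1, yi1)


def train_detector(
    train_manifest: DatasetManifest,
    val_manifest: DatasetManifest | None,
    config: DetectorConfig,
    log_dir: str | Path | None = None,
) -> DetectorModel:
    """Fit the window-scoring model on annotated frames.

    One positive window per annotated box plus seeded random negatives per frame;
    one incremental pass over a reshuffled sample set per epoch, logging the training
    log-loss so convergence is inspectable.
    """
    boxed = [s for s in train_manifest if s.valve_box is not None]
    if not boxed:
        raise DataError("training manifest has no annotated samples")
    bb = DETECTOR_BACKBONES[config.backbone_id]
    patch = bb["patch"]
    rng = np.random.default_rng(config.seed)

    feats, labels, sizes = [], [], []
    for sample in boxed:
        image = sample.load_image()
        small, factor, pad = _prepare_frame(image, config)
        lim = small.shape[0]
        tb = _map_box_to_small(sample.valve_box, factor, pad, lim)
        if tb is None:
            continue
        sizes.append((tb[2] - tb[0], tb[3] - tb[1]))
        feats.append(_window_features(small, tb, patch))
        labels.append(1)
        # jittered positives stabilize the decision boundary
        for _ in range(2):
            jx, jy = rng.integers(-2, 3, size=2)
            jb = (tb[0] + jx, tb[1] + jy, tb[2] + jx, tb[3] + jy)
            if 0 <= jb[0] < jb[2] <= lim and 0 <= jb[1] < jb[3] <= lim:
                feats.append(_window_features(small, jb, patch))
                labels.append(1)
        truth = BoundingBox(*tb)
        w, h = tb[2] - tb[0], tb[3] - tb[1]
        # hard negatives: the truth window shifted by ~60% of its size and rescaled,
        # so partially-overlapping and wrongly-sized windows learn to score low
        cx, cy = (tb[0] + tb[2]) / 2.0, (tb[1] + tb[3]) / 2.0
        hard = []
        for fx, fy in ((0.6, 0), (-0.6, 0), (0, 0.6), (0, -0.6), (0.5, 0.5), (-0.5, -0.5)):
            hard.append((cx + fx * w, cy + fy * h, w, h))
        for f in (0.5, 1.7):
            hard.append((cx, cy, w * f, h * f))
        for hcx, hcy, hw, hh in hard:
            x0 = int(round(hcx - hw / 2))
            y0 = int(round(hcy - hh / 2))
            x1, y1 = int(round(x0 + hw)), int(round(y0 + hh))
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, lim), min(y1, lim)
            if x1 - x0 < 4 or y1 - y0 < 4:
                continue
            cand = BoundingBox(x0, y0, x1, y1)
            if iou(cand, truth) > 0.45:
                continue
            feats.append(_window_features(small, cand.astuple(), patch))
            labels.append(0)
        tries = 0
        added = 0
        while added < bb["negatives_per_image"] and tries < 200:
            tries += 1
            nw = max(4, int(round(w * rng.uniform(0.7, 1.3))))
            nh = max(4, int(round(h * rng.uniform(0.7, 1.3))))
            if nw >= lim or nh >= lim:
                continue
            x0 = int(rng.integers(0, lim - nw))
            y0 = int(rng.integers(0, lim - nh))
            cand = BoundingBox(x0, y0, x0 + nw, y0 + nh)
            if iou(cand, truth) > 0.2:
                continue
            feats.append(_window_features(small, cand.astuple(), patch))
            labels.append(0)
            added += 1

    x = np.asarray(feats)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DataError("window sampling produced a single class; check annotations")

    clf = SGDClassifier(
        loss="log_loss", alpha=1e-4, learning_rate="optimal", random_state=config.seed
    )
    loss_log = []
    for _ in range(config.epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            clf.partial_fit(x[idx], y[idx], classes=np.array([0, 1]))
        with np.errstate(over="ignore"):
            proba = 1.0 / (1.0 + np.exp(-clf.decision_function(x)))
        loss_log.append(float(log_loss(y, np.clip(proba, 1e-12, 1 - 1e-12), labels=[0, 1])))

    med_w = float(np.median([s[0] for s in sizes]))
    med_h = float(np.median([s[1] for s in sizes]))
    model = DetectorModel(config=config, classifier=clf, box_size=(med_w, med_h),
                          loss_log=loss_log)
    if log_dir is not None:
        model.write_logs(log_dir)
    return model


def _nms(results: list[DetectionResult], threshold: float = 0.4) -> list[DetectionResult]:
    keep: list[DetectionResult] = []
    for r in sorted(results, key=lambda r: -r.rank_key):
        if all(iou(r.box, k.box) < threshold for k in keep):
            keep.append(r)
    return keep


def detect_valve(
    model: DetectorModel, image: np.ndarray, scales: tuple[float, ...] = (0.8, 1.0, 1.2)
) -> list[DetectionResult]:
    """Score sliding windows at three scales around the training median box size;
    return confidence-sorted detections above the configured threshold (possibly
    empty), after non-maximum suppression, in the source image's coordinates."""
    config = model.config
    bb = DETECTOR_BACKBONES[config.backbone_id]
    patch, stride = bb["patch"], bb["stride"]
    small, factor, pad = _prepare_frame(image, config)
    lim = small.shape[0]

    windows, feats = [], []
    for s in scales:
        w = max(4, int(round(model.box_size[0] * s)))
        h = max(4, int(round(model.box_size[1] * s)))
        if w >= lim or h >= lim:
            continue
        for y0 in range(0, lim - h + 1, stride):
            for x0 in range(0, lim - w + 1, stride):
                windows.append((x0, y0, x0 + w, y0 + h))
                feats.append(_window_features(small, windows[-1], patch))
    if not feats:
        return []
    scores = model.classifier.decision_function(np.asarray(feats))
    with np.errstate(over="ignore"):
        conf = 1.0 / (1.0 + np.exp(-scores))

    h_img, w_img = image.shape[:2]
    results = []
    for (x0, y0, x1, y1), c, raw in zip(windows, conf, scores):
        if c < config.confidence_threshold:
            continue
        sx0 = (x0 - pad[0]) / factor
        sy0 = (y0 - pad[1]) / factor
        sx1 = (x1 - pad[0]) / factor
        sy1 = (y1 - pad[1]) / factor
        bx = BoundingBox(
            max(int(round(sx0)), 0),
            max(int(round(sy0)), 0),
            min(int(round(sx1)), w_img),
            min(int(round(sy1)), h_img),
        )
        results.append(DetectionResult(box=bx, confidence=float(min(c, 1.0)), margin=float(raw)))
    return _nms(results)


def select_best(results: list[DetectionResult]) -> DetectionResult | None:
    """The single most confident detection (one aortic valve per short-axis view);
    ties break by list order (stable sort)."""
    if not results:
        return None
    return sorted(results, key=lambda r: -r.rank_key)[0]


# ---------------------------------------------------------------------------
# Learned classifier
# ---------------------------------------------------------------------------

#: Fixed random-filter "backbone" families.  Channel widths loosely mirror the
#: relative capacities of the public families they stand in for; each name maps to
#: (filter counts per conv stage, rng seed for the frozen weights).
CLASSIFIER_BACKBONES = {
    "efficient-b0": ((12, 24, 48), 101),
    "efficient-b4": ((16, 32, 64), 102),
    "residual-50": ((16, 32, 64), 103),
    "residual-152": ((16, 32, 96), 104),
    "mobile-small": ((8, 16, 32), 105),
    "mobile-large": ((12, 24, 48), 106),
}

POOLING_MODES = ("none", "max", "avg")
_INTERNAL_RESOLUTION = 64  # conv stack input; ROI is first resized to config.input_size


@dataclass
class ClassifierConfig:
    input_size: int = 224
    batch_size: int = 1
    epochs: int = 50
    split: tuple[float, float] = (0.8, 0.2)
    backbone_id: str = "mobile-small"
    pooling: str = "none"
    head_width: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone_id not in CLASSIFIER_BACKBONES:
            raise ConfigError(
                f"unknown classifier backbone {self.backbone_id!r}; "
                f"one of {sorted(CLASSIFIER_BACKBONES)}"
            )
        if self.pooling not in POOLING_MODES:
            raise ConfigError(f"pooling must be one of {POOLING_MODES}, got {self.pooling!r}")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ConfigError(f"split must sum to 1, got {self.split}")


def _conv2d_relu(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Valid 3x3 convolution + ReLU via im2col; x is (H, W, Cin), weights (3, 3, Cin, Cout)."""
    from numpy.lib.stride_tricks import sliding_window_view

    win = sliding_window_view(x, (3, 3), axis=(0, 1))  # (H-2, W-2, Cin, 3, 3)
    h, w = win.shape[:2]
    cols = win.transpose(0, 1, 3, 4, 2).reshape(h * w, -1)  # rows: (3*3*Cin)
    kernel = weights.transpose(0, 1, 2, 3).reshape(-1, weights.shape[-1])
    out = cols @ kernel
    return np.maximum(out, 0.0).reshape(h, w, weights.shape[-1])


def _max_pool2(x: np.ndarray) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h // 2, w // 2
    return x[: h2 * 2, : w2 * 2].reshape(h2, 2, w2, 2, c).max(axis=(1, 3))


class FeatureExtractor:
    """Frozen stack of seeded random 3x3 conv filters with ReLU and 2x2 max pooling.

    Random convolutional features preserve the brightness/texture structure that
    separates calcified from healthy valve crops while providing a fixed,
    deterministic embedding — the role a pretrained backbone plays at full scale.
    """

    def __init__(self, backbone_id: str):
        if backbone_id not in CLASSIFIER_BACKBONES:
            raise ConfigError(f"unknown classifier backbone {backbone_id!r}")
        channels, seed = CLASSIFIER_BACKBONES[backbone_id]
        rng = np.random.default_rng(seed)
        self.backbone_id = backbone_id
        self.layers = []
        c_in = 1
        for c_out in channels:
            scale = math.sqrt(2.0 / (9 * c_in))
            self.layers.append(rng.normal(0.0, scale, size=(3, 3, c_in, c_out)))
            c_in = c_out
        self.out_channels = channels[-1]

    def feature_map(self, roi: np.ndarray) -> np.ndarray:
        """Last convolutional map for one ROI crop (any size), as (h, w, channels)."""
        gray = _to_gray(roi) / 255.0
        x = resize(gray, (_INTERNAL_RESOLUTION, _INTERNAL_RESOLUTION), order=1,
                   anti_aliasing=True, preserve_range=True)[:, :, None]
        for weights in self.layers:
            x = _conv2d_relu(x, weights)
            x = _max_pool2(x)
        return x

    def features(self, roi: np.ndarray, pooling: str) -> np.ndarray:
        fmap = self.feature_map(roi)
        if pooling == "none":
            return fmap.ravel()
        if pooling == "max":
            return fmap.max(axis=(0, 1))
        if pooling == "avg":
            return fmap.mean(axis=(0, 1))
        raise ConfigError(f"pooling must be one of {POOLING_MODES}, got {pooling!r}")


@dataclass
class ClassifierModel:
    config: ClassifierConfig
    extractor: FeatureExtractor
    head: Pipeline | None = None  # scaler + trained MLP head; None until train_classifier
    _random_head: tuple[np.ndarray, np.ndarray, np.ndarray, float] | None = None

    def _features(self, roi: np.ndarray) -> np.ndarray:
        # the 224x224 resize mirrors the fixed input shape of the backbone contract
        roi224 = resize(roi.astype(float), (self.config.input_size, self.config.input_size)
                        + roi.shape[2:], order=1, anti_aliasing=True, preserve_range=True)
        return self.extractor.features(roi224.astype(np.uint8), self.config.pooling)

    def predict_probability(self, roi: np.ndarray) -> float:
        f = self._features(roi)
        if self.head is not None:
            return float(self.head.predict_proba(f[None, :])[0, 1])
        # untrained: seeded random dense(120)+ReLU -> logistic unit, still in (0, 1)
        if self._random_head is None or self._random_head[0].shape[1] != f.size:
            rng = np.random.default_rng(self.config.seed)
            w1 = rng.normal(0, 1 / math.sqrt(f.size), size=(self.config.head_width, f.size))
            b1 = rng.normal(0, 0.1, size=self.config.head_width)
            w2 = rng.normal(0, 1 / math.sqrt(self.config.head_width),
                            size=self.config.head_width)
            b2 = float(rng.normal(0, 0.1))
            self._random_head = (w1, b1, w2, b2)
        w1, b1, w2, b2 = self._random_head
        hidden = np.maximum(w1 @ f + b1, 0.0)
        z = float(w2 @ hidden + b2)
        return 1.0 / (1.0 + math.exp(-z))


def build_classifier(config: ClassifierConfig) -> ClassifierModel:
    """Assemble feature extractor + dense(120) + sigmoid head (untrained)."""
    return ClassifierModel(config=config, extractor=FeatureExtractor(config.backbone_id))


def train_classifier(
    train_manifest: DatasetManifest, config: ClassifierConfig
) -> ClassifierModel:
    """Fit the dense head on ROI crops; the convolutional features stay frozen.

    Raises :class:`DataError` when the training manifest contains a single class
    (the head cannot learn a decision boundary; a model trained this way would
    predict the majority class for everything).
    """
    model = build_classifier(config)
    feats, labels = [], []
    for sample in train_manifest:
        if sample.calcified is None:
            continue
        feats.append(model._features(sample.load_image()))
        labels.append(int(sample.calcified))
    if not feats:
        raise DataError("training manifest has no labeled samples")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DataError("training split contains a single class; cannot fit the head")
    if min(np.bincount(y)) < 3:
        warnings.warn("a class has fewer than 3 training samples; expect unstable training",
                      stacklevel=2)
    x = np.asarray(feats)
    head = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "mlp",
                MLPClassifier(
                    hidden_layer_sizes=(config.head_width,),
                    activation="relu",
                    solver="adam",
                    # batch-1 training on tens of samples: a larger step than the
                    # adam default converges within the small epoch budget
                    learning_rate_init=0.01,
                    batch_size=max(config.batch_size, 1),
                    max_iter=config.epochs,
                    random_state=config.seed,
                ),
            ),
        ]
    )
    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        head.fit(x, y)
    model.head = head
    return model


def classify(
    model: ClassifierModel, roi_image: np.ndarray, cutoff: float = 0.5
) -> ClassificationResult:
    """Probability of calcification for one valve crop; label = probability >= cutoff."""
    return ClassificationResult.from_probability(model.predict_probability(roi_image), cutoff)
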