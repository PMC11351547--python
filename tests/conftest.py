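"""Shared fixtures: fast small-canvas scene parameters and session-scoped datasets.

The canonical clinical dataset shape is 61 parasternal short-axis frames, 22
calcified / 39 not.  Tests reproduce that shape on a 320-px canvas (the geometry
scales linearly) so the whole suite stays fast.
"""

from dataclasses import replace

import numpy as np
import pytest

from echocalc.annotations import crop_roi
from echocalc.augment import augment_dataset, balance_by_duplication
from echocalc.manifest import DatasetManifest
from echocalc.synth import SceneParams, generate_dataset, generate_scene

SMALL_PARAMS = SceneParams(
    image_size=320,
    cone_apex=(160.0, 8.0),
    cone_radius=280.0,
    valve_center=(160.0, 170.0),
    valve_outer_radius=34.0,
    valve_inner_radius=22.0,
)


@pytest.fixture(scope="session")
def small_params() -> SceneParams:
    return SMALL_PARAMS


@pytest.fixture(scope="session")
def dataset61(small_params) -> DatasetManifest:
    """The 61-frame synthetic fixture with the clinical class split (22/39)."""
    return generate_dataset(22, 39, base_params=small_params, seed=11)


@pytest.fixture(scope="session")
def aug183(dataset61) -> DatasetManifest:
    """Rotation-augmented detector training set: 61 * 3 = 183 records."""
    return augment_dataset(dataset61, ["rotation"])


def to_roi_manifest(manifest: DatasetManifest) -> DatasetManifest:
    """Crop every sample to its ground-truth valve box (the classifier's input)."""
    return DatasetManifest(
        [
            replace(s, image=crop_roi(s.load_image(), s.valve_box), path=None, valve_box=None)
            for s in manifest
        ]
    )


@pytest.fixture(scope="session")
def roi234(dataset61) -> DatasetManifest:
    """Balanced (78) then rotation-augmented (234) ROI-crop classification set."""
    rois = to_roi_manifest(dataset61)
    return augment_dataset(balance_by_duplication(rois), ["rotation"])


def easy_scene(seed: int, calcified: bool, params: SceneParams = SMALL_PARAMS):
    """One 'easy' scene: peak-255 calcium when calcified, all other pixels <= 200."""
    rng = np.random.default_rng(seed)
    blobs = []
    if calcified:
        cx, cy = params.valve_center
        rho = rng.uniform(0, params.valve_inner_radius * 0.4)
        phi = rng.uniform(0, 2 * np.pi)
        blobs.append(((cx + rho * np.cos(phi), cy + rho * np.sin(phi)), 4.0, 255))
    p = replace(params, calcium_blobs=tuple(blobs), seed=seed)
    return generate_scene(p)
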