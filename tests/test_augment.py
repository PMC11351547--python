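"""Augmentation operators vs brute-force mask oracles, count laws and balancing."""

from dataclasses import replace

import numpy as np
import pytest

from echocalc.annotations import BoundingBox
from echocalc.augment import (
    AugmentationSpec,
    augment_dataset,
    balance_by_duplication,
    gamma_contrast,
    rotate,
    translate,
    zoom,
)
from echocalc.errors import BalanceError, BoxLostError
from echocalc.manifest import DatasetManifest, LabeledSample
from echocalc.synth import generate_scene


def oracle_tight_box(mask: np.ndarray) -> BoundingBox:
    ys, xs = np.nonzero(mask)
    return BoundingBox(int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)


def box_mask(box: BoundingBox, shape) -> np.ndarray:
    m = np.zeros(shape + (3,), np.uint8)
    m[box.y_min : box.y_max, box.x_min : box.x_max] = 255
    return m


class TestTranslate:
    def test_zero_fraction_identity(self):
        rng = np.random.default_rng(0)
        image = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        box = BoundingBox(10, 10, 30, 30)
        out, nb = translate(image, box, 0.0)
        assert np.array_equal(out, image) and nb == box

    def test_spec_shift_arithmetic(self):
        image = np.zeros((640, 640, 3), np.uint8)
        _, nb = translate(image, BoundingBox(100, 100, 200, 200), 0.2)
        assert nb.astuple() == (228, 228, 328, 328)

    def test_pixel_content_equality_on_overlap(self):
        rng = np.random.default_rng(1)
        image = rng.integers(0, 255, (50, 50, 3)).astype(np.uint8)
        out, _ = translate(image, BoundingBox(20, 20, 30, 30), 0.1)
        dx = dy = round(0.1 * 50)
        assert np.array_equal(out[dy:, dx:], image[: 50 - dy, : 50 - dx])
        assert (out[:dy, :] == 0).all() and (out[:, :dx] == 0).all()

    def test_box_lost(self):
        image = np.zeros((100, 100, 3), np.uint8)
        with pytest.raises(BoxLostError):
            translate(image, BoundingBox(0, 0, 10, 10), -0.5)


class TestZoom:
    def test_unit_scale_identity_box(self):
        image = np.zeros((640, 640, 3), np.uint8)
        _, nb = zoom(image, BoundingBox(100, 120, 200, 240), 1.0)
        assert nb.astuple() == (100, 120, 200, 240)

    def test_spec_half_scale_arithmetic(self):
        image = np.zeros((640, 640, 3), np.uint8)
        _, nb = zoom(image, BoundingBox(220, 220, 420, 420), 0.5)
        assert nb.astuple() == (270, 270, 370, 370)

    def test_enlarge_then_shrink_recovers_central_box(self):
        image = np.zeros((640, 640, 3), np.uint8)
        box = BoundingBox(280, 280, 360, 360)
        img2, b2 = zoom(image, box, 2.0)
        _, b3 = zoom(img2, b2, 0.5)
        assert all(abs(a - b) <= 1 for a, b in zip(b3.astuple(), box.astuple()))


class TestRotate:
    def test_zero_angle_identity_box(self):
        image = np.zeros((640, 640, 3), np.uint8)
        _, nb = rotate(image, BoundingBox(100, 100, 200, 220), 0.0)
        assert nb.astuple() == (100, 100, 200, 220)

    def test_centered_box_stays_centered(self):
        image = np.zeros((640, 640, 3), np.uint8)
        for angle in (10.0, -10.0, 33.0):
            _, nb = rotate(image, BoundingBox(220, 220, 420, 420), angle)
            assert nb.center == (320.0, 320.0)

    def test_angle_limit(self):
        with pytest.raises(ValueError):
            rotate(np.zeros((10, 10, 3), np.uint8), None, 60.0)

    def test_rotated_ring_box_contains_rotated_ring(self, small_params):
        """The co-transformed box (corner hull) covers the physically rotated valve
        ring, and its overestimate stays within the analytic corner-hull growth
        R*(cos a + sin a - 1) + 2 px (a round object never fills its rotated
        rectangle's corners)."""
        import math

        params = replace(small_params, speckle_sd=0.0, speckle_mean=30.0)
        image, truth = generate_scene(params)
        angle = 10.0
        out, nb = rotate(image, truth.valve_box, angle)
        ring = out[..., 0] >= params.valve_level - 10
        derived = oracle_tight_box(ring)
        # containment (2 px slack for bilinear edge fade)
        assert nb.x_min <= derived.x_min + 2 and nb.y_min <= derived.y_min + 2
        assert nb.x_max >= derived.x_max - 2 and nb.y_max >= derived.y_max - 2
        a = math.radians(angle)
        growth = 0.5 * max(truth.valve_box.width, truth.valve_box.height) * (
            math.cos(a) + math.sin(a) - 1.0
        )
        assert all(
            abs(got - ref) <= growth + 2
            for got, ref in zip(nb.astuple(), derived.astuple())
        )


class TestGamma:
    def test_unit_gamma_identity(self):
        rng = np.random.default_rng(2)
        image = rng.integers(0, 255, (16, 16, 3)).astype(np.uint8)
        out, _ = gamma_contrast(image, None, 1.0)
        assert np.array_equal(out, image)

    def test_formula_at_midgray(self):
        image = np.full((1, 1, 3), 128, np.uint8)
        out, _ = gamma_contrast(image, None, 0.5)
        assert out[0, 0, 0] == 181  # round(255 * (128/255)**0.5)

    def test_matches_direct_evaluation_everywhere(self):
        levels = np.arange(256, dtype=np.uint8).reshape(16, 16, 1).repeat(3, axis=2)
        for gamma in (0.5, 1.2):
            out, _ = gamma_contrast(levels, None, gamma)
            expected = np.rint(255.0 * (levels / 255.0) ** gamma).astype(np.uint8)
            assert np.array_equal(out, expected)

    def test_monotone_in_input(self):
        ramp = np.arange(256, dtype=np.uint8)[:, None, None].repeat(3, axis=2)
        out, _ = gamma_contrast(ramp, None, 1.2)
        assert (np.diff(out[:, 0, 0].astype(int)) >= 0).all()


@pytest.mark.parametrize("op,param", [(translate, 0.13), (zoom, 0.7), (zoom, 1.6), (rotate, -7.0)])
def test_box_agrees_with_mask_transform_oracle(op, param):
    """Transform a solid box mask with the operator itself, re-derive the tight box
    and compare with the co-transformed annotation box (2 px tolerance)."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        x0, y0 = rng.integers(40, 160, 2)
        bw, bh = rng.integers(20, 80, 2)
        box = BoundingBox(int(x0), int(y0), int(x0 + bw), int(y0 + bh))
        mask = box_mask(box, (256, 256))
        try:
            out, nb = op(mask, box, param)
        except BoxLostError:
            continue
        transformed = out[..., 0] > 127
        if not transformed.any():
            continue
        derived = oracle_tight_box(transformed)
        assert all(abs(a - b) <= 2 for a, b in zip(nb.astuple(), derived.astuple()))


def tiny_manifest(n_pos: int, n_neg: int, size: int = 40) -> DatasetManifest:
    rng = np.random.default_rng(n_pos * 100 + n_neg)
    samples = []
    for i in range(n_pos + n_neg):
        img = rng.integers(0, 200, (size, size, 3)).astype(np.uint8)
        samples.append(
            LabeledSample(
                image_id=f"S{i:02d}",
                image=img,
                valve_box=BoundingBox(10, 10, 30, 30),
                calcified=i < n_pos,
            )
        )
    return DatasetManifest(samples)


class TestAugmentDataset:
    @pytest.mark.parametrize("n,techniques", [(3, ["rotation"]), (2, ["translation", "gamma"]),
                                              (1, ["translation", "zoom", "rotation", "gamma"])])
    def test_count_law(self, n, techniques):
        out = augment_dataset(tiny_manifest(n, 0), techniques)
        assert len(out) == n * (1 + 2 * len(techniques))

    def test_originals_preserved_first(self):
        m = tiny_manifest(1, 1)
        out = augment_dataset(m, ["gamma"])
        assert [s.image_id for s in out][:2] == [s.image_id for s in m]
        assert all(s.augmentation for s in out[2:])

    def test_variants_keep_label_and_group(self):
        out = augment_dataset(tiny_manifest(1, 1), ["rotation"])
        for s in out:
            assert s.group in {"S00", "S01"}
            assert s.calcified == (s.group == "S00")

    def test_unknown_technique_rejected(self):
        with pytest.raises(ValueError):
            augment_dataset(tiny_manifest(1, 0), ["shear"])

    def test_nonstandard_parameters_need_custom_flag(self):
        spec = AugmentationSpec("rotation", (30.0, -30.0))
        with pytest.raises(ValueError):
            augment_dataset(tiny_manifest(1, 0), [spec])
        out = augment_dataset(tiny_manifest(1, 0), [spec], custom=True)
        assert len(out) == 3

    def test_box_lost_reports_image_id(self):
        m = DatasetManifest(
            [
                LabeledSample(
                    image_id="EDGE",
                    image=np.zeros((100, 100, 3), np.uint8),
                    valve_box=BoundingBox(0, 0, 8, 8),
                )
            ]
        )
        with pytest.raises(BoxLostError, match="EDGE"):
            augment_dataset(m, ["translation"])


class TestBalanceByDuplication:
    def test_already_balanced_unchanged(self):
        m = tiny_manifest(10, 10)
        out = balance_by_duplication(m)
        assert len(out) == 20 and out.class_counts() == (10, 10)

    def test_cyclic_duplication_one_vs_five(self):
        out = balance_by_duplication(tiny_manifest(1, 5))
        assert len(out) == 10
        dups = [s for s in out if s.duplicate_of is not None]
        assert len(dups) == 4 and all(d.duplicate_of == "S00" for d in dups)

    def test_empty_class_raises(self):
        with pytest.raises(BalanceError):
            balance_by_duplication(tiny_manifest(0, 5))

    def test_balance_then_rotation_triples(self):
        out = augment_dataset(balance_by_duplication(tiny_manifest(2, 5)), ["rotation"])
        assert len(out) == 2 * 5 * 3
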