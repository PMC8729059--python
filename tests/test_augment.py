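"""Photometric filter bank, flips, 36x expansion, scale and erase augmentation."""

import numpy as np
import pytest

from cytoscreen import (
    AugmentationPlan,
    BoundingBox,
    CellImage,
    ConfigError,
    FilterSpec,
    apply_filter,
    default_filter_bank,
    expand_dataset,
    flip,
    flip_boxes,
    random_erase,
    scale_augment,
)
from cytoscreen.augment import save_image
from cytoscreen.synthetic import generate_scene, SyntheticSceneSpec


def tiny_images(n, size=8, seed=0):
    rng = np.random.default_rng(seed)
    return [
        CellImage(
            pixels=rng.integers(0, 256, size=(size, size, 3), dtype=np.uint8),
            id=f"img{i:03d}",
        )
        for i in range(n)
    ]


class TestFilters:
    @pytest.mark.parametrize(
        "spec",
        [
            FilterSpec("brightness", {"delta": 0}),
            FilterSpec("gamma", {"gamma": 1.0}),
            FilterSpec("contrast", {"factor": 1.0}),
        ],
    )
    def test_identity_parameters(self, random_image, spec):
        out = apply_filter(random_image, spec)
        assert np.array_equal(out.pixels, random_image.pixels)

    def test_brightness_arithmetic_with_clipping(self, flat_image):
        out = apply_filter(flat_image, FilterSpec("brightness", {"delta": 30}))
        assert np.all(out.pixels == 158)
        bright = CellImage(pixels=np.full((4, 4, 3), 240, np.uint8), id="b")
        out = apply_filter(bright, FilterSpec("brightness", {"delta": 30}))
        assert np.all(out.pixels == 255)

    def test_unknown_filter_rejected(self, flat_image):
        with pytest.raises(ConfigError):
            apply_filter(flat_image, FilterSpec("posterize", {}))

    def test_bank_has_nine_dimension_preserving_deterministic_filters(
        self, random_image
    ):
        bank = default_filter_bank()
        assert len(bank) == 9
        for f in bank:
            a = apply_filter(random_image, f)
            b = apply_filter(random_image, f)
            assert a.pixels.shape == random_image.pixels.shape
            assert a.pixels.dtype == np.uint8
            assert np.array_equal(a.pixels, b.pixels)


class TestFlips:
    @pytest.mark.parametrize("state", ["horizontal", "vertical"])
    def test_involution(self, random_image, state):
        twice = flip(flip(random_image, state), state)
        assert np.array_equal(twice.pixels, random_image.pixels)

    def test_both_is_composition(self, random_image):
        both = flip(random_image, "both")
        comp = flip(flip(random_image, "horizontal"), "vertical")
        assert np.array_equal(both.pixels, comp.pixels)

    def test_single_pixel_coordinate_oracle(self):
        px = np.zeros((5, 9, 3), dtype=np.uint8)
        px[2, 1] = 255
        out = flip(CellImage(pixels=px, id="p"), "horizontal")
        assert out.pixels[2, 9 - 1 - 1].tolist() == [255, 255, 255]
        assert out.pixels.sum() == 3 * 255

    def test_boxes_mirrored_with_image(self):
        boxes = [BoundingBox(cx=0.2, cy=0.6, w=0.1, h=0.1)]
        h = flip_boxes(boxes, "horizontal")[0]
        v = flip_boxes(boxes, "vertical")[0]
        b = flip_boxes(boxes, "both")[0]
        assert (h.cx, h.cy) == pytest.approx((0.8, 0.6))
        assert (v.cx, v.cy) == pytest.approx((0.2, 0.4))
        assert (b.cx, b.cy) == pytest.approx((0.8, 0.4))


class TestExpansion:
    @pytest.mark.parametrize("k", [0, 1, 3])
    def test_exactly_36x(self, k):
        out = expand_dataset(tiny_images(k))
        assert len(out) == 36 * k

    def test_provenance_tags_distinct_and_original_absent(self):
        (img,) = tiny_images(1)
        out = expand_dataset([img])
        ids = {o.id for o in out}
        assert len(ids) == 36
        assert img.id not in ids
        assert all(o.id.startswith(img.id + "__") for o in out)

    @pytest.mark.parametrize(
        "k,expected",
        [(104, 3744), (123, 4428), (138, 4968), (119, 4284), (91, 3276),
         (118, 4248), (121, 4356), (114, 4104), (131, 4716), (201, 7236),
         (267, 9612)],
    )
    def test_expansion_arithmetic_for_published_row_counts(self, k, expected):
        assert AugmentationPlan().expansion_factor * k == expected

    def test_plan_requires_nine_filters(self):
        with pytest.raises(ConfigError):
            AugmentationPlan(filters=tuple(default_filter_bank()[:5]))

    def test_expansion_is_reproducible(self):
        imgs = tiny_images(2, seed=7)
        a = expand_dataset(imgs)
        b = expand_dataset(imgs)
        assert all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))


class TestScaleAugment:
    def test_dimensions_preserved_and_seed_deterministic(self, random_image):
        a = scale_augment(random_image, (1.0, 1.25), rng=5)
        b = scale_augment(random_image, (1.0, 1.25), rng=5)
        assert a.pixels.shape == random_image.pixels.shape
        assert np.array_equal(a.pixels, b.pixels)

    def test_unit_scale_is_identity(self, random_image):
        out = scale_augment(random_image, (1.0, 1.0), rng=0)
        assert np.array_equal(out.pixels, random_image.pixels)

    def test_low_below_one_rejected(self, random_image):
        with pytest.raises(ConfigError):
            scale_augment(random_image, (0.8, 1.2), rng=0)

    def test_values_bounded_by_input_range(self):
        px = np.zeros((20, 20, 3), dtype=np.uint8)
        px[:, 10:] = 200
        img = CellImage(pixels=px, id="hw")
        out = scale_augment(img, (2.0, 2.0), rng=3)
        assert out.pixels.min() >= 0 and out.pixels.max() <= 200


class TestRandomErase:
    def test_zero_probability_is_identity(self, random_image):
        out = random_erase(random_image, erase_prob=0.0, rng=1)
        assert np.array_equal(out.pixels, random_image.pixels)

    def test_seed_deterministic(self, random_image):
        a = random_erase(random_image, erase_prob=1.0, rng=9)
        b = random_erase(random_image, erase_prob=1.0, rng=9)
        assert np.array_equal(a.pixels, b.pixels)

    def test_changes_confined_to_one_rectangle_within_area_range(self):
        rng = np.random.default_rng(0)
        img = CellImage(
            pixels=rng.integers(0, 256, (40, 50, 3), dtype=np.uint8), id="e"
        )
        out = random_erase(img, erase_prob=1.0, area=(0.1, 0.3), rng=11)
        diff = np.any(out.pixels != img.pixels, axis=2)
        rows, cols = np.nonzero(diff)
        assert rows.size > 0
        rect_area = (rows.max() - rows.min() + 1) * (cols.max() - cols.min() + 1)
        frac = rect_area / (40 * 50)
        assert 0.05 <= frac <= 0.35

    def test_infeasible_area_rejected(self, random_image):
        with pytest.raises(ConfigError):
            random_erase(random_image, area=(0.0, 1.5), rng=0)


def test_full_augmentation_byte_reproducible_from_master_seed(tmp_path):
    """Directory expansion of a seeded synthetic scene is bit-stable."""
    img, truth = generate_scene(SyntheticSceneSpec(seed=12, width=48, height=48))
    from cytoscreen.boxes import write_darknet
    for d in ("a", "b"):
        (tmp_path / d).mkdir()
        save_image(img, tmp_path / d / "scene.png")
        write_darknet(tmp_path / d / "scene.txt", list(truth.boxes))
    from cytoscreen import expand_directory
    ma = expand_directory(tmp_path / "a", tmp_path / "out_a")
    mb = expand_directory(tmp_path / "b", tmp_path / "out_b")
    assert len(ma) == len(mb) == 36
    for pa, pb in zip(sorted((tmp_path / "out_a").glob("*.png")),
                      sorted((tmp_path / "out_b").glob("*.png"))):
        assert pa.read_bytes() == pb.read_bytes()
    # annotation sidecars carried over and remapped
    assert len(list((tmp_path / "out_a").glob("*.txt"))) == 36
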