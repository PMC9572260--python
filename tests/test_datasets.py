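"""Annotation IO, rasterization, resizing, augmentation and splits."""

import json

import numpy as np
import pytest

from wheatvision import datasets
from wheatvision.datasets import PolygonAnnotation


def brute_force_rasterize(annotations, width, height):
    """Independent oracle: per-pixel even-odd ray casting, later polygon wins."""
    mask = np.zeros((height, width), dtype=np.uint8)
    for ann in annotations:
        pts = list(ann.points)
        if _area(pts) == 0:
            continue
        n = len(pts)
        for y in range(height):
            for x in range(width):
                inside = False
                for k in range(n):
                    x1, y1 = pts[k]
                    x2, y2 = pts[(k + 1) % n]
                    if (y1 <= y < y2) or (y2 <= y < y1):
                        xi = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                        if xi > x:
                            inside = not inside
                if inside:
                    mask[y, x] = ann.label
    return mask


def _area(pts):
    s = 0.0
    for k in range(len(pts)):
        x1, y1 = pts[k]
        x2, y2 = pts[(k + 1) % len(pts)]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2


class TestLabelme:
    def test_single_triangle(self, tmp_path):
        path = tmp_path / "a.json"
        datasets.write_labelme(
            path,
            [PolygonAnnotation(label=1, points=((1, 1), (5, 1), (3, 4)))],
            "a.png", 8, 8,
        )
        anns = datasets.read_labelme(path)
        assert len(anns) == 1
        assert anns[0].label == 1
        assert len(anns[0].points) == 3

    def test_empty_shapes(self, tmp_path):
        path = tmp_path / "empty.json"
        datasets.write_labelme(path, [], "a.png", 8, 8)
        assert datasets.read_labelme(path) == []

    def test_unknown_label_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        doc = {"shapes": [{"label": "weed", "points": [[0, 0], [1, 0], [1, 1]]}]}
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="weed"):
            datasets.read_labelme(path)

    def test_malformed_json_names_path(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="broken.json"):
            datasets.read_labelme(path)


class TestRasterize:
    def test_full_canvas_polygon(self):
        ann = PolygonAnnotation(
            label=1, points=((-1, -1), (20, -1), (20, 20), (-1, 20))
        )
        mask = datasets.rasterize([ann], 8, 8)
        assert (mask == 1).all()

    def test_later_polygon_wins(self):
        grain = PolygonAnnotation(label=1, points=((-1, -1), (8, -1), (8, 8), (-1, 8)))
        imp = PolygonAnnotation(label=2, points=((-1, -1), (8, -1), (8, 8), (-1, 8)))
        mask = datasets.rasterize([grain, imp], 8, 8)
        assert (mask == 2).all()

    def test_degenerate_polygon_skipped_with_warning(self):
        bad = PolygonAnnotation(label=1, points=((2, 2), (2, 2), (2, 2)))
        with pytest.warns(UserWarning, match="degenerate"):
            mask = datasets.rasterize([bad], 8, 8)
        assert (mask == 0).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        anns = []
        for _ in range(rng.integers(1, 5)):
            n_pts = int(rng.integers(3, 9))
            pts = tuple(
                (float(x), float(y)) for x, y in rng.uniform(-4, 36, (n_pts, 2))
            )
            anns.append(PolygonAnnotation(label=int(rng.integers(1, 3)), points=pts))
        fast = datasets.rasterize(anns, 32, 32)
        slow = brute_force_rasterize(anns, 32, 32)
        assert np.array_equal(fast, slow)


class TestResize:
    def test_identity_when_already_target(self, rendered):
        im, mk = datasets.resize_pair(rendered.image, rendered.mask, (128, 128))
        assert np.array_equal(im, rendered.image)
        assert np.array_equal(mk, rendered.mask)

    def test_downscale_label_set_preserved(self):
        rng = np.random.default_rng(0)
        mask = rng.integers(0, 3, (1024, 1280)).astype(np.uint8)
        image = rng.integers(0, 255, (1024, 1280, 3)).astype(np.uint8)
        im, mk = datasets.resize_pair(image, mask, (512, 512))
        assert mk.shape == (512, 512)
        assert im.shape == (512, 512, 3)
        assert set(np.unique(mk)) <= {0, 1, 2}

    def test_constant_image_stays_constant(self):
        image = np.full((64, 48, 3), 77, dtype=np.uint8)
        out = datasets.resize_image(image, (32, 24))
        assert (out == 77).all()

    def test_nonpositive_target_rejected(self, rendered):
        with pytest.raises(ValueError):
            datasets.resize_image(rendered.image, (0, 10))


class TestAugment:
    def test_exactly_six_variants(self, rendered):
        assert len(datasets.augment(rendered.image, rendered.mask)) == 6

    def test_dataset_multiplied_by_seven(self, rendered):
        pairs = [(rendered.image, rendered.mask)] * 3
        assert len(datasets.augment_dataset(pairs)) == 21

    def test_rotations_and_mirrors_preserve_counts(self, rendered):
        base = np.bincount(rendered.mask.ravel(), minlength=3)
        variants = datasets.augment(rendered.image, rendered.mask)
        for idx in (0, 1, 4, 5):  # rot90, rot270, hflip, vflip
            counts = np.bincount(variants[idx][1].ravel(), minlength=3)
            assert np.array_equal(counts, base)

    def test_scaled_variants_keep_canvas_and_labels(self, rendered):
        variants = datasets.augment(rendered.image, rendered.mask)
        for idx in (2, 3):
            im, mk = variants[idx]
            assert im.shape == rendered.image.shape
            assert mk.shape == rendered.mask.shape
            assert set(np.unique(mk)) <= {0, 1, 2}

    def test_four_rot90_is_identity(self, rendered):
        mask = rendered.mask
        for _ in range(4):
            mask = np.rot90(mask, 1)
        assert np.array_equal(mask, rendered.mask)

    def test_misaligned_pair_rejected(self, rendered):
        with pytest.raises(ValueError):
            datasets.augment(rendered.image, rendered.mask[:-1])


class TestSplit:
    def test_sizes_and_disjointness(self):
        files = [f"im{i}" for i in range(500)]
        split = datasets.split_dataset(files, counts=(350, 50, 100), seed=1)
        assert (len(split.train), len(split.val), len(split.test)) == (350, 50, 100)
        union = set(split.train) | set(split.val) | set(split.test)
        assert len(union) == 500

    def test_all_in_train(self):
        files = list("abcde")
        split = datasets.split_dataset(files, counts=(5, 0, 0), seed=0)
        assert sorted(split.train) == files
        assert split.val == () and split.test == ()

    def test_deterministic_under_seed(self):
        files = [f"im{i}" for i in range(30)]
        a = datasets.split_dataset(files, counts=(20, 5, 5), seed=9)
        b = datasets.split_dataset(files, counts=(20, 5, 5), seed=9)
        assert a == b

    def test_insufficient_files_error_states_counts(self):
        with pytest.raises(ValueError, match="350"):
            datasets.split_dataset(["a"], counts=(350, 50, 100), seed=0)
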