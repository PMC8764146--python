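"""Synthetic generator, preprocessing, augmentation, folds and PNG I/O."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from msstgan.data import (PHENOTYPES, SyntheticSample, augment,
                          generate_dataset, generate_sample, load_manifest,
                          make_folds, read_pair, resize_bilinear, resize_mask,
                          write_pair)


class TestGenerateSample:
    def test_determinism_byte_identical(self):
        a = generate_sample("flaky", 64, seed=5)
        b = generate_sample("flaky", 64, seed=5)
        np.testing.assert_array_equal(a.image, b.image)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_point_like_unlabeled_by_default(self):
        s = generate_sample("point_like", 64, seed=0)
        assert s.mask is None
        assert generate_sample("point_like", 64, seed=0, labeled=True).mask is not None

    def test_flaky_mask_area_within_band(self):
        # lesion fraction of image area over 100 seeds
        fracs = [generate_sample("flaky", 128, seed=i).mask.mean() for i in range(100)]
        assert 0.01 <= min(fracs) and max(fracs) <= 0.25

    def test_phenotype_component_areas_strictly_ordered(self):
        means = {}
        for ph in PHENOTYPES:
            areas = []
            for seed in range(100):
                mask = generate_sample(ph, 128, seed=seed, labeled=True).mask
                _, n = ndi.label(mask)
                if n:
                    areas.append(mask.sum() / n)
            means[ph] = np.mean(areas)
        assert means["point_like"] < means["point_flaky"] < means["flaky"]

    def test_mask_confined_to_cornea_disk(self):
        # lesion pixels must be bright-green cornea pixels, never background
        s = generate_sample("flaky", 128, seed=3, noise=False)
        ys, xs = np.nonzero(s.mask)
        center = np.array([64.0, 64.0])
        dists = np.hypot(ys - center[0], xs - center[1])
        assert dists.max() <= 0.45 * 128 * 0.95 + 3

    def test_noiseless_mask_is_exact_lesion_support(self):
        s = generate_sample("flaky", 64, seed=1, noise=False)
        # lesion pixels are green-dominant and brighter than cornea base
        green = s.image[:, :, 1].astype(int)
        assert green[s.mask == 1].min() > 150
        assert (green[s.mask == 0] <= 150).mean() > 0.99

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="phenotype"):
            generate_sample("nodular", 64, 0)
        with pytest.raises(ValueError, match="size"):
            generate_sample("flaky", 50, 0)


class TestPreprocessing:
    def test_native_resolution_resized_to_512(self, rng):
        big = rng.integers(0, 255, size=(1728, 2592, 3), dtype=np.uint8)
        assert resize_bilinear(big, 512).shape == (512, 512, 3)

    def test_already_target_size_shape_unchanged(self, rng):
        img = rng.integers(0, 255, size=(512, 512, 3), dtype=np.uint8)
        assert resize_bilinear(img, 512).shape == (512, 512, 3)

    def test_constant_image_stays_constant(self):
        img = np.full((256, 256, 3), 77, dtype=np.uint8)
        out = resize_bilinear(img, 128)
        assert (out == 77).all()

    def test_mask_resize_stays_binary(self, rng):
        mask = (rng.uniform(size=(200, 200)) > 0.5).astype(np.uint8)
        out = resize_mask(mask, 64)
        assert set(np.unique(out)) <= {0, 1}

    def test_indivisible_target_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            resize_bilinear(np.zeros((64, 64, 3), dtype=np.uint8), 100)


def _draws(seed):
    """Replicate the augmentation pipeline's five coin flips for a seed."""
    rng = np.random.default_rng(seed)
    flips = []
    coins = []
    for _ in range(5):
        c = rng.random() < 0.5
        coins.append(c)
        if c and len(coins) == 1:
            rng.uniform(-10, 10)  # rotation angle draw
    return coins


def _seed_with(pattern):
    for seed in range(5000):
        if _draws(seed) == pattern:
            return seed
    raise AssertionError("no seed found for pattern")


class TestAugment:
    @staticmethod
    def _disk_sample(size=64):
        img = np.zeros((size, size, 3), dtype=np.uint8)
        mask = np.zeros((size, size), dtype=np.uint8)
        yy, xx = np.ogrid[:size, :size]
        disk = (yy - 40) ** 2 + (xx - 22) ** 2 <= 64
        img[disk] = (80, 220, 70)
        mask[disk] = 1
        return SyntheticSample(image=img, mask=mask, phenotype="flaky", seed=0)

    def test_no_op_seed_leaves_sample_unchanged(self):
        seed = _seed_with([False] * 5)
        s = self._disk_sample()
        out = augment(s, seed=seed)
        np.testing.assert_array_equal(out.image, s.image)
        np.testing.assert_array_equal(out.mask, s.mask)

    def test_horizontal_flip_mirrors_mask_centroid(self):
        seed = _seed_with([False, True, False, False, False])
        s = self._disk_sample()
        out = augment(s, seed=seed)
        col = ndi.center_of_mass(s.mask)[1]
        col_flipped = ndi.center_of_mass(out.mask)[1]
        assert abs((s.mask.shape[1] - 1 - col) - col_flipped) <= 1.0

    def test_pure_flip_is_exact_on_masks(self):
        seed = _seed_with([False, True, True, False, False])
        s = self._disk_sample()
        out = augment(s, seed=seed)
        np.testing.assert_array_equal(out.mask, s.mask[::-1, ::-1])

    def test_rotation_round_trip_keeps_disk(self):
        from skimage.transform import rotate

        s = self._disk_sample()
        once = rotate(s.mask.astype(float), 10, order=0) > 0.5
        back = rotate(once.astype(float), -10, order=0) > 0.5
        inter = (back & (s.mask > 0)).sum()
        union = (back | (s.mask > 0)).sum()
        assert inter / union >= 0.95

    def test_mask_stays_binary_and_geometry_shared(self):
        s = self._disk_sample()
        for seed in range(10):
            out = augment(s, seed=seed)
            assert set(np.unique(out.mask)) <= {0, 1}
            assert out.image.shape == s.image.shape
            # lesion pixels remain green-dominant after shared warp
            if out.mask.sum():
                ys, xs = np.nonzero(out.mask)
                greens = out.image[ys, xs, 1]
                assert np.median(greens) > 100


class TestFolds:
    def test_historical_sizes_for_354_ids(self):
        assignment = make_folds(range(354), k=4, seed=1)
        sizes = [sum(1 for f in assignment.values() if f == i) for i in range(4)]
        assert sizes == [90, 90, 90, 84]

    def test_even_split_of_eight(self):
        assignment = make_folds(range(8), k=4, seed=0)
        sizes = [sum(1 for f in assignment.values() if f == i) for i in range(4)]
        assert sizes == [2, 2, 2, 2]

    def test_partition_property(self):
        ids = [f"img{i}" for i in range(23)]
        assignment = make_folds(ids, k=5, seed=3)
        assert set(assignment) == set(ids)
        assert set(assignment.values()) == set(range(5))

    def test_bad_sizes_rejected(self):
        with pytest.raises(ValueError, match="partition"):
            make_folds(range(10), k=2, sizes=[4, 4])


class TestIO:
    def test_png_round_trip_is_lossless(self, tmp_path):
        s = generate_sample("flaky", 64, seed=2)
        write_pair(s, tmp_path / "img.png", tmp_path / "mask.png")
        back = read_pair(tmp_path / "img.png", tmp_path / "mask.png")
        np.testing.assert_array_equal(back.image, s.image)
        np.testing.assert_array_equal(back.mask, s.mask)

    def test_non_binary_mask_file_rejected(self, tmp_path):
        from PIL import Image

        Image.fromarray(np.full((8, 8), 128, dtype=np.uint8)).save(tmp_path / "m.png")
        s = generate_sample("point_like", 64, seed=0)
        write_pair(s, tmp_path / "i.png")
        with pytest.raises(ValueError, match="not binary"):
            read_pair(tmp_path / "i.png", tmp_path / "m.png")

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="nowhere.png"):
            read_pair(tmp_path / "nowhere.png")


class TestDataset:
    def test_counts_and_manifest_bulk_load(self, tiny_manifest):
        assert len(tiny_manifest.labeled) == 8
        assert len(tiny_manifest.unlabeled) == 8
        samples = tiny_manifest.load_labeled() + tiny_manifest.load_unlabeled()
        assert len(samples) == 16
        assert all(s.mask is not None for s in samples[:8])
        assert all(s.mask is None for s in samples[8:])

    def test_labeled_phenotypes_exclude_point_like(self, tiny_manifest):
        assert all(e["phenotype"] in ("point_flaky", "flaky")
                   for e in tiny_manifest.labeled)
        assert all(e["phenotype"] == "point_like" for e in tiny_manifest.unlabeled)

    def test_regeneration_is_deterministic(self, tmp_path):
        m1 = generate_dataset(4, 2, 64, master_seed=3, outdir=tmp_path / "a")
        m2 = generate_dataset(4, 2, 64, master_seed=3, outdir=tmp_path / "b")
        assert [e["seed"] for e in m1.labeled] == [e["seed"] for e in m2.labeled]
        img1 = (tmp_path / "a" / m1.labeled[0]["image"]).read_bytes()
        img2 = (tmp_path / "b" / m2.labeled[0]["image"]).read_bytes()
        assert img1 == img2

    def test_manifest_round_trip(self, tmp_path):
        m = generate_dataset(4, 2, 64, master_seed=1, outdir=tmp_path)
        loaded = load_manifest(tmp_path / "manifest.json")
        assert loaded.labeled == m.labeled
        assert loaded.master_seed == 1

    def test_too_few_labeled_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="at least 4"):
            generate_dataset(2, 2, 64, 0, tmp_path)
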