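"""The seven-step image preparation chain."""

import numpy as np
import pytest
from PIL import Image

from btcnn.preprocess import (
    CLASSES,
    MRIPreprocessor,
    PreprocessConfig,
    binary_mask,
    clahe,
    find_crop_box,
    gaussian_blur,
    gaussian_kernel,
    load_dataset,
    morphology_clean,
    one_hot,
    preprocess_array,
    preprocess_image,
    resize,
    to_grayscale,
)


class TestGrayscale:
    def test_gray_input_unchanged(self):
        img = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(to_grayscale(img), img)

    def test_equal_channels_preserved(self):
        rgb = np.full((4, 4, 3), 77.0)
        np.testing.assert_allclose(to_grayscale(rgb), np.full((4, 4), 77.0))

    def test_pure_white(self):
        assert to_grayscale(np.full((2, 2, 3), 255.0))[0, 0] == pytest.approx(255.0)

    def test_luminance_weights(self):
        px = np.zeros((1, 1, 3))
        px[0, 0] = [100, 0, 0]
        assert to_grayscale(px)[0, 0] == pytest.approx(29.9)

    def test_two_channels_rejected(self):
        with pytest.raises(ValueError):
            to_grayscale(np.zeros((4, 4, 2)))


class TestGaussianKernel:
    @pytest.mark.parametrize("sigma", [0.3, 0.8, 2.0])
    def test_normalized(self, sigma):
        assert gaussian_kernel(sigma, (3, 3)).sum() == pytest.approx(1.0)

    def test_symmetric(self):
        k = gaussian_kernel(1.1, (5, 5))
        np.testing.assert_allclose(k, k[::-1, :])
        np.testing.assert_allclose(k, k[:, ::-1])
        np.testing.assert_allclose(k, k.T)

    def test_large_sigma_approaches_uniform(self):
        k = gaussian_kernel(1e4, (3, 3))
        np.testing.assert_allclose(k, np.full((3, 3), 1 / 9), atol=1e-6)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_kernel(0.0, (3, 3))


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((10, 12), 42.0)
        np.testing.assert_allclose(gaussian_blur(img), img)

    def test_mass_conserved_for_interior_impulse(self):
        img = np.zeros((9, 9))
        img[4, 4] = 100.0
        out = gaussian_blur(img)
        assert out.sum() == pytest.approx(100.0)
        assert np.all(out[4 + 2 :, :] == 0)  # mass stays in the 3x3 neighbourhood

    def test_no_overshoot(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, size=(20, 20))
        out = gaussian_blur(img)
        assert out.min() >= img.min() - 1e-9
        assert out.max() <= img.max() + 1e-9

    def test_default_sigma_from_window(self):
        assert PreprocessConfig().effective_sigma() == pytest.approx(0.8)
        assert PreprocessConfig(blur_sigma=0.3).effective_sigma() == 0.3


class TestClahe:
    def test_range_bounded(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 255, size=(64, 64))
        out = clahe(img, clip=2.0, tiles=(8, 8))
        assert out.min() >= 0.0 and out.max() <= 255.0

    def test_single_tile_large_clip_is_global_equalization(self):
        """With one tile and no effective clipping, the map is the global
        histogram-equalisation CDF."""
        rng = np.random.default_rng(2)
        img = np.clip(rng.normal(120, 10, size=(64, 64)), 0, 255)
        out = clahe(img, clip=1e9, tiles=(1, 1))
        levels = img.astype(int)
        hist = np.bincount(levels.ravel(), minlength=256).astype(float)
        expected = hist.cumsum() * 255.0 / levels.size
        np.testing.assert_allclose(out, expected[levels], atol=1e-6)

    def test_low_contrast_ramp_gains_contrast(self):
        ramp = np.tile(np.linspace(100, 140, 64), (64, 1))
        out = clahe(ramp, clip=2.0, tiles=(8, 8))
        assert out.std() > ramp.std()

    def test_degenerate_image_rejected(self):
        with pytest.raises(ValueError):
            clahe(np.empty((0, 0)))


class TestMaskAndMorphology:
    def test_threshold_boundary(self):
        img = np.array([[44, 45], [0, 255]])
        mask = binary_mask(img, 45)
        assert not mask[0, 0]  # 44 < 45 -> background
        assert mask[0, 1]  # 45 is foreground ("less than 45" excludes 45)
        assert not mask[1, 0] and mask[1, 1]

    def test_all_zero_image_empty_mask(self):
        assert not binary_mask(np.zeros((5, 5)), 45).any()

    def test_empty_mask_stays_empty(self):
        assert not morphology_clean(np.zeros((10, 10), dtype=bool)).any()

    def test_solid_interior_survives(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[5:25, 5:25] = True
        out = morphology_clean(mask)
        assert out[10:20, 10:20].all()

    def test_isolated_pixel_removed(self):
        mask = np.zeros((11, 11), dtype=bool)
        mask[5, 5] = True
        assert not morphology_clean(mask).any()


class TestCropBox:
    def test_single_block(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:6, 3:7] = True
        assert find_crop_box(mask) == (2, 3, 5, 6)

    def test_empty_mask_full_frame(self):
        assert find_crop_box(np.zeros((8, 12), dtype=bool)) == (0, 0, 7, 11)

    def test_largest_component_wins(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[1:4, 1:4] = True  # area 9
        mask[10:12, 10:12] = True  # area 4
        assert find_crop_box(mask) == (1, 1, 3, 3)

    def test_box_contains_all_foreground_of_single_component(self):
        rng = np.random.default_rng(4)
        blob = np.zeros((30, 30), dtype=bool)
        r, c = rng.integers(5, 20, size=2)
        blob[r : r + 6, c : c + 4] = True
        r0, c0, r1, c1 = find_crop_box(blob)
        rows, cols = np.nonzero(blob)
        assert r0 <= rows.min() and rows.max() <= r1
        assert c0 <= cols.min() and cols.max() <= c1


class TestResize:
    def test_exact_target(self):
        out = resize(np.random.default_rng(0).uniform(size=(100, 100)), (200, 200))
        assert out.shape == (200, 200)

    def test_constant_preserved(self):
        out = resize(np.full((13, 7), 3.0), (20, 20))
        np.testing.assert_allclose(out, 3.0)

    def test_identity_resize(self):
        img = np.random.default_rng(1).uniform(size=(50, 50))
        np.testing.assert_array_equal(resize(img, (50, 50)), img)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            resize(np.empty((0, 5)), (10, 10))


class TestOneHot:
    @pytest.mark.parametrize("idx, pos", [(0, 0), (2, 2), (3, 3)])
    def test_encoding(self, idx, pos):
        v = one_hot(idx)
        assert v[pos] == 1.0 and v.sum() == 1.0 and len(v) == 4

    @pytest.mark.parametrize("idx", [-1, 4, 5])
    def test_out_of_range(self, idx):
        with pytest.raises(ValueError):
            one_hot(idx)


def _write_png(path, arr):
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)


class TestFullChain:
    def test_output_contract(self, tmp_path):
        img = np.full((120, 140), 10.0)
        img[30:90, 40:100] = 200.0
        path = tmp_path / "glioma" / "x.png"
        _write_png(path, img)
        ex = preprocess_image(path)
        assert ex.image.shape == (200, 200)
        assert 0.0 <= ex.image.min() and ex.image.max() <= 1.0
        np.testing.assert_array_equal(ex.label, [1, 0, 0, 0])
        assert ex.source_path == str(path)

    def test_all_black_image_full_frame_fallback(self, tmp_path):
        path = tmp_path / "notumor" / "black.png"
        _write_png(path, np.zeros((60, 80)))
        ex = preprocess_image(path)
        assert ex.image.shape == (200, 200)

    def test_crop_magnifies_off_centre_lesion(self):
        """After cropping to the bright region, the bright pixels occupy a
        larger fraction of the frame."""
        img = np.full((200, 200), 5.0)
        img[120:180, 130:190] = 220.0
        out, box = preprocess_array(img)
        frac_before = (img > 100).mean()
        frac_after = (out > 0.5).mean()
        assert frac_after > frac_before
        assert box[0] > 0 and box[1] > 0

    def test_crop_box_contains_cleaned_mask(self):
        rng = np.random.default_rng(9)
        img = np.full((150, 150), 8.0)
        img[40:110, 30:120] = rng.uniform(80, 255, size=(70, 90))
        cfg = PreprocessConfig()
        from btcnn.preprocess import clahe as _clahe, gaussian_blur as _blur

        enhanced = _clahe(_blur(img, cfg), cfg.clahe_clip, cfg.clahe_tiles)
        mask = morphology_clean(binary_mask(enhanced, cfg.threshold), cfg)
        r0, c0, r1, c1 = find_crop_box(mask)
        rows, cols = np.nonzero(mask)
        # the box bounds the largest component; here there is only one
        assert r0 <= rows.min() and rows.max() <= r1
        assert c0 <= cols.min() and cols.max() <= c1

    def test_deterministic(self, tmp_path):
        rng = np.random.default_rng(12)
        img = rng.uniform(0, 255, size=(90, 90))
        path = tmp_path / "pituitary" / "p.png"
        _write_png(path, img)
        a = preprocess_image(path)
        b = preprocess_image(path)
        np.testing.assert_array_equal(a.image, b.image)

    def test_unknown_class_directory_rejected(self, tmp_path):
        path = tmp_path / "mystery" / "x.png"
        _write_png(path, np.full((30, 30), 100.0))
        with pytest.raises(ValueError):
            preprocess_image(path)

    def test_unreadable_file_raises_oserror(self, tmp_path):
        path = tmp_path / "glioma" / "broken.png"
        path.parent.mkdir(parents=True)
        path.write_bytes(b"not a png")
        with pytest.raises(OSError):
            preprocess_image(path)


class TestLoadDataset:
    def test_stack_and_manifest(self, tmp_path):
        rng = np.random.default_rng(3)
        for cls in CLASSES:
            for i in range(2):
                _write_png(tmp_path / cls / f"{i}.png",
                           rng.uniform(0, 255, size=(64, 64)))
        X, Y, manifest = load_dataset(tmp_path)
        assert X.shape == (8, 200, 200)
        assert Y.shape == (8, 4)
        np.testing.assert_array_equal(Y.sum(axis=1), 1.0)
        assert sorted(manifest["class"].unique()) == sorted(CLASSES)
        assert {"path", "class_index", "row_min"} <= set(manifest.columns)

    def test_missing_directory(self, tmp_path):
        with pytest.raises(OSError):
            load_dataset(tmp_path / "nope")


def test_transformer_in_pipeline(tmp_path):
    from sklearn.pipeline import Pipeline

    rng = np.random.default_rng(5)
    X = rng.uniform(0, 255, size=(3, 80, 80))
    pipe = Pipeline([("prep", MRIPreprocessor())])
    out = pipe.fit_transform(X)
    assert out.shape == (3, 200, 200)
    assert out.max() <= 1.0
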