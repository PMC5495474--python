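"""Illumination-correction chain: each stage against an independent oracle."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from tubulequant import (
    GrayImage,
    PreprocessParams,
    close_mask,
    correct_illumination,
    downsample,
    extract_background,
    fit_illumination,
    local_entropy,
    preprocess_image,
    threshold_entropy,
)
from tubulequant.preprocess import IlluminationModel, _poly_exponents, disc_footprint
from tubulequant.types import BinaryMask, CannotFillError, ConditioningError


class TestDownsample:
    def test_dimension_arithmetic(self):
        img = GrayImage(np.zeros((80, 100)), pixel_size=2.0)
        out = downsample(img, 0.5)
        assert out.shape == (40, 50)
        assert out.pixel_size == 4.0

    def test_identity_factor(self, rng):
        img = GrayImage(rng.random((40, 40)))
        out = downsample(img, 1.0)
        assert out.shape == img.shape
        assert np.array_equal(out.pixels, img.pixels)

    def test_intensity_range_preserved(self, rng):
        img = GrayImage(rng.random((64, 64)))
        out = downsample(img, 0.25)
        assert out.pixels.min() >= img.pixels.min() - 1e-12
        assert out.pixels.max() <= img.pixels.max() + 1e-12

    @pytest.mark.parametrize("factor", [0.0, -0.5, 1.5])
    def test_invalid_factor(self, factor):
        with pytest.raises(ValueError):
            downsample(GrayImage(np.zeros((64, 64))), factor)


class TestLocalEntropy:
    def test_constant_image_has_zero_entropy(self):
        ent = local_entropy(GrayImage(np.full((32, 32), 0.5)), window=9)
        assert np.all(ent == 0.0)

    def test_checkerboard_matches_hand_histogram(self):
        # interior 9x9 window of a binary checkerboard holds 40 of one value
        # and 41 of the other
        board = np.indices((41, 41)).sum(axis=0) % 2
        ent = local_entropy(GrayImage(board.astype(float)), window=9)
        p = np.array([40 / 81, 41 / 81])
        expected = float(-(p * np.log2(p)).sum())
        interior = ent[4:-4, 4:-4]
        assert np.allclose(interior, expected, atol=1e-9)

    def test_uniform_noise_entropy_matches_sampling_oracle(self, rng):
        # Monte-Carlo oracle: expected entropy of a 256-bin histogram built
        # from 81 i.i.d. uniform samples
        samples = rng.integers(0, 256, size=(2000, 81))
        ents = []
        for row in samples:
            counts = np.bincount(row, minlength=256)
            p = counts[counts > 0] / 81
            ents.append(-(p * np.log2(p)).sum())
        expected = np.mean(ents)
        img = GrayImage(rng.random((64, 64)))
        ent = local_entropy(img, window=9)
        measured = ent[4:-4, 4:-4].mean()
        assert measured == pytest.approx(expected, rel=0.10)

    def test_bounds(self, rng):
        ent = local_entropy(GrayImage(rng.random((32, 32))), window=5)
        assert ent.min() >= 0.0
        assert ent.max() <= np.log2(256)

    @pytest.mark.parametrize("window", [2, 4, 1, 101])
    def test_invalid_window(self, window):
        with pytest.raises(ValueError):
            local_entropy(GrayImage(np.zeros((32, 32))), window=window)


class TestThresholdEntropy:
    def test_zero_threshold_keeps_all_textured(self, rng):
        ent = local_entropy(GrayImage(rng.random((32, 32))), window=5)
        mask = threshold_entropy(ent, 0.0)
        assert mask.pixels.all()

    def test_threshold_above_max_is_empty(self, rng):
        ent = local_entropy(GrayImage(rng.random((32, 32))), window=5)
        assert not threshold_entropy(ent, ent.max() + 1.0).pixels.any()

    def test_auto_threshold_separates_cells_from_background(self, small_scene):
        _spec, img, gt = small_scene
        ent = local_entropy(img, window=9)
        mask = close_mask(threshold_entropy(ent, "auto"), 8)
        cells = gt.label_mask.pixels != 0
        iou = (mask.pixels & cells).sum() / (mask.pixels | cells).sum()
        assert iou >= 0.8

    def test_constant_entropy_map_yields_empty_mask(self):
        assert not threshold_entropy(np.zeros((16, 16)), "auto").pixels.any()


def _oracle_close(m: np.ndarray, radius: int) -> np.ndarray:
    """Brute-force closing: explicit disc-offset enumeration on a padded
    frame (dilate = union of shifts, erode = intersection of shifts)."""
    offs = np.argwhere(disc_footprint(radius)) - radius
    pad = 2 * radius
    p = np.pad(m, pad)
    dil = np.zeros_like(p)
    for dy, dx in offs:
        dil |= np.roll(np.roll(p, dy, 0), dx, 1)
    ero = np.ones_like(p)
    for dy, dx in offs:
        ero &= np.roll(np.roll(dil, -dy, 0), -dx, 1)
    return ero[pad:-pad, pad:-pad]


class TestCloseMask:
    def test_fills_hole_inside_annulus(self):
        yy, xx = np.mgrid[:40, :40]
        r = np.hypot(yy - 20, xx - 20)
        annulus = (r >= 5) & (r <= 15)
        closed = close_mask(BinaryMask(annulus), 8)
        assert closed.pixels[20, 20]  # hole of radius 5 filled
        assert np.array_equal(closed.pixels, _oracle_close(annulus, 8))

    def test_all_true_unchanged(self):
        m = BinaryMask(np.ones((32, 32), bool))
        assert close_mask(m, 8).pixels.all()

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(arrays(bool, (24, 24), elements=st.booleans()))
    def test_idempotent(self, m):
        once = close_mask(BinaryMask(m), 3)
        twice = close_mask(once, 3)
        assert np.array_equal(once.pixels, twice.pixels)


class TestExtractBackground:
    def test_empty_mask_is_identity(self, rng):
        img = GrayImage(rng.random((24, 24)))
        out = extract_background(img, BinaryMask(np.zeros((24, 24), bool)))
        assert np.array_equal(out.pixels, img.pixels)

    def test_constant_image_stays_constant(self):
        img = GrayImage(np.full((24, 24), 0.3))
        mask = np.zeros((24, 24), bool)
        mask[8:16, 8:16] = True
        out = extract_background(img, BinaryMask(mask))
        assert np.allclose(out.pixels, 0.3)

    def test_filled_values_bounded_by_region_boundary(self):
        # linear gradient with one masked disk: discrete maximum principle
        yy, xx = np.mgrid[:40, :40]
        img = GrayImage(xx / 39.0)
        mask = np.hypot(yy - 20, xx - 20) <= 8
        out = extract_background(img, BinaryMask(mask))
        boundary = np.zeros_like(mask)
        for dy, dx in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            boundary |= np.roll(np.roll(mask, dy, 0), dx, 1)
        boundary &= ~mask
        lo, hi = img.pixels[boundary].min(), img.pixels[boundary].max()
        assert out.pixels[mask].min() >= lo - 1e-9
        assert out.pixels[mask].max() <= hi + 1e-9
        assert np.array_equal(out.pixels[~mask], img.pixels[~mask])

    def test_full_mask_cannot_fill(self):
        with pytest.raises(CannotFillError):
            extract_background(
                GrayImage(np.zeros((16, 16))), BinaryMask(np.ones((16, 16), bool))
            )


class TestIlluminationFit:
    def test_polynomial_surface_recovered_exactly(self, rng):
        exps = _poly_exponents(4)
        coeffs = rng.normal(0, 0.1, len(exps))
        model_true = IlluminationModel(coeffs, exps, 4, 0.0)
        img = GrayImage(model_true.evaluate((48, 64)) + 0.5)
        fitted = fit_illumination(img, degree=4)
        assert fitted.residual_rms < 1e-6
        surf = fitted.evaluate((48, 64))
        assert np.allclose(surf, img.pixels, atol=1e-6)
        # constant term absorbs the +0.5; all others recovered exactly
        rec = fitted.coeff_dict()
        for (i, j), c in zip(exps, coeffs):
            target = c + 0.5 if (i, j) == (0, 0) else c
            assert rec[(i, j)] == pytest.approx(target, abs=1e-6)

    def test_constant_image_fits_constant(self):
        fitted = fit_illumination(GrayImage(np.full((32, 32), 0.7)), degree=4)
        assert np.allclose(fitted.evaluate((32, 32)), 0.7, atol=1e-9)

    def test_degenerate_geometry_raises(self):
        with pytest.raises(ConditioningError):
            fit_illumination(GrayImage(np.zeros((1, 40))), degree=4)


class TestCorrectIllumination:
    def test_constant_surface_is_identity(self, rng):
        img = GrayImage(rng.random((32, 32)))
        model = fit_illumination(GrayImage(np.full((32, 32), 0.4)), degree=0)
        out = correct_illumination(img, model)
        assert np.allclose(out.pixels, img.pixels, atol=1e-12)

    def test_mean_preserved(self, rng):
        img = GrayImage(rng.random((48, 48)))
        model = fit_illumination(img, degree=4)
        out = correct_illumination(img, model)
        assert abs(out.pixels.mean() - img.pixels.mean()) < 1e-9

    def test_foreground_contrast_sign_preserved(self, clean_scene):
        # cells darker than their surroundings stay darker after correction
        _spec, img, gt = clean_scene
        res = preprocess_image(img, PreprocessParams(downsample_factor=1.0))
        cells = gt.label_mask.pixels != 0
        bg_med_in = np.median(img.pixels[~cells])
        bg_med_out = np.median(res.corrected.pixels[~cells])
        assert np.all((img.pixels[cells] - bg_med_in < 0)
                      == (res.corrected.pixels[cells] - bg_med_out < 0))


class TestPreprocessImage:
    def test_uniform_image_unchanged(self):
        img = GrayImage(np.full((96, 96), 0.5))
        res = preprocess_image(img, PreprocessParams(downsample_factor=1.0))
        assert np.allclose(res.corrected.pixels, 0.5, atol=1e-6)

    def test_deterministic(self, small_scene):
        _spec, img, _gt = small_scene
        p = PreprocessParams(downsample_factor=0.5)
        r1 = preprocess_image(img, p)
        r2 = preprocess_image(img, p)
        assert np.array_equal(r1.corrected.pixels, r2.corrected.pixels)

    def test_background_flatness_improves(self):
        # noiseless textured scene: the residual spread reflects only the
        # quality of the fitted surface, not the sensor-noise floor
        from tubulequant import SceneSpec, generate_scene

        spec = SceneSpec(width_px=256, height_px=256, n_spheroids=3,
                         n_tubule_nodes=8, noise_sd=0.0, seed=7)
        img, gt = generate_scene(spec)
        res = preprocess_image(img, PreprocessParams(downsample_factor=1.0))
        bg = gt.label_mask.pixels == 0
        sd_in = img.pixels[bg].std()
        sd_out = res.corrected.pixels[bg].std()
        assert sd_out / sd_in < 0.2
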