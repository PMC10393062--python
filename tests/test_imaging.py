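"""Image substrate: thresholds vs brute-force oracles, filters, corrections."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from optorecruit.imaging import (
    ImageStack,
    background_correct,
    bleach_correct_exponential,
    gaussian_blur,
    load_rois,
    make_membrane_cytosol_rois,
    read_stack,
    save_rois,
    threshold_huang,
    threshold_isodata,
    threshold_otsu,
    write_stack,
)
from optorecruit.scenes import SceneConfig, simulate_recruitment_stack

from .oracles import huang_bruteforce, isodata_bruteforce, otsu_bruteforce


def _random_images(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        kind = i % 4
        if kind == 0:  # bimodal gaussian mixture
            w = rng.uniform(0.1, 0.9)
            n0 = int(400 * w)
            img = np.concatenate(
                [
                    rng.normal(rng.uniform(20, 80), rng.uniform(2, 15), n0),
                    rng.normal(rng.uniform(120, 240), rng.uniform(2, 25), 400 - n0),
                ]
            ).reshape(20, 20)
        elif kind == 1:  # uniform noise
            img = rng.uniform(0, 255, size=(20, 20))
        elif kind == 2:  # structured: disk on background + noise
            yy, xx = np.mgrid[-10:10, -10:10]
            img = np.where(yy**2 + xx**2 < rng.integers(9, 64), 200.0, 30.0)
            img = img + rng.normal(0, 5, img.shape)
        else:  # skewed exponential
            img = rng.exponential(rng.uniform(10, 60), size=(20, 20))
        out.append(img)
    return out


class TestThresholdOracleEquivalence:
    """Each thresholder must equal its exhaustive/iterative oracle exactly."""

    @pytest.mark.parametrize(
        "impl,oracle",
        [
            (threshold_huang, huang_bruteforce),
            (threshold_otsu, otsu_bruteforce),
            (threshold_isodata, isodata_bruteforce),
        ],
        ids=["huang", "otsu", "isodata"],
    )
    def test_matches_bruteforce_on_many_images(self, impl, oracle):
        for img in _random_images(40, seed=7):
            assert impl(img) == oracle(img)

    @pytest.mark.parametrize(
        "impl", [threshold_huang, threshold_otsu, threshold_isodata]
    )
    def test_constant_image_raises(self, impl):
        with pytest.raises(ValueError):
            impl(np.full((16, 16), 42.0))


def test_huang_two_valued_separates_minority_class():
    rng = np.random.default_rng(1)
    img = rng.permutation(np.array([50.0] * 900 + [200.0] * 100)).reshape(25, 40)
    thr = threshold_huang(img)
    assert 50.0 < thr < 200.0
    assert int((img > thr).sum()) == 100


def test_otsu_balanced_bimodal_thresholds_at_midpoint():
    img = np.array([10.0] * 500 + [250.0] * 500).reshape(25, 40)
    assert threshold_otsu(img) == pytest.approx(130.0, abs=(250 - 10) / 256)


def test_isodata_symmetric_bimodal_midpoint():
    img = np.array([40.0] * 300 + [200.0] * 300).reshape(20, 30)
    assert threshold_isodata(img) == pytest.approx(120.0, abs=(200 - 40) / 256)


class TestGaussianBlur:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.5)
        assert np.allclose(gaussian_blur(img, 2.0), img)

    def test_sigma_zero_is_identity(self, rng):
        img = rng.normal(size=(16, 16))
        assert np.array_equal(gaussian_blur(img, 0.0), img)

    def test_intensity_conserved_for_interior_spot(self):
        img = np.zeros((101, 101))
        img[50, 50] = 1000.0
        out = gaussian_blur(img, 3.0)
        assert out.sum() == pytest.approx(1000.0, rel=1e-6)

    def test_impulse_response_is_analytic_gaussian(self):
        sigma = 2.0
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        out = gaussian_blur(img, sigma)
        yy, xx = np.mgrid[-20:21, -20:21]
        analytic = np.exp(-(yy**2 + xx**2) / (2 * sigma**2))
        analytic /= analytic.sum()
        # discretization error: finite kernel truncation and discrete
        # renormalization leave a ~1e-6 residual
        assert np.abs(out - analytic).max() < 1e-5

    def test_input_not_modified(self, rng):
        img = rng.normal(size=(8, 8))
        before = img.copy()
        gaussian_blur(img, 1.0)
        assert np.array_equal(img, before)


class TestBackgroundCorrect:
    def _stack(self, offset):
        data = np.zeros((3, 1, 10, 10))
        data[:, :, 4:6, 4:6] = 100.0
        data += np.asarray(offset).reshape(-1, 1, 1, 1)
        return ImageStack(data=data)

    def test_constant_offset_removed_exactly(self):
        stack = self._stack([50.0, 50.0, 50.0])
        bg = np.ones((10, 10), dtype=bool)
        bg[4:6, 4:6] = False
        out = background_correct(stack, bg)
        assert np.allclose(out.data[:, :, 0, 0], 0.0)
        assert np.allclose(out.data[:, :, 4:6, 4:6], 100.0)

    def test_frame_varying_offset_removed_per_frame(self):
        offsets = [10.0, 30.0, 70.0]
        stack = self._stack(offsets)
        bg = np.ones((10, 10), dtype=bool)
        bg[4:6, 4:6] = False
        out = background_correct(stack, bg)
        assert np.allclose(out.data[:, :, 4:6, 4:6], 100.0)

    def test_zero_background_unchanged_and_idempotent(self):
        stack = self._stack([0.0, 0.0, 0.0])
        bg = np.ones((10, 10), dtype=bool)
        bg[4:6, 4:6] = False
        once = background_correct(stack, bg)
        twice = background_correct(once, bg)
        assert np.array_equal(once.data, stack.data.astype(float))
        assert np.array_equal(twice.data, once.data)


class TestBleachCorrect:
    def test_exponential_decay_flattened(self):
        t = np.arange(20) * 2.0
        data = np.ones((20, 1, 8, 8)) * np.exp(-0.05 * t)[:, None, None, None] * 500
        stack = ImageStack(data=data, frame_interval=2.0)
        out, ok = bleach_correct_exponential(stack, 0)
        assert ok
        means = out.data[:, 0].mean(axis=(1, 2))
        assert np.abs(means / means[0] - 1.0).max() < 1e-6

    def test_constant_stack_unchanged(self):
        data = np.full((10, 1, 8, 8), 200.0)
        stack = ImageStack(data=data)
        out, ok = bleach_correct_exponential(stack, 0)
        assert np.allclose(out.data, data)

    def test_increasing_series_flagged_and_unchanged(self):
        t = np.arange(15)
        data = np.ones((15, 1, 4, 4)) * (100 + 10 * t)[:, None, None, None]
        stack = ImageStack(data=data)
        with pytest.warns(UserWarning):
            out, ok = bleach_correct_exponential(stack, 0)
        assert not ok
        assert np.array_equal(out.data, data.astype(float))


class TestStackIO:
    def test_round_trip_bit_identical(self, tmp_path, recruitment_scene):
        _, stack, _ = recruitment_scene
        p = tmp_path / "scene.tif"
        write_stack(stack, p)
        back = read_stack(p)
        assert np.array_equal(back.data, stack.data)
        assert back.frame_interval == stack.frame_interval
        assert back.channel_roles == stack.channel_roles

    def test_single_frame_promoted(self, tmp_path):
        import tifffile

        p = tmp_path / "one.tif"
        tifffile.imwrite(p, np.arange(12, dtype=np.uint16).reshape(3, 4))
        stack = read_stack(p)
        assert stack.shape == (1, 1, 3, 4)

    def test_five_dim_rejected(self, tmp_path):
        import tifffile

        p = tmp_path / "bad.tif"
        tifffile.imwrite(p, np.zeros((2, 2, 2, 2, 2), dtype=np.uint8))
        with pytest.raises(ValueError):
            read_stack(p)


class TestMembraneCytosolRois:
    def test_recovers_known_membrane_band(self, recruitment_scene):
        _, stack, truth = recruitment_scene
        rois = make_membrane_cytosol_rois(stack.channel("bait")[0], band_px=3)
        overlap = (rois["membrane"] & truth.membrane_mask).sum()
        assert overlap / truth.membrane_mask.sum() >= 0.9

    def test_membrane_cytosol_disjoint(self, recruitment_scene):
        _, stack, _ = recruitment_scene
        rois = make_membrane_cytosol_rois(stack.channel("bait")[0])
        assert not np.any(rois["membrane"] & rois["cytosol"])

    def test_roi_json_round_trip(self, tmp_path, recruitment_scene):
        _, stack, _ = recruitment_scene
        rois = make_membrane_cytosol_rois(stack.channel("bait")[0])
        p = tmp_path / "rois.json"
        save_rois(rois, p)
        back = load_rois(p)
        for name, mask in rois.masks.items():
            assert np.array_equal(back[name], mask)

    def test_tiny_cell_fully_eroded_raises(self):
        img = np.zeros((32, 32))
        img[15:18, 15:18] = 100.0
        with pytest.raises(ValueError):
            make_membrane_cytosol_rois(img, band_px=3, erode_px=2)


@settings(max_examples=25, deadline=None, database=None)
@given(
    img=hnp.arrays(
        dtype=np.float64,
        shape=st.tuples(st.integers(4, 12), st.integers(4, 12)),
        elements=st.floats(0, 255, allow_nan=False),
    )
)
def test_threshold_oracle_property(img):
    """Thresholders agree with their oracles on arbitrary small images."""
    if img.min() == img.max():
        return
    assert threshold_otsu(img) == otsu_bruteforce(img)
    assert threshold_isodata(img) == isodata_bruteforce(img)
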