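"""Pre-processing chain: calibration, cropping, smoothing, decimation,
normalization, absorbance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsibrain import (
    HSCube,
    ReferenceFrames,
    calibrate,
    crop_extreme_bands,
    decimate_spectra,
    normalize_minmax,
    smooth_spectra,
    to_absorbance,
)
from hsibrain.core import default_wavelengths
from hsibrain.preprocess import (
    CalibrationError,
    StageError,
    decimation_indices,
    moving_average,
    renormalize,
)

from conftest import make_cube


def _raw(data):
    return HSCube(
        data=data, wavelengths=default_wavelengths(data.shape[2]), stage="raw"
    )


class TestCalibrate:
    def test_white_input_gives_unit_reflectance(self):
        shape = (3, 3, 826)
        white = np.full(shape, 0.9)
        dark = np.full(shape, 0.1)
        out = calibrate(_raw(white.copy()), ReferenceFrames(white, dark))
        np.testing.assert_allclose(out.data, 1.0)
        assert out.stage == "calibrated"

    def test_dark_input_gives_zero_reflectance(self):
        shape = (3, 3, 826)
        white, dark = np.full(shape, 0.9), np.full(shape, 0.1)
        out = calibrate(_raw(dark.copy()), ReferenceFrames(white, dark))
        np.testing.assert_allclose(out.data, 0.0)

    def test_direct_arithmetic(self):
        shape = (1, 1, 826)
        out = calibrate(
            _raw(np.full(shape, 5.0)),
            ReferenceFrames(np.full(shape, 9.0), np.full(shape, 1.0)),
        )
        np.testing.assert_allclose(out.data, 0.5)

    def test_geometry_mismatch_rejected(self):
        raw = _raw(np.zeros((2, 2, 826)))
        with pytest.raises(ValueError, match="geometry"):
            calibrate(raw, ReferenceFrames(np.ones((3, 3, 826)), np.zeros((3, 3, 826))))

    def test_widespread_invalid_white_is_calibration_error(self):
        shape = (2, 2, 826)
        white = np.zeros(shape)  # white <= dark everywhere
        with pytest.raises(CalibrationError):
            calibrate(_raw(np.ones(shape)), ReferenceFrames(white, np.ones(shape)))

    def test_stage_enforced(self):
        cube = make_cube(np.random.default_rng(0).random((2, 2, 10)))
        with pytest.raises(StageError):
            calibrate(cube, ReferenceFrames(np.ones((2, 2, 10)), np.zeros((2, 2, 10))))


class TestCrop:
    def test_operating_band_keeps_645_of_826(self):
        cube = _raw(np.ones((1, 1, 826))).replace(stage="calibrated")
        out = crop_extreme_bands(cube)
        assert out.bands == 645
        assert out.wavelengths[0] >= 440.5 and out.wavelengths[-1] <= 909.1
        assert out.stage == "cropped"

    def test_full_band_keeps_everything(self):
        cube = _raw(np.ones((1, 1, 826))).replace(stage="calibrated")
        assert crop_extreme_bands(cube, (400, 1000)).bands == 826

    def test_empty_window_rejected(self):
        cube = _raw(np.ones((1, 1, 826))).replace(stage="calibrated")
        with pytest.raises(ValueError, match="no channels"):
            crop_extreme_bands(cube, (909.2, 909.5))


class TestSmooth:
    def test_constant_spectrum_unchanged(self):
        cube = make_cube(np.full((2, 2, 9), 3.25), stage="cropped")
        np.testing.assert_allclose(smooth_spectra(cube, 5).data, 3.25)

    def test_impulse_centre_value(self):
        cube = make_cube(np.array([[[0, 0, 5, 0, 0]]], dtype=float), stage="cropped")
        out = smooth_spectra(cube, 5)
        assert out.data[0, 0, 2] == pytest.approx(1.0)

    def test_matches_bruteforce_truncated_window_oracle(self):
        rng = np.random.default_rng(6)
        data = rng.random((3, 4, 17))
        window = 5
        out = smooth_spectra(make_cube(data, stage="cropped"), window).data

        half = window // 2
        expected = np.empty_like(data)
        for r in range(3):
            for c in range(4):
                for b in range(17):
                    lo, hi = max(0, b - half), min(17, b + half + 1)
                    expected[r, c, b] = data[r, c, lo:hi].mean()
        np.testing.assert_allclose(out, expected)

    def test_linear_ramp_interior_unchanged(self):
        ramp = np.arange(20.0)[None, None, :]
        out = smooth_spectra(make_cube(ramp, stage="cropped"), 5).data[0, 0]
        np.testing.assert_allclose(out[2:-2], ramp[0, 0, 2:-2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_never_increases_spectral_range(self, seed):
        data = np.random.default_rng(seed).random((2, 2, 15))
        out = smooth_spectra(make_cube(data, stage="cropped"), 5).data
        assert (out.max(axis=2) - out.min(axis=2) <=
                data.max(axis=2) - data.min(axis=2) + 1e-12).all()

    def test_window_larger_than_bands_rejected(self):
        with pytest.raises(ValueError):
            smooth_spectra(make_cube(np.ones((1, 1, 3)), stage="cropped"), 5)


class TestDecimate:
    def test_cropped_grid_reduces_to_128(self):
        wl = default_wavelengths()
        keep = (wl >= 440.5) & (wl <= 909.1)
        cube = HSCube(np.ones((1, 1, keep.sum())), wl[keep], stage="smoothed")
        out = decimate_spectra(cube, 128)
        assert out.bands == 128
        assert out.stage == "decimated"
        # stride-5 on the 0.727-nm grid: mean spacing ~3.64 nm
        assert np.diff(out.wavelengths).mean() == pytest.approx(3.636, abs=0.05)

    def test_target_equals_bands_is_identity(self):
        cube = make_cube(np.random.default_rng(7).random((2, 2, 12)), stage="smoothed")
        out = decimate_spectra(cube, 12)
        np.testing.assert_array_equal(out.data, cube.data)

    def test_target_above_bands_rejected(self):
        with pytest.raises(ValueError):
            decimation_indices(10, 11)


class TestNormalize:
    def test_every_pixel_spans_unit_interval(self):
        rng = np.random.default_rng(8)
        cube = make_cube(rng.random((4, 4, 16)) * 5 + 1, stage="decimated")
        out = normalize_minmax(cube)
        np.testing.assert_allclose(out.data.min(axis=2), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data.max(axis=2), 1.0, atol=1e-12)
        assert out.stage == "normalized"

    def test_constant_pixel_flagged_degenerate(self):
        data = np.ones((2, 2, 8))
        data[1, 1] = np.linspace(0, 1, 8)
        out = normalize_minmax(make_cube(data, stage="decimated"))
        assert out.degenerate[0, 0] and not out.degenerate[1, 1]
        np.testing.assert_array_equal(out.data[0, 0], 0.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.random((3, 3, 10))
        a = normalize_minmax(make_cube(s, stage="decimated")).data
        b = normalize_minmax(make_cube(2.7 * s + 0.4, stage="decimated")).data
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(10)
        once = normalize_minmax(make_cube(rng.random((2, 2, 9)), stage="decimated"))
        twice = renormalize(once)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-12)


class TestAbsorbance:
    @pytest.mark.parametrize(
        "r, a", [(1.0, 0.0), (0.1, 1.0), (0.5, 0.30103)]
    )
    def test_log10_convention(self, r, a):
        assert to_absorbance(np.array([r]))[0] == pytest.approx(a, abs=1e-5)

    def test_all_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            to_absorbance(np.array([0.0, -1.0]))


def test_pipeline_order_enforced():
    """Each stage refuses input that skipped a prior stage."""
    normalized = make_cube(np.random.default_rng(11).random((2, 2, 10)))
    with pytest.raises(StageError):
        crop_extreme_bands(normalized, (440, 910))
    with pytest.raises(StageError):
        smooth_spectra(normalized, 3)
    with pytest.raises(StageError):
        decimate_spectra(normalized, 5)
    with pytest.raises(StageError):
        normalize_minmax(normalized)


def test_wavelengths_strictly_increasing_through_chain(small_normalized):
    cube, _ = small_normalized
    assert (np.diff(cube.wavelengths) > 0).all()
    assert cube.bands == 128
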