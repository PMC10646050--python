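"""Radiometric calibration and spectral pre-processing chain.

The chain is fixed: calibrate -> crop extreme bands -> moving-average smooth
-> decimate -> per-pixel min-max normalize. Each stage stamps the cube's
``stage`` field and refuses out-of-order input, so a normalized cube is
guaranteed to have passed every prior step.

Calibration converts raw sensor counts RI to reflectance CI using white (WI)
and dark (DI) reference frames::

    CI = (RI - DI) / (WI - DI)

The extreme sensor channels are dropped because the camera is noisy there,
leaving 645 channels over 440.5-909.1 nm on the uniform 826-band grid;
decimation then subsamples to 128 channels (mean spacing ~3.6 nm). Spectra
can also be converted to absorbance A = -log10(R) for comparison against
chromophore extinction curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .core import HSCube, ReferenceFrames


class CalibrationError(ValueError):
    """White reference does not exceed dark over too many elements."""


class StageError(ValueError):
    """Pre-processing stage applied out of order."""


@dataclass
class PreprocessConfig:
    """Knobs of the pre-processing chain.

    smoothing_window is in spectral samples (odd); operating_band in nm;
    target_bands is the post-decimation channel count.
    """

    smoothing_window: int = 5
    operating_band: tuple[float, float] = (440.5, 909.1)
    target_bands: int = 128
    max_invalid_fraction: float = 0.05  # tolerated WI<=DI elements
    absorbance_floor: float = 1e-6

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and >= 1")
        low, high = self.operating_band
        if not low < high:
            raise ValueError("operating_band low must be < high")
        if self.target_bands < 2:
            raise ValueError("target_bands must be >= 2")


def _require_stage(cube: HSCube, expected: str) -> None:
    if cube.stage != expected:
        raise StageError(f"expected a {expected!r} cube, got {cube.stage!r}")


def calibrate(
    raw: HSCube, refs: ReferenceFrames, max_invalid_fraction: float = 0.05
) -> HSCube:
    """Convert raw counts to reflectance with white/dark references.

    Elements where WI <= DI have no defined reflectance; they are set to 0
    and tolerated up to ``max_invalid_fraction`` of all elements. Negative
    reflectance from sensor noise is clipped to 0.
    """
    _require_stage(raw, "raw")
    if refs.white.shape != raw.shape:
        raise ValueError(
            f"reference geometry {refs.white.shape} != cube {raw.shape}"
        )
    denom = refs.white - refs.dark
    invalid = denom <= 0
    frac = invalid.mean()
    if frac > max_invalid_fraction:
        raise CalibrationError(
            f"white <= dark on {frac:.1%} of elements "
            f"(tolerance {max_invalid_fraction:.1%})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = (raw.data - refs.dark) / denom
    ci = np.where(invalid, 0.0, ci)
    ci = np.clip(ci, 0.0, None)
    return raw.replace(data=ci, stage="calibrated")


def crop_extreme_bands(
    cube: HSCube, band: tuple[float, float] = (440.5, 909.1)
) -> HSCube:
    """Keep only channels whose centre wavelength lies in ``band`` (nm)."""
    _require_stage(cube, "calibrated")
    low, high = band
    keep = (cube.wavelengths >= low) & (cube.wavelengths <= high)
    if not keep.any():
        raise ValueError(f"no channels inside operating band {band}")
    return cube.replace(
        data=cube.data[:, :, keep],
        wavelengths=cube.wavelengths[keep],
        stage="cropped",
    )


def smooth_spectra(cube: HSCube, window: int = 5) -> HSCube:
    """Centred moving-average along the spectral axis.

    Edge samples use truncated windows so the band count is preserved.
    """
    _require_stage(cube, "cropped")
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if window > cube.bands:
        raise ValueError(f"window {window} exceeds band count {cube.bands}")
    smoothed = moving_average(cube.data, window, axis=2)
    return cube.replace(data=smoothed, stage="smoothed")


def moving_average(values: np.ndarray, window: int, axis: int = -1) -> np.ndarray:
    """Length-preserving moving mean with truncated (shrunken) edge windows."""
    values = np.asarray(values, dtype=float)
    sums = uniform_filter1d(values, size=window, axis=axis, mode="constant") * window
    ones = np.ones(values.shape[axis])
    counts = uniform_filter1d(ones, size=window, mode="constant") * window
    shape = [1] * values.ndim
    shape[axis] = -1
    return sums / counts.reshape(shape)


def decimation_indices(bands: int, target: int) -> np.ndarray:
    """Uniform-stride channel selection: stride = bands // target, start 0.

    On the 645-channel cropped grid with target 128 this is a stride of 5;
    the 129th stride position is dropped to hit the target exactly.
    """
    if target > bands:
        raise ValueError(f"target {target} exceeds band count {bands}")
    stride = max(1, bands // target)
    idx = np.arange(0, bands, stride)[:target]
    if len(idx) < target:
        idx = np.linspace(0, bands - 1, target).round().astype(int)
    return idx


def decimate_spectra(cube: HSCube, target: int = 128) -> HSCube:
    """Subsample spectral channels to ``target`` bands."""
    _require_stage(cube, "smoothed")
    idx = decimation_indices(cube.bands, target)
    return cube.replace(
        data=cube.data[:, :, idx],
        wavelengths=cube.wavelengths[idx],
        stage="decimated",
    )


def normalize_minmax(cube: HSCube) -> HSCube:
    """Scale every pixel spectrum independently to [0, 1].

    Constant spectra cannot be scaled; they map to all-zeros and are flagged
    in ``cube.degenerate``. Idempotent.
    """
    _require_stage(cube, "decimated")
    lo = cube.data.min(axis=2, keepdims=True)
    hi = cube.data.max(axis=2, keepdims=True)
    span = hi - lo
    degenerate = span[:, :, 0] <= 0
    safe = np.where(span > 0, span, 1.0)
    out = (cube.data - lo) / safe
    out[degenerate] = 0.0
    return cube.replace(data=out, stage="normalized", degenerate=degenerate)


def renormalize(cube: HSCube) -> HSCube:
    """Min-max normalize a cube that is already at the normalized stage."""
    return normalize_minmax(cube.replace(stage="decimated"))


def to_absorbance(
    reflectance: np.ndarray, floor: float = 1e-6
) -> np.ndarray:
    """Absorbance A = -log10(R); reflectance <= 0 is clipped to ``floor``."""
    r = np.asarray(reflectance, dtype=float)
    if np.all(r <= 0):
        raise ValueError("all reflectance values are non-positive")
    return -np.log10(np.clip(r, floor, None))


def preprocess_cube(
    raw: HSCube, refs: ReferenceFrames, cfg: PreprocessConfig | None = None
) -> HSCube:
    """Run the full chain raw -> normalized."""
    cfg = cfg or PreprocessConfig()
    cube = calibrate(raw, refs, cfg.max_invalid_fraction)
    cube = crop_extreme_bands(cube, cfg.operating_band)
    cube = smooth_spectra(cube, cfg.smoothing_window)
    cube = decimate_spectra(cube, cfg.target_bands)
    return normalize_minmax(cube)
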