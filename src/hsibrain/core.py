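"""Core in-memory containers for intraoperative hyperspectral (HS) data.

An HS cube is a rows x cols x bands reflectance raster in which every pixel
carries a full spectrum; the acquisition system this package models is a
visible/near-infrared pushbroom camera delivering 826 spectral channels over
400-1000 nm. Label maps carry the four-class surgical annotation scheme:
normal tissue (NT), tumour tissue (TT), blood vessel (BV) and background (BG),
with unlabelled pixels set to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Raw sensor geometry: 826 channels uniformly covering 400-1000 nm.
RAW_BANDS = 826
WAVELENGTH_MIN_NM = 400.0
WAVELENGTH_MAX_NM = 1000.0

# Label codes. The clinical annotation convention colours NT green, TT red,
# BV blue and BG black; unlabelled pixels are white.
UNLABELLED = 0
NT = 1
TT = 2
BV = 3
BG = 4

CLASS_CODES = (NT, TT, BV, BG)
CLASS_NAMES = {UNLABELLED: "unlabelled", NT: "NT", TT: "TT", BV: "BV", BG: "BG"}

# colour (R, G, B) -> label code, used by the PNG label-map reader/writer.
DEFAULT_PALETTE = {
    (255, 0, 0): TT,
    (0, 255, 0): NT,
    (0, 0, 255): BV,
    (0, 0, 0): BG,
    (255, 255, 255): UNLABELLED,
}

# Pipeline stages in their mandatory order.
STAGES = ("raw", "calibrated", "cropped", "smoothed", "decimated", "normalized")


def default_wavelengths(bands: int = RAW_BANDS) -> np.ndarray:
    """Band-centre wavelengths: uniform grid over [400, 1000] nm."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, bands)


class FormatError(ValueError):
    """Malformed on-disk file (missing header fields, bad palette...)."""


class CorruptionError(ValueError):
    """Header metadata inconsistent with raster payload."""


@dataclass
class HSCube:
    """Hyperspectral cube: ``data[row, col, band]`` with band wavelengths.

    Parameters
    ----------
    data : ndarray, shape (rows, cols, bands)
        Non-negative reflectance (or raw-count) raster.
    wavelengths : ndarray, shape (bands,)
        Strictly increasing band-centre wavelengths in nm.
    stage : str
        Position in the pre-processing chain; ``raw`` cubes must carry the
        full 826-channel sensor output.
    degenerate : ndarray of bool, shape (rows, cols), optional
        Pixels whose spectrum could not be processed meaningfully (e.g.
        constant spectra hit by min-max normalization).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    stage: str = "raw"
    patient_id: str = ""
    capture_id: str = ""
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.bands:
            raise CorruptionError(
                f"wavelength vector length {self.wavelengths.size} does not "
                f"match band count {self.bands}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.stage == "raw" and self.bands != RAW_BANDS:
            raise ValueError(
                f"raw cubes must have {RAW_BANDS} bands, got {self.bands}"
            )

    @property
    def rows(self) -> int:
        return self.data.shape[0]

    @property
    def cols(self) -> int:
        return self.data.shape[1]

    @property
    def bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def pixels(self) -> np.ndarray:
        """Flatten to an (rows*cols, bands) matrix (row-major)."""
        return self.data.reshape(-1, self.bands)

    def replace(self, **kwargs) -> "HSCube":
        """Return a copy with some fields replaced."""
        fields_ = dict(
            data=self.data,
            wavelengths=self.wavelengths,
            stage=self.stage,
            patient_id=self.patient_id,
            capture_id=self.capture_id,
            degenerate=self.degenerate,
        )
        fields_.update(kwargs)
        return HSCube(**fields_)


@dataclass
class ReferenceFrames:
    """White and dark reference frames for radiometric calibration.

    The white frame records the sensor response to a standard tile reflecting
    ~99% of incident light under the surgical illumination; the dark frame is
    captured with the shutter closed and measures dark current.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white)
        self.dark = np.asarray(self.dark)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark frames must share geometry")


@dataclass
class LabelMap:
    """Per-pixel class raster using the codes in :data:`CLASS_CODES`."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        bad = set(np.unique(self.labels)) - {UNLABELLED, *CLASS_CODES}
        if bad:
            raise ValueError(f"unknown label codes: {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class PixelDataset:
    """Flattened labelled spectra with per-pixel patient provenance."""

    spectra: np.ndarray  # (n_pixels, bands)
    labels: np.ndarray  # class codes, (n_pixels,)
    patient_ids: np.ndarray  # (n_pixels,) strings

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.patient_ids = np.asarray(self.patient_ids)
        n = len(self.spectra)
        if not (len(self.labels) == len(self.patient_ids) == n):
            raise ValueError("spectra, labels and patient_ids must align")

    def __len__(self) -> int:
        return len(self.spectra)

    def subset(self, mask: np.ndarray) -> "PixelDataset":
        return PixelDataset(
            self.spectra[mask], self.labels[mask], self.patient_ids[mask]
        )

    def class_counts(self) -> dict[int, int]:
        codes, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))

    @staticmethod
    def concatenate(parts: list["PixelDataset"]) -> "PixelDataset":
        return PixelDataset(
            np.concatenate([p.spectra for p in parts]),
            np.concatenate([p.labels for p in parts]),
            np.concatenate([p.patient_ids for p in parts]),
        )


def labelled_pixels(cube: HSCube, labels: LabelMap) -> PixelDataset:
    """Extract the labelled pixels of a cube as a :class:`PixelDataset`."""
    if labels.shape != (cube.rows, cube.cols):
        raise ValueError("label map geometry does not match cube")
    mask = labels.labels.reshape(-1) > 0
    spectra = cube.pixels()[mask]
    codes = labels.labels.reshape(-1)[mask]
    pids = np.full(mask.sum(), cube.patient_id, dtype=object)
    return PixelDataset(spectra, codes, pids)
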