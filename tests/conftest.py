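"""Shared fixtures: small phantom scenes reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from hsibrain import (
    HSCube,
    PhantomConfig,
    PixelDataset,
    generate_scene,
    labelled_pixels,
    phantom_captures,
    preprocess_cube,
)
from hsibrain.core import default_wavelengths


@pytest.fixture(scope="session")
def small_scene():
    """One 64x64 noisy phantom capture: (raw cube, refs, truth)."""
    return generate_scene(PhantomConfig(rows=64, cols=64, bg_margin=10, seed=7))


@pytest.fixture(scope="session")
def small_normalized(small_scene):
    raw, refs, truth = small_scene
    return preprocess_cube(raw, refs), truth


@pytest.fixture(scope="session")
def phantom_pixels(small_normalized) -> PixelDataset:
    cube, truth = small_normalized
    return labelled_pixels(cube, truth.labels)


@pytest.fixture(scope="session")
def recovery_captures():
    """Four small synthetic patients for classifier-recovery experiments."""
    return phantom_captures(n_patients=4, seed=11, rows=96, cols=96, bg_margin=12)


def make_cube(
    data: np.ndarray, stage: str = "normalized", wavelengths=None
) -> HSCube:
    """Build a cube around an arbitrary array, defaulting the wavelength grid."""
    data = np.asarray(data, dtype=float)
    if wavelengths is None:
        wavelengths = np.linspace(440.0, 910.0, data.shape[2])
    return HSCube(data=data, wavelengths=wavelengths, stage=stage)
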