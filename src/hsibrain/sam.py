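"""Spectral Angle Mapper (SAM) similarity and semi-automatic labelling.

SAM measures the angle between two spectra seen as vectors, so it is
invariant to per-pixel illumination scale — the property that makes it the
standard similarity for growing high-confidence label regions from an
operator-chosen seed pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CLASS_CODES, HSCube, LabelMap


def sam_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Spectral angle arccos(<a,b> / (|a||b|)) in radians, in [0, pi]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("SAM undefined for a zero spectrum")
    cos = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.arccos(cos))


def sam_angles(spectra: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Vectorized SAM of each row of ``spectra`` against one reference."""
    spectra = np.asarray(spectra, dtype=float)
    reference = np.asarray(reference, dtype=float).ravel()
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ValueError("SAM undefined for a zero reference")
    norms = np.linalg.norm(spectra, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos = spectra @ reference / (norms * ref_norm)
    cos = np.clip(cos, -1.0, 1.0)
    angles = np.arccos(cos)
    # zero pixels have no direction; treat as maximally dissimilar
    angles[norms == 0] = np.pi
    return angles


@dataclass
class SAMQuery:
    """A labelling query: reference spectrum (or seed), angular threshold."""

    reference: np.ndarray | None = None
    threshold: float = 0.1
    seed: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.threshold <= np.pi:
            raise ValueError("threshold must be in [0, pi]")
        if self.reference is None and self.seed is None:
            raise ValueError("query needs a reference spectrum or a seed pixel")


def grow_label(cube: HSCube, query: SAMQuery, class_code: int) -> LabelMap:
    """Mark every pixel within the SAM threshold of the reference spectrum.

    Returns a delta label map (``class_code`` where selected, 0 elsewhere)
    intended for operator review before merging into the ground truth. The
    criterion is purely spectral: spatial connectivity to the seed is not
    enforced.
    """
    if class_code not in CLASS_CODES:
        raise ValueError(f"class_code must be one of {CLASS_CODES}")
    reference = query.reference
    if reference is None:
        r, c = query.seed  # type: ignore[misc]
        if not (0 <= r < cube.rows and 0 <= c < cube.cols):
            raise IndexError(f"seed {query.seed} outside cube {cube.rows}x{cube.cols}")
        reference = cube.data[r, c]
    angles = sam_angles(cube.pixels(), reference).reshape(cube.rows, cube.cols)
    labels = np.where(angles <= query.threshold, class_code, 0)
    return LabelMap(labels)


def merge_labels(base: LabelMap, delta: LabelMap, overwrite: bool = False) -> LabelMap:
    """Merge a reviewed delta into an existing label map."""
    if base.shape != delta.shape:
        raise ValueError("label map geometries differ")
    out = base.labels.copy()
    mask = delta.labels > 0
    if not overwrite:
        mask &= base.labels == 0
    out[mask] = delta.labels[mask]
    return LabelMap(out)
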