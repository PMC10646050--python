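"""Class-balanced training-set reduction via per-class K-means + SAM ranking.

Training several of the pixel classifiers on every labelled pixel is
needlessly expensive and class-imbalanced. The reducer clusters each class's
pixels into K centroids (K-means, k-means++ init) and keeps, per centroid,
the n labelled pixels of that class with the smallest spectral angle to the
centroid. The result is an exactly balanced selection of K*n pixels per
class drawn from the original data (selection, never synthesis).

Pixels are assigned without replacement: when a pixel ranks among the n
closest of two centroids it goes to the centroid where it ranks best
(globally smallest angle), and the other centroid takes its next candidate.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .core import PixelDataset


class ReductionError(ValueError):
    """A class has too few pixels to fill its centroid quota."""


def _sam_angle_matrix(spectra: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    sn = spectra / np.linalg.norm(spectra, axis=1, keepdims=True).clip(1e-300)
    cn = centroids / np.linalg.norm(centroids, axis=1, keepdims=True).clip(1e-300)
    return np.arccos(np.clip(sn @ cn.T, -1.0, 1.0))


def _greedy_assign(angles: np.ndarray, per_centroid: int) -> np.ndarray:
    """Fill each centroid with its ``per_centroid`` best pixels, without
    replacement, processing (pixel, centroid) pairs by increasing angle.

    Ties in angle are broken by pixel index, then centroid index (the
    flattened order of a stable sort).
    """
    n_pix, n_cent = angles.shape
    order = np.argsort(angles, axis=None, kind="stable")
    quota = np.full(n_cent, per_centroid)
    taken = np.zeros(n_pix, dtype=bool)
    selected: list[int] = []
    remaining = per_centroid * n_cent
    for flat in order:
        pix, cent = divmod(int(flat), n_cent)
        if taken[pix] or quota[cent] == 0:
            continue
        taken[pix] = True
        quota[cent] -= 1
        selected.append(pix)
        remaining -= 1
        if remaining == 0:
            break
    return np.sort(np.array(selected, dtype=int))


class KMeansSAMReducer(BaseEstimator):
    """Per-class K-means + SAM prototype selection.

    Parameters
    ----------
    clusters_per_class : int, default 100
        Number of K-means centroids fitted per class.
    per_centroid : int, default 10
        Labelled pixels kept per centroid (the reduced set has
        ``clusters_per_class * per_centroid`` pixels per class).
    random_state : int or None
        Seed for the k-means++ initialisation.

    Attributes
    ----------
    centroids_ : dict[int, ndarray]
        Fitted centroids per class code, each ``(clusters_per_class, bands)``.
    selected_indices_ : ndarray
        Indices into the fitted dataset of the selected pixels.
    """

    def __init__(
        self,
        clusters_per_class: int = 100,
        per_centroid: int = 10,
        random_state: int | None = None,
        n_init: int = 3,
        max_iter: int = 300,
    ) -> None:
        self.clusters_per_class = clusters_per_class
        self.per_centroid = per_centroid
        self.random_state = random_state
        self.n_init = n_init
        self.max_iter = max_iter

    def fit_resample(self, dataset: PixelDataset) -> PixelDataset:
        """Select the reduced, balanced training set."""
        if self.per_centroid < 1:
            raise ValueError("per_centroid must be >= 1")
        k = self.clusters_per_class
        need = k * self.per_centroid
        self.centroids_ = {}
        picked: list[np.ndarray] = []
        rng = np.random.default_rng(self.random_state)
        for code in sorted(np.unique(dataset.labels)):
            idx = np.flatnonzero(dataset.labels == code)
            if len(idx) < max(k, need):
                raise ReductionError(
                    f"class {code} has {len(idx)} pixels; needs >= {max(k, need)} "
                    f"for {k} centroids x {self.per_centroid}"
                )
            spectra = dataset.spectra[idx]
            km = KMeans(
                n_clusters=k,
                init="k-means++",
                n_init=self.n_init,
                max_iter=self.max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(spectra)
            self.centroids_[int(code)] = km.cluster_centers_
            angles = _sam_angle_matrix(spectra, km.cluster_centers_)
            local = _greedy_assign(angles, self.per_centroid)
            picked.append(idx[local])
        self.selected_indices_ = np.sort(np.concatenate(picked))
        return dataset.subset(self.selected_indices_)


def reduce_training_set(
    train: PixelDataset,
    clusters_per_class: int = 100,
    per_centroid: int = 10,
    seed: int | None = None,
) -> PixelDataset:
    """Functional wrapper over :class:`KMeansSAMReducer`."""
    reducer = KMeansSAMReducer(
        clusters_per_class=clusters_per_class,
        per_centroid=per_centroid,
        random_state=seed,
    )
    return reducer.fit_resample(train)
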