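"""Spatial-spectral fusion: guide image, probability filtering, segmentation,
majority voting and tumour-density rendering.

The supervised classifiers are purely spectral; this stage injects spatial
context. A one-band PCA guide image summarises the cube; a guided KNN filter
averages each pixel's class posteriors over its K nearest neighbours in a
joint (row, col, intensity) feature space restricted to a band of nearby
image rows; a hierarchical (bisecting) k-means splits the cube into K_seg
spectrally homogeneous regions; majority voting paints each region with the
modal filtered class; and the three-maximum-density (TMD) rendering colours
each region with RGB = (fraction TT, fraction NT, fraction BV) so a surgeon
reads tumour density directly as red saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import BisectingKMeans
from sklearn.neighbors import NearestNeighbors

from .core import BG, BV, NT, TT, HSCube


def pca_guide(cube: HSCube) -> np.ndarray:
    """First-principal-component scores of the cube's own pixels, min-max
    rescaled to [0, 1]."""
    if cube.stage != "normalized":
        raise ValueError("pca_guide expects a normalized cube")
    X = cube.pixels()
    Xc = X - X.mean(axis=0)
    if not np.any(Xc):
        raise ValueError("constant image: first principal component undefined")
    # first right singular vector == first PC direction
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        raise ValueError("degenerate image: PC1 scores are constant")
    return ((scores - lo) / (hi - lo)).reshape(cube.rows, cube.cols)


@dataclass
class KNNFilterConfig:
    """Guided-filter parameters: intensity weight lambda, neighbour count K,
    half-window height in image rows, Euclidean metric."""

    lam: float = 1.0
    k: int = 40
    window_rows: int = 8

    def __post_init__(self) -> None:
        if self.k < 1 or self.window_rows < 1:
            raise ValueError("K and window_rows must be >= 1")


def knn_filter(
    probs: np.ndarray, guide: np.ndarray, cfg: KNNFilterConfig | None = None
) -> np.ndarray:
    """Average each pixel's posterior over its K nearest neighbours.

    The neighbour feature is f(j) = (row_j / w, col_j / w, lam * g_j) with
    w the window height, so spatial coordinates and guide intensity live on
    comparable scales; candidates are restricted to pixels within
    +/- window_rows image rows (any column). The output is a convex
    combination of input posteriors, hence stays on the simplex.
    """
    cfg = cfg or KNNFilterConfig()
    probs = np.asarray(probs, dtype=float)
    guide = np.asarray(guide, dtype=float)
    if probs.ndim != 3 or probs.shape[:2] != guide.shape:
        raise ValueError("probability map and guide geometries differ")
    rows, cols, _ = probs.shape
    w = cfg.window_rows
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    feats = np.stack(
        [rr.ravel() / w, cc.ravel() / w, cfg.lam * guide.ravel()], axis=1
    )
    flat_probs = probs.reshape(-1, probs.shape[2])
    out = np.empty_like(flat_probs)
    for r in range(rows):
        lo, hi = max(0, r - w), min(rows, r + w + 1)
        cand = np.arange(lo * cols, hi * cols)
        if cfg.k > len(cand):
            raise ValueError(
                f"K={cfg.k} exceeds the {len(cand)} candidates in the row window"
            )
        nn = NearestNeighbors(n_neighbors=cfg.k).fit(feats[cand])
        q = np.arange(r * cols, (r + 1) * cols)
        _, idx = nn.kneighbors(feats[q])
        out[q] = flat_probs[cand[idx]].mean(axis=1)
    return out.reshape(probs.shape)


class HierarchicalKMeans(BaseEstimator, ClusterMixin):
    """Bisecting k-means segmenter: repeatedly 2-means-split the cluster with
    the largest within-cluster sum of squares until ``n_clusters`` remain.

    ``fit_predict`` returns labels in 1..n_clusters.
    """

    def __init__(self, n_clusters: int = 24, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.random_state = random_state

    def fit_predict(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if len(X) < self.n_clusters:
            raise ValueError(
                f"{len(X)} samples cannot form {self.n_clusters} clusters"
            )
        if self.n_clusters == 1:
            self.labels_ = np.ones(len(X), dtype=int)
            return self.labels_
        km = BisectingKMeans(
            n_clusters=self.n_clusters,
            bisecting_strategy="biggest_inertia",
            init="k-means++",
            random_state=self.random_state,
        ).fit(X)
        self.labels_ = km.labels_ + 1
        return self.labels_

    def fit(self, X, y=None):
        self.fit_predict(X)
        return self


def hkm_segment(
    cube: HSCube, k_seg: int = 24, seed: int | None = None
) -> np.ndarray:
    """Segment a normalized cube into ``k_seg`` spectral clusters (1..k_seg)."""
    if cube.stage != "normalized":
        raise ValueError("hkm_segment expects a normalized cube")
    labels = HierarchicalKMeans(n_clusters=k_seg, random_state=seed).fit_predict(
        cube.pixels()
    )
    return labels.reshape(cube.rows, cube.cols)


def majority_vote(class_map: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Replace every pixel's class by the modal class of its cluster.

    Ties break to the lowest class code (NT < TT < BV < BG).
    """
    class_map = np.asarray(class_map)
    clusters = np.asarray(clusters)
    if class_map.shape != clusters.shape:
        raise ValueError("class map and cluster map geometries differ")
    out = np.empty_like(class_map)
    for cid in np.unique(clusters):
        mask = clusters == cid
        votes = np.bincount(class_map[mask].ravel())
        out[mask] = int(np.argmax(votes))  # argmax returns the lowest tied code
    return out


def tmd_render(class_map: np.ndarray, clusters: np.ndarray) -> np.ndarray:
    """Three-maximum-density image: per cluster, RGB = class fractions.

    R, G and B carry the fractions of TT, NT and BV pixels among *all*
    pixels of the cluster, so background-dominated clusters render dark and
    R+G+B <= 1 with equality exactly when the cluster has no BG pixels.
    """
    class_map = np.asarray(class_map)
    clusters = np.asarray(clusters)
    if class_map.shape != clusters.shape:
        raise ValueError("class map and cluster map geometries differ")
    rgb = np.zeros((*class_map.shape, 3), dtype=float)
    for cid in np.unique(clusters):
        mask = clusters == cid
        total = mask.sum()
        rgb[mask, 0] = np.sum(class_map[mask] == TT) / total
        rgb[mask, 1] = np.sum(class_map[mask] == NT) / total
        rgb[mask, 2] = np.sum(class_map[mask] == BV) / total
    return rgb


def fuse(
    cube: HSCube,
    probs: np.ndarray,
    knn_cfg: KNNFilterConfig | None = None,
    k_seg: int = 24,
    seed: int | None = None,
) -> dict[str, np.ndarray]:
    """Run the full spatial-spectral stage on one cube.

    Returns the guide image, filtered probability map, filtered class map,
    cluster map, majority-voted class map and TMD image.
    """
    from .core import CLASS_CODES

    guide = pca_guide(cube)
    filtered = knn_filter(probs, guide, knn_cfg)
    filtered_classes = np.array(CLASS_CODES)[np.argmax(filtered, axis=2)]
    clusters = hkm_segment(cube, k_seg=k_seg, seed=seed)
    mv = majority_vote(filtered_classes, clusters)
    tmd = tmd_render(filtered_classes, clusters)
    return {
        "guide": guide,
        "filtered_probs": filtered,
        "filtered_classes": filtered_classes,
        "clusters": clusters,
        "mv": mv,
        "tmd": tmd,
    }
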