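"""Spatial-spectral stage: PCA guide, guided KNN filter, HKM, MV, TMD."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from hsibrain import (
    KNNFilterConfig,
    generate_blob_scene,
    hkm_segment,
    knn_filter,
    majority_vote,
    pca_guide,
    preprocess_cube,
    tmd_render,
)
from hsibrain.core import BG, BV, NT, TT
from conftest import make_cube


class TestPcaGuide:
    def test_rank_one_cube_reproduces_amplitude_ordering(self):
        rng = np.random.default_rng(0)
        v = rng.random(10) + 0.1
        amps = rng.random((6, 6))
        cube = make_cube(amps[:, :, None] * v[None, None, :])
        guide = pca_guide(cube)
        # PC1 scores of rank-1 data are affine in the amplitudes
        flat_a, flat_g = amps.ravel(), guide.ravel()
        order_a = np.argsort(flat_a)
        assert (
            np.array_equal(order_a, np.argsort(flat_g))
            or np.array_equal(order_a, np.argsort(-flat_g))
        )
        assert guide.min() == 0.0 and guide.max() == 1.0

    def test_duplicate_image_rows_give_duplicate_guide_rows(self):
        rng = np.random.default_rng(1)
        row = rng.random((1, 5, 8))
        data = np.concatenate([row, row, rng.random((2, 5, 8))], axis=0)
        guide = pca_guide(make_cube(data))
        np.testing.assert_allclose(guide[0], guide[1], atol=1e-12)

    def test_pc1_variance_beats_random_projections(self):
        rng = np.random.default_rng(2)
        cube = make_cube(rng.random((8, 8, 12)))
        X = cube.pixels()
        Xc = X - X.mean(axis=0)
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        pc1_var = np.var(Xc @ vt[0])
        for _ in range(50):
            w = rng.standard_normal(12)
            w /= np.linalg.norm(w)
            assert np.var(Xc @ w) <= pc1_var + 1e-12

    def test_constant_cube_rejected(self):
        with pytest.raises(ValueError):
            pca_guide(make_cube(np.ones((4, 4, 6))))


class TestKnnFilter:
    def test_uniform_probability_map_unchanged(self):
        probs = np.tile(np.array([0.6, 0.2, 0.1, 0.1]), (10, 10, 1))
        guide = np.random.default_rng(3).random((10, 10))
        out = knn_filter(probs, guide, KNNFilterConfig(k=15, window_rows=4))
        np.testing.assert_allclose(out, probs, atol=1e-12)

    def test_salt_noise_pixel_pulled_to_region_consensus(self):
        """A single dissenting pixel inside a homogeneous region flips back;
        results equal a brute-force neighbour search on the same features."""
        rows = cols = 20
        probs = np.tile(np.array([0.9, 0.05, 0.03, 0.02]), (rows, cols, 1))
        probs[10, 10] = [0.05, 0.9, 0.03, 0.02]  # lone TT vote in NT field
        guide = np.full((rows, cols), 0.5)
        cfg = KNNFilterConfig(lam=1.0, k=40, window_rows=8)
        out = knn_filter(probs, guide, cfg)
        assert np.argmax(out[10, 10]) == 0  # back to the NT consensus

        # independent brute-force oracle
        feats = np.array(
            [
                (r / cfg.window_rows, c / cfg.window_rows, cfg.lam * guide[r, c])
                for r in range(rows)
                for c in range(cols)
            ]
        )
        flat = probs.reshape(-1, 4)
        expected = np.empty_like(flat)
        for i in range(rows * cols):
            r = i // cols
            cand = [
                j
                for j in range(rows * cols)
                if abs(j // cols - r) <= cfg.window_rows
            ]
            d = np.linalg.norm(feats[cand] - feats[i], axis=1)
            nearest = np.array(cand)[np.argsort(d, kind="stable")[: cfg.k]]
            expected[i] = flat[nearest].mean(axis=0)
        np.testing.assert_allclose(
            out.reshape(-1, 4).sum(axis=1), 1.0, atol=1e-12
        )
        np.testing.assert_allclose(out[10, 10], expected[10 * cols + 10], atol=1e-9)

    def test_output_stays_on_simplex(self):
        rng = np.random.default_rng(4)
        probs = rng.dirichlet(np.ones(4), size=(12, 9))
        out = knn_filter(probs, rng.random((12, 9)), KNNFilterConfig(k=20, window_rows=3))
        assert (out >= 0).all()
        np.testing.assert_allclose(out.sum(axis=2), 1.0, atol=1e-9)
        assert out.min() >= probs.min() - 1e-12  # convex hull of inputs

    def test_k_exceeding_window_population_rejected(self):
        probs = np.tile(np.array([1.0, 0, 0, 0]), (5, 5, 1))
        with pytest.raises(ValueError, match="candidates"):
            knn_filter(probs, np.zeros((5, 5)), KNNFilterConfig(k=100, window_rows=1))


class TestHkmSegment:
    def test_blob_phantom_recovered(self):
        raw, refs, regions = generate_blob_scene(
            rows=48, cols=48, n_blobs=8, noise_sd=0.01, seed=21
        )
        cube = preprocess_cube(raw, refs)
        clusters = hkm_segment(cube, k_seg=8, seed=5)
        assert len(np.unique(clusters)) == 8
        assert adjusted_rand_score(regions.ravel(), clusters.ravel()) >= 0.95

    def test_single_cluster(self):
        cube = make_cube(np.random.default_rng(5).random((4, 4, 6)))
        assert (hkm_segment(cube, k_seg=1, seed=0) == 1).all()

    def test_more_clusters_than_pixels_rejected(self):
        cube = make_cube(np.random.default_rng(6).random((2, 2, 6)))
        with pytest.raises(ValueError):
            hkm_segment(cube, k_seg=5, seed=0)


class TestMajorityVote:
    def test_modal_class_wins(self):
        classes = np.array([[TT, TT, NT]])
        clusters = np.ones((1, 3), dtype=int)
        np.testing.assert_array_equal(majority_vote(classes, clusters), TT)

    def test_result_piecewise_constant_on_clusters(self):
        rng = np.random.default_rng(7)
        classes = rng.integers(1, 5, (8, 8))
        clusters = np.repeat(np.arange(1, 5), 16).reshape(8, 8)
        mv = majority_vote(classes, clusters)
        for cid in range(1, 5):
            assert len(np.unique(mv[clusters == cid])) == 1

    def test_tie_breaks_to_lowest_class_code(self):
        classes = np.array([[TT, NT, TT, NT]])
        clusters = np.ones((1, 4), dtype=int)
        assert (majority_vote(classes, clusters) == NT).all()


class TestTmdRender:
    def test_pure_tumour_cluster_is_bright_red(self):
        classes = np.full((2, 2), TT)
        rgb = tmd_render(classes, np.ones((2, 2), dtype=int))
        np.testing.assert_allclose(rgb, np.broadcast_to([1.0, 0, 0], (2, 2, 3)))

    def test_tumour_vessel_mix_is_purple(self):
        classes = np.array([[TT, BV]])
        rgb = tmd_render(classes, np.ones((1, 2), dtype=int))
        np.testing.assert_allclose(rgb[0, 0], [0.5, 0.0, 0.5])

    def test_background_cluster_is_black(self):
        classes = np.full((2, 2), BG)
        rgb = tmd_render(classes, np.ones((2, 2), dtype=int))
        np.testing.assert_allclose(rgb, 0.0)

    def test_channel_sum_below_one_iff_background_present(self):
        classes = np.array([[TT, NT, BV, BG], [TT, NT, BV, NT]])
        clusters = np.array([[1, 1, 1, 1], [2, 2, 2, 2]])
        rgb = tmd_render(classes, clusters)
        assert rgb[0, 0].sum() == pytest.approx(0.75)  # BG in cluster 1
        assert rgb[1, 0].sum() == pytest.approx(1.0)  # no BG in cluster 2
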