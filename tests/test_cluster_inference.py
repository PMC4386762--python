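"""Cluster labeling, Gaussian smoothing, smoothness estimation and the
Monte Carlo cluster-extent threshold."""

import numpy as np
import pytest
from scipy import ndimage

from lffcouple.cluster_inference import (
    ClusterThresholdSpec,
    FWHM_TO_SIGMA,
    estimate_fwhm,
    label_clusters,
    simulate_cluster_threshold,
    smooth_gaussian,
)


def sparse_mask_1000():
    """1000 voxels with no face-adjacent pairs (checkerboard parity),
    so the independent-voxel binomial oracle applies exactly."""
    side = 16
    grid = np.indices((side, side, side)).sum(axis=0)
    mask = (grid % 2) == 0
    flat = np.flatnonzero(mask.ravel())
    keep = np.zeros(side**3, dtype=bool)
    keep[flat[:1000]] = True
    return keep.reshape((side, side, side))


class TestSmoothing:
    def test_fwhm_zero_is_bitwise_identity(self, rng):
        vol = rng.standard_normal((6, 6, 6))
        assert np.array_equal(smooth_gaussian(vol, 0.0), vol)

    def test_delta_impulse_matches_analytic_kernel(self):
        # response ratios to the peak equal the continuous Gaussian exactly
        vol = np.zeros((17, 17, 17))
        vol[8, 8, 8] = 1.0
        fwhm, voxel = 8.0, 2.0
        sigma = fwhm * FWHM_TO_SIGMA / voxel
        out = smooth_gaussian(vol, fwhm, voxel)
        for off in range(4):
            expected = np.exp(-(off**2) / (2 * sigma**2))
            assert out[8 + off, 8, 8] / out[8, 8, 8] == pytest.approx(
                expected, abs=1e-6
            )

    def test_white_noise_smoothness_round_trip(self, rng):
        field = rng.standard_normal((40, 40, 40))
        out = smooth_gaussian(field, 4.0)
        mask = np.zeros((40, 40, 40), dtype=bool)
        mask[5:35, 5:35, 5:35] = True  # avoid zero-padded borders
        est = estimate_fwhm(out, mask)
        assert np.all(np.abs(est - 4.0) / 4.0 < 0.15)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros((3, 3, 3)), -1.0)

    def test_4d_smooths_spatial_axes_only(self, rng):
        vol = rng.standard_normal((8, 8, 8, 5))
        out = smooth_gaussian(vol, 2.0)
        ref = np.stack(
            [smooth_gaussian(vol[..., i], 2.0) for i in range(5)], axis=-1
        )
        assert np.allclose(out, ref, atol=1e-12)


class TestEstimateFwhm:
    def test_unsmoothed_white_noise_is_subvoxel(self, rng):
        field = rng.standard_normal((24, 24, 24))
        mask = np.ones((24, 24, 24), dtype=bool)
        est = estimate_fwhm(field, mask)
        assert np.all(est < 1.2)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            estimate_fwhm(np.ones((8, 8, 8)), np.ones((8, 8, 8), dtype=bool))

    def test_thin_mask_rejected(self, rng):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[3, :, :] = True
        with pytest.raises(ValueError, match="thinner"):
            estimate_fwhm(rng.standard_normal((8, 8, 8)), mask)


class TestLabelClusters:
    def test_single_block_is_one_cluster(self):
        stat = np.zeros((9, 9, 9))
        stat[2:5, 2:5, 2:5] = 5.0
        labels, table = label_clusters(stat, 3.0)
        assert len(table) == 1
        assert table.iloc[0]["size"] == 27
        assert (labels > 0).sum() == 27

    def test_corner_touch_depends_on_connectivity(self):
        stat = np.zeros((8, 8, 8))
        stat[1:3, 1:3, 1:3] = 4.0
        stat[3:5, 3:5, 3:5] = 4.0  # touches only at the (3,3,3) corner
        _, faces = label_clusters(stat, 3.0, connectivity="faces")
        _, corners = label_clusters(stat, 3.0, connectivity="faces_edges_corners")
        assert len(faces) == 2
        assert len(corners) == 1

    def test_two_sided_includes_negative_clusters(self):
        stat = np.zeros((8, 8, 8))
        stat[1:3, 1, 1] = -5.0
        _, two = label_clusters(stat, 3.0, two_sided=True)
        _, one = label_clusters(stat, 3.0, two_sided=False)
        assert len(two) == 1 and len(one) == 0

    def test_partition_matches_flood_fill(self, rng):
        stat = rng.standard_normal((10, 10, 10))
        thr = 1.0
        labels, table = label_clusters(stat, thr, connectivity="faces")
        supra = np.abs(stat) >= thr
        assert np.array_equal(labels > 0, supra)
        # brute-force BFS flood fill oracle
        seen = np.zeros_like(supra)
        sizes = []
        for idx in np.argwhere(supra):
            if seen[tuple(idx)]:
                continue
            stack, size = [tuple(idx)], 0
            seen[tuple(idx)] = True
            while stack:
                x, y, z = stack.pop()
                size += 1
                for dx, dy, dz in (
                    (1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)
                ):
                    p = (x + dx, y + dy, z + dz)
                    if all(0 <= c < 10 for c in p) and supra[p] and not seen[p]:
                        seen[p] = True
                        stack.append(p)
            sizes.append(size)
        assert sorted(table["size"]) == sorted(sizes)

    def test_min_size_filters_both_outputs(self, rng):
        stat = rng.standard_normal((10, 10, 10)) * 2
        labels, table = label_clusters(stat, 2.5, min_size=3)
        assert (table["size"] >= 3).all()
        assert set(np.unique(labels)) - {0} == set(table["cluster_id"])

    def test_nan_never_clusters(self):
        stat = np.full((5, 5, 5), np.nan)
        stat[2, 2, 2] = 10.0
        labels, table = label_clusters(stat, 3.0)
        assert len(table) == 1 and table.iloc[0]["size"] == 1


class TestSimulateClusterThreshold:
    def test_independent_voxels_match_binomial_oracle(self):
        # 1000 non-adjacent voxels at p=0.005: P(any suprathreshold voxel)
        # = 1 - 0.995^1000 ≈ 0.993 > alpha, and two voxels can never touch,
        # so k_min must be 2 (clusters of size 2 are impossible)
        spec = ClusterThresholdSpec(
            mask=sparse_mask_1000(),
            fwhm_mm=0.0,
            voxel_p=0.005,
            alpha=0.05,
            n_iterations=2000,
            seed=9,
        )
        k_min = simulate_cluster_threshold(spec)
        assert k_min in (1, 2)

    def test_alpha_one_needs_no_correction(self):
        spec = ClusterThresholdSpec(
            mask=np.ones((8, 8, 8), dtype=bool),
            voxel_p=0.005,
            alpha=1.0,
            n_iterations=200,
            seed=1,
        )
        assert simulate_cluster_threshold(spec) == 1

    def test_k_min_nondecreasing_in_smoothness(self):
        mask = np.ones((16, 16, 16), dtype=bool)
        ks = [
            simulate_cluster_threshold(
                ClusterThresholdSpec(
                    mask=mask,
                    fwhm_mm=f,
                    voxel_p=0.005,
                    alpha=0.05,
                    n_iterations=1000,
                    seed=5,
                )
            )
            for f in (0.0, 2.0, 4.0)
        ]
        assert ks == sorted(ks)

    def test_same_seed_same_k_min(self):
        spec = dict(
            mask=np.ones((12, 12, 12), dtype=bool),
            fwhm_mm=2.0,
            voxel_p=0.01,
            alpha=0.05,
            n_iterations=300,
            seed=77,
        )
        a = simulate_cluster_threshold(ClusterThresholdSpec(**spec))
        b = simulate_cluster_threshold(ClusterThresholdSpec(**spec))
        assert a == b

    def test_unresolvable_alpha_rejected(self):
        spec = ClusterThresholdSpec(
            mask=np.ones((6, 6, 6), dtype=bool), alpha=0.001, n_iterations=100
        )
        with pytest.raises(ValueError, match="unresolvable"):
            simulate_cluster_threshold(spec)

    def test_null_distribution_returned(self):
        spec = ClusterThresholdSpec(
            mask=np.ones((8, 8, 8), dtype=bool),
            voxel_p=0.01,
            alpha=0.05,
            n_iterations=200,
            seed=3,
        )
        k, null = simulate_cluster_threshold(spec, return_null=True)
        assert null.shape == (200,)
        assert (null >= k).mean() <= 0.05


def test_spec_validation():
    with pytest.raises(ValueError, match="voxel_p"):
        ClusterThresholdSpec(mask=np.ones((4, 4, 4), dtype=bool), voxel_p=1.5)
    with pytest.raises(ValueError, match="connectivity"):
        ClusterThresholdSpec(mask=np.ones((4, 4, 4), dtype=bool), connectivity="x")
    with pytest.raises(ValueError, match="nonempty"):
        ClusterThresholdSpec(mask=np.zeros((4, 4, 4), dtype=bool))


def test_restricted_mask_needs_smaller_clusters():
    """Small-mask inference: the cluster-extent threshold for a mask
    restricted to a subregion is no larger than the whole-mask one."""
    full = np.ones((20, 20, 20), dtype=bool)
    sub = np.zeros_like(full)
    sub[4:10, 4:10, 4:10] = True
    kw = dict(fwhm_mm=2.0, voxel_p=0.005, alpha=0.05, n_iterations=1000, seed=13)
    k_full = simulate_cluster_threshold(ClusterThresholdSpec(mask=full, **kw))
    k_sub = simulate_cluster_threshold(ClusterThresholdSpec(mask=sub, **kw))
    assert k_sub <= k_full
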