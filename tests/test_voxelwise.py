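"""Smoothing, GLM, TFCE (with brute-force oracle) and permutation FWE."""

import numpy as np
import pytest

from helpers_tfce import brute_force_tfce, full_mask
from lcquant.core import RegionMask, VolumeGrid
from lcquant.stats import two_sample_t
from lcquant.voxelwise import (
    MaskGraph,
    TfceParams,
    _partition_design,
    extract_clusters,
    glm_t,
    neglog10,
    permutation_fwe,
    smooth_cnr,
    tfce,
    tfce_values,
)


class TestSmoothing:
    def test_constant_map_unchanged(self):
        grid = VolumeGrid(np.full((12, 12, 12), 3.0), np.diag([0.5, 0.5, 0.5, 1.0]))
        sm = smooth_cnr(grid, 1.0)
        np.testing.assert_allclose(sm.data, 3.0, atol=1e-9)

    def test_total_intensity_conserved(self):
        rng = np.random.default_rng(0)
        grid = VolumeGrid(rng.normal(size=(16, 16, 16)), np.diag([0.5, 0.5, 0.5, 1.0]))
        sm = smooth_cnr(grid, 1.0)
        assert sm.data.sum() == pytest.approx(grid.data.sum(), abs=1e-6)

    def test_delta_peaks_at_origin_voxel(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 1.0
        sm = smooth_cnr(VolumeGrid(data, np.diag([0.5, 0.5, 0.5, 1.0])), 1.0)
        assert np.unravel_index(np.argmax(sm.data), sm.shape) == (5, 5, 5)

    def test_masking_applied_after_smoothing(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 1.0
        grid = VolumeGrid(data, np.diag([0.5, 0.5, 0.5, 1.0]))
        mask = RegionMask((11, 11, 11), [[5, 5, 6]])  # neighbour only
        sm = smooth_cnr(grid, 1.0, mask)
        assert sm.data[5, 5, 6] > 0  # signal bled in before masking
        assert sm.data[5, 5, 5] == 0.0  # outside mask zeroed


class TestGlmT:
    def test_equal_groups_give_zero_t(self):
        X = np.column_stack([np.ones(10), np.repeat([0, 1], 5)])
        Y = np.tile(np.linspace(1, 2, 5), 2)[:, None] * np.ones((1, 7))
        t = glm_t(Y, X, [0, 1])
        np.testing.assert_allclose(t, 0.0, atol=1e-12)

    def test_matches_pooled_t_test(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(14, 1))
        y[7:] += 0.8
        X = np.column_stack([np.ones(14), np.repeat([0, 1], 7)])
        t_glm = glm_t(y, X, [0, 1])[0]
        # contrast tests group2 - group1; two_sample_t is mean1 - mean2
        t_ref = -two_sample_t(y[:7, 0], y[7:, 0]).value
        assert t_glm == pytest.approx(t_ref, abs=1e-10)

    def test_contrast_sign_flip(self):
        rng = np.random.default_rng(2)
        Y = rng.normal(size=(12, 20))
        X = np.column_stack([np.ones(12), rng.normal(size=12)])
        np.testing.assert_allclose(
            glm_t(Y, X, [0, 1]), -glm_t(Y, X, [0, -1]), atol=1e-12
        )

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        with pytest.raises(ValueError, match="rank"):
            glm_t(np.zeros((8, 3)), X, [0, 1])


class TestPartition:
    def test_partitioned_t_equals_direct_contrast_t(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n, p = 20, 4
            X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
            Y = rng.normal(size=(n, 6))
            c = rng.normal(size=p)
            T, Z = _partition_design(X, c)
            W = np.hstack([T, Z])
            t_direct = glm_t(Y, X, c)
            t_part = glm_t(Y, W, np.eye(p)[0])
            np.testing.assert_allclose(t_part, t_direct, atol=1e-8)


class TestTfce:
    def test_all_zero_map(self):
        mask = full_mask((4, 4, 4))
        graph = MaskGraph.build(mask)
        out = tfce_values(np.zeros(64), graph, TfceParams())
        np.testing.assert_array_equal(out, 0.0)

    def test_single_voxel_hand_computed_value(self):
        """Isolated unit voxel: dh * sum_k (k dh)^2 = 0.33835 at dh=0.01."""
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1.0
        grid = VolumeGrid(data, np.eye(4))
        out = tfce(grid, full_mask((5, 5, 5)), TfceParams())
        expected = 0.01 * sum((0.01 * k) ** 2 for k in range(1, 101))
        assert out.data[2, 2, 2] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.33835, abs=1e-6)

    def test_two_adjacent_voxels_scale_by_sqrt2(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = data[2, 2, 3] = 1.0
        out = tfce(VolumeGrid(data, np.eye(4)), full_mask((5, 5, 5)), TfceParams())
        single = 0.01 * sum((0.01 * k) ** 2 for k in range(1, 101))
        assert out.data[2, 2, 2] == pytest.approx(np.sqrt(2) * single, abs=1e-9)
        assert out.data[2, 2, 3] == pytest.approx(np.sqrt(2) * single, abs=1e-9)

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_oracle(self, connectivity):
        rng = np.random.default_rng(4)
        params = TfceParams(connectivity=connectivity)
        mask = full_mask((8, 8, 8))
        graph = MaskGraph.build(mask, connectivity)
        for _ in range(5):
            arr = rng.normal(size=(8, 8, 8)).clip(0, None)
            fast = np.zeros((8, 8, 8))
            fast[tuple(graph.voxels.T)] = tfce_values(
                arr[tuple(graph.voxels.T)], graph, params
            )
            np.testing.assert_allclose(
                fast, brute_force_tfce(arr, connectivity=connectivity), atol=1e-9
            )

    def test_monotone_in_input(self):
        rng = np.random.default_rng(5)
        mask = full_mask((6, 6, 6))
        graph = MaskGraph.build(mask)
        params = TfceParams()
        vals = rng.normal(size=216).clip(0, None)
        base = tfce_values(vals, graph, params)
        for idx in rng.integers(0, 216, size=5):
            bumped = vals.copy()
            bumped[idx] += 0.5
            out = tfce_values(bumped, graph, params)
            assert np.all(out >= base - 1e-12)

    def test_negative_values_contribute_nothing(self):
        data = np.zeros((5, 5, 5))
        data[1, 1, 1] = -2.0
        out = tfce(VolumeGrid(data, np.eye(4)), full_mask((5, 5, 5)), TfceParams())
        np.testing.assert_array_equal(out.data, 0.0)


def _two_group_data(rng, n_per=8, n_vox_shape=(6, 4, 4), effect=0.0):
    shape = n_vox_shape
    mask = full_mask(shape)
    grid = VolumeGrid(np.zeros(shape), np.diag([0.5, 0.5, 0.5, 1.0]))
    n = 2 * n_per
    Y = rng.normal(size=(n, len(mask)))
    Y[n_per:, : len(mask) // 2] += effect
    X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n_per)])
    contrasts = {"g2>g1": np.array([0.0, 1.0])}
    return Y, X, contrasts, mask, grid


class TestPermutationFwe:
    def test_minimum_attainable_p(self):
        rng = np.random.default_rng(6)
        Y, X, contrasts, mask, grid = _two_group_data(rng, effect=3.0)
        params = TfceParams(n_perm=199, seed=1)
        res = permutation_fwe(Y, X, contrasts, mask, grid, params)
        pmap = res.contrasts["g2>g1"].fwe_p_map
        pvals = pmap.data[tuple(mask.voxels.T)]
        assert pvals.min() >= 1.0 / 200.0
        assert pvals.min() == pytest.approx(1.0 / 200.0)

    def test_strong_effect_detected_and_localized(self):
        rng = np.random.default_rng(7)
        Y, X, contrasts, mask, grid = _two_group_data(rng, n_per=12, effect=2.5)
        res = permutation_fwe(Y, X, contrasts, mask, grid, TfceParams(n_perm=299, seed=2))
        assert len(res.clusters) >= 1
        assert res.clusters["n_voxels"].sum() > 0

    def test_exhaustive_enumeration_for_tiny_n(self):
        rng = np.random.default_rng(8)
        shape = (3, 3, 3)
        mask = full_mask(shape)
        grid = VolumeGrid(np.zeros(shape), np.eye(4))
        Y = rng.normal(size=(5, len(mask)))
        X = np.column_stack([np.ones(5), np.array([0, 0, 1, 1, 1.0])])
        with pytest.warns(UserWarning, match="exhaustively"):
            res = permutation_fwe(
                Y, X, {"c": np.array([0.0, 1.0])}, mask, grid,
                TfceParams(n_perm=500, seed=3),
            )
        assert len(res.null_max) == 120  # 5!

    def test_relabeling_invariance_under_exhaustive_permutations(self):
        rng = np.random.default_rng(9)
        shape = (3, 3, 3)
        mask = full_mask(shape)
        grid = VolumeGrid(np.zeros(shape), np.eye(4))
        Y = rng.normal(size=(5, len(mask)))
        X = np.column_stack([np.ones(5), np.array([0, 0, 1, 1, 1.0])])
        c = {"c": np.array([0.0, 1.0])}
        order = np.array([3, 1, 4, 0, 2])
        with pytest.warns(UserWarning):
            res1 = permutation_fwe(Y, X, c, mask, grid, TfceParams(n_perm=500, seed=3))
            res2 = permutation_fwe(
                Y[order], X[order], c, mask, grid, TfceParams(n_perm=500, seed=3)
            )
        np.testing.assert_allclose(
            res1.contrasts["c"].fwe_p_map.data,
            res2.contrasts["c"].fwe_p_map.data,
            atol=1e-12,
        )

    def test_corrcon_is_conservative(self):
        rng = np.random.default_rng(10)
        Y, X, contrasts, mask, grid = _two_group_data(rng, effect=1.0)
        params = TfceParams(n_perm=199, seed=4)
        res1 = permutation_fwe(Y, X, contrasts, mask, grid, params)
        both = {**contrasts, "g1>g2": np.array([0.0, -1.0])}
        res2 = permutation_fwe(Y, X, both, mask, grid, params)
        p1 = res1.contrasts["g2>g1"].fwe_p_map.data
        p2 = res2.contrasts["g2>g1"].fwe_p_map.data
        assert np.all(p2 >= p1 - 1e-12)


class TestNeglog10AndClusters:
    def test_neglog_values(self):
        grid = VolumeGrid(np.full((2, 2, 2), 0.05), np.eye(4))
        out = neglog10(grid)
        assert out.data[0, 0, 0] == pytest.approx(1.301, abs=1e-3)
        grid1 = VolumeGrid(np.ones((2, 2, 2)), np.eye(4))
        np.testing.assert_allclose(neglog10(grid1).data, 0.0)

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            neglog10(VolumeGrid(np.zeros((2, 2, 2)), np.eye(4)))

    def test_cluster_volume_convention(self):
        shape = (10, 10, 10)
        affine = np.diag([0.5, 0.5, 0.5, 1.0])
        p = np.ones(shape)
        t = np.zeros(shape)
        vox = [(i % 10, (i // 10) % 10, 5) for i in range(46)]
        for v in vox:
            p[v] = 0.01
            t[v] = 3.0
        t[vox[3]] = 3.43  # peak
        mask = full_mask(shape)
        tab = extract_clusters(
            VolumeGrid(p, affine), VolumeGrid(t, affine), mask, TfceParams()
        )
        assert tab["n_voxels"].sum() == 46
        assert tab["volume_mm3"].sum() == pytest.approx(5.75)
        assert tab["peak_t"].max() == pytest.approx(3.43)

    def test_empty_cluster_table(self):
        shape = (4, 4, 4)
        tab = extract_clusters(
            VolumeGrid(np.ones(shape), np.eye(4)),
            VolumeGrid(np.zeros(shape), np.eye(4)),
            full_mask(shape),
            TfceParams(),
        )
        assert len(tab) == 0
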