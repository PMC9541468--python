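"""CNR mapping, atlas thresholding, subregion/hemisphere extraction."""

import numpy as np
import pytest

from lcquant.cnr import (
    ReferenceStats,
    cnr_map,
    reference_box_mask,
    reference_stats,
    regional_cnr,
    snr,
    split_hemispheres,
    split_subregions,
    threshold_atlas,
)
from lcquant.core import RegionMask, VolumeGrid
from lcquant.synthetic import (
    SimulationConfig,
    make_atlas,
    make_grid,
    make_subject_volume,
    small_config,
)


def _grid_with_values(values_at, shape=(8, 8, 8)):
    data = np.zeros(shape)
    for idx, v in values_at.items():
        data[idx] = v
    return VolumeGrid(data, np.eye(4))


class TestReferenceStats:
    def test_mean_and_sample_sd(self):
        grid = _grid_with_values({(0, 0, 0): 1, (0, 0, 1): 2, (0, 0, 2): 3})
        box = RegionMask((8, 8, 8), [[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        ref = reference_stats(grid, box)
        assert ref.mean == pytest.approx(2.0)
        assert ref.sd == pytest.approx(1.0)  # sample SD of 1,2,3

    def test_constant_box_rejected(self):
        grid = VolumeGrid(np.ones((8, 8, 8)), np.eye(4))
        box = RegionMask((8, 8, 8), [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="zero reference SD"):
            reference_stats(grid, box)

    def test_default_box_voxel_count_on_half_mm_grid(self):
        cfg = SimulationConfig()
        grid = make_grid(cfg)
        box = reference_box_mask(grid, (0.0, -38.5, -25.0))
        assert len(box) == 8 * 8 * 9  # 4 x 4 x 4.5 mm at 0.5 mm iso


class TestCnrMap:
    def test_definition(self):
        grid = _grid_with_values({(1, 1, 1): 4.0})
        ref = ReferenceStats(mean=2.0, sd=1.0, n_voxels=10)
        cm = cnr_map(grid, ref)
        assert cm.data[1, 1, 1] == pytest.approx(2.0)
        assert cm.data[0, 0, 0] == pytest.approx(-2.0)

    def test_reference_voxels_center_to_zero(self):
        rng = np.random.default_rng(1)
        grid = VolumeGrid(rng.normal(100, 5, size=(10, 10, 10)), np.eye(4))
        box = RegionMask((10, 10, 10), np.argwhere(np.ones((4, 4, 4))) + 3)
        ref = reference_stats(grid, box)
        cm = cnr_map(grid, ref)
        assert abs(np.mean(box.values_from(cm))) < 1e-9

    def test_invariant_to_affine_intensity_transform(self):
        rng = np.random.default_rng(2)
        grid = VolumeGrid(rng.normal(100, 5, size=(10, 10, 10)), np.eye(4))
        box = RegionMask((10, 10, 10), np.argwhere(np.ones((4, 4, 4))) + 3)
        cm1 = cnr_map(grid, reference_stats(grid, box))
        grid2 = grid.like(3.0 * grid.data + 17.0)
        cm2 = cnr_map(grid2, reference_stats(grid2, box))
        np.testing.assert_allclose(cm1.data, cm2.data, atol=1e-10)


class TestThresholdAtlas:
    def test_inclusive_convention(self):
        mask = RegionMask(
            (4, 4, 4), [[0, 0, 0], [0, 0, 1], [0, 0, 2]],
            "probabilistic", [0.04, 0.05, 0.9],
        )
        assert len(threshold_atlas(mask, 0.05)) == 2

    def test_unreachable_level_rejected(self):
        mask = RegionMask((4, 4, 4), [[0, 0, 0]], "probabilistic", [0.9])
        with pytest.raises(ValueError, match="empty mask"):
            threshold_atlas(mask, 0.95)

    def test_count_non_increasing_in_level(self):
        atlas = make_atlas(small_config())
        counts = [len(threshold_atlas(atlas, lv)) for lv in (0.05, 0.2, 0.5, 0.9)]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] > counts[2]


class TestSplitSubregions:
    @pytest.mark.parametrize(
        "n_slices, expected",
        [(12, (4, 4, 4)), (13, (4, 5, 4)), (3, (1, 1, 1)), (16, (5, 6, 5))],
    )
    def test_block_sizes(self, n_slices, expected):
        vox = [[2, 2, z] for z in range(n_slices)]
        mask = RegionMask((5, 5, max(n_slices, 5)), vox)
        rostral, central, caudal = split_subregions(mask)
        # rostral owns the highest z block
        sizes = (
            len(np.unique(rostral.voxels[:, 2])),
            len(np.unique(central.voxels[:, 2])),
            len(np.unique(caudal.voxels[:, 2])),
        )
        assert sizes == expected
        assert rostral.voxels[:, 2].min() > central.voxels[:, 2].max()
        assert central.voxels[:, 2].min() > caudal.voxels[:, 2].max()

    def test_rounding_rule_matches_enumeration(self):
        # independent oracle: enumerate slice assignment from the stated rule
        for n in range(3, 31):
            vox = [[0, 0, z] for z in range(n)]
            mask = RegionMask((1, 1, n), vox)
            r, c, k = split_subregions(mask)
            b1 = int(np.floor(n / 3 + 0.5))
            b2 = int(np.floor(2 * n / 3 + 0.5))
            assert len(k) == b1
            assert len(c) == b2 - b1
            assert len(r) == n - b2

    def test_partition_property(self):
        atlas = make_atlas(small_config())
        mask = threshold_atlas(atlas, 0.05)
        r, c, k = split_subregions(mask)
        union = np.vstack([r.voxels, c.voxels, k.voxels])
        assert len(union) == len(mask)
        assert {tuple(v) for v in union.tolist()} == mask.index_set()

    def test_too_few_slices(self):
        mask = RegionMask((3, 3, 3), [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="at least 3"):
            split_subregions(mask)


class TestSplitHemispheres:
    def test_symmetric_atlas_splits_evenly(self, small_cfg):
        mask = threshold_atlas(make_atlas(small_cfg), 0.05)
        grid = make_grid(small_cfg)
        left, right = split_hemispheres(mask, grid)
        assert len(left) == len(right)
        assert len(left) + len(right) == len(mask)

    def test_one_sided_mask_warns(self):
        grid = VolumeGrid(np.zeros((8, 8, 8)), np.eye(4))  # all x >= 0
        mask = RegionMask((8, 8, 8), [[2, 2, 2], [3, 3, 3]])
        with pytest.warns(UserWarning, match="hemisphere"):
            left, right = split_hemispheres(mask, grid)
        assert len(left) == 0 and len(right) == 2


class TestRegionalCnr:
    def test_constant_map(self, small_cfg):
        mask = threshold_atlas(make_atlas(small_cfg), 0.05)
        grid = make_grid(small_cfg)
        cm = grid.like(np.full(grid.shape, 2.5))
        s = regional_cnr(cm, "s1", mask, grid)
        for v in s.values.values():
            assert v == pytest.approx(2.5)
        assert all(p == pytest.approx(2.5) for p in s.slice_profile)

    def test_whole_is_weighted_mean_of_hemispheres(self, small_cfg):
        mask = threshold_atlas(make_atlas(small_cfg), 0.05)
        grid = make_grid(small_cfg)
        rng = np.random.default_rng(3)
        cm = grid.like(rng.normal(size=grid.shape))
        s = regional_cnr(cm, "s1", mask, grid)
        left, right = split_hemispheres(mask, grid)
        w = (len(left) * s.values["left"] + len(right) * s.values["right"]) / len(mask)
        assert s.values["whole"] == pytest.approx(w, abs=1e-9)
        r, c, k = split_subregions(mask)
        w2 = (
            len(r) * s.values["rostral"]
            + len(c) * s.values["central"]
            + len(k) * s.values["caudal"]
        ) / len(mask)
        assert s.values["whole"] == pytest.approx(w2, abs=1e-9)

    def test_slice_profile_is_rostral_first(self, small_cfg):
        mask = threshold_atlas(make_atlas(small_cfg), 0.05)
        grid = make_grid(small_cfg)
        # value increases with z, so rostral-first profile must decrease
        zz = np.broadcast_to(np.arange(grid.shape[2], dtype=float), grid.shape)
        s = regional_cnr(grid.like(zz.copy()), "s1", mask, grid)
        assert s.slice_profile == sorted(s.slice_profile, reverse=True)
        assert len(s.slice_profile) == len(np.unique(mask.voxels[:, 2]))

    def test_caudal_deficit_orders_subregions_noise_free(self):
        cfg = small_config(noise_sd=0.0, attenuation_sd=0.0)
        vol, _ = make_subject_volume(cfg, "PSP", 0)
        mask = threshold_atlas(make_atlas(cfg), 0.05)
        ref = ReferenceStats(mean=cfg.background, sd=cfg.noise_sd or 5.0, n_voxels=576)
        s = regional_cnr(cnr_map(vol, ref), "s1", mask, make_grid(cfg))
        assert s.values["caudal"] < s.values["central"] < s.values["rostral"]


class TestSnr:
    def test_value(self):
        grid = _grid_with_values({(0, 0, 0): 2, (0, 0, 1): 4, (0, 0, 2): 6})
        mask = RegionMask((8, 8, 8), [[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        assert snr(grid, mask).snr == pytest.approx(2.0)  # mean 4 / SD 2

    def test_scale_invariance_and_shift(self):
        rng = np.random.default_rng(4)
        grid = VolumeGrid(rng.normal(10, 2, size=(6, 6, 6)), np.eye(4))
        mask = RegionMask((6, 6, 6), np.argwhere(np.ones((3, 3, 3))))
        base = snr(grid, mask).snr
        assert snr(grid.like(5.0 * grid.data), mask).snr == pytest.approx(base)
        assert snr(grid.like(grid.data + 3.0), mask).snr > base

    def test_zero_sd_rejected(self):
        grid = VolumeGrid(np.ones((4, 4, 4)), np.eye(4))
        mask = RegionMask((4, 4, 4), [[0, 0, 0], [0, 0, 1]])
        with pytest.raises(ValueError, match="zero SD"):
            snr(grid, mask)


class TestAttenuationRecovery:
    def test_noise_free_recovery_of_configured_attenuation(self):
        """Extracted caudal attenuation matches ground truth to 1e-6."""
        cfg = small_config(noise_sd=0.0, attenuation_sd=0.0, asymmetry_sd=0.0)
        cfg.degeneration = {"HC": (0, 0, 0), "PD": (0, 0, 0), "PSP": (0.1, 0.2, 0.3)}
        vol, truth = make_subject_volume(cfg, "PSP", 0)
        mask = threshold_atlas(make_atlas(cfg), 0.05)
        _, _, caudal = split_subregions(mask)
        mean_int = float(np.mean(caudal.values_from(vol)))
        recovered = 1.0 - mean_int / (cfg.background * cfg.baseline_lc_gain)
        assert recovered == pytest.approx(0.3, abs=1e-6)
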