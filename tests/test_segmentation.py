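"""Scalar k-means, MIP masking and the two-stage tumour segmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peridce import (
    PeridceError,
    PhantomSpec,
    SegmentationConfig,
    ValidationError,
    VolumeMask,
    apply_mip_mask,
    binarize_enhanced,
    crop,
    deinterleave,
    generate_phantom,
    kmeans,
    largest_component_3d,
    max_intensity_projection,
    refine_tumour,
    remove_small_objects_2d,
    segment_adipose,
    segment_fgt,
    segment_tumour,
)
from conftest import HEALTHY_BOX, TUMOUR_BOX, dice


class TestMip:
    def test_constant_volume_projects_to_constant(self):
        assert np.all(max_intensity_projection(np.full((4, 5, 6), 3.0)) == 3.0)

    def test_single_bright_voxel(self):
        vol = np.zeros((4, 5, 6))
        vol[2, 3, 4] = 9.0
        mip = max_intensity_projection(vol, axis=0)
        assert mip[3, 4] == 9.0 and mip.sum() == 9.0

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(0)
        vol = rng.random((5, 6, 7))
        mip = max_intensity_projection(vol)
        for y in range(6):
            for x in range(7):
                assert mip[y, x] == max(vol[z, y, x] for z in range(5))

    def test_non_3d_rejected(self):
        with pytest.raises(ValidationError):
            max_intensity_projection(np.zeros((4, 4)))


def _best_two_partition_sse(values):
    """Exhaustive minimum within-cluster SSE over contiguous 2-partitions."""
    v = np.sort(np.asarray(values, float))
    best = None
    for cut in range(1, v.size):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if best is None or sse < best[0]:
            best = (sse, cut)
    return best


class TestKmeans:
    def test_separable_values(self):
        res = kmeans(np.array([0, 0, 0, 10, 10, 10.0]), k=2)
        assert np.allclose(res.centroids, [0, 10])
        assert np.array_equal(res.labels, [0, 0, 0, 1, 1, 1])

    def test_defaults_accepted_from_config(self):
        cfg = SegmentationConfig()
        assert cfg.k_initial == 2 and cfg.tolerance == 1e-4
        res = kmeans(np.arange(6, dtype=float), k=cfg.k_initial, tolerance=cfg.tolerance)
        assert res.tolerance == 1e-4 and res.k == 2

    def test_fewer_distinct_values_rejected(self):
        with pytest.raises(ValidationError):
            kmeans(np.array([1.0, 1.0, 1.0]), k=2)

    def test_centroids_sorted_ascending(self):
        rng = np.random.default_rng(2)
        res = kmeans(rng.random(50) * 100, k=4, seed=3)
        assert np.all(np.diff(res.centroids) > 0)
        assert set(np.unique(res.labels)) <= set(range(4))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        vals = rng.random(200)
        a = kmeans(vals, k=3, seed=11)
        b = kmeans(vals, k=3, seed=11)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centroids, b.centroids)

    def test_sse_non_increasing_across_iterations(self):
        rng = np.random.default_rng(5)
        res = kmeans(rng.random(300), k=3, seed=0)
        assert np.all(np.diff(res.sse_history) <= 1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=100,
                              allow_nan=False, allow_infinity=False),
                    min_size=4, max_size=12, unique=True))
    def test_matches_exhaustive_partition_oracle(self, values):
        oracle_sse, _ = _best_two_partition_sse(values)
        res = kmeans(np.array(values), k=2, seed=0, n_init=20)
        assert res.sse == pytest.approx(oracle_sse, rel=1e-6, abs=1e-9)


class TestMipMaskStage:
    def test_binarize_keeps_brighter_cluster(self):
        res = kmeans(np.array([0.0, 0, 10, 10]), k=2)
        assert np.array_equal(binarize_enhanced(res), [False, False, True, True])

    def test_binarize_matches_centroid_midpoint_threshold(self):
        rng = np.random.default_rng(6)
        mip = np.concatenate([rng.normal(10, 1, 80), rng.normal(50, 2, 40)])
        res = kmeans(mip, k=2, seed=0)
        mask = binarize_enhanced(res)
        midpoint = res.centroids.mean()
        assert np.array_equal(mask, mip > midpoint)

    def test_binarize_requires_k2(self):
        res = kmeans(np.arange(10, dtype=float), k=3)
        with pytest.raises(ValidationError):
            binarize_enhanced(res)

    def test_small_objects_removed_by_area(self):
        mask = np.zeros((20, 20), bool)
        mask[1:11, 1:11] = True          # area 100
        mask[15:18, 15:16] = True        # area 3
        out = remove_small_objects_2d(mask, min_area=10)
        assert out.sum() == 100
        assert not out[15:18, 15:16].any()

    def test_min_area_zero_is_identity(self):
        rng = np.random.default_rng(7)
        mask = rng.random((15, 15)) > 0.6
        assert np.array_equal(remove_small_objects_2d(mask, 0), mask)

    def test_large_component_untouched(self):
        mask = np.zeros((10, 10), bool)
        mask[2:8, 2:8] = True
        assert np.array_equal(remove_small_objects_2d(mask, 10), mask)

    def test_apply_mip_mask_equals_per_slice_multiplication(self):
        rng = np.random.default_rng(8)
        vols = [rng.random((4, 6, 7)) for _ in range(3)]
        mip_mask = rng.random((6, 7)) > 0.5
        out = apply_mip_mask(vols, mip_mask)
        for vol, masked in zip(vols, out):
            for z in range(4):
                assert np.array_equal(masked[z], vol[z] * mip_mask)

    def test_all_true_mask_is_identity(self):
        vol = np.arange(24.0).reshape(2, 3, 4)
        out = apply_mip_mask([vol], np.ones((3, 4), bool))
        assert np.array_equal(out[0], vol)

    def test_single_column_mask_keeps_column_at_all_z(self):
        vol = np.ones((5, 3, 3))
        mask = np.zeros((3, 3), bool)
        mask[1, 2] = True
        out = apply_mip_mask([vol], mask)[0]
        assert out[:, 1, 2].sum() == 5 and out.sum() == 5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            apply_mip_mask([np.ones((2, 3, 3))], np.ones((4, 4), bool))


class TestLargestComponent:
    def test_single_object_unchanged(self):
        grid = np.zeros((5, 5, 5), bool)
        grid[1:3, 1:3, 1:3] = True
        out = largest_component_3d(VolumeMask(grid))
        assert np.array_equal(out.grid, grid)

    def test_keeps_largest_of_two(self):
        grid = np.zeros((8, 8, 8), bool)
        grid[0:2, 0:2, 0:2] = True       # 8 voxels... make sizes 10 and 3
        grid[0, 0, 2] = True
        grid[0, 1, 2] = True
        small = np.zeros_like(grid)
        small[6, 6, 5:8] = True
        out = largest_component_3d(VolumeMask(grid | small))
        assert out.n_voxels == 10
        assert not out.grid[6, 6, 5:8].any()

    def test_tie_broken_lexicographically(self):
        grid = np.zeros((6, 6, 6), bool)
        grid[0, 0, 0:5] = True           # 5 voxels, seed (0,0,0)
        grid[4, 4, 0:5] = True           # 5 voxels, seed (4,4,0)
        out = largest_component_3d(VolumeMask(grid))
        assert out.grid[0, 0, 0] and not out.grid[4, 4, 0]

    def test_empty_mask_rejected(self):
        with pytest.raises(PeridceError):
            largest_component_3d(VolumeMask(np.zeros((3, 3, 3), bool)))


class TestRefineTumour:
    def test_two_blobs_keep_larger(self):
        vol = np.zeros((12, 20, 20))
        vol[2:10, 2:12, 2:12] = 50.0     # background-ish cluster material
        vol[2:10, 13:18, 2:7] = 150.0    # mid-intensity material
        vol[2:5, 13:18, 8:12] = 250.0    # fourth intensity level
        vol[3:8, 3:8, 3:8] = 500.0       # 125-voxel bright blob
        vol[10, 15:18, 15:18] = 500.0    # 9-voxel bright blob
        cfg = SegmentationConfig(k_refine=4, min_object_area_2d=0)
        out = refine_tumour(vol, cfg)
        assert out.grid[4, 4, 4] and not out.grid[10, 16, 16]

    def test_manual_cluster_rule_honoured(self):
        rng = np.random.default_rng(9)
        vol = rng.choice([10.0, 20.0, 30.0, 40.0], size=(6, 6, 6))
        vol[0, 0, 0] = 0.0  # excluded from clustering
        cfg = SegmentationConfig(tumour_cluster_rule=[2, 3])
        out = refine_tumour(vol, cfg)
        expect = (vol >= 30) & (vol > 0)
        # manual rule keeps clusters 2 and 3 before component filtering
        assert np.array_equal(out.grid, largest_component_3d(VolumeMask(expect)).grid)

    def test_empty_selection_reports_no_tumour_cluster(self):
        vol = np.zeros((4, 4, 4))
        with pytest.raises(PeridceError):
            refine_tumour(vol, SegmentationConfig())


class TestPhantomSegmentation:
    def test_tumour_recovered_with_high_dice(self, default_phantom):
        spec, series, truth = default_phantom
        tumour_series = crop(series, TUMOUR_BOX)
        mask, mip_mask = segment_tumour(
            deinterleave(tumour_series), SegmentationConfig(),
            spacing=series.voxel_spacing)
        sz, sy, sx = TUMOUR_BOX.slices(series.spatial_shape)
        true_t = truth.masks["tumour"].grid[sz, sy, sx]
        assert dice(mask.grid, true_t) >= 0.90
        # refinement output is confined to the MIP-mask cylinder
        assert not np.any(mask.grid & ~mip_mask[None, :, :])

    def test_fgt_recovered_and_skin_stripped(self):
        spec = PhantomSpec(seed=3, skin_thickness=1.0)
        series, truth = generate_phantom(spec)
        pre = deinterleave(crop(series, HEALTHY_BOX))[0]
        cfg = SegmentationConfig(erosion_iterations=1)
        fgt = segment_fgt(pre, cfg, spacing=series.voxel_spacing)
        sz, sy, sx = HEALTHY_BOX.slices(series.spatial_shape)
        assert dice(fgt.grid, truth.masks["fgt"].grid[sz, sy, sx]) >= 0.85
        assert not np.any(fgt.grid & truth.masks["skin"].grid[sz, sy, sx])

    def test_without_erosion_skin_remains(self):
        spec = PhantomSpec(seed=3, skin_thickness=1.0)
        series, truth = generate_phantom(spec)
        pre = deinterleave(crop(series, HEALTHY_BOX))[0]
        fgt = segment_fgt(pre, SegmentationConfig(erosion_iterations=0),
                          spacing=series.voxel_spacing)
        sz, sy, sx = HEALTHY_BOX.slices(series.spatial_shape)
        assert np.sum(fgt.grid & truth.masks["skin"].grid[sz, sy, sx]) > 0

    def test_erosion_of_thin_structure_errors(self):
        vol = np.zeros((8, 8, 8))
        vol[4, 4, :] = 100.0             # 1-voxel-thick bright line
        vol[0:2] = 1.0                   # darker material for other clusters
        vol[2, 2, 2] = 50.0
        cfg = SegmentationConfig(erosion_iterations=1)
        with pytest.raises(PeridceError):
            segment_fgt(vol, cfg)

    def test_adipose_recovered_and_disjoint_from_fgt(self, default_phantom):
        spec, series, truth = default_phantom
        pre = deinterleave(crop(series, HEALTHY_BOX))[0]
        cfg = SegmentationConfig(erosion_iterations=1)
        adipose = segment_adipose(pre, cfg, spacing=series.voxel_spacing)
        fgt = segment_fgt(pre, cfg, spacing=series.voxel_spacing)
        sz, sy, sx = HEALTHY_BOX.slices(series.spatial_shape)
        assert dice(adipose.grid, truth.masks["adipose"].grid[sz, sy, sx]) >= 0.85
        assert not np.any(adipose.grid & fgt.grid)

    def test_adipose_cluster_rank_configurable(self, default_phantom):
        spec, series, truth = default_phantom
        pre = deinterleave(crop(series, HEALTHY_BOX))[0]
        brightest = segment_adipose(
            pre, SegmentationConfig(adipose_cluster_rank=-1),
            spacing=series.voxel_spacing)
        default = segment_adipose(pre, SegmentationConfig(),
                                  spacing=series.voxel_spacing)
        assert not np.array_equal(brightest.grid, default.grid)

    def test_segmentation_deterministic_given_seed(self, default_phantom):
        spec, series, truth = default_phantom
        vols = deinterleave(crop(series, TUMOUR_BOX))
        a, _ = segment_tumour(vols, SegmentationConfig(seed=5))
        b, _ = segment_tumour(vols, SegmentationConfig(seed=5))
        assert np.array_equal(a.grid, b.grid)
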