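"""Patch grids, localization targets, batch sampling and stitching."""

import numpy as np
import pytest

import vertiseg as vs
from vertiseg.core import LabelMap
from vertiseg.patching import (
    DEFAULT_PATCH_SIZE,
    NotATargetError,
    build_patch_grid,
    localization_target,
    stitch_predictions,
)


def _lm(values, spacing=(1.0, 1.0, 1.0)):
    return LabelMap(np.asarray(values, dtype=np.int32), spacing)


class TestPatchGrid:
    def test_lattice_count_oracle(self):
        """Oracle: lattice positions per axis are floor((L-P)/S)+1 (plus the
        clamped last patch when the stride does not divide evenly)."""
        grid = build_patch_grid((64, 96, 96), (32, 48, 48), 0.5)
        assert len(grid) == 27
        for L, P in zip((64, 96, 96), (32, 48, 48)):
            assert (L - P) % (P // 2) == 0

    def test_single_patch_when_voi_equals_patch(self):
        grid = build_patch_grid((32, 48, 48), (32, 48, 48), 0.5)
        assert len(grid) == 1
        assert np.array_equal(grid.origins[0], [0, 0, 0])

    def test_oversized_patch_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            grid = build_patch_grid((16, 48, 48), (32, 48, 48), 0.5)
        assert grid.patch_size == (16, 48, 48)

    def test_full_coverage_randomized(self):
        """Oracle: explicit coverage-count array; every voxel covered >= 1."""
        rng = np.random.default_rng(0)
        for _ in range(10):
            size = tuple(int(s) for s in rng.integers(20, 70, 3))
            grid = build_patch_grid(size, (16, 16, 16), 0.5)
            cover = np.zeros(size, dtype=int)
            for o in grid.origins:
                cover[grid.patch_slices(o)] += 1
            assert (cover >= 1).all()

    def test_non_integer_stride_rejected(self):
        with pytest.raises(ValueError):
            build_patch_grid((60, 60, 60), (15, 15, 15), 0.5)  # stride 7.5


def _three_vertebra_fixture():
    """Three consecutive box vertebrae with exact in-patch fractions
    600/4000, 1000/4000 and 400/4000 for a (32,48,48) patch at (20,0,0)."""
    arr = np.zeros((80, 48, 96), dtype=np.int32)
    arr[3:23, 5:15, 5:25] = 1  # 4000 voxels, 3 z-slices inside the patch
    arr[25:45, 5:15, 43:63] = 2  # 4000 voxels, x-overlap of 5 columns
    arr[50:70, 5:15, 5:25] = 3  # 4000 voxels, 2 z-slices inside
    lm = _lm(arr)
    centers = vs.all_body_centers(lm)
    return lm, centers


class TestLocalizationTarget:
    patch_origin = (20, 0, 0)
    patch_size = (32, 48, 48)

    def test_three_visible_confidences_are_volume_fractions(self):
        """A patch holding 15%, 25% and 10% of three consecutive vertebrae
        yields confidence scores (0.15, 0.25, 0.10) exactly."""
        lm, centers = _three_vertebra_fixture()
        tgt = localization_target(self.patch_origin, self.patch_size, lm, centers)
        assert tgt.conf_bottom == 0.15
        assert tgt.conf_mid == 0.25
        assert tgt.conf_top == 0.10

    def test_offsets_point_to_body_centers(self):
        lm, centers = _three_vertebra_fixture()
        tgt = localization_target(self.patch_origin, self.patch_size, lm, centers)
        patch_center = np.asarray(self.patch_origin) + np.asarray(self.patch_size) / 2
        assert np.allclose(patch_center + tgt.offsets[1], centers[2])
        assert np.allclose(patch_center + tgt.offsets[0], centers[3])
        assert np.allclose(patch_center + tgt.offsets[2], centers[1])

    def test_single_vertebra_rule(self):
        arr = np.zeros((32, 48, 48), dtype=np.int32)
        arr[10:20, 10:30, 10:30] = 1
        lm = _lm(arr)
        centers = vs.all_body_centers(lm)
        tgt = localization_target((0, 0, 0), (32, 48, 48), lm, centers)
        assert tgt.conf_mid == 1.0
        assert tgt.conf_top == 0.0 and tgt.conf_bottom == 0.0

    def test_two_visible_lower_is_mid(self):
        arr = np.zeros((64, 48, 48), dtype=np.int32)
        arr[5:15, 10:30, 10:30] = 1
        arr[20:30, 10:30, 10:30] = 2
        lm = _lm(arr)
        centers = vs.all_body_centers(lm)
        tgt = localization_target((0, 0, 0), (32, 48, 48), lm, centers)
        patch_center = np.array([16.0, 24.0, 24.0])
        assert np.allclose(patch_center + tgt.offsets[1], centers[1])  # lower is mid
        assert tgt.conf_top == 1.0  # label 2 fully inside
        assert tgt.conf_bottom == 0.0  # no label 0: mirrored position
        # mirror rule: bottom position = 2*mid - top
        assert np.allclose(patch_center + tgt.offsets[2], 2 * centers[1] - centers[2])

    def test_more_than_three_drops_lowest_confidence(self):
        arr = np.zeros((100, 48, 48), dtype=np.int32)
        # five vertebrae with different fractions inside the z in [20, 52) patch
        spans = [(0, 22), (24, 34), (36, 46), (48, 58), (60, 90)]
        for l, (z0, z1) in enumerate(spans, start=1):
            arr[z0:z1, 10:30, 10:30] = l
        lm = _lm(arr)
        centers = vs.all_body_centers(lm)
        tgt = localization_target((20, 0, 0), (32, 48, 48), lm, centers)
        # fractions: v1 2/22, v2 10/10, v3 10/10, v4 4/10, v5 0 -> keep {2,3,4}, mid=3
        patch_center = np.array([36.0, 24.0, 24.0])
        assert np.allclose(patch_center + tgt.offsets[1], centers[3])
        assert tgt.conf_mid == 1.0

    def test_empty_patch_rejected(self):
        with pytest.raises(NotATargetError):
            localization_target((0, 0, 0), (16, 16, 16), _lm(np.zeros((32, 48, 48))), {})

    def test_translation_equivariance(self):
        """Shifting patch and labels together leaves offsets unchanged."""
        lm, centers = _three_vertebra_fixture()
        tgt0 = localization_target((20, 0, 0), self.patch_size, lm, centers)
        shifted = np.zeros_like(lm.values)
        shifted[5:, 3:, :] = lm.values[:-5, :-3, :]
        lm2 = _lm(shifted)
        centers2 = {l: c + np.array([5.0, 3.0, 0.0]) for l, c in centers.items()}
        tgt1 = localization_target((25, 3, 0), self.patch_size, lm2, centers2)
        assert np.allclose(tgt0.offsets, tgt1.offsets)
        assert np.allclose(tgt0.confidences, tgt1.confidences)

    def test_vector_serialization_order(self):
        tgt = vs.LocalizationTarget(np.arange(9).reshape(3, 3), [0.1, 0.2, 0.3])
        vec = tgt.to_vector()
        assert np.array_equal(vec[:3], [0, 1, 2])  # top offset first
        assert np.array_equal(vec[9:], [0.1, 0.2, 0.3])
        back = vs.LocalizationTarget.from_vector(vec)
        assert np.array_equal(back.offsets, tgt.offsets)


def test_interior_confidence_sums_to_eight():
    """With 50% overlap each interior voxel lies in exactly 8 patches, so the
    per-patch volume fractions of an interior vertebra sum to 8."""
    arr = np.zeros((64, 96, 96), dtype=np.int32)
    arr[28:36, 44:52, 44:52] = 1  # entirely inside the 2x2x2-covered core
    lm = _lm(arr)
    centers = vs.all_body_centers(lm)
    grid = build_patch_grid((64, 96, 96), (32, 48, 48), 0.5)
    total = 0.0
    for o in grid.origins:
        try:
            tgt = localization_target(o, grid.patch_size, lm, centers)
        except NotATargetError:
            continue
        total += tgt.conf_mid
    assert total == pytest.approx(8.0)


class TestSampleTrainingBatch:
    def _setup(self):
        arr = np.zeros((64, 64, 64), dtype=np.int32)
        arr[4:20, 4:20, 4:20] = 1
        arr[28:40, 4:20, 4:20] = 2
        arr[48:60, 4:20, 4:20] = 3
        lm = _lm(arr)
        grid = build_patch_grid((64, 64, 64), (16, 16, 16), 0.5)
        return grid, lm

    def test_at_least_half_intersect_vertebrae(self):
        grid, lm = self._setup()
        origins = vs.sample_training_batch(grid, lm, 32, 0.5, seed=0)
        assert len(origins) == 32
        n_vert = sum((lm.values[grid.patch_slices(o)] > 0).any() for o in origins)
        assert n_vert >= 16

    def test_fraction_one_all_intersect(self):
        grid, lm = self._setup()
        origins = vs.sample_training_batch(grid, lm, 8, 1.0, seed=1)
        assert all((lm.values[grid.patch_slices(o)] > 0).any() for o in origins)

    def test_seed_determinism(self):
        grid, lm = self._setup()
        a = vs.sample_training_batch(grid, lm, 16, 0.5, seed=5)
        b = vs.sample_training_batch(grid, lm, 16, 0.5, seed=5)
        assert np.array_equal(a, b)

    def test_no_vertebra_patches_rejected(self):
        grid, _ = self._setup()
        empty = _lm(np.zeros((64, 64, 64)))
        with pytest.raises(ValueError):
            vs.sample_training_batch(grid, empty, 8, 0.5, seed=0)


class TestStitch:
    def test_unanimous_patches(self):
        grid = build_patch_grid((16, 16, 16), (8, 8, 8), 0.5)
        blocks = []
        for _ in grid.origins:
            b = np.zeros((3, 8, 8, 8), dtype=np.float32)
            b[1] = 1.0
            blocks.append(b)
        tlm = stitch_predictions(blocks, grid)
        assert (tlm.values == 1).all()

    def test_all_background(self):
        grid = build_patch_grid((16, 16, 16), (8, 8, 8), 0.5)
        blocks = []
        for _ in grid.origins:
            b = np.zeros((3, 8, 8, 8), dtype=np.float32)
            b[0] = 1.0
            blocks.append(b)
        tlm = stitch_predictions(blocks, grid)
        assert not tlm.foreground_mask.any()

    def test_conflicting_probabilities_argmax_of_mean(self):
        """Oracle: explicit sum and count accumulation arrays."""
        rng = np.random.default_rng(3)
        grid = build_patch_grid((12, 8, 8), (8, 8, 8), 0.5)
        blocks = [rng.dirichlet(np.ones(3), size=(8, 8, 8)).transpose(3, 0, 1, 2).astype(np.float32)
                  for _ in grid.origins]
        tlm = stitch_predictions(blocks, grid)
        acc = np.zeros((3, 12, 8, 8))
        cnt = np.zeros((12, 8, 8))
        for b, o in zip(blocks, grid.origins):
            slc = grid.patch_slices(o)
            acc[(slice(None),) + slc] += b
            cnt[slc] += 1
        expect = np.argmax(acc / cnt, axis=0)
        assert np.array_equal(tlm.values, expect)

    def test_missing_block_rejected(self):
        grid = build_patch_grid((16, 16, 16), (8, 8, 8), 0.5)
        with pytest.raises(ValueError):
            stitch_predictions([np.zeros((3, 8, 8, 8))], grid)
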