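"""Watershed instance separation, recovery and cleanup, checked against
brute-force geometry oracles."""

import numpy as np
import pytest

import vertiseg as vs
from vertiseg.core import LabelMap
from vertiseg.instance import InstanceSegmentation, MAX_VERTEBRAE

from oracles import flood_fill_from_border, signed_distance_bf, watershed_bf


def _ball(shape, center, r):
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2) <= r**2


class TestSignedDistance:
    def test_ball_center_depth(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        d = vs.signed_distance_map(mask)
        assert d[10, 10, 10] == pytest.approx(-7.0, abs=1.0)  # distance to nearest bg voxel
        assert (d[mask] < 0).all() and (d[~mask] > 0).all()

    def test_surface_adjacent_magnitude(self):
        from scipy import ndimage

        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[3:6, 3:6, 3:6] = True
        d = vs.signed_distance_map(mask)
        surface = mask & ~ndimage.binary_erosion(mask)
        assert np.all(np.abs(d[surface]) <= np.sqrt(3))

    def test_matches_brute_force(self):
        """Oracle: exhaustive nearest-opposite-phase search on a random mask."""
        rng = np.random.default_rng(0)
        mask = rng.random((16, 16, 16)) < 0.4
        mask[0, 0, 0] = True  # guarantee nonempty
        got = vs.signed_distance_map(mask, spacing=(1.0, 1.0, 1.0))
        expect = signed_distance_bf(mask)
        assert np.allclose(got, expect)

    def test_anisotropic_spacing(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[4, 4, 4] = True
        d = vs.signed_distance_map(mask, spacing=(2.0, 1.0, 1.0))
        assert d[3, 4, 4] == pytest.approx(2.0)
        assert d[4, 3, 4] == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            vs.signed_distance_map(np.zeros((4, 4, 4), dtype=bool))


class TestRefineCenters:
    def test_fixed_point_unchanged(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        d = vs.signed_distance_map(mask)
        out = vs.refine_centers(np.array([[10, 10, 10]]), d)
        assert np.array_equal(out[0], [10, 10, 10])

    def test_off_center_moves_to_minimum(self):
        """Oracle: windowed argmin by enumeration, iterated."""
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        d = vs.signed_distance_map(mask)
        out = vs.refine_centers(np.array([[8, 10, 12]]), d)
        assert d[tuple(out[0])] <= d[8, 10, 12]
        assert np.array_equal(out[0], np.array([10, 10, 10]))

    def test_independent_blobs(self):
        mask = _ball((40, 21, 21), (10, 10, 10), 5) | _ball((40, 21, 21), (28, 10, 10), 5)
        d = vs.signed_distance_map(mask)
        out = vs.refine_centers(np.array([[9, 10, 10], [29, 10, 10]]), d)
        assert np.array_equal(out[0], [10, 10, 10])
        assert np.array_equal(out[1], [28, 10, 10])


class TestSplitWatershed:
    def test_disjoint_blobs_uncontested(self):
        mask = _ball((40, 21, 21), (10, 10, 10), 5) | _ball((40, 21, 21), (28, 10, 10), 5)
        lab = vs.split_watershed(mask, np.array([[10, 10, 10], [28, 10, 10]]))
        assert np.array_equal(lab == 1, _ball((40, 21, 21), (10, 10, 10), 5))
        assert np.array_equal(lab == 2, _ball((40, 21, 21), (28, 10, 10), 5))

    def test_single_seed_takes_all(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        lab = vs.split_watershed(mask, np.array([[10, 10, 10]]))
        assert np.array_equal(lab > 0, mask)
        assert set(np.unique(lab)) == {0, 1}

    def test_fused_spheres_split_at_neck(self):
        """Two equal spheres fused by a thin neck must split there, each
        region close to one sphere's volume."""
        shape = (32, 17, 17)
        s1 = _ball(shape, (8, 8, 8), 6)
        s2 = _ball(shape, (23, 8, 8), 6)
        neck = np.zeros(shape, dtype=bool)
        neck[13:19, 7:10, 7:10] = True
        mask = s1 | s2 | neck
        lab = vs.split_watershed(mask, np.array([[8, 8, 8], [23, 8, 8]]))
        v1, v2 = (lab == 1).sum(), (lab == 2).sum()
        assert abs(v1 - v2) / mask.sum() < 0.05
        # the split surface lies inside the neck
        boundary_z = [z for z in range(shape[0]) if (lab[z] == 1).any() and (lab[z + 1] == 2).any()]
        assert all(13 <= z < 19 for z in boundary_z)

    def test_matches_brute_force_priority_flood(self):
        """Oracle: heap-based priority flood on random masks and maps."""
        rng = np.random.default_rng(1)
        for _ in range(3):
            mask = rng.random((20, 20, 20)) < 0.7
            dmap = rng.random((20, 20, 20))
            cand = np.argwhere(mask)
            seeds = cand[rng.choice(len(cand), 3, replace=False)]
            got = vs.split_watershed(mask, seeds, dmap=dmap)
            expect = watershed_bf(dmap, seeds, mask)
            assert np.array_equal(got, expect)

    def test_unseeded_component_stays_unlabeled(self):
        mask = _ball((40, 21, 21), (10, 10, 10), 5) | _ball((40, 21, 21), (28, 10, 10), 5)
        lab = vs.split_watershed(mask, np.array([[10, 10, 10]]))
        assert (lab[_ball((40, 21, 21), (28, 10, 10), 5)] == 0).all()

    def test_seed_outside_mask_rejected(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 5)
        with pytest.raises(ValueError):
            vs.split_watershed(mask, np.array([[0, 0, 0]]))


class TestRecoverBoundary:
    def test_no_boundary_no_change(self, small_phantom):
        _, lm, _ = small_phantom
        tlm = vs.encode_three_label(lm)
        body_only = vs.ThreeLabelMap(
            np.where(tlm.values == 1, 1, 0).astype(np.int8), tlm.spacing, tlm.origin
        )
        labels = np.where(tlm.values == 1, lm.values, 0)
        out = vs.recover_boundary(labels, body_only)
        assert np.array_equal(out, labels)

    def test_single_instance_full_recovery(self):
        arr = np.zeros((16, 16, 16), dtype=np.int32)
        arr[4:12, 4:12, 4:12] = 1
        lm = LabelMap(arr, (1, 1, 1))
        tlm = vs.encode_three_label(lm)
        labels = np.where(tlm.body_mask, 1, 0)
        out = vs.recover_boundary(labels, tlm)
        assert np.array_equal(out > 0, arr > 0)

    def test_containment_random_inputs(self):
        """Oracle: set containment — no output voxel outside body ∪ boundary."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            arr = np.zeros((18, 18, 18), dtype=np.int32)
            c = rng.integers(5, 13, 3)
            arr[tuple(slice(x - 4, x + 4) for x in c)] = 1
            lm = LabelMap(arr, (1, 1, 1))
            tlm = vs.encode_three_label(lm)
            labels = np.where(tlm.body_mask, 1, 0)
            out = vs.recover_boundary(labels, tlm)
            assert not (out[~tlm.foreground_mask] > 0).any()

    def test_phantom_boundary_assigned_to_own_instance(self, small_phantom):
        _, lm, _ = small_phantom
        tlm = vs.encode_three_label(lm)
        labels = np.where(tlm.body_mask, lm.values, 0)
        out = vs.recover_boundary(labels, tlm)
        assert np.array_equal(out, lm.values)


class TestFillIslandsHoles:
    def test_solid_ball_unchanged(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        assert np.array_equal(vs.fill_islands_holes(mask), mask)

    def test_satellite_removed(self):
        mask = _ball((21, 21, 21), (10, 10, 10), 6)
        mask[1, 1, 1] = True
        out = vs.fill_islands_holes(mask)
        assert not out[1, 1, 1]
        assert np.array_equal(out, _ball((21, 21, 21), (10, 10, 10), 6))

    def test_hollow_shell_filled(self):
        """Oracle: flood fill from the volume border identifies the cavity."""
        outer = _ball((25, 25, 25), (12, 12, 12), 8)
        inner = _ball((25, 25, 25), (12, 12, 12), 4)
        shell = outer & ~inner
        out = vs.fill_islands_holes(shell)
        reach = flood_fill_from_border(shell)
        assert np.array_equal(out, ~reach)
        assert np.array_equal(out, outer | out)  # cavity filled to the solid ball


class TestRelabel:
    def _phantom_labels(self, small_phantom):
        return small_phantom[1]

    def test_identity_when_ordered(self, small_phantom):
        lm = small_phantom[1]
        out = vs.relabel_bottom_to_top(lm)
        assert np.array_equal(out.values, lm.values)

    def test_reversed_numbering_restored(self, small_phantom):
        lm = small_phantom[1]
        k = lm.n_instances
        reversed_vals = np.where(lm.values > 0, k + 1 - lm.values, 0).astype(lm.values.dtype)
        out = vs.relabel_bottom_to_top(LabelMap(reversed_vals, lm.spacing))
        assert np.array_equal(out.values, lm.values)

    def test_random_permutation_restored(self, small_phantom):
        """Oracle: sort by center-of-mass z."""
        lm = small_phantom[1]
        rng = np.random.default_rng(0)
        perm = rng.permutation(lm.n_instances) + 1
        mapped = np.where(lm.values > 0, perm[lm.values - 1], 0).astype(lm.values.dtype)
        out = vs.relabel_bottom_to_top(LabelMap(mapped, lm.spacing))
        assert np.array_equal(out.values, lm.values)


class TestRecoverMissing:
    def test_no_unlabeled_components_is_identity(self, small_phantom, distance_model):
        _, lm, _ = small_phantom
        tlm = vs.encode_three_label(lm)
        seg = InstanceSegmentation(labels=lm)
        out = vs.recover_missing(seg, tlm, distance_model)
        assert out is seg

    def test_dropped_vertebra_recovered(self, distance_model):
        spec = vs.PhantomSpec(n_vertebrae=6, seed=5)
        _, lm, centers = vs.spine_phantom_with_centers(spec)
        tlm = vs.encode_three_label(lm)
        dropped = np.where(lm.values == 3, 0, lm.values).astype(lm.values.dtype)
        dropped = np.where(dropped > 3, dropped - 1, dropped)
        seg = InstanceSegmentation(labels=LabelMap(dropped, lm.spacing))
        out = vs.recover_missing(seg, tlm, distance_model)
        assert out.k == 6
        assert out.provenance[3] == "recovered"
        assert np.array_equal(out.labels.values, lm.values)

    def test_cap_at_eighteen(self, distance_model):
        spec = vs.PhantomSpec(n_vertebrae=18, seed=11)
        _, lm = vs.generate_spine_phantom(spec)
        tlm = vs.encode_three_label(lm)
        # add an extra unlabeled blob above the stack
        extra = tlm.values.copy()
        extra[-6:-2, 2:6, 2:6] = 2
        tlm2 = vs.ThreeLabelMap(extra, tlm.spacing, tlm.origin)
        seg = InstanceSegmentation(labels=lm)
        out = vs.recover_missing(seg, tlm2, distance_model)
        assert out.k == MAX_VERTEBRAE
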