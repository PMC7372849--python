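"""Geometric metric unit tests: hand-checkable examples, brute-force oracle
equivalence, and the algebraic invariants the metrics must satisfy."""

import numpy as np
import pytest

from contoureval import (
    GeometryError,
    SurfacePointSet,
    UndefinedMetricError,
    directed_distances,
    evaluate_pair,
    extract_surface,
    hausdorff,
    hd95,
    msd,
    overlap_metrics,
)
from conftest import (
    brute_force_directed,
    brute_force_surface_indices,
    cube_mask,
    make_mask,
)


class TestOverlapMetrics:
    def test_identity_pair_is_perfect(self):
        m = cube_mask((12, 12, 12), 2, 5)
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_disjoint_masks_are_zero(self):
        a = cube_mask((20, 10, 10), 0, 4)
        b = cube_mask((20, 10, 10), (10, 0, 0), 4)
        assert overlap_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_shifted_cube_overlap(self):
        # 10^3 cube vs itself shifted 2 voxels: |intersection| = 8*10*10
        a = cube_mask((20, 20, 20), 0, 10)
        b = cube_mask((20, 20, 20), (2, 0, 0), 10)
        dsc, recall, precision = overlap_metrics(a, b)
        assert dsc == pytest.approx(0.8)
        assert recall == pytest.approx(0.8)
        assert precision == pytest.approx(0.8)

    def test_empty_mask_raises(self):
        full = cube_mask((5, 5, 5), 1, 2)
        empty = make_mask(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(UndefinedMetricError):
            overlap_metrics(empty, full)
        with pytest.raises(UndefinedMetricError):
            overlap_metrics(full, empty)

    def test_geometry_mismatch_raises(self):
        a = cube_mask((5, 5, 5), 1, 2, spacing=(0.1, 0.1, 0.1))
        b = cube_mask((5, 5, 5), 1, 2, spacing=(0.2, 0.1, 0.1))
        with pytest.raises(GeometryError):
            overlap_metrics(a, b)

    def test_dsc_is_harmonic_mean_of_precision_recall(self, random_mask_pair):
        for _ in range(20):
            a, b = random_mask_pair()
            dsc, r, p = overlap_metrics(a, b)
            if r + p > 0:
                assert abs(dsc - 2 * p * r / (p + r)) <= 1e-12

    def test_recall_precision_swap_symmetry(self, random_mask_pair):
        a, b = random_mask_pair()
        _, r_ab, p_ab = overlap_metrics(a, b)
        _, r_ba, p_ba = overlap_metrics(b, a)
        assert r_ab == p_ba and p_ab == r_ba


class TestSurfaceExtraction:
    def test_single_voxel_surface(self):
        arr = np.zeros((5, 5, 5), dtype=bool)
        arr[2, 2, 2] = True
        surf = extract_surface(make_mask(arr))
        np.testing.assert_allclose(surf.points, [[0.2, 0.2, 0.2]])

    def test_solid_cube_surface_count(self):
        # 5^3 solid: all but the 3^3 interior voxels are boundary
        surf = extract_surface(cube_mask((9, 9, 9), 2, 5))
        assert len(surf) == 5**3 - 3**3

    def test_thin_plate_all_surface(self):
        arr = np.zeros((8, 8, 8), dtype=bool)
        arr[:, :, 3] = True
        assert len(extract_surface(make_mask(arr))) == 64

    def test_grid_edge_voxels_are_boundary(self):
        arr = np.ones((3, 3, 3), dtype=bool)
        assert len(extract_surface(make_mask(arr))) == 27 - 1

    def test_matches_brute_force_on_random_masks(self, random_mask_pair):
        for _ in range(10):
            m, _ = random_mask_pair()
            surf = extract_surface(m)
            oracle_idx = brute_force_surface_indices(m.voxels)
            oracle_pts = m.geometry.index_to_physical(oracle_idx)
            got = set(map(tuple, np.round(surf.points, 9)))
            want = set(map(tuple, np.round(oracle_pts, 9)))
            assert got == want

    def test_empty_mask_raises(self):
        with pytest.raises(UndefinedMetricError):
            extract_surface(make_mask(np.zeros((4, 4, 4))))


class TestSurfaceDistances:
    def test_directed_distances_hand_examples(self):
        a = SurfacePointSet(np.array([[0.0, 0.0, 0.0]]))
        b = SurfacePointSet(np.array([[3.0, 0, 0], [0, 4.0, 0]]))
        np.testing.assert_allclose(directed_distances(a, b), [3.0])
        np.testing.assert_allclose(directed_distances(b, a), [3.0, 4.0])

    def test_identity_distances_zero(self):
        pts = SurfacePointSet(np.random.default_rng(0).random((30, 3)))
        assert directed_distances(pts, pts).max() == 0.0
        assert hausdorff(pts, pts) == 0.0
        assert hd95(pts, pts) == 0.0
        assert msd(pts, pts) == 0.0

    def test_hausdorff_hand_example(self):
        a = SurfacePointSet(np.array([[0.0, 0.0, 0.0]]))
        b = SurfacePointSet(np.array([[3.0, 0, 0], [0, 4.0, 0]]))
        assert hausdorff(a, b) == pytest.approx(4.0)
        assert hausdorff(b, a) == pytest.approx(4.0)  # symmetric

    def test_msd_hand_example(self):
        a = SurfacePointSet(np.array([[0.0, 0.0, 0.0]]))
        b = SurfacePointSet(np.array([[3.0, 0, 0], [0, 4.0, 0]]))
        assert msd(a, b) == pytest.approx((3.0 + 3.5) / 2)

    def test_hd95_directed_percentile_average(self):
        # 20 points each direction: 19 coincide, one is 10 cm off
        base = np.column_stack([np.arange(20) * 1e-9, np.zeros(20), np.zeros(20)])
        far = base.copy()
        far[-1] = [10.0, 0, 0]
        a = SurfacePointSet(base)
        b = SurfacePointSet(far)
        d_ab = np.sort(brute_force_directed(base, far))
        d_ba = np.sort(brute_force_directed(far, base))

        def p95(d):  # independent linear-interpolation percentile
            rank = 0.95 * (len(d) - 1)
            lo, hi = int(np.floor(rank)), int(np.ceil(rank))
            return d[lo] + (rank - lo) * (d[hi] - d[lo])

        assert hd95(a, b) == pytest.approx((p95(d_ab) + p95(d_ba)) / 2, abs=1e-12)

    def test_hd95_nearest_rank_mode(self):
        a = SurfacePointSet(np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)]))
        b = SurfacePointSet(np.array([[0.0, 0.0, 0.0]]))
        d = np.sort(brute_force_directed(a.points, b.points))  # 0, 1, ..., 19
        # nearest-rank 95th of 20 values is the ceil(0.95*20) = 19th order
        # statistic (d[18]); the reverse direction is a single 0.
        assert hd95(a, b, percentile_mode="nearest_rank") == pytest.approx(d[18] / 2)

    def test_parallel_plates_msd_equals_gap(self):
        arr = np.zeros((10, 10, 12), dtype=bool)
        arr[:, :, 2] = True
        a = make_mask(arr)
        arr2 = np.zeros((10, 10, 12), dtype=bool)
        arr2[:, :, 7] = True
        b = make_mask(arr2)
        assert msd(extract_surface(a), extract_surface(b)) == pytest.approx(0.5)
        assert hausdorff(extract_surface(a), extract_surface(b)) == pytest.approx(0.5)

    def test_slab_translation_recovery(self):
        # big slab shifted k whole voxels along x: HD = MSD = k * spacing
        k = 3
        a = cube_mask((48, 44, 44), (2, 2, 2), 40)
        b = cube_mask((48, 44, 44), (2 + k, 2, 2), 40)
        sa, sb = extract_surface(a), extract_surface(b)
        assert hausdorff(sa, sb) == pytest.approx(k * 0.1)
        assert msd(sa, sb) <= k * 0.1 + 1e-9

    def test_oracle_equivalence_on_random_masks(self, random_mask_pair):
        """KD-tree distances match the O(n^2) brute force to <= 1e-9 cm."""
        for _ in range(50):
            a, b = random_mask_pair(max_side=15)
            sa, sb = extract_surface(a), extract_surface(b)
            d_ab = brute_force_directed(sa.points, sb.points)
            d_ba = brute_force_directed(sb.points, sa.points)
            np.testing.assert_allclose(directed_distances(sa, sb), d_ab, atol=1e-9)
            assert hausdorff(sa, sb) == pytest.approx(
                max(d_ab.max(), d_ba.max()), abs=1e-9
            )
            assert msd(sa, sb) == pytest.approx(
                (d_ab.mean() + d_ba.mean()) / 2, abs=1e-9
            )
            assert hd95(sa, sb) == pytest.approx(
                (np.percentile(d_ab, 95) + np.percentile(d_ba, 95)) / 2, abs=1e-9
            )

    def test_hd95_never_exceeds_hd(self, random_mask_pair):
        for _ in range(10):
            a, b = random_mask_pair()
            sa, sb = extract_surface(a), extract_surface(b)
            assert hd95(sa, sb) <= hausdorff(sa, sb) + 1e-12


class TestEvaluatePair:
    def test_identical_masks_record(self):
        m = cube_mask((10, 10, 10), 2, 5, organ="M-R")
        rec = evaluate_pair(m, m, case_id="c1")
        assert (rec.dsc, rec.recall, rec.precision) == (1.0, 1.0, 1.0)
        assert (rec.hd, rec.hd95, rec.msd) == (0.0, 0.0, 0.0)
        assert rec.organ == "M-R" and rec.case_id == "c1"

    def test_symmetry_of_symmetric_metrics(self, random_mask_pair):
        a, b = random_mask_pair()
        r1 = evaluate_pair(a, b)
        r2 = evaluate_pair(b, a)
        assert r1.dsc == pytest.approx(r2.dsc, abs=1e-12)
        assert r1.hd == pytest.approx(r2.hd, abs=1e-12)
        assert r1.hd95 == pytest.approx(r2.hd95, abs=1e-12)
        assert r1.msd == pytest.approx(r2.msd, abs=1e-12)
        assert r1.recall == pytest.approx(r2.precision, abs=1e-15)

    def test_record_invariants_on_random_pairs(self, random_mask_pair):
        for _ in range(10):
            a, b = random_mask_pair()
            r = evaluate_pair(a, b)
            assert 0 <= r.dsc <= 1 and 0 <= r.recall <= 1 and 0 <= r.precision <= 1
            assert r.msd <= r.hd + 1e-12 and r.hd95 <= r.hd + 1e-12

    def test_scale_equivariance(self):
        a = cube_mask((16, 16, 16), 2, 8)
        b = cube_mask((16, 16, 16), (4, 3, 2), 8)
        a2 = cube_mask((16, 16, 16), 2, 8, spacing=(0.2, 0.2, 0.2))
        b2 = cube_mask((16, 16, 16), (4, 3, 2), 8, spacing=(0.2, 0.2, 0.2))
        r1, r2 = evaluate_pair(a, b), evaluate_pair(a2, b2)
        assert r2.dsc == r1.dsc and r2.recall == r1.recall and r2.precision == r1.precision
        assert r2.hd == pytest.approx(2 * r1.hd)
        assert r2.hd95 == pytest.approx(2 * r1.hd95)
        assert r2.msd == pytest.approx(2 * r1.msd)

    def test_empty_test_mask_error_carries_context(self):
        ref = cube_mask((5, 5, 5), 1, 2, organ="MP-L")
        empty = make_mask(np.zeros((5, 5, 5)), organ="MP-L", provenance="abas")
        with pytest.raises(UndefinedMetricError, match="MP-L"):
            evaluate_pair(ref, empty, case_id="case-007")
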