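"""Planar slicing, gingival reduction, and the five pairwise strategies."""

import numpy as np
import pytest

import odontomatch as om
from odontomatch.mesh_io import PointCloud, Tissue
from odontomatch.segmentation import (Plane, SegmentationMethod,
                                      SegmentationParams, compare_pair,
                                      fit_slicing_plane, gingival_reduction,
                                      plane_slice, segment_pair)

ICP_FAST = om.ICPParams(sample_size=4000)


def labeled_cloud(rng, n=600):
    pts = rng.normal(size=(n, 3)) * 5
    tissue = rng.choice([int(Tissue.TOOTH), int(Tissue.GINGIVA)], size=n)
    tooth = np.where(tissue == int(Tissue.TOOTH), 11, 0).astype(np.int16)
    return PointCloud(pts, tissue.astype(np.int8), tooth)


class TestPlaneSlice:
    def test_vacuous_plane_keeps_everything(self, arch_cloud):
        plane = Plane([0, 0, 1], -1000.0)
        assert len(plane_slice(arch_cloud, plane)) == len(arch_cloud)

    def test_membership_matches_signed_distance_oracle(self):
        rng = np.random.default_rng(0)
        cloud = labeled_cloud(rng, 1000)
        plane = Plane(rng.normal(size=3), 0.7)
        kept = plane_slice(cloud, plane)
        oracle = np.array([float(np.dot(plane.normal, p)) - plane.offset >= 0
                           for p in cloud.points])
        assert len(kept) == oracle.sum()
        assert np.array_equal(kept.points, cloud.points[oracle])
        assert np.array_equal(kept.tissue, cloud.tissue[oracle])

    def test_point_exactly_on_plane_retained(self):
        cloud = PointCloud([[0, 0, 2.0], [0, 0, 1.0]])
        kept = plane_slice(cloud, Plane([0, 0, 1], 2.0))
        assert len(kept) == 1
        assert kept.points[0, 2] == 2.0

    def test_slice_is_subset_preserving_order(self, arch_cloud):
        plane = Plane([0, 0, 1], 0.0)
        kept = plane_slice(arch_cloud, plane)
        mask = arch_cloud.points[:, 2] >= 0
        assert np.array_equal(kept.points, arch_cloud.points[mask])


class TestFitSlicingPlane:
    def flat_config(self):
        g = np.mgrid[0:10, 0:10].reshape(2, -1).T.astype(float)
        base = np.column_stack([g, np.zeros(len(g))])          # gingiva at z=0
        crowns = np.column_stack([g, np.full(len(g), 5.0)])    # teeth at z=5
        pts = np.vstack([base, crowns])
        tissue = np.array([int(Tissue.GINGIVA)] * len(base)
                          + [int(Tissue.TOOTH)] * len(crowns), np.int8)
        return PointCloud(pts, tissue)

    def test_normal_points_to_occlusal_side(self):
        plane = fit_slicing_plane(self.flat_config(), SegmentationParams())
        assert np.abs(plane.normal - [0, 0, 1]).max() < 1e-6

    def test_deterministic_without_jitter(self, arch_cloud):
        p1 = fit_slicing_plane(arch_cloud, SegmentationParams())
        p2 = fit_slicing_plane(arch_cloud, SegmentationParams())
        assert np.array_equal(p1.normal, p2.normal)
        assert p1.offset == p2.offset

    def test_jitter_perturbs_plane(self, arch_cloud):
        sp = SegmentationParams(plane_jitter_sd=0.5)
        p1 = fit_slicing_plane(arch_cloud, sp, seed=1)
        p2 = fit_slicing_plane(arch_cloud, sp, seed=2)
        assert not np.array_equal(p1.normal, p2.normal)

    def test_plane_drop_moves_cut_toward_gingiva(self, arch_cloud):
        p0 = fit_slicing_plane(arch_cloud, SegmentationParams(plane_drop=0.0))
        p1 = fit_slicing_plane(arch_cloud, SegmentationParams(plane_drop=2.0))
        assert p1.offset == pytest.approx(p0.offset - 2.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_slicing_plane(PointCloud([[0, 0, 0], [1, 0, 0]]),
                              SegmentationParams())


class TestGingivalReduction:
    def test_manual_keeps_exactly_tooth_points(self):
        cloud = labeled_cloud(np.random.default_rng(1))
        out = gingival_reduction(cloud, "manual")
        assert np.all(out.tissue == int(Tissue.TOOTH))
        assert len(out) == int(np.sum(cloud.tissue == int(Tissue.TOOTH)))

    def test_zero_margin_semi_auto_equals_manual(self):
        cloud = labeled_cloud(np.random.default_rng(2))
        man = gingival_reduction(cloud, "manual")
        semi = gingival_reduction(cloud, "semi_auto",
                                  SegmentationParams(margin_offset=0.0))
        assert np.array_equal(man.points, semi.points)

    def test_manual_identity_without_gingiva(self):
        pts = np.random.default_rng(3).normal(size=(50, 3))
        cloud = PointCloud(pts, np.full(50, int(Tissue.TOOTH), np.int8),
                           np.full(50, 11, np.int16))
        out = gingival_reduction(cloud, "manual")
        assert np.array_equal(out.points, cloud.points)

    def test_semi_auto_matches_brute_force_collar(self):
        cloud = labeled_cloud(np.random.default_rng(4), n=500)
        margin = 1.5
        out = gingival_reduction(cloud, "semi_auto",
                                 SegmentationParams(margin_offset=margin))
        tooth_pts = cloud.points[cloud.tissue == int(Tissue.TOOTH)]
        keep = []
        for p, t in zip(cloud.points, cloud.tissue):
            if t == int(Tissue.TOOTH):
                keep.append(True)
            elif t == int(Tissue.GINGIVA):
                keep.append(np.min(np.linalg.norm(tooth_pts - p, axis=1)) <= margin)
            else:
                keep.append(False)
        assert np.array_equal(out.points, cloud.points[np.array(keep)])

    def test_unlabeled_cloud_rejected_with_guidance(self):
        cloud = PointCloud(np.random.default_rng(5).normal(size=(20, 3)))
        with pytest.raises(ValueError, match="M4/M5"):
            gingival_reduction(cloud, "manual")

    def test_manual_subset_of_semi_auto_subset_of_input(self):
        cloud = labeled_cloud(np.random.default_rng(6))
        man = gingival_reduction(cloud, "manual")
        semi = gingival_reduction(cloud, "semi_auto",
                                  SegmentationParams(margin_offset=2.0))
        assert len(man) <= len(semi) <= len(cloud)


@pytest.fixture(scope="module")
def am_pm_clouds(mini_cohort):
    scans = {(s.participant_id, s.arch, s.capture): s for s in mini_cohort}
    am = om.sample_surface(scans[("P1", "upper", "AM")].mesh, 12000, 1)
    pm = om.sample_surface(scans[("P1", "upper", "PM")].mesh, 12000, 2)
    return am, pm


class TestSegmentPair:
    def test_m1_returns_inputs_unchanged(self, am_pm_clouds):
        am, pm = am_pm_clouds
        seg = segment_pair(am, pm, "M1")
        assert seg.am_segmented.points is am.points
        assert seg.pm_segmented.points is pm.points

    def test_m5_on_exact_rigid_copy_slices_identically(self, arch_cloud):
        T = om.RigidTransform.from_axis_angle([0, 1, 0], 0.3, (8, -5, 3))
        pm = PointCloud(T.inverse().apply(arch_cloud.points), arch_cloud.tissue,
                        arch_cloud.tooth_id)
        seg = segment_pair(arch_cloud, pm, "M5", icp=ICP_FAST)
        assert np.array_equal(seg.am_indices, seg.pm_indices)

    def test_m5_records_transform_and_plane(self, am_pm_clouds):
        am, pm = am_pm_clouds
        seg = segment_pair(am, pm, "M5", icp=ICP_FAST)
        assert seg.initial_transform is not None
        assert seg.plane_used is not None
        # pm_segmented stays in the PM native frame
        assert np.array_equal(seg.pm_segmented.points, pm.points[seg.pm_indices])

    def test_m4_equals_m5_given_the_joint_plane(self, am_pm_clouds):
        """Feeding the joint plane back as the per-image plane reproduces M5's
        retained subsets exactly."""
        am, pm = am_pm_clouds
        seg = segment_pair(am, pm, "M5", icp=ICP_FAST)
        pm_in_am = PointCloud(seg.initial_transform.apply(pm.points), pm.tissue,
                              pm.tooth_id)
        assert np.array_equal(np.flatnonzero(seg.plane_used.mask(am.points)),
                              seg.am_indices)
        assert np.array_equal(np.flatnonzero(seg.plane_used.mask(pm_in_am.points)),
                              seg.pm_indices)

    def test_m5_frame_invariance(self, am_pm_clouds):
        am, pm = am_pm_clouds
        base = segment_pair(am, pm, "M5", icp=ICP_FAST)
        G = om.RigidTransform.from_axis_angle([2, 1, 0], 0.35, (10, 4, -6))
        moved = segment_pair(am, PointCloud(G.apply(pm.points), pm.tissue,
                                            pm.tooth_id), "M5", icp=ICP_FAST)
        assert np.array_equal(base.am_indices, moved.am_indices)
        assert np.array_equal(base.pm_indices, moved.pm_indices)

    def test_segmented_outputs_are_subsets(self, am_pm_clouds):
        am, pm = am_pm_clouds
        for method in ("M2", "M3", "M4"):
            seg = segment_pair(am, pm, method, icp=ICP_FAST)
            assert len(seg.am_segmented) <= len(am)
            assert np.array_equal(seg.am_segmented.points,
                                  am.points[seg.am_indices])
        m3 = segment_pair(am, pm, "M3", icp=ICP_FAST)
        m2 = segment_pair(am, pm, "M2", icp=ICP_FAST)
        assert set(m3.am_indices) <= set(m2.am_indices)


class TestComparePair:
    def test_perfect_copy_gives_zero_rms_all_methods(self, arch_cloud):
        for method in SegmentationMethod:
            rec = compare_pair(arch_cloud, arch_cloud, method, icp=ICP_FAST,
                               meta={"participant_a": "P1", "participant_b": "P1"})
            assert rec.rms <= 1e-9, method

    def test_rms_bit_stable_across_reruns(self, am_pm_clouds):
        am, pm = am_pm_clouds
        r1 = compare_pair(am, pm, "M5", SegmentationParams(seed=3), ICP_FAST)
        r2 = compare_pair(am, pm, "M5", SegmentationParams(seed=3), ICP_FAST)
        assert r1.rms == r2.rms

    def test_m5_frame_invariant_rms(self, am_pm_clouds):
        am, pm = am_pm_clouds
        G = om.RigidTransform.from_axis_angle([0, 1, 1], 0.25, (-4, 9, 2))
        r1 = compare_pair(am, pm, "M5", icp=ICP_FAST)
        r2 = compare_pair(am, PointCloud(G.apply(pm.points), pm.tissue,
                                         pm.tooth_id), "M5", icp=ICP_FAST)
        assert abs(r1.rms - r2.rms) <= 1e-6

    def test_method_parse_accepts_aliases(self):
        assert SegmentationMethod.parse("m5") is SegmentationMethod.M5_JOINT_PLANAR
        assert SegmentationMethod.parse(3) is SegmentationMethod.M3_MANUAL_GINGIVAL
        assert SegmentationMethod.parse("M4_PLANAR") is SegmentationMethod.M4_PLANAR
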