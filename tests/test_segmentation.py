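"""Enclosing polygons, point assignment, bottom/gap filling."""
import numpy as np
import pytest
import shapely

from conftest import make_measurements
from segmetry.cloud import PointCloud
from segmetry.keypoints import BiomechKeypoints
from segmetry.segmentation import (
    ALPHA_DEFAULTS, PRIORITY, SEGMENTS, SegmentationConfig, SegmentCloud,
    assign_points, bottom_fill, build_enclosing_polygons, gap_fill,
    segment_alpha,
)

NO_PAD = SegmentationConfig(width_margin=1.0, axial_width_margin=1.0,
                            extremity_offset_margin=1.0, cut_inset=0.0,
                            shoulder_width_factor=1.0)


def _skeleton_2d() -> BiomechKeypoints:
    """A supine skeleton laid out along +x (head at large x), y lateral."""
    kp = {
        "KP1": [1.80, 0.0], "KP2": [1.62, 0.0], "KP15": [1.14, 0.0],
        "KP19": [1.70, 0.0], "KP18": [1.47, 0.0], "KP17": [1.30, 0.0],
    }
    for sign, (sh, el, wr, hip, kn, an) in (
        (1, ("KP3", "KP4", "KP5", "KP9", "KP10", "KP11")),
        (-1, ("KP6", "KP7", "KP8", "KP12", "KP13", "KP14")),
    ):
        kp[sh] = [1.62, 0.22 * sign]
        kp[el] = [1.34, 0.23 * sign]
        kp[wr] = [1.08, 0.23 * sign]
        kp[hip] = [1.14, 0.10 * sign]
        kp[kn] = [0.69, 0.10 * sign]
        kp[an] = [0.26, 0.10 * sign]
    return BiomechKeypoints(kp, frame="bed_aligned")


class TestPolygons:
    def test_straight_limb_is_exact_rectangle(self):
        """Shoulder at origin, elbow 0.3 m along +x, half-width 0.06."""
        kps = _skeleton_2d()
        kps.kp["KP3"] = np.array([0.0, 0.0])
        kps.kp["KP4"] = np.array([0.3, 0.0])
        mm = make_measurements()
        mm.limbs["arm_left"].O_p = mm.limbs["arm_left"].O_d = 0.06 * 2 * np.pi
        eps = build_enclosing_polygons(kps, mm, NO_PAD)
        expected = shapely.Polygon([(0, -0.06), (0, 0.06), (0.3, 0.06), (0.3, -0.06)])
        assert eps["left_arm"].polygon.symmetric_difference(expected).area < 1e-12

    def test_all_17_polygons_simple_with_positive_area(self):
        eps = build_enclosing_polygons(_skeleton_2d(), make_measurements())
        assert set(eps) == set(SEGMENTS)
        for ep in eps.values():
            assert ep.polygon.is_valid and ep.polygon.is_simple
            assert ep.polygon.area > 0

    def test_foot_closing_edge_at_offset(self):
        """The foot EP's distal edge lies exactly `offset` beyond the ankle
        along the shank axis."""
        cfg = SegmentationConfig(foot_offset=0.25, extremity_offset_margin=1.0,
                                 cut_inset=0.0)
        eps = build_enclosing_polygons(_skeleton_2d(), make_measurements(), cfg)
        xs = np.asarray(eps["left_foot"].polygon.exterior.coords)[:, 0]
        # shank runs toward -x, so the foot extends 0.25 m below the ankle
        assert xs.min() == pytest.approx(0.26 - 0.25, abs=1e-9)

    def test_shoulders_polygon_has_eight_edges(self):
        eps = build_enclosing_polygons(_skeleton_2d(), make_measurements())
        assert len(eps["shoulders"].polygon.exterior.coords) - 1 == 8

    def test_equivariant_under_inplane_rigid_transform(self):
        mm = make_measurements()
        kps = _skeleton_2d()
        a = np.radians(25.0)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        t = np.array([0.4, -0.2])
        moved = BiomechKeypoints({k: R @ v + t for k, v in kps.kp.items()},
                                 frame="bed_aligned")
        eps0 = build_enclosing_polygons(kps, mm)
        eps1 = build_enclosing_polygons(moved, mm)
        for label in SEGMENTS:
            transformed = shapely.transform(
                eps0[label].polygon, lambda p: p @ R.T + t)
            assert transformed.symmetric_difference(eps1[label].polygon).area < 1e-9

    def test_degenerate_axis_rejected(self):
        kps = _skeleton_2d()
        kps.kp["KP4"] = kps.kp["KP3"].copy()
        with pytest.raises(ValueError, match="degenerate"):
            build_enclosing_polygons(kps, make_measurements())


class TestAssignment:
    def _cloud(self, pts):
        return PointCloud(np.asarray(pts, dtype=float), frame="bed_aligned")

    def test_point_in_single_polygon(self):
        eps = build_enclosing_polygons(_skeleton_2d(), make_measurements())
        segs, un = assign_points(self._cloud([[0.45, 0.10, 1.5]]), eps)
        assert len(segs["left_shank"].points) == 1
        assert len(un) == 0

    def test_overlap_resolved_axial_first(self):
        """A point inside both the pelvis and a thigh EP goes to the pelvis
        (axial before limbs in the priority order)."""
        from segmetry.segmentation import EnclosingPolygon
        sq = lambda x0, x1: shapely.Polygon(
            [(x0, -0.2), (x1, -0.2), (x1, 0.2), (x0, 0.2)])
        polys = {"pelvis": EnclosingPolygon("pelvis", sq(1.0, 1.3)),
                 "left_thigh": EnclosingPolygon("left_thigh", sq(0.6, 1.15))}
        pt = [1.1, 0.0, 1.5]
        assert all(shapely.contains_xy(p.polygon, pt[0], pt[1])
                   for p in polys.values())
        segs, _ = assign_points(self._cloud([pt]), polys)
        assert len(segs["pelvis"].points) == 1
        assert len(segs["left_thigh"].points) == 0

    def test_partition_property(self, clean_run):
        *_, out = clean_run
        total = sum(len(sc.points) for sc in out.segments.values())
        # fills are extra; original assigned points partition PCfine exactly
        segs, un = assign_points(out.filter_result.cloud, out.polygons)
        assert sum(len(s.points) for s in segs.values()) + len(un) == \
            len(out.filter_result.cloud)

    def test_wrong_frame_rejected(self):
        eps = build_enclosing_polygons(_skeleton_2d(), make_measurements())
        with pytest.raises(ValueError, match="bed_aligned"):
            assign_points(PointCloud(np.zeros((1, 3)), frame="camera_metric"), eps)

    def test_priority_covers_all_segments(self):
        assert set(PRIORITY) == set(SEGMENTS)


class TestFilling:
    def _sc(self, pts):
        return SegmentCloud("left_arm", np.asarray(pts, dtype=float))

    def test_bottom_fill_copies_every_point_to_bed(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform([-1, -1, 1.4], [1, 1, 1.5], (100, 3))
        out = bottom_fill(self._sc(pts), bed_z=2.0)
        assert len(out.fill_bottom) == 100
        assert np.max(np.abs(out.fill_bottom[:, 2] - 2.0)) == 0.0
        assert np.array_equal(out.points, pts)  # originals untouched bitwise
        assert np.array_equal(out.fill_bottom[:, :2], pts[:, :2])

    def test_gap_fill_zero_levels_is_identity(self):
        pts = np.random.default_rng(1).uniform(0, 1, (50, 3))
        cfg = SegmentationConfig(gap_fill_levels=0)
        out = gap_fill(self._sc(pts), bed_z=2.0, cfg=cfg)
        assert len(out.fill_gap) == 0
        assert np.array_equal(out.points, pts)

    def test_gap_fill_levels_interpolate_to_bed(self):
        """Boundary point at Z=1.8, bed at 2.0, k=3 -> fills at 1.85/1.90/1.95."""
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        ring = np.column_stack([0.05 * np.cos(theta), 0.05 * np.sin(theta),
                                np.full(40, 1.8)])
        cfg = SegmentationConfig(gap_fill_levels=3, edge_radius=0.02)
        out = gap_fill(self._sc(ring), bed_z=2.0, cfg=cfg)
        zs = np.unique(np.round(out.fill_gap[:, 2], 9))
        assert np.allclose(zs, [1.85, 1.90, 1.95])
        # every ring point is on the 2D boundary -> k fills per point
        assert len(out.fill_gap) == 3 * 40

    def test_gap_fill_reduces_volume_error_on_gapped_cone(self):
        """Truncated-cone shell with a 2 cm equatorial band removed: the gap
        fill brings the Monte Carlo volume closer to the analytic truth."""
        from segmetry.volumetry import MonteCarloConfig, alpha_shape, monte_carlo_volume

        rng = np.random.default_rng(2)
        n = 4000
        L, rp, rd = 0.3, 0.08, 0.05
        x = rng.uniform(0, L, n)
        r = rp + (rd - rp) * x / L
        th = rng.uniform(0, np.pi, n)
        pts = np.column_stack([x, r * np.cos(th), 2.0 - r * np.sin(th)])
        gap = np.abs(pts[:, 0] - L / 2) < 0.01
        sc = SegmentCloud("left_arm", pts[~gap], alpha=1 / 0.05)
        truth = np.pi * L * (rp ** 2 + rd ** 2 + rp * rd) / 6  # upper half
        cfg = SegmentationConfig(gap_fill_levels=6, edge_radius=0.015)
        errs = {}
        for tag, cloud in (("plain", bottom_fill(sc, 2.0)),
                           ("filled", gap_fill(bottom_fill(sc, 2.0), 2.0, cfg))):
            shape = alpha_shape(cloud.all_points, 0.05, require_watertight=False)
            mc = monte_carlo_volume(shape, MonteCarloConfig(200_000, 9))
            errs[tag] = abs(mc.volume - truth)
        assert errs["filled"] <= errs["plain"]


def test_alpha_defaults_and_aliases():
    assert segment_alpha("left_thigh") == ALPHA_DEFAULTS["thigh"]
    assert segment_alpha("head") == 0.08
    # the published list calls the thighs "legs"
    assert segment_alpha("right_thigh", {"legs": 0.3}) == 0.3


def test_hemisphere_bottom_fill_closes_to_analytic_volume():
    """Hemisphere on a plane: bottom-filled alpha-shape volume within 5%."""
    from segmetry.volumetry import MonteCarloConfig, alpha_shape, monte_carlo_volume

    rng = np.random.default_rng(3)
    n, r = 4000, 0.25
    u = rng.uniform(0, 2 * np.pi, n)
    v = np.arccos(rng.uniform(0, 1, n))
    pts = np.column_stack([r * np.sin(v) * np.cos(u), r * np.sin(v) * np.sin(u),
                           2.0 - r * np.cos(v)])
    sc = bottom_fill(SegmentCloud("head", pts, alpha=0.08), 2.0)
    shape = alpha_shape(sc.all_points, 0.08, require_watertight=False)
    mc = monte_carlo_volume(shape, MonteCarloConfig(300_000, 11))
    assert mc.volume == pytest.approx(2 * np.pi * r ** 3 / 3, rel=0.05)
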