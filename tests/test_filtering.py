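"""Scene filtering: coarse crop, bed plane, axis alignment, cleaning."""
import numpy as np
import pytest

from segmetry.cloud import PointCloud, RigidTransform
from segmetry.filtering import (
    EmptyCloudError, FilterConfig, align_bed_axes, apply_transform,
    coarse_filter, fit_bed_plane, remove_bed_and_clean,
)
from segmetry.keypoints import BiomechKeypoints

CFG = FilterConfig(xy_padding=0.10, seed=0, pca_fill_n=100_000)


def _grid(x0, x1, y0, y1, z, step=0.02, jitter=0.0, seed=0):
    xs = np.arange(x0, x1, step)
    ys = np.arange(y0, y1, step)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    if jitter:
        pts += np.random.default_rng(seed).normal(0, jitter, pts.shape)
    return pts


class TestCoarse:
    def test_z_cutoff_is_mean_plus_padding(self):
        """Far points are cut exactly at mean(Z) + z_padding of the crop."""
        bed = _grid(-1, 1, -0.5, 0.5, 2.0)
        floor = _grid(-1, 1, -0.5, 0.5, 2.45, step=0.1)
        pc = PointCloud(np.vstack([bed, floor]))
        cutoff = pc.points[:, 2].mean() + 0.40
        assert 2.0 < cutoff < 2.45  # floor is beyond the cut, bed is not
        out = coarse_filter(pc, FilterConfig(z_padding=0.40, seed=0))
        assert len(out) == len(bed)
        # a padding generous enough keeps the floor
        out2 = coarse_filter(pc, FilterConfig(z_padding=2.45 - cutoff + 0.41, seed=0))
        assert len(out2) == len(pc)

    def test_structure_outside_area_of_interest_removed(self):
        bed = _grid(-1, 1, -0.5, 0.5, 2.0)
        posts = _grid(1.4, 1.8, -0.1, 0.1, 2.0, step=0.05)
        pc = PointCloud(np.vstack([bed, posts]))
        out = coarse_filter(pc, FilterConfig(seed=0))
        assert out.points[:, 0].max() < 1.3

    def test_min_max_padding_mode(self):
        bed = _grid(-1, 1, -0.5, 0.5, 2.0)
        posts = _grid(1.5, 1.8, -0.1, 0.1, 2.0, step=0.05)
        pc = PointCloud(np.vstack([bed, posts]))
        cfg = FilterConfig(crop_half_extent=None, xy_padding=0.45, seed=0)
        out = coarse_filter(pc, cfg)
        assert out.points[:, 0].max() < 1.4

    def test_predicate_oracle_on_phantom(self, clean_phantom):
        """Retained set equals point-by-point evaluation of the crop + Z rule."""
        *_, pc = clean_phantom
        cfg = FilterConfig(seed=0)
        out = coarse_filter(pc, cfg)
        p = pc.points
        center = np.median(p[:, :2], axis=0)
        m = np.all(np.abs(p[:, :2] - center) <= np.asarray(cfg.crop_half_extent),
                   axis=1)
        m &= p[:, 2] <= p[m, 2].mean() + cfg.z_padding
        assert len(out) == m.sum()
        assert np.array_equal(out.points, p[m])

    def test_idempotent(self, clean_phantom):
        *_, pc = clean_phantom
        cfg = FilterConfig(seed=0)
        once = coarse_filter(pc, cfg)
        twice = coarse_filter(once, cfg)
        assert np.array_equal(once.points, twice.points)

    def test_empty_cloud(self):
        with pytest.raises(EmptyCloudError):
            coarse_filter(PointCloud(np.empty((0, 3))), CFG)


def _tilted_scene(tilt_deg, seed=0):
    bed = _grid(-1, 1, -0.5, 0.5, 0.0, jitter=1e-4, seed=seed)
    body = _grid(-0.5, 0.5, -0.2, 0.2, -0.10, step=0.03, jitter=1e-4, seed=seed + 1)
    pts = np.vstack([bed, body])
    t = np.radians(tilt_deg)
    R = np.array([[1, 0, 0], [0, np.cos(t), -np.sin(t)], [0, np.sin(t), np.cos(t)]])
    pts = pts @ R.T
    pts[:, 2] += 2.0
    return PointCloud(pts), len(bed)


class TestBedPlane:
    def test_already_aligned_gives_identity_rotation(self):
        pc, _ = _tilted_scene(0.0)
        T1, _ = fit_bed_plane(pc, CFG)
        angle = np.arccos(np.clip((np.trace(T1.rotation) - 1) / 2, -1, 1))
        assert angle < 1e-4

    def test_5deg_tilt_recovered(self):
        """After T1, the SVD-fitted bed normal is within 0.1 deg of the Z axis."""
        pc, n_bed = _tilted_scene(5.0)
        T1, out = fit_bed_plane(pc, CFG)
        bed_pts = out.points[:n_bed]
        c = bed_pts.mean(axis=0)
        _, _, vt = np.linalg.svd(bed_pts - c, full_matrices=False)
        n = vt[-1]
        assert np.degrees(np.arccos(abs(n[2]))) < 0.1

    def test_seeded_determinism(self):
        pc, _ = _tilted_scene(3.0)
        T1a, _ = fit_bed_plane(pc, CFG, np.random.default_rng(CFG.seed))
        T1b, _ = fit_bed_plane(pc, CFG, np.random.default_rng(CFG.seed))
        assert np.array_equal(T1a.matrix, T1b.matrix)


class TestAxisAlignment:
    def _rect_cloud(self, angle_deg):
        pts = _grid(-1.0, 1.0, -0.5, 0.5, 2.0, step=0.015, jitter=1e-4)
        a = np.radians(angle_deg)
        R = np.array([[np.cos(a), -np.sin(a), 0],
                      [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        return PointCloud(pts @ R.T)

    def test_axis_aligned_rectangle_is_noop(self):
        T2, _ = align_bed_axes(self._rect_cloud(0.0), CFG)
        angle = np.degrees(np.arctan2(T2.rotation[1, 0], T2.rotation[0, 0]))
        assert abs(angle) < 0.5

    @pytest.mark.parametrize("angle", [30.0, -17.0])
    def test_inplane_rotation_recovered(self, angle):
        """Closed-form second moments of a uniform rectangle: the fill's
        principal axes recover the rotation to within 0.5 deg."""
        T2, _ = align_bed_axes(self._rect_cloud(angle), CFG)
        rec = np.degrees(np.arctan2(T2.rotation[1, 0], T2.rotation[0, 0]))
        assert abs(rec + angle) < 0.5  # T2 undoes the applied rotation


class TestBedRemoval:
    def test_plane_only_cloud_is_error(self):
        pc = PointCloud(_grid(-1, 1, -0.5, 0.5, 2.0, jitter=1e-4))
        with pytest.raises(EmptyCloudError):
            remove_bed_and_clean(pc, CFG)

    def test_isolated_point_removed(self):
        bed = _grid(-1, 1, -0.5, 0.5, 2.0, jitter=1e-4)
        body = _grid(-0.4, 0.4, -0.2, 0.2, 1.88, step=0.01, jitter=1e-4, seed=5)
        lone = np.array([[0.0, 0.0, 0.9]])  # 1 m above the body
        pc = PointCloud(np.vstack([bed, body, lone]))
        out, bed_z = remove_bed_and_clean(pc, CFG)
        assert bed_z == pytest.approx(2.0, abs=0.005)
        assert out.points[:, 2].min() > 1.5
        assert len(out) <= len(body)


class TestApplyTransform:
    def test_identity_bitwise(self):
        pc = PointCloud(np.random.default_rng(0).normal(size=(20, 3)))
        out = apply_transform(pc, RigidTransform.identity())
        assert np.array_equal(out.points, pc.points)
        assert out.frame == "bed_aligned"

    def test_pixel_frame_rejected(self):
        kps = BiomechKeypoints({"KP1": [1.0, 2.0]}, frame="pixel")
        with pytest.raises(ValueError, match="pixel"):
            apply_transform(kps, RigidTransform.identity())

    def test_unsupported_type_rejected(self):
        with pytest.raises(TypeError):
            apply_transform(np.zeros((3, 3)), RigidTransform.identity())


def test_composite_transform_matches_sequential(clean_run):
    *_, out = clean_run
    fres = out.filter_result
    pts = np.random.default_rng(7).normal(size=(50, 3))
    seq = fres.T2.apply(fres.T1.apply(pts))
    assert np.allclose(fres.T.apply(pts), seq, atol=1e-9)
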