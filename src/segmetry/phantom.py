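"""Synthetic supine-subject phantoms with analytic ground truth.

A phantom is a supine "subject" assembled from analytic solids — truncated
cones (limbs), elliptic cylinders (trunk, extremities) and ellipsoids (head)
— lying on a bed plane, rendered into a single overhead depth frame exactly
the way the real acquisition sees it: top surface only, z-buffered at the
depth sensor's resolution, with optional Gaussian depth noise and dropout.
Every quantity the pipeline estimates is known in closed form (per-segment
volume, length, equivalent diameter, per-pixel segment labels, 2D/3D
keypoints, bed plane), which makes the phantom the oracle for every other
module.

By default each body solid is the *half*-solid cut by the bed plane (flat
face down).  This mirrors the measurement principle: a single overhead view
closed by bottom filling can only ever recover the region between the top
surface and the bed, so the phantom's analytic truth is defined as exactly
that region.  Full solids are also supported (their hidden lower half is
simply never rendered).

World frame: X along the bed's long axis (feet -> head), Y across, Z up from
the bed surface.  Camera frame: X, Y as world, Z pointing down (increasing
away from the camera), camera at ``camera_height`` above the bed plane.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil, pi, sqrt

import numpy as np
import pandas as pd

from .camera import CameraIntrinsics, DepthFrame, depth_to_cloud, project
from .cloud import PointCloud
from .keypoints import (
    ASI_FRACTION, C7_FRACTION, T12_FRACTION,
    LimbMeasurement, ManualMeasurements, RawPoseKeypoints,
)
from .segmentation import SEGMENTS

__all__ = [
    "TruncatedCone", "EllipticCylinder", "Ellipsoid",
    "PlacedSolid", "PhantomSpec", "PhantomTruth", "PhantomRender",
    "default_spec", "generate_phantom", "phantom_cloud",
    "phantom_manual_measurements", "ellipse_perimeter",
]

BED_CODE, FLOOR_CODE, POST_CODE = len(SEGMENTS), len(SEGMENTS) + 1, len(SEGMENTS) + 2


def ellipse_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation (relative error < 1e-4 for body-like ratios)."""
    return pi * (3 * (a + b) - sqrt((3 * a + b) * (a + 3 * b)))


# ---------------------------------------------------------------------------
# analytic solids (local frame: axis along +X in [0, L], resting on z = 0)
# ---------------------------------------------------------------------------

def _segment_area_factor(t: float) -> float:
    """Area of {z >= -t*b} in a unit-area-normalized ellipse: the fraction of
    pi*a*b above a chord at depth t in [0, 1] below the centre."""
    return (pi / 2 + np.arcsin(t) + t * np.sqrt(1 - t * t)) / pi


@dataclass(frozen=True)
class TruncatedCone:
    """Circular truncated cone resting on z = 0.

    ``half=True``: the solid is the part of the cone above a horizontal cut
    plane ``sink * r_min`` below the axis (the axis sits at that height, so
    the widest visible silhouette rides above the bed, as a body segment's
    does on a mattress).  ``sink=0`` is the plain half-cone.  ``half=False``
    is the full cone, axis at ``max(r_p, r_d)``.
    """

    length: float
    r_p: float  # proximal radius (local x = 0)
    r_d: float  # distal radius (local x = L)
    half: bool = True
    sink: float = 0.0

    def radius(self, x: np.ndarray) -> np.ndarray:
        return self.r_p + (self.r_d - self.r_p) * x / self.length

    @property
    def axis_height(self) -> float:
        return self.sink * min(self.r_p, self.r_d) if self.half else max(self.r_p, self.r_d)

    @property
    def volume(self) -> float:
        v_full = self.length * pi * (self.r_p ** 2 + self.r_d ** 2 + self.r_p * self.r_d) / 3.0
        if not self.half:
            return v_full
        if self.sink == 0.0:
            return v_full / 2
        from scipy.integrate import quad
        c = self.axis_height
        area = lambda x: pi * self.radius(np.asarray(x)) ** 2 * _segment_area_factor(
            c / float(self.radius(np.asarray(x))))
        val, _ = quad(area, 0.0, self.length, epsabs=1e-12, epsrel=1e-10)
        return val

    def section(self, x: float) -> tuple[float, float]:
        r = float(self.radius(np.asarray(x)))
        return r, r

    def height_local(self, lx: np.ndarray, ly: np.ndarray) -> np.ndarray:
        r = self.radius(lx)
        with np.errstate(invalid="ignore"):
            z = np.sqrt(r ** 2 - ly ** 2)
        ok = (lx >= 0) & (lx <= self.length) & (np.abs(ly) <= r)
        return np.where(ok, self.axis_height + z, -np.inf)


@dataclass(frozen=True)
class EllipticCylinder:
    """Elliptic cylinder: cross-section semi-axes a (lateral) x b (vertical).

    ``half=True`` keeps the part above a horizontal cut ``sink * b`` below
    the centre line (``sink=0``: exact half)."""

    length: float
    a: float
    b: float
    half: bool = True
    sink: float = 0.0

    @property
    def axis_height(self) -> float:
        return self.sink * self.b if self.half else self.b

    @property
    def volume(self) -> float:
        v = pi * self.a * self.b * self.length
        return v * _segment_area_factor(self.sink) if self.half else v

    def section(self, x: float) -> tuple[float, float]:
        return self.a, self.b

    def height_local(self, lx, ly):
        with np.errstate(invalid="ignore"):
            z = self.b * np.sqrt(1 - (ly / self.a) ** 2)
        ok = (lx >= 0) & (lx <= self.length) & (np.abs(ly) <= self.a)
        return np.where(ok, self.axis_height + z, -np.inf)


@dataclass(frozen=True)
class Ellipsoid:
    """Ellipsoid with semi-axes rx (axial), ry (lateral), rz (vertical).

    ``half=True`` keeps the part above a horizontal cut ``sink * rz`` below
    the centre (``sink=0``: exact half)."""

    rx: float
    ry: float
    rz: float
    half: bool = True
    sink: float = 0.0

    @property
    def length(self) -> float:
        return 2 * self.rx

    @property
    def axis_height(self) -> float:
        return self.sink * self.rz if self.half else self.rz

    @property
    def volume(self) -> float:
        if not self.half:
            return 4.0 / 3.0 * pi * self.rx * self.ry * self.rz
        s = self.sink
        return pi * self.rx * self.ry * self.rz * (2.0 / 3.0 + s - s ** 3 / 3.0)

    def section(self, x: float) -> tuple[float, float]:
        u = np.clip(x / self.rx - 1.0, -1.0, 1.0)
        s = sqrt(max(1 - u * u, 0.0))
        return self.ry * s, self.rz * s

    def height_local(self, lx, ly):
        u = lx / self.rx - 1.0
        v = ly / self.ry
        s = 1 - u ** 2 - v ** 2
        with np.errstate(invalid="ignore"):
            z = self.rz * np.sqrt(np.clip(s, 0, None))
        return np.where(s >= 0, self.axis_height + z, -np.inf)


Solid = TruncatedCone | EllipticCylinder | Ellipsoid


@dataclass(frozen=True)
class PlacedSolid:
    """A solid placed in the world XY plane: local +X along ``direction``."""

    solid: Solid
    origin: tuple[float, float]
    direction: tuple[float, float] = (1.0, 0.0)

    def _axes(self):
        d = np.asarray(self.direction, float)
        d = d / np.linalg.norm(d)
        return d, np.array([-d[1], d[0]])

    def to_world(self, local: np.ndarray) -> np.ndarray:
        d, n = self._axes()
        o = np.asarray(self.origin, float)
        xy = o + np.outer(local[:, 0], d) + np.outer(local[:, 1], n)
        return np.column_stack([xy, local[:, 2]])

    def height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Top-surface height above the bed at world (x, y); -inf outside."""
        d, n = self._axes()
        o = np.asarray(self.origin, float)
        dx, dy = np.asarray(x, float) - o[0], np.asarray(y, float) - o[1]
        return self.solid.height_local(dx * d[0] + dy * d[1], dx * n[0] + dy * n[1])

    def sample_top(self, spacing: float) -> np.ndarray:
        """Quasi-uniform sample of the camera-visible surface (local frame).

        Samples down to the bed cut; sub-equator overhang points are included
        and lose to the top surface in the z-buffer, like a real camera.
        """
        s = self.solid
        c = s.axis_height
        if isinstance(s, Ellipsoid):
            v_max = pi / 2 + (np.arcsin(s.sink) if s.half else 0.0)
            rows = max(4, ceil(v_max * s.rz / spacing))
            pts = [np.array([[s.rx, 0.0, c + s.rz]])]
            for v in np.linspace(0, v_max, rows, endpoint=True)[1:]:
                ring_a, ring_b = s.ry * np.sin(v), s.rx * np.sin(v)
                n_u = max(8, ceil(ellipse_perimeter(ring_a, ring_b) / spacing))
                u = np.linspace(0, 2 * pi, n_u, endpoint=False)
                pts.append(np.column_stack([
                    s.rx + s.rx * np.sin(v) * np.cos(u),
                    s.ry * np.sin(v) * np.sin(u),
                    np.full(n_u, c + s.rz * np.cos(v)),
                ]))
            return np.concatenate(pts)
        n_x = max(2, ceil(s.length / spacing) + 1)
        out = []
        for x in np.linspace(0.0, s.length, n_x):
            a, b = s.section(x)
            if a <= 0 or b <= 0:
                out.append(np.array([[x, 0.0, c]]))
                continue
            t = min(c / b, 1.0) if s.half else 0.0
            phi0 = np.arcsin(t)
            n_t = max(6, ceil(ellipse_perimeter(a, b) * (0.5 + phi0 / pi) / spacing))
            phi = np.linspace(-phi0, pi + phi0, n_t)
            out.append(np.column_stack([
                np.full(n_t, x), a * np.cos(phi), c + b * np.sin(phi)
            ]))
        return np.concatenate(out)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

def _default_intrinsics() -> CameraIntrinsics:
    # NFOV-unbinned-like geometry: 640x576 px over ~75x65 degrees
    return CameraIntrinsics(fx=417.0, fy=452.0, cx=320.0, cy=288.0,
                            width=640, height=576)


@dataclass
class PhantomSpec:
    """Scene description: body solids, joints, bed, camera, noise."""

    segments: dict[str, PlacedSolid]
    joints: dict[str, tuple[float, float]]     # raw landmark name -> world XY
    bed_center: tuple[float, float] = (0.97, 0.0)
    bed_size: tuple[float, float] = (2.06, 1.06)
    camera_height: float = 1.55                # camera to bed plane (m)
    floor_offset: float = 0.45                 # bed plane to floor (m)
    intrinsics: CameraIntrinsics = field(default_factory=_default_intrinsics)
    bed_tilt_deg: float = 0.0                  # rotation about world X
    bed_yaw_deg: float = 0.0                   # in-plane rotation about Z
    noise_sigma: float = 0.0                   # depth noise (m)
    dropout: float = 0.0                       # invalid-pixel fraction
    body_spacing: float = 0.0025               # surface sampling step (m)
    bed_spacing: float = 0.004
    seed: int = 0
    posts: bool = True                         # frame posts outside the bed

    def surface_height(self, x, y) -> np.ndarray:
        """Max top-surface height over all solids; 0 on the bare bed."""
        h = np.full(np.shape(x), 0.0)
        for ps in self.segments.values():
            h = np.maximum(h, ps.height(x, y))
        return h


@dataclass
class PhantomTruth:
    segments: pd.DataFrame          # label, volume_m3, length_m, eq_diameter_m
    labels_px: np.ndarray           # (H, W) int16 codes; -1 empty
    label_names: list[str]
    raw_keypoints: RawPoseKeypoints
    kp3d: dict[str, np.ndarray]     # landmark name -> camera-frame xyz (m)
    bed_point_cam: np.ndarray
    bed_normal_cam: np.ndarray      # unit, pointing away from the camera
    bed_tilt_deg: float
    bed_yaw_deg: float


@dataclass
class PhantomRender:
    depth: DepthFrame
    intrinsics: CameraIntrinsics
    truth: PhantomTruth


def default_spec(**overrides) -> PhantomSpec:
    """A ~1.86 m supine phantom proportioned like the study cohort.

    Segment interfaces coincide with the cut lines the vertebral-keypoint
    construction produces (neck, C7, T12, mid-ASI, mid-hip) so that the
    per-pixel truth labels are directly comparable with the pipeline's
    enclosing-polygon assignment.
    """
    x_hip, x_sh = 1.14, 1.615
    w_hip = 0.34
    mid_body = x_sh - x_hip
    x_asi = x_hip + ASI_FRACTION * w_hip          # mid-ASI cut
    x_t12 = x_asi + T12_FRACTION * mid_body       # T12 cut
    x_c7 = x_sh + C7_FRACTION * mid_body          # C7 cut
    y_hip, y_sh, y_el = 0.10, 0.22, 0.23

    sink = 0.25  # solids bulge past the mattress contact, like real tissue
    segs: dict[str, PlacedSolid] = {
        "pelvis": PlacedSolid(EllipticCylinder(x_asi - x_hip, 0.17, 0.095, sink=sink), (x_hip, 0.0)),
        "abdomen": PlacedSolid(EllipticCylinder(x_t12 - x_asi, 0.15, 0.10, sink=sink), (x_asi, 0.0)),
        "thorax": PlacedSolid(EllipticCylinder(x_sh - x_t12, 0.16, 0.11, sink=sink), (x_t12, 0.0)),
        # 1 cm neck dip between the shoulder mass and the skull
        "shoulders": PlacedSolid(EllipticCylinder(x_c7 - x_sh - 0.01, 0.24, 0.10, sink=sink), (x_sh, 0.0)),
        "head": PlacedSolid(Ellipsoid(0.10, 0.085, 0.09, sink=sink), (x_c7, 0.0)),
    }
    for sign, side in ((1.0, "left"), (-1.0, "right")):
        sh = (x_sh, sign * y_sh)
        el = (1.34, sign * y_el)
        wr = (1.075, sign * y_el)
        arm_l = float(np.hypot(el[0] - sh[0], el[1] - sh[1]))
        segs[f"{side}_arm"] = PlacedSolid(
            TruncatedCone(arm_l, 0.045, 0.040, sink=sink), sh,
            ((el[0] - sh[0]) / arm_l, (el[1] - sh[1]) / arm_l))
        segs[f"{side}_forearm"] = PlacedSolid(
            TruncatedCone(el[0] - wr[0], 0.040, 0.028, sink=sink), el, (-1.0, 0.0))
        segs[f"{side}_hand"] = PlacedSolid(
            EllipticCylinder(0.19, 0.035, 0.03, sink=sink), wr, (-1.0, 0.0))
        segs[f"{side}_thigh"] = PlacedSolid(
            TruncatedCone(0.45, 0.075, 0.055, sink=sink), (x_hip, sign * y_hip), (-1.0, 0.0))
        segs[f"{side}_shank"] = PlacedSolid(
            TruncatedCone(0.43, 0.052, 0.035, sink=sink), (0.69, sign * y_hip), (-1.0, 0.0))
        segs[f"{side}_foot"] = PlacedSolid(
            EllipticCylinder(0.22, 0.04, 0.040, sink=sink), (0.26, sign * y_hip), (-1.0, 0.0))

    # shoulder/hip landmarks sit a few mm inside the arm/thigh so the depth
    # read under a pose landmark comes from one smooth surface, as it does
    # for a real joint centre over muscle mass
    joints = {"nose": (x_c7 + 0.10, 0.0)}
    for sign, side in ((1.0, "left"), (-1.0, "right")):
        joints[f"{side}_shoulder"] = (x_sh - 0.006, sign * y_sh)
        joints[f"{side}_elbow"] = (1.34, sign * y_el)
        joints[f"{side}_wrist"] = (1.075, sign * y_el)
        joints[f"{side}_hip"] = (x_hip - 0.006, sign * y_hip)
        joints[f"{side}_knee"] = (0.69, sign * y_hip)
        joints[f"{side}_ankle"] = (0.26, sign * y_hip)

    spec = PhantomSpec(segments=segs, joints=joints)
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _scene_rotation(spec: PhantomSpec) -> np.ndarray:
    tilt, yaw = np.radians(spec.bed_tilt_deg), np.radians(spec.bed_yaw_deg)
    cx_, sx_ = np.cos(tilt), np.sin(tilt)
    cz, sz = np.cos(yaw), np.sin(yaw)
    Rx = np.array([[1, 0, 0], [0, cx_, -sx_], [0, sx_, cx_]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Rx


def _world_to_cam(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Apply the bed tilt/yaw about the bed centre, then world -> camera."""
    R = _scene_rotation(spec)
    c = np.array([*spec.bed_center, 0.0])
    w = (points - c) @ R.T + c
    return np.column_stack([
        w[:, 0] - spec.bed_center[0],
        w[:, 1] - spec.bed_center[1],
        spec.camera_height - w[:, 2],
    ])


def _grid(x0, x1, y0, y1, z, spacing) -> np.ndarray:
    xs = np.arange(x0, x1 + spacing / 2, spacing)
    ys = np.arange(y0, y1 + spacing / 2, spacing)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, z)])


def generate_phantom(spec: PhantomSpec) -> PhantomRender:
    """Render the phantom scene into a depth frame with per-pixel truth."""
    for name in spec.segments:
        if name not in SEGMENTS:
            raise ValueError(f"unknown segment label {name!r} in spec")
    intr = spec.intrinsics
    H, W = intr.height, intr.width
    rng = np.random.default_rng(spec.seed)

    samples: list[np.ndarray] = []
    codes: list[np.ndarray] = []
    seg_rows = []
    for name, ps in spec.segments.items():
        pts = ps.to_world(ps.sample_top(spec.body_spacing))
        samples.append(pts)
        codes.append(np.full(len(pts), SEGMENTS.index(name), dtype=np.int16))
        s = ps.solid
        seg_rows.append({
            "label": name,
            "volume_m3": s.volume,
            "length_m": s.length,
            "eq_diameter_m": sqrt(4 * s.volume / (pi * s.length)),
        })
    bx, by = spec.bed_center
    lx, ly = spec.bed_size
    bed = _grid(bx - lx / 2, bx + lx / 2, by - ly / 2, by + ly / 2, 0.0, spec.bed_spacing)
    samples.append(bed)
    codes.append(np.full(len(bed), BED_CODE, dtype=np.int16))
    floor = _grid(bx - 1.7, bx + 1.7, by - 1.45, by + 1.45,
                  -spec.floor_offset, 0.02)
    samples.append(floor)
    codes.append(np.full(len(floor), FLOOR_CODE, dtype=np.int16))
    if spec.posts:
        for sx in (-1, 1):
            for sy in (-1, 1):
                zs = np.arange(-spec.floor_offset, -0.02, 0.01)
                post = np.column_stack([
                    np.full(len(zs), bx + sx * (lx / 2 + 0.06)),
                    np.full(len(zs), by + sy * (ly / 2 + 0.06)), zs])
                samples.append(post)
                codes.append(np.full(len(post), POST_CODE, dtype=np.int16))

    world = np.concatenate(samples)
    code = np.concatenate(codes)
    cam = _world_to_cam(world, spec)
    ok = cam[:, 2] > 0.05
    cam, code = cam[ok], code[ok]
    uv = project(cam, intr)
    ui = np.round(uv[:, 0]).astype(int)
    vi = np.round(uv[:, 1]).astype(int)
    ok = (ui >= 0) & (ui < W) & (vi >= 0) & (vi < H)
    ui, vi, cam, code = ui[ok], vi[ok], cam[ok], code[ok]

    # z-buffer pass 1: the closest sample decides which object owns the pixel
    order = np.argsort(-cam[:, 2], kind="stable")
    labels = np.full((H, W), -1, dtype=np.int16)
    labels[vi[order], ui[order]] = code[order]
    # pass 2: pixel depth = mean depth of the owning object's in-pixel samples
    # (a ToF pixel integrates over its footprint; resolving mixed boundary
    # pixels to the foreground object avoids a skirt of floating points)
    own = labels[vi, ui] == code
    flat = vi[own] * W + ui[own]
    zsum = np.zeros(H * W)
    zcnt = np.zeros(H * W)
    np.add.at(zsum, flat, cam[own, 2])
    np.add.at(zcnt, flat, 1.0)
    zbuf = np.zeros((H, W))
    hit = zcnt > 0
    zbuf.ravel()[hit] = zsum[hit] / zcnt[hit]

    valid = zbuf > 0
    depth_m = zbuf.copy()
    if spec.noise_sigma > 0:
        depth_m[valid] += rng.normal(0.0, spec.noise_sigma, int(valid.sum()))
    if spec.dropout > 0:
        drop = rng.random((H, W)) < spec.dropout
        valid &= ~drop
    data = np.where(valid, np.round(depth_m / intr.depth_scale), 0).astype(np.uint16)
    labels[~valid] = -1
    depth = DepthFrame(data)

    # keypoint truth: joints on the analytic top surface, scene-transformed
    kp3d: dict[str, np.ndarray] = {}
    raw_lm: dict[str, tuple[float, float, float]] = {}
    for name, (jx, jy) in spec.joints.items():
        z = float(spec.surface_height(np.array([jx]), np.array([jy]))[0])
        p_cam = _world_to_cam(np.array([[jx, jy, z]]), spec)[0]
        kp3d[name] = p_cam
        u, v = project(p_cam, intr)
        raw_lm[name] = (float(u), float(v), 1.0)

    n_bed = _world_to_cam(np.array([[bx, by, 1.0]]), spec)[0] - _world_to_cam(
        np.array([[bx, by, 0.0]]), spec)[0]
    n_bed /= np.linalg.norm(n_bed)
    if n_bed[2] < 0:
        n_bed = -n_bed  # report the away-from-camera orientation
    truth = PhantomTruth(
        segments=pd.DataFrame(seg_rows),
        labels_px=labels,
        label_names=list(SEGMENTS) + ["bed", "floor", "post"],
        raw_keypoints=RawPoseKeypoints(raw_lm, image_size=(W, H)),
        kp3d=kp3d,
        bed_point_cam=_world_to_cam(np.array([[bx, by, 0.0]]), spec)[0],
        bed_normal_cam=n_bed,
        bed_tilt_deg=spec.bed_tilt_deg,
        bed_yaw_deg=spec.bed_yaw_deg,
    )
    return PhantomRender(depth=depth, intrinsics=intr, truth=truth)


def phantom_cloud(render: PhantomRender) -> PointCloud:
    """Point cloud of the rendered depth frame with per-point truth labels."""
    pc = depth_to_cloud(render.depth, render.intrinsics)
    vv, uu = np.nonzero(render.depth.valid)
    pc.labels = render.truth.labels_px[vv, uu]
    return pc


# ---------------------------------------------------------------------------
# analytic manual measurements
# ---------------------------------------------------------------------------

def _section_perimeter(solid: Solid, x: float) -> float:
    a, b = solid.section(x)
    return ellipse_perimeter(a, b)


def phantom_manual_measurements(spec: PhantomSpec, table=None) -> ManualMeasurements:
    """Tape-measure equivalents computed analytically from the solids.

    Circumferences are those of the full (mirrored) cross-section, matching
    how a tape wraps a real limb even though the phantom solid is the half
    cut by the bed plane.
    """
    segs = spec.segments
    limbs: dict[str, LimbMeasurement] = {}
    for side in ("left", "right"):
        for part in ("arm", "forearm", "thigh", "shank"):
            s = segs[f"{side}_{part}"].solid
            limbs[f"{part}_{side}"] = LimbMeasurement(
                L=s.length,
                O_p=_section_perimeter(s, 0.0),
                O_d=_section_perimeter(s, s.length),
            )
    head, thorax = segs["head"].solid, segs["thorax"].solid
    abdomen, pelvis = segs["abdomen"].solid, segs["pelvis"].solid
    hand, foot = segs["left_hand"].solid, segs["left_foot"].solid
    shank = segs["left_shank"].solid
    x_sh = segs["shoulders"].origin[0]
    x_hip = segs["pelvis"].origin[0]
    mid_body = x_sh - x_hip
    x_head_tip = segs["head"].origin[0] + head.length
    x_heel = segs["left_foot"].origin[0] - foot.length
    height = x_head_tip - x_heel

    if table is None:
        from .anthro import AnthropometricTable
        table = AnthropometricTable.default()
    mass = sum(ps.solid.volume * table.density(name) for name, ps in segs.items())

    d_sh = abs(spec.joints["left_shoulder"][1] - spec.joints["right_shoulder"][1])
    return ManualMeasurements(
        H_subject=height,
        M_subject=mass,
        L_head=head.length,
        O_head=ellipse_perimeter(head.ry, head.rz),
        limbs=limbs,
        L_trunk=(x_sh - segs["thorax"].origin[0]) + C7_FRACTION * mid_body,
        D_shoulders=d_sh,
        W_sternum=2 * thorax.a,
        O_chest=ellipse_perimeter(thorax.a, thorax.b),
        O_sternum=0.98 * ellipse_perimeter(thorax.a, thorax.b),
        L_abdomen=abdomen.length,
        W_T10=2 * abdomen.a,
        O_T10=ellipse_perimeter(abdomen.a, abdomen.b),
        D_asi=0.24,
        O_asi=ellipse_perimeter(pelvis.a, pelvis.b),
        W_hip=2 * pelvis.a,
        W_troch=2 * pelvis.b,
        D_asi_troch=pelvis.b,
        L_hand=hand.length,
        W_hand=2 * hand.a,
        L_foot=foot.length,
        W_foot=2 * foot.a,
        H_foot=foot.b,
        O_ankle=_section_perimeter(shank, shank.length),
    )
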