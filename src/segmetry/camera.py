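"""Pinhole unprojection of pixel keypoints and depth frames into metric 3D.

The proprietary camera-SDK registration is replaced by its standard open
equivalent: depth frames are assumed to be registered to the colour frame,
and a generic pinhole model with Brown-Conrady distortion (rational model,
k1..k6, p1, p2) maps between pixels and camera-frame metres.  Undistortion
is iterative (fixed point on the distortion map, tolerance 1e-6 px).

Camera frame convention: X right, Y down in the image, Z along the optical
axis *away* from the camera.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from PIL import Image

__all__ = [
    "CameraIntrinsics",
    "DepthFrame",
    "project",
    "unproject",
    "undistort_pixels",
    "keypoints_to_3d",
    "depth_to_cloud",
    "NoDepthError",
]

from .cloud import PointCloud
from .keypoints import BiomechKeypoints


class NoDepthError(ValueError):
    """No valid depth return available at/near the requested pixel."""


@dataclass
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    # Brown-Conrady rational distortion; all zero = ideal pinhole.
    k1: float = 0.0
    k2: float = 0.0
    k3: float = 0.0
    k4: float = 0.0
    k5: float = 0.0
    k6: float = 0.0
    p1: float = 0.0
    p2: float = 0.0
    depth_scale: float = 0.001  # metres per stored depth unit (16-bit mm PNG)
    width: int | None = None
    height: int | None = None

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if self.depth_scale <= 0:
            raise ValueError("depth_scale must be positive")

    @property
    def has_distortion(self) -> bool:
        return any((self.k1, self.k2, self.k3, self.k4, self.k5, self.k6, self.p1, self.p2))

    def distort_normalized(self, xn: np.ndarray, yn: np.ndarray):
        """Apply the distortion map to normalized camera coordinates."""
        r2 = xn * xn + yn * yn
        radial = (1 + r2 * (self.k1 + r2 * (self.k2 + r2 * self.k3))) / (
            1 + r2 * (self.k4 + r2 * (self.k5 + r2 * self.k6))
        )
        xd = xn * radial + 2 * self.p1 * xn * yn + self.p2 * (r2 + 2 * xn * xn)
        yd = yn * radial + self.p1 * (r2 + 2 * yn * yn) + 2 * self.p2 * xn * yn
        return xd, yd

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def load(cls, path) -> "CameraIntrinsics":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: v for k, v in vars(self).items() if v is not None}, fh)


@dataclass
class DepthFrame:
    """H x W grid of stored depth units with a validity mask (0 = no return)."""

    data: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]
    operating_range: tuple[float, float] = (0.5, 3.86)  # metres

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("depth frame must be 2D")
        if self.valid is None:
            self.valid = self.data > 0
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("validity mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def depth_m(self, intr: CameraIntrinsics) -> np.ndarray:
        return self.data.astype(float) * intr.depth_scale

    @classmethod
    def load(cls, path) -> "DepthFrame":
        """Read a 16-bit single-channel PNG (stored units, usually mm)."""
        img = Image.open(path)
        arr = np.asarray(img)
        if arr.ndim != 2:
            raise ValueError("expected single-channel depth PNG")
        return cls(arr.astype(np.uint16))

    def save(self, path) -> None:
        arr = np.where(self.valid, self.data, 0).astype(np.uint16)
        Image.fromarray(arr).save(path)


def project(points: np.ndarray, intr: CameraIntrinsics) -> np.ndarray:
    """Camera-frame 3D points -> distorted pixel coordinates (u, v)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    if np.any(p[:, 2] <= 0):
        raise ValueError("cannot project points at or behind the camera (Z <= 0)")
    xn, yn = p[:, 0] / p[:, 2], p[:, 1] / p[:, 2]
    xd, yd = intr.distort_normalized(xn, yn)
    uv = np.stack([xd * intr.fx + intr.cx, yd * intr.fy + intr.cy], axis=1)
    return uv[0] if np.asarray(points).ndim == 1 else uv


def undistort_pixels(
    u: np.ndarray, v: np.ndarray, intr: CameraIntrinsics,
    tol: float = 1e-6, max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Distorted pixels -> ideal (undistorted) normalized coordinates.

    Fixed-point iteration on the distortion map; converges in a few steps for
    the moderate distortions of consumer depth cameras.  ``tol`` is in pixels.
    """
    xd = (np.asarray(u, dtype=float) - intr.cx) / intr.fx
    yd = (np.asarray(v, dtype=float) - intr.cy) / intr.fy
    if not intr.has_distortion:
        return xd, yd
    xn, yn = xd.copy(), yd.copy()
    f = max(intr.fx, intr.fy)
    for _ in range(max_iter):
        xe, ye = intr.distort_normalized(xn, yn)
        dx, dy = xe - xd, ye - yd
        xn, yn = xn - dx, yn - dy
        if np.max(np.hypot(dx, dy)) * f < tol:
            break
    return xn, yn


def unproject(u, v, d, intr: CameraIntrinsics) -> np.ndarray:
    """Pixel (u, v) at metric depth ``d`` -> camera-frame 3D point (m).

    X = x_n * d, Y = y_n * d, Z = d, with (x_n, y_n) the undistorted
    normalized coordinates of the pixel.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise NoDepthError("no depth return (d <= 0)")
    xn, yn = undistort_pixels(np.asarray(u, float), np.asarray(v, float), intr)
    pts = np.stack([xn * d, yn * d, np.broadcast_to(d, np.shape(xn))], axis=-1)
    return pts


def _fallback_depth(depth: DepthFrame, u: int, v: int, max_window: int = 9) -> float:
    """Median of valid depths in a growing square window (3x3 -> max_window)."""
    H, W = depth.shape
    for half in range(1, max_window // 2 + 1):
        r0, r1 = max(v - half, 0), min(v + half + 1, H)
        c0, c1 = max(u - half, 0), min(u + half + 1, W)
        patch = depth.data[r0:r1, c0:c1]
        ok = depth.valid[r0:r1, c0:c1]
        if ok.any():
            return float(np.median(patch[ok]))
    raise NoDepthError(f"no valid depth within {max_window}x{max_window} of ({u}, {v})")


def keypoints_to_3d(
    kps: BiomechKeypoints, depth: DepthFrame, intr: CameraIntrinsics,
    window: int = 5,
) -> BiomechKeypoints:
    """Unproject pixel-frame keypoints to camera-frame metres.

    Each keypoint's depth is the median of the valid depths in a
    ``window`` x ``window`` neighbourhood — a single-pixel read would be at
    the mercy of sensor noise and dropout, and a centimetre depth error
    shifts the unprojected joint (hence every cut line derived from it)
    laterally.  If the window is empty it grows (up to 9x9) before a per-KP
    error is raised.
    """
    if kps.frame != "pixel":
        raise ValueError(f"expected pixel-frame keypoints, got {kps.frame!r}")
    H, W = depth.shape
    half = max(window // 2, 0)
    new: dict[str, np.ndarray] = {}
    for name, (u, v) in kps.kp.items():
        ui, vi = int(round(u)), int(round(v))
        ui, vi = min(max(ui, 0), W - 1), min(max(vi, 0), H - 1)
        patch = depth.data[max(vi - half, 0):vi + half + 1, max(ui - half, 0):ui + half + 1]
        ok = depth.valid[max(vi - half, 0):vi + half + 1, max(ui - half, 0):ui + half + 1]
        if ok.any():
            d = float(np.median(patch[ok]))
        else:
            try:
                d = _fallback_depth(depth, ui, vi)
            except NoDepthError as err:
                raise NoDepthError(f"keypoint {name}: {err}") from None
        new[name] = unproject(u, v, d * intr.depth_scale, intr)
    return BiomechKeypoints(new, frame="camera_metric", low_visibility=set(kps.low_visibility))


def depth_to_cloud(
    depth: DepthFrame, intr: CameraIntrinsics, color: np.ndarray | None = None
) -> PointCloud:
    """One 3D point per valid depth pixel (row-major pixel order)."""
    if not depth.valid.any():
        raise NoDepthError("empty depth frame")
    vv, uu = np.nonzero(depth.valid)
    d = depth.data[vv, uu].astype(float) * intr.depth_scale
    pts = unproject(uu.astype(float), vv.astype(float), d, intr)
    colors = color[vv, uu] if color is not None else None
    return PointCloud(pts, colors=colors, frame="camera_metric")
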