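"""Point-cloud and rigid-transform containers shared by every pipeline stage.

Coordinates are metres. The camera frame has Z increasing *away* from the
camera (the camera hangs above the bed and looks down), so the bed plane sits
at the largest Z values of the scene and the subject's body at smaller Z.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

__all__ = ["PointCloud", "RigidTransform", "FrameError"]

#: Allowed frame tags, in pipeline order.
FRAMES = ("pixel", "camera_metric", "bed_aligned")


class FrameError(ValueError):
    """Raised when an operation receives data in an incompatible frame."""


@dataclass
class PointCloud:
    """N x 3 metric point set with an optional colour channel and labels.

    ``labels`` is only populated by the phantom generator (per-point ground
    truth segment index); real acquisitions carry ``labels=None``.
    """

    points: np.ndarray
    colors: np.ndarray | None = None
    labels: np.ndarray | None = None
    frame: str = "camera_metric"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (N, 3), got {self.points.shape}")
        if self.frame not in FRAMES:
            raise FrameError(f"unknown frame {self.frame!r}")
        for name in ("colors", "labels"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != len(self.points):
                raise ValueError(f"{name} length {len(arr)} != points {len(self.points)}")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, mask: np.ndarray) -> "PointCloud":
        """Return a sub-cloud; carries colours/labels along."""
        return PointCloud(
            self.points[mask],
            None if self.colors is None else self.colors[mask],
            None if self.labels is None else self.labels[mask],
            self.frame,
        )

    def transformed(self, T: "RigidTransform", frame: str | None = None) -> "PointCloud":
        pts = T.apply(self.points)
        out = replace(self, points=pts)
        if frame is not None:
            out.frame = frame
        return out

    # -- I/O ---------------------------------------------------------------
    def save(self, path) -> None:
        """Write PLY (binary little-endian) via trimesh."""
        trimesh.PointCloud(self.points, colors=self.colors).export(path)

    @classmethod
    def load(cls, path, frame: str = "camera_metric") -> "PointCloud":
        loaded = trimesh.load(path)
        colors = None
        if hasattr(loaded, "colors") and loaded.colors is not None and len(loaded.colors):
            colors = np.asarray(loaded.colors)[:, :3]
        return cls(np.asarray(loaded.vertices, dtype=float), colors, frame=frame)


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid map (proper rotation + translation)."""

    matrix: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", M)
        if M.shape != (4, 4):
            raise ValueError("rigid transform must be 4x4")
        R = M[:3, :3]
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block has det -1 (reflection)")
        if not np.allclose(M[3], [0, 0, 0, 1]):
            raise ValueError("last row must be [0, 0, 0, 1]")

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_rotation(cls, R: np.ndarray, center: np.ndarray | None = None) -> "RigidTransform":
        """Rotation about ``center`` (defaults to the origin)."""
        M = np.eye(4)
        M[:3, :3] = R
        if center is not None:
            c = np.asarray(center, dtype=float)
            M[:3, 3] = c - R @ c
        return cls(M)

    @classmethod
    def from_translation(cls, t: np.ndarray) -> "RigidTransform":
        M = np.eye(4)
        M[:3, 3] = np.asarray(t, dtype=float)
        return cls(M)

    def then(self, other: "RigidTransform") -> "RigidTransform":
        """Composite map: apply ``self`` first, then ``other``."""
        return RigidTransform(other.matrix @ self.matrix)

    def inverse(self) -> "RigidTransform":
        R = self.rotation.T
        return RigidTransform.from_rotation(R).then(
            RigidTransform.from_translation(-R @ self.translation)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        out = p @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    # -- I/O ---------------------------------------------------------------
    def save(self, path) -> None:
        np.savetxt(path, self.matrix, fmt="%.17g")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls(np.loadtxt(path))


def rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking unit vector ``a`` onto unit vector ``b``."""
    a = np.asarray(a, float) / np.linalg.norm(a)
    b = np.asarray(b, float) / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any axis orthogonal to a
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        K = _skew(axis)
        return np.eye(3) + 2.0 * K @ K
    K = _skew(v)
    return np.eye(3) + K + K @ K * (1.0 / (1.0 + c))


def _skew(v: np.ndarray) -> np.ndarray:
    return np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]], dtype=float)
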