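"""Scene filtering: isolate the subject's body and align the bed to the axes.

Stages (in order), starting from the raw camera-frame cloud:

1. ``coarse_filter``       - crop to the bed's padded XY footprint, then drop
                             everything deeper than mean(Z) + z_padding
                             (floor, surrounding clutter).
2. ``fit_bed_plane``       - seeded RANSAC plane fit; T1 is the minimal
                             rotation bringing the bed normal onto the Z axis.
3. ``align_bed_axes``      - uniform Monte Carlo fill of the bed footprint,
                             PCA of the fill; T2 rotates the in-plane
                             principal axes onto X (long side) and Y.
4. ``remove_bed_and_clean``- drop bed-plane inliers and everything beyond
                             them, then statistical outlier removal and
                             radius denoising; the result is the body-only
                             open surface (PCfine).

The composite T = T1 then T2 is also applied to the 3D keypoints so that
segmentation can work in the bed-aligned XY projection.  Z still increases
away from the camera, so the bed plane is the *maximum* Z of the scene and
the body rises toward smaller Z.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

from .cloud import PointCloud, RigidTransform, rotation_between
from .keypoints import BiomechKeypoints

__all__ = [
    "FilterConfig",
    "coarse_filter",
    "fit_bed_plane",
    "align_bed_axes",
    "remove_bed_and_clean",
    "apply_transform",
    "filter_cloud",
    "FilterResult",
    "EmptyCloudError",
    "NoPlaneError",
]

log = logging.getLogger(__name__)


class EmptyCloudError(ValueError):
    pass


def replace_points(pc: PointCloud, points: np.ndarray) -> PointCloud:
    return PointCloud(points, pc.colors, pc.labels, pc.frame)


class NoPlaneError(ValueError):
    pass


@dataclass
class FilterConfig:
    #: half-extents (m) of the XY area of interest, centred on the cloud's
    #: XY median.  The default covers the bed's half-diagonal (so an
    #: in-plane-rotated bed survives intact) plus a small margin; the
    #: surrounding frame/floor is discarded.  Set to None to fall back to
    #: min/max-minus-padding cropping.
    crop_half_extent: tuple[float, float] | None = (1.21, 1.21)
    #: m trimmed off each side of the raw XY span (used when
    #: crop_half_extent is None; scalar or per-axis pair)
    xy_padding: float | tuple[float, float] = 0.45
    z_padding: float = 0.40           # m beyond mean Z; deeper points discarded
    ransac_distance: float = 0.01     # m plane inlier threshold
    ransac_iterations: int = 200
    min_inlier_fraction: float = 0.2  # below this the plane fit is rejected
    outlier_k: int = 20               # statistical outlier removal neighbours
    #: isolated returns sit many sigma out in mean k-NN distance, while the
    #: sparsely sampled grazing-incidence silhouette of the body is real
    #: signal only ~2-3 sigma out; 6.0 keeps the silhouette and still
    #: rejects isolated points.
    outlier_std_ratio: float = 6.0
    denoise_radius: float = 0.02      # m radius denoising
    denoise_min_neighbors: int = 5
    #: depth denoising: each point's Z is replaced by the median Z of its k
    #: nearest neighbours (0 disables).  The camera noise is along the view
    #: axis, and an envelope-following surface reconstruction would otherwise
    #: ride the positive noise extremes.
    smooth_k: int = 9
    #: flying-pixel trim: points more than this far above the median Z of
    #: their trim_k neighbours are dropped (0 disables).
    trim_tol: float = 0.002
    trim_k: int = 25
    pca_fill_n: int = 1_000_000       # Monte Carlo points filling the bed footprint
    seed: int = 0                     # mandatory for reproducible RANSAC/fill

    def __post_init__(self) -> None:
        if isinstance(self.xy_padding, (int, float)):
            self.xy_padding = (float(self.xy_padding), float(self.xy_padding))
        else:
            self.xy_padding = (float(self.xy_padding[0]), float(self.xy_padding[1]))
        if min(self.xy_padding) <= 0:
            raise ValueError("xy_padding must be positive")
        for name in ("z_padding", "ransac_distance", "denoise_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FilterResult:
    """Everything downstream stages need from the filtering pass."""

    cloud: PointCloud                 # PCfine, bed_aligned
    T1: RigidTransform
    T2: RigidTransform
    bed_z: float                      # bed plane Z in the aligned frame
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def T(self) -> RigidTransform:
        return self.T1.then(self.T2)


def coarse_filter(pc: PointCloud, cfg: FilterConfig) -> PointCloud:
    """Crop to the padded bed footprint and cut deep (floor) points."""
    if len(pc) == 0:
        raise EmptyCloudError("empty input cloud")
    p = pc.points
    if cfg.crop_half_extent is not None:
        # fixed-size area of interest on the robust centre: re-applying the
        # crop is a no-op (median stays put once the margins are gone)
        center = np.median(p[:, :2], axis=0)
        half = np.asarray(cfg.crop_half_extent)
        mask = np.all(np.abs(p[:, :2] - center) <= half, axis=1)
    else:
        pad = np.asarray(cfg.xy_padding)
        lo = p[:, :2].min(axis=0) + pad
        hi = p[:, :2].max(axis=0) - pad
        mask = np.all((p[:, :2] >= lo) & (p[:, :2] <= hi), axis=1)
    if not mask.any():
        raise EmptyCloudError("no subject/bed found inside the padded XY area")
    z_cut = p[mask, 2].mean() + cfg.z_padding
    mask &= p[:, 2] <= z_cut
    out = pc.select(mask)
    if len(out) == 0:
        raise EmptyCloudError("no subject/bed found below the Z cutoff")
    log.info("coarse filter: %d -> %d points (z cutoff %.3f m)", len(pc), len(out), z_cut)
    return out


def _ransac_plane(
    points: np.ndarray, threshold: float, iterations: int, rng: np.random.Generator
) -> tuple[np.ndarray, float, np.ndarray]:
    """Seeded 3-point RANSAC plane with SVD refinement on the inlier set.

    Returns (unit normal with n_z >= 0, plane offset d with n.p = d, inlier mask).
    """
    n_pts = len(points)
    if n_pts < 3:
        raise NoPlaneError("fewer than 3 points")
    best_mask = None
    best_count = -1
    for _ in range(iterations):
        idx = rng.choice(n_pts, size=3, replace=False)
        a, b, c = points[idx]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        dist = np.abs((points - a) @ n)
        mask = dist < threshold
        count = int(mask.sum())
        if count > best_count:
            best_count, best_mask = count, mask
    if best_mask is None:
        raise NoPlaneError("RANSAC found no valid plane hypothesis")
    # refine: total least squares on inliers (two passes to stabilise the set)
    for _ in range(2):
        inl = points[best_mask]
        centroid = inl.mean(axis=0)
        _, _, vt = np.linalg.svd(inl - centroid, full_matrices=False)
        n = vt[-1]
        if n[2] < 0:
            n = -n
        d = float(n @ centroid)
        best_mask = np.abs(points @ n - d) < threshold
    return n, d, best_mask


def fit_bed_plane(
    pc: PointCloud, cfg: FilterConfig, rng: np.random.Generator | None = None
) -> tuple[RigidTransform, PointCloud]:
    """RANSAC-fit the dominant (bed) plane and rotate its normal onto +Z."""
    rng = rng or np.random.default_rng(cfg.seed)
    n, _, mask = _ransac_plane(pc.points, cfg.ransac_distance, cfg.ransac_iterations, rng)
    frac = mask.mean()
    if frac < cfg.min_inlier_fraction:
        raise NoPlaneError(f"no dominant plane: inlier fraction {frac:.2f}")
    center = pc.points[mask].mean(axis=0)
    T1 = RigidTransform.from_rotation(rotation_between(n, [0.0, 0.0, 1.0]), center=center)
    log.info("bed plane: %.0f%% inliers, normal %s", 100 * frac, np.round(n, 4))
    return T1, pc.transformed(T1)


def _bed_inlier_mask(points: np.ndarray, cfg: FilterConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Plane inliers of an already Z-aligned cloud, plus the plane Z."""
    n, d, mask = _ransac_plane(points, cfg.ransac_distance, cfg.ransac_iterations, rng)
    if mask.mean() < cfg.min_inlier_fraction:
        raise NoPlaneError("no dominant plane in aligned cloud")
    return mask, d / n[2]


def align_bed_axes(
    pc: PointCloud, cfg: FilterConfig,
    rng: np.random.Generator | None = None,
    bed_mask: np.ndarray | None = None,
) -> tuple[RigidTransform, PointCloud]:
    """In-plane alignment: PCA of a uniform fill of the bed footprint.

    The bed inliers' raw density is biased by perspective, so their 2D
    footprint (convex hull) is filled with ``pca_fill_n`` uniform Monte Carlo
    points first; the PCA axes of that fill define the bed's long/short
    sides, which are rotated onto X and Y.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    if bed_mask is None:
        bed_mask, _ = _bed_inlier_mask(pc.points, cfg, rng)
    xy = pc.points[bed_mask][:, :2]
    hull = ConvexHull(xy)
    tri = Delaunay(xy[hull.vertices])
    lo, hi = xy.min(axis=0), xy.max(axis=0)
    # rejection sampling of the hull interior
    fills: list[np.ndarray] = []
    need = cfg.pca_fill_n
    while need > 0:
        cand = rng.uniform(lo, hi, size=(int(need / max(hull.volume / np.prod(hi - lo), 0.1)) + 16, 2))
        cand = cand[tri.find_simplex(cand) >= 0]
        fills.append(cand[:need])
        need -= len(cand[:need])
    fill = np.concatenate(fills)
    cov = np.cov(fill.T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[1] > 0 and evals[0] / evals[1] < 1.05:
        warnings.warn("near-square bed footprint: in-plane axes ambiguous, "
                      "tie-break by longer side -> X", stacklevel=2)
    major = evecs[:, 0]
    # sign/quadrant convention: choose the in-plane rotation of minimal angle
    angle = np.arctan2(major[1], major[0])
    if angle > np.pi / 2:
        angle -= np.pi
    elif angle < -np.pi / 2:
        angle += np.pi
    ca, sa = np.cos(-angle), np.sin(-angle)
    R = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    center = np.append(xy.mean(axis=0), 0.0)
    T2 = RigidTransform.from_rotation(R, center=center)
    log.info("bed axes: in-plane rotation %.2f deg (eigenvalue ratio %.2f)",
             np.degrees(angle), evals[0] / max(evals[1], 1e-12))
    return T2, pc.transformed(T2)


def remove_bed_and_clean(
    pc: PointCloud, cfg: FilterConfig, rng: np.random.Generator | None = None
) -> tuple[PointCloud, float]:
    """Remove bed-plane points and denoise; returns (PCfine, bed plane Z)."""
    rng = rng or np.random.default_rng(cfg.seed + 2)
    if cfg.smooth_k > 0 and len(pc) > cfg.smooth_k:
        tree = cKDTree(pc.points)
        _, nn = tree.query(pc.points, k=cfg.smooth_k)
        smoothed = pc.points.copy()
        smoothed[:, 2] = np.median(pc.points[nn, 2], axis=1)
        pc = replace_points(pc, smoothed)
    if cfg.trim_tol > 0 and len(pc) > cfg.trim_k:
        # flying-pixel trim: drop points standing above their neighbourhood
        # median by more than the local Z spread warrants, so spikes over
        # flat regions go while silhouette walls/rims (large spread) stay
        tree = cKDTree(pc.points)
        _, nn = tree.query(pc.points, k=cfg.trim_k)
        zn = pc.points[nn, 2]
        z_med = np.median(zn, axis=1)
        iqr = np.percentile(zn, 75, axis=1) - np.percentile(zn, 25, axis=1)
        height = z_med - pc.points[:, 2]  # >0: closer to the camera than peers
        pc = pc.select(height < np.maximum(cfg.trim_tol, 2.0 * iqr))
    mask, bed_z = _bed_inlier_mask(pc.points, cfg, rng)
    # everything at bed level or beyond it (mattress, straggler returns) goes
    keep = pc.points[:, 2] < bed_z - cfg.ransac_distance
    body = pc.select(keep)
    if len(body) == 0:
        raise EmptyCloudError("no body points above the bed plane")
    # statistical outlier removal: z-score of mean k-NN distance
    if len(body) > cfg.outlier_k + 1:
        tree = cKDTree(body.points)
        dists, _ = tree.query(body.points, k=cfg.outlier_k + 1)
        mean_d = dists[:, 1:].mean(axis=1)
        keep2 = mean_d <= mean_d.mean() + cfg.outlier_std_ratio * mean_d.std()
        body = body.select(keep2)
    # radius denoising
    if len(body) > cfg.denoise_min_neighbors:
        tree = cKDTree(body.points)
        counts = tree.query_ball_point(
            body.points, cfg.denoise_radius, return_length=True
        )
        body = body.select(counts >= cfg.denoise_min_neighbors + 1)  # self included
    if len(body) == 0:
        raise EmptyCloudError("denoising removed every body point")
    body.frame = pc.frame
    log.info("bed removal: %d -> %d body points (bed z %.3f m)", len(pc), len(body), bed_z)
    return body, bed_z


def apply_transform(x, T: RigidTransform):
    """Apply a rigid map to a PointCloud or BiomechKeypoints -> bed_aligned."""
    if isinstance(x, (PointCloud, BiomechKeypoints)):
        if getattr(x, "frame", None) == "pixel":
            raise ValueError("cannot rigidly transform pixel-frame data")
        return x.transformed(T, frame="bed_aligned")
    raise TypeError(f"cannot transform {type(x).__name__}")


def filter_cloud(pc: PointCloud, cfg: FilterConfig) -> FilterResult:
    """Full filtering pass: coarse crop, T1, T2, bed removal, denoising."""
    rng = np.random.default_rng(cfg.seed)
    counts = {"raw": len(pc)}
    coarse = coarse_filter(pc, cfg)
    counts["coarse"] = len(coarse)
    T1, pc1 = fit_bed_plane(coarse, cfg, rng)
    T2, pc2 = align_bed_axes(pc1, cfg, rng)
    fine, bed_z = remove_bed_and_clean(pc2, cfg, rng)
    fine.frame = "bed_aligned"
    counts["fine"] = len(fine)
    return FilterResult(cloud=fine, T1=T1, T2=T2, bed_z=bed_z, counts=counts)
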