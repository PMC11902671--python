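"""Body-segment separation in the bed-aligned XY projection.

Once the cloud is bed-aligned, the supine body can be projected onto the XY
plane without deformation, and each of the 17 body segments is captured by a
2D *enclosing polygon* (EP) built from the corrected keypoints:

* limb EPs (arm, forearm, thigh, shank) are quadrilaterals bounded by two cut
  lines perpendicular to the proximal-distal axis through the joint keypoints
  and two lateral lines at half-width offsets derived from the measured
  circumferences (half-width = O / 2pi, padded by a margin);
* the axial EPs (thorax, abdomen, pelvis) are bands between the vertebral cut
  lines (C7/neck/T12/mid-ASI/mid-hip), with lateral lines from the measured
  trunk widths;
* the shoulders EP is an eight-line polygon (a chamfered band between the
  neck and C7 cut lines);
* head, hands and feet have no distal keypoint: their EP is closed by a copy
  of the proximal keypoint moved outward along the parent axis by a
  per-segment offset (defaulting to the measured segment length).

The published construction is an ad-hoc routine that was never printed; the
rules above are a faithful constructive reconstruction, not a line-for-line
copy.

Because the single overhead view leaves the body's underside empty, each
segment cloud is then augmented: *bottom filling* copies every point to the
bed plane Z, and *gap filling* drapes the detected 2D boundary of the top
surface down to the bed in ``k`` evenly spaced levels, so that a closed
alpha shape can later be built.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon

from .cloud import PointCloud
from .keypoints import BiomechKeypoints, ManualMeasurements

__all__ = [
    "SEGMENTS",
    "PRIORITY",
    "ALPHA_DEFAULTS",
    "EnclosingPolygon",
    "SegmentCloud",
    "SegmentationConfig",
    "build_enclosing_polygons",
    "assign_points",
    "bottom_fill",
    "gap_fill",
    "boundary_points_2d",
]

log = logging.getLogger(__name__)

_SIDES = ("left", "right")
_LIMB_PARTS = ("arm", "forearm", "hand", "thigh", "shank", "foot")

#: The 17 body segments.
SEGMENTS: tuple[str, ...] = (
    "head", "shoulders", "thorax", "abdomen", "pelvis",
    *(f"{s}_{p}" for p in _LIMB_PARTS for s in _SIDES),
)

#: Overlap tie-break: axial segments first (prevents thigh/pelvis double
#: counting), then limbs proximal-to-distal, left before right.
PRIORITY: tuple[str, ...] = (
    "head", "shoulders", "thorax", "abdomen", "pelvis",
    "left_arm", "right_arm", "left_forearm", "right_forearm",
    "left_hand", "right_hand", "left_thigh", "right_thigh",
    "left_shank", "right_shank", "left_foot", "right_foot",
)

#: Per-segment alpha-shape parameter defaults ("legs" = the thighs; the
#: shanks are listed separately).
ALPHA_DEFAULTS: dict[str, float] = {
    "head": 0.08, "shoulders": 0.08, "pelvis": 0.08,
    "arm": 0.08, "shank": 0.08, "foot": 0.08,
    "forearm": 0.05, "hand": 0.05,
    "thorax": 0.15, "abdomen": 0.2, "thigh": 0.22,
}
ALPHA_ALIASES = {"legs": "thigh", "trunk": "thorax"}

#: (proximal KP, distal KP) per limb quadrilateral.
_LIMB_KPS = {
    "left_arm": ("KP3", "KP4"), "left_forearm": ("KP4", "KP5"),
    "right_arm": ("KP6", "KP7"), "right_forearm": ("KP7", "KP8"),
    "left_thigh": ("KP9", "KP10"), "left_shank": ("KP10", "KP11"),
    "right_thigh": ("KP12", "KP13"), "right_shank": ("KP13", "KP14"),
}
#: (proximal KP, axis-parent KP) for the open-ended extremities.
_EXTREMITY_KPS = {
    "left_hand": ("KP5", "KP4"), "right_hand": ("KP8", "KP7"),
    "left_foot": ("KP11", "KP10"), "right_foot": ("KP14", "KP13"),
}


def segment_alpha(label: str, overrides: dict[str, float] | None = None) -> float:
    """Default alpha parameter for a (possibly sided) segment label."""
    table = dict(ALPHA_DEFAULTS)
    for alias, target in ALPHA_ALIASES.items():
        if overrides and alias in overrides:
            table[target] = overrides[alias]
    if overrides:
        table.update({k: v for k, v in overrides.items() if k not in ALPHA_ALIASES})
    part = label.split("_", 1)[1] if "_" in label else label
    return table[part]


@dataclass
class SegmentationConfig:
    width_margin: float = 1.15        # padding factor on circumference-derived half-widths
    axial_width_margin: float = 1.05  # padding factor on measured trunk widths
    shoulder_width_factor: float = 1.1
    shoulder_chamfer: float = 0.02    # m corner chamfer of the 8-line shoulders EP
    head_offset: float | None = None  # m; None -> L_head from the measurements
    hand_offset: float | None = None
    foot_offset: float | None = None
    extremity_offset_margin: float = 1.05
    #: m inset of every cut line toward the segment interior.  Depth pixels
    #: straddling a joint are resolved to one side at the sensor's lateral
    #: resolution; without the inset a few high pixels from the neighbouring
    #: segment bleed across the cut and stretch the alpha shape.
    cut_inset: float = 0.004
    #: per-segment spike trim: after assignment, points standing above the
    #: median Z of their within-segment neighbours by more than this (or the
    #: local spread) are dropped.  Catches neighbouring-segment pixels that
    #: bled across a cut line at a height step, which would otherwise prop up
    #: the segment's alpha shape.
    segment_trim_tol: float = 0.002
    segment_trim_k: int = 15
    edge_radius: float = 0.03         # m gap-fill boundary detection radius
    gap_fill_levels: int = 5
    gap_fill_segments: tuple[str, ...] = ("shoulders", "thorax", "abdomen", "pelvis")
    alpha_overrides: dict[str, float] = field(default_factory=dict)


@dataclass
class EnclosingPolygon:
    label: str
    polygon: Polygon
    construction: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ValueError(f"EP for {self.label!r} is self-intersecting")
        if self.polygon.area <= 0:
            raise ValueError(f"EP for {self.label!r} has zero area")

    @property
    def wkt(self) -> str:
        return self.polygon.wkt


@dataclass
class SegmentCloud:
    """One labelled segment: original points plus artificial fill points."""

    label: str
    points: np.ndarray                      # (N, 3) original surface points
    fill_bottom: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    fill_gap: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))
    alpha: float = 0.08

    @property
    def all_points(self) -> np.ndarray:
        return np.vstack([self.points, self.fill_bottom, self.fill_gap])

    @property
    def n_fill(self) -> int:
        return len(self.fill_bottom) + len(self.fill_gap)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError("degenerate axis: proximal and distal keypoints coincide")
    return v / n


def _perp(u: np.ndarray) -> np.ndarray:
    return np.array([-u[1], u[0]])


def _quad(p, d, axis, w_p, w_d, label, note,
          inset_p: float = 0.0, inset_d: float = 0.0) -> EnclosingPolygon:
    """Quadrilateral bounded by two cut lines through p and d (perpendicular
    to ``axis``, which points from p toward d) and two lateral lines at the
    given half-width offsets.  Cut lines are inset toward the interior."""
    p = p + inset_p * axis
    d = d - inset_d * axis
    n = _perp(axis)
    poly = shapely.geometry.polygon.orient(
        Polygon([p - w_p * n, p + w_p * n, d + w_d * n, d - w_d * n])
    )
    return EnclosingPolygon(label, poly, [note])


def build_enclosing_polygons(
    kps: BiomechKeypoints,
    mm: ManualMeasurements,
    cfg: SegmentationConfig | None = None,
) -> dict[str, EnclosingPolygon]:
    """Construct all 17 enclosing polygons from the bed-aligned keypoints."""
    cfg = cfg or SegmentationConfig()
    for required in ("KP1", "KP2", "KP15", "KP17", "KP18", "KP19"):
        if required not in kps:
            raise KeyError(f"corrected keypoint {required} missing")
    xy = {k: np.asarray(v, float)[:2] for k, v in kps.kp.items()}
    axis = _unit(xy["KP2"] - xy["KP15"])  # midBody direction, hip -> neck
    m = cfg.width_margin
    am = cfg.axial_width_margin
    eps: dict[str, EnclosingPolygon] = {}

    # --- limb quadrilaterals -------------------------------------------------
    for label, (p_id, d_id) in _LIMB_KPS.items():
        part, side = label.split("_")[1], label.split("_")[0]
        lm = mm.limb(part, side)
        u = _unit(xy[d_id] - xy[p_id])
        eps[label] = _quad(
            xy[p_id], xy[d_id], u,
            lm.O_p / (2 * np.pi) * m, lm.O_d / (2 * np.pi) * m,
            label, f"cuts at {p_id}/{d_id}, half-widths O/(2pi) x {m}",
            inset_p=cfg.cut_inset, inset_d=cfg.cut_inset,
        )

    # --- axial bands ---------------------------------------------------------
    for label, (p_id, d_id, half_w) in {
        "thorax": ("KP18", "KP2", mm.W_sternum / 2 * am),
        "abdomen": ("KP17", "KP18", mm.W_T10 / 2 * am),
        "pelvis": ("KP15", "KP17", mm.W_hip / 2 * am),
    }.items():
        eps[label] = _quad(xy[p_id], xy[d_id], axis, half_w, half_w,
                           label, f"band {p_id}->{d_id}, half-width {half_w:.3f}",
                           inset_p=cfg.cut_inset, inset_d=cfg.cut_inset)

    # --- shoulders: chamfered 8-line polygon ---------------------------------
    a = xy["KP2"] + cfg.cut_inset * axis
    b = xy["KP19"] - cfg.cut_inset * axis
    hw = mm.D_shoulders / 2 * cfg.shoulder_width_factor
    c = min(cfg.shoulder_chamfer, 0.49 * hw, 0.49 * float(np.linalg.norm(b - a)))
    n = _perp(axis)
    u = axis
    eps["shoulders"] = EnclosingPolygon(
        "shoulders",
        shapely.geometry.polygon.orient(Polygon([
            a - (hw - c) * n, a + (hw - c) * n, a + hw * n + c * u,
            b + hw * n - c * u, b + (hw - c) * n, b - (hw - c) * n,
            b - hw * n - c * u, a - hw * n + c * u,
        ])),
        [f"8-line chamfered band KP2->KP19, half-width {hw:.3f}"],
    )

    # --- open-ended extremities ----------------------------------------------
    om = cfg.extremity_offset_margin
    head_dir = _unit(xy["KP1"] - xy["KP2"])
    head_off = (cfg.head_offset or mm.L_head) * om
    eps["head"] = _quad(xy["KP19"], xy["KP19"] + head_off * head_dir, head_dir,
                        mm.O_head / (2 * np.pi) * m, mm.O_head / (2 * np.pi) * m,
                        "head", f"proximal KP19 offset {head_off:.3f} along KP2->KP1",
                        inset_p=cfg.cut_inset)
    for label, (p_id, parent_id) in _EXTREMITY_KPS.items():
        part = label.split("_")[1]
        off = ((cfg.hand_offset if part == "hand" else cfg.foot_offset)
               or getattr(mm, f"L_{part}")) * om
        w = getattr(mm, f"W_{part}") / 2 * m
        u = _unit(xy[p_id] - xy[parent_id])
        eps[label] = _quad(xy[p_id], xy[p_id] + off * u, u, w, w, label,
                           f"proximal {p_id} offset {off:.3f} along {parent_id}->{p_id}",
                           inset_p=cfg.cut_inset)

    return eps


def assign_points(
    pc: PointCloud,
    polys: dict[str, EnclosingPolygon],
    cfg: SegmentationConfig | None = None,
    priority: tuple[str, ...] = PRIORITY,
) -> tuple[dict[str, SegmentCloud], np.ndarray]:
    """Assign each point to the first EP (in priority order) containing its
    XY projection.  Returns (label -> SegmentCloud, indices of unassigned)."""
    cfg = cfg or SegmentationConfig()
    if pc.frame != "bed_aligned":
        raise ValueError(f"cloud must be bed_aligned, got {pc.frame!r}")
    pts = pc.points
    taken = np.zeros(len(pts), dtype=bool)
    out: dict[str, SegmentCloud] = {}
    for label in priority:
        if label not in polys:
            continue
        free = ~taken
        inside = np.zeros(len(pts), dtype=bool)
        inside[free] = shapely.contains_xy(polys[label].polygon, pts[free, 0], pts[free, 1])
        out[label] = SegmentCloud(
            label, pts[inside], alpha=segment_alpha(label, cfg.alpha_overrides)
        )
        taken |= inside
    unassigned = np.nonzero(~taken)[0]
    frac = len(unassigned) / max(len(pts), 1)
    if frac > 0.20:
        import warnings
        warnings.warn(f"{100 * frac:.0f}% of points unassigned: check keypoints",
                      stacklevel=2)
    log.info("assignment: %d points, %d unassigned (%.1f%%)",
             len(pts), len(unassigned), 100 * frac)
    return out, unassigned


def trim_segment_spikes(sc: SegmentCloud, cfg: SegmentationConfig | None = None) -> SegmentCloud:
    """Drop points standing above their within-segment neighbourhood.

    Flatness-aware (threshold scales with the local Z spread), so silhouette
    walls survive while isolated high points — typically bleed from a taller
    neighbouring segment across a cut line — are removed.
    """
    cfg = cfg or SegmentationConfig()
    k = cfg.segment_trim_k
    if cfg.segment_trim_tol <= 0 or len(sc.points) <= k:
        return sc
    from scipy.spatial import cKDTree

    tree = cKDTree(sc.points)
    _, nn = tree.query(sc.points, k=k)
    zn = sc.points[nn, 2]
    z_med = np.median(zn, axis=1)
    iqr = np.percentile(zn, 75, axis=1) - np.percentile(zn, 25, axis=1)
    height = z_med - sc.points[:, 2]
    keep = height < np.maximum(cfg.segment_trim_tol, 2.0 * iqr)
    return replace(sc, points=sc.points[keep])


def bottom_fill(sc: SegmentCloud, bed_z: float) -> SegmentCloud:
    """Copy every original point onto the bed plane (Z := bed_z)."""
    fill = sc.points.copy()
    fill[:, 2] = bed_z
    return replace(sc, fill_bottom=fill)


def boundary_points_2d(points_xy: np.ndarray, edge_radius: float) -> np.ndarray:
    """Indices of points on the 2D alpha-boundary of an XY point set.

    Triangulates the projection, keeps triangles with circumradius below
    ``edge_radius``, and returns the vertices of edges used by exactly one
    kept triangle.
    """
    if len(points_xy) < 3:
        return np.arange(len(points_xy))
    tri = Delaunay(points_xy)
    simp = tri.simplices
    a, b, c = (points_xy[simp[:, i]] for i in range(3))
    la, lb, lc = (np.linalg.norm(y - x, axis=1) for x, y in ((b, c), (a, c), (a, b)))
    ab, ac = b - a, c - a
    area2 = np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        circum_r = np.where(area2 > 1e-15, la * lb * lc / (2 * area2), np.inf)
    kept = simp[circum_r < edge_radius]
    if len(kept) == 0:
        # degenerate/sparse projection: every point is boundary
        return np.arange(len(points_xy))
    edges = np.sort(np.concatenate([kept[:, [0, 1]], kept[:, [1, 2]], kept[:, [0, 2]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])


def gap_fill(
    sc: SegmentCloud,
    bed_z: float,
    cfg: SegmentationConfig | None = None,
) -> SegmentCloud:
    """Drape the top surface's detected 2D boundary down to the bed plane.

    For each boundary point at surface height z, ``gap_fill_levels`` points
    are appended at Z linearly interpolated between z and bed_z (exclusive).
    ``gap_fill_levels=0`` is the identity.
    """
    cfg = cfg or SegmentationConfig()
    k = cfg.gap_fill_levels
    if k <= 0 or len(sc.points) < 3:
        return sc
    idx = boundary_points_2d(sc.points[:, :2], cfg.edge_radius)
    boundary = sc.points[idx]
    levels = np.arange(1, k + 1) / (k + 1)
    fills = boundary[None, :, :] + levels[:, None, None] * (
        np.array([0.0, 0.0, 1.0]) * (bed_z - boundary[:, 2])[None, :, None]
    )
    return replace(sc, fill_gap=fills.reshape(-1, 3))


def assignment_report(segments: dict[str, SegmentCloud]) -> pd.DataFrame:
    """Per-segment point/fill counts (CSV-friendly)."""
    return pd.DataFrame(
        [{"label": sc.label, "n_points": len(sc.points), "n_fill": sc.n_fill,
          "alpha": sc.alpha} for sc in segments.values()]
    )
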