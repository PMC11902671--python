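"""End-to-end orchestration: keypoints -> 3D -> filter -> separate -> volume.

:func:`process` is the in-memory core (used by tests and scripted analyses);
:func:`run_pipeline` is the file-based wrapper behind the CLI, reading the
inputs named in a :class:`~segmetry.config.PipelineConfig` and writing the
per-stage artifacts into its output directory.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import compare
from .anthro import AnthropometricTable
from .camera import CameraIntrinsics, DepthFrame, depth_to_cloud, keypoints_to_3d
from .cloud import PointCloud
from .config import PipelineConfig
from .filtering import FilterResult, apply_transform, filter_cloud
from .keypoints import (
    BiomechKeypoints, ManualMeasurements, RawPoseKeypoints,
    compute_corrected_keypoints, compute_midpoints, select_keypoints,
)
from .segmentation import (
    SEGMENTS, EnclosingPolygon, SegmentCloud, assign_points,
    assignment_report, bottom_fill, build_enclosing_polygons, gap_fill,
    trim_segment_spikes,
)
from .volumetry import (
    AlphaShapeError, MonteCarloConfig, alpha_shape, monte_carlo_volume,
    segment_mass,
)

__all__ = ["process", "run_pipeline", "PipelineOutput", "RESULT_COLUMNS"]

log = logging.getLogger(__name__)

_LIMB_PARTS_WITH_CONE = ("arm", "forearm", "thigh", "shank")

#: (proximal, distal) keypoints defining the scanner length of each segment.
_LENGTH_KPS = {
    "shoulders": ("KP2", "KP19"), "thorax": ("KP18", "KP2"),
    "abdomen": ("KP17", "KP18"), "pelvis": ("KP15", "KP17"),
    "left_arm": ("KP3", "KP4"), "left_forearm": ("KP4", "KP5"),
    "right_arm": ("KP6", "KP7"), "right_forearm": ("KP7", "KP8"),
    "left_thigh": ("KP9", "KP10"), "left_shank": ("KP10", "KP11"),
    "right_thigh": ("KP12", "KP13"), "right_shank": ("KP13", "KP14"),
}
_MANUAL_LENGTH = {"head": "L_head", "thorax": "L_trunk", "abdomen": "L_abdomen",
                  "hand": "L_hand", "foot": "L_foot"}

RESULT_COLUMNS = [
    "label", "n_points", "n_fill", "V_scan_dm3", "mc_se_dm3", "M_scan_kg",
    "L_scan_m", "V_ref_dm3", "V_cone_dm3", "dV_scan_ref_dm3", "dV_scan_cone_dm3",
    "dL_scan_ref", "dL_scan_manual", "D_scan_m", "D_ref_m",
    "Dhat_scan", "Dhat_ref", "dD", "M_norm_pct",
]


@dataclass
class PipelineOutput:
    results: pd.DataFrame
    filter_result: FilterResult
    keypoints_aligned: BiomechKeypoints
    polygons: dict[str, EnclosingPolygon]
    segments: dict[str, SegmentCloud]
    unassigned: np.ndarray
    segment_results: dict[str, compare.SegmentResult] = field(default_factory=dict)


def _manual_length(mm: ManualMeasurements, label: str) -> float:
    part = label.split("_", 1)[1] if "_" in label else label
    if part in _LIMB_PARTS_WITH_CONE and "_" in label:
        side = label.split("_", 1)[0]
        return mm.limb(part, side).L
    if part in _MANUAL_LENGTH:
        return getattr(mm, _MANUAL_LENGTH[part])
    return float("nan")


def _scan_length(kps: BiomechKeypoints, label: str,
                 mm: ManualMeasurements, cfg: PipelineConfig) -> float:
    if label in _LENGTH_KPS:
        p, d = _LENGTH_KPS[label]
        return float(np.linalg.norm(kps[d] - kps[p]))
    # open-ended extremities: the EP closing offset is the scanner length
    part = label.split("_", 1)[1] if "_" in label else label
    seg = cfg.segmentation
    base = {"head": seg.head_offset or mm.L_head,
            "hand": seg.hand_offset or mm.L_hand,
            "foot": seg.foot_offset or mm.L_foot}[part]
    return base * seg.extremity_offset_margin


def process(
    raw_kps: RawPoseKeypoints,
    depth: DepthFrame | None,
    intrinsics: CameraIntrinsics | None,
    mm: ManualMeasurements,
    cfg: PipelineConfig | None = None,
    table: AnthropometricTable | None = None,
    cloud: PointCloud | None = None,
    kps_metric: BiomechKeypoints | None = None,
) -> PipelineOutput:
    """Run the full measurement chain on in-memory inputs.

    Either ``depth`` + ``intrinsics`` or a pre-computed metric ``cloud`` (with
    ``kps_metric``) must be provided.
    """
    cfg = cfg or PipelineConfig()
    table = table or AnthropometricTable.default()

    # 1. skeleton: select landmarks, metric conversion, midpoints, correction.
    # Midpoints are taken *after* unprojection: a pixel-space midpoint would
    # be unprojected at the mid-body surface depth, which perspective-shifts
    # the neck/mid-hip laterally by centimetres.
    if kps_metric is None:
        if depth is None or intrinsics is None:
            raise ValueError("need depth + intrinsics (or a metric cloud + keypoints)")
        kps_px = select_keypoints(raw_kps, cfg.visibility_floor)
        kps_metric = keypoints_to_3d(kps_px, depth, intrinsics)
    if "KP2" not in kps_metric:
        kps_metric = compute_midpoints(kps_metric)
    kps_metric = compute_corrected_keypoints(kps_metric, mm)

    # 2. cloud conversion + filtering + alignment
    if cloud is None:
        cloud = depth_to_cloud(depth, intrinsics)
    fres = filter_cloud(cloud, cfg.filter.build(cfg.seed))
    kps_aligned = apply_transform(kps_metric, fres.T)

    # 3. segment separation + filling
    seg_cfg = cfg.segmentation.build()
    polys = build_enclosing_polygons(kps_aligned, mm, seg_cfg)
    segments, unassigned = assign_points(fres.cloud, polys, seg_cfg)
    for label, sc in segments.items():
        sc = trim_segment_spikes(sc, seg_cfg)
        sc = bottom_fill(sc, fres.bed_z)
        if label in seg_cfg.gap_fill_segments:
            sc = gap_fill(sc, fres.bed_z, seg_cfg)
        segments[label] = sc

    # 4. per-segment volume, mass, comparisons
    seg_results: dict[str, compare.SegmentResult] = {}
    for i, label in enumerate(SEGMENTS):
        sc = segments.get(label)
        res = compare.SegmentResult(label=label, V_scan=float("nan"))
        if sc is not None and len(sc.points) >= cfg.min_segment_points:
            try:
                shape = alpha_shape(sc.all_points, sc.alpha,
                                    convention=cfg.monte_carlo.alpha_convention,
                                    require_watertight=False)
                mc = monte_carlo_volume(
                    shape, MonteCarloConfig(cfg.monte_carlo.n_points, cfg.seed + 101 + i))
                res.V_scan = mc.volume
                res.mc_se = mc.se
                res.M_scan = segment_mass(mc.volume, table.density(label))
                res.n_points, res.n_fill = len(sc.points), sc.n_fill
            except AlphaShapeError as err:
                warnings.warn(f"{label}: {err}", stacklevel=2)
        elif sc is not None:
            warnings.warn(f"{label}: only {len(sc.points)} points, skipped", stacklevel=2)
        res.L_scan = _scan_length(kps_aligned, label, mm, cfg)
        res.L_manual = _manual_length(mm, label)
        if label in table:
            res.V_ref = compare.v_ref(table, mm.M_subject, label)
            res.L_ref = table.reference_length(label, mm.H_subject)
        part = label.split("_", 1)[1] if "_" in label else label
        if part in _LIMB_PARTS_WITH_CONE and "_" in label:
            lmb = mm.limb(part, label.split("_", 1)[0])
            res.V_cone = compare.v_cone(lmb.L, lmb.O_p, lmb.O_d)
        if np.isfinite(res.V_scan):
            compare.deltas(res, mm.H_subject, mm.M_subject,
                           cfg.dhat_scan_uses_manual_length)
        seg_results[label] = res

    rows = []
    for label in SEGMENTS:
        r = seg_results[label]
        rows.append({
            "label": label, "n_points": r.n_points, "n_fill": r.n_fill,
            "V_scan_dm3": r.V_scan * 1e3, "mc_se_dm3": r.mc_se * 1e3,
            "M_scan_kg": r.M_scan, "L_scan_m": r.L_scan,
            "V_ref_dm3": r.V_ref * 1e3, "V_cone_dm3": r.V_cone * 1e3,
            "dV_scan_ref_dm3": r.dV_scan_ref * 1e3,
            "dV_scan_cone_dm3": r.dV_scan_cone * 1e3,
            "dL_scan_ref": r.dL_scan_ref, "dL_scan_manual": r.dL_scan_manual,
            "D_scan_m": r.D_scan, "D_ref_m": r.D_ref,
            "Dhat_scan": r.Dhat_scan, "Dhat_ref": r.Dhat_ref, "dD": r.dD,
            "M_norm_pct": r.M_norm_pct,
        })
    results = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return PipelineOutput(results, fres, kps_aligned, polys, segments,
                          unassigned, seg_results)


def run_pipeline(cfg: PipelineConfig) -> pd.DataFrame:
    """File-based pipeline: load inputs, process, write per-stage artifacts."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if cfg.keypoints_path is None:
        raise FileNotFoundError("keypoints file not configured")
    if cfg.measurements_path is None:
        raise FileNotFoundError("measurements file not configured")
    raw = RawPoseKeypoints.load(cfg.keypoints_path)
    mm = ManualMeasurements.load(cfg.measurements_path)
    table = (AnthropometricTable.from_csv(cfg.table_path)
             if cfg.table_path else AnthropometricTable.default())

    depth = intr = cloud = kps_metric = None
    if cfg.depth_path:
        if not cfg.intrinsics_path:
            raise FileNotFoundError("intrinsics file required with a depth frame")
        depth = DepthFrame.load(cfg.depth_path)
        intr = CameraIntrinsics.load(cfg.intrinsics_path)
    elif cfg.cloud_path:
        raise ValueError("direct cloud input also needs metric keypoints; "
                         "use the library API (process) for that path")
    else:
        raise FileNotFoundError("no depth frame or cloud configured")

    out = process(raw, depth, intr, mm, cfg, table, cloud, kps_metric)

    sid = cfg.subject_id
    out.filter_result.cloud.save(out_dir / f"{sid}_pcfine.ply")
    out.filter_result.T.save(out_dir / f"{sid}_transform.txt")
    out.keypoints_aligned.save(out_dir / f"{sid}_keypoints_aligned.json")
    with open(out_dir / f"{sid}_polygons.wkt", "w") as fh:
        for label, ep in out.polygons.items():
            fh.write(f"{label}\t{ep.wkt}\n")
    assignment_report(out.segments).to_csv(out_dir / f"{sid}_report.csv", index=False)
    out.results.to_csv(out_dir / f"{sid}_results.csv", index=False,
                       float_format="%.8g")
    log.info("pipeline complete: %d segments -> %s", len(out.results), out_dir)
    return out.results
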