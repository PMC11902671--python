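"""Comparison layer: reference-table volumes, truncated cones, equivalent
diameters, normalized deltas and Bland-Altman agreement.

Scanner outputs are compared against two classical baselines:

* the anthropometric reference volume V_ref = (mass fraction x body mass) / density
  (the reference mass divided by the reference density);
* the truncated-cone volume from the manual tape measurements,
  V_cone = (1/3) L pi (r_d^2 + r_p^2 + r_p r_d), with r = O / 2pi at each end.

Shape agreement uses the *equivalent diameter*: the diameter of the cylinder
with the segment's volume and length, D = sqrt(4 V / (pi L)).  Both diameters
are normalized by the manually measured segment length (D-hat = D / L_manual)
and their difference is further normalized by the subject's height:

    dD = (D-hat_scan - D-hat_ref) / H_subject.

Whether D-hat_scan should instead use the scanner length is genuinely open;
``dhat_scan_uses_manual_length=False`` switches the normalization.  Length
deltas are normalized by the subject height as well, and masses by the body
weight (reported in %).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from math import pi, sqrt

import numpy as np

__all__ = [
    "SegmentResult",
    "BlandAltman",
    "v_ref",
    "v_cone",
    "equivalent_diameter",
    "delta_d",
    "deltas",
    "bland_altman",
]


def v_ref(table, body_mass: float, label: str) -> float:
    """Reference volume (m^3) = reference mass / reference density."""
    if label not in table:
        raise KeyError(f"no table entry for segment {label!r}")
    return table.reference_mass(label, body_mass) / table.density(label)


def v_cone(L: float, O_p: float, O_d: float) -> float:
    """Truncated-cone volume (m^3) from length and end circumferences."""
    if min(L, O_p, O_d) <= 0:
        raise ValueError("length and circumferences must be positive")
    r_p, r_d = O_p / (2 * pi), O_d / (2 * pi)
    return L * pi * (r_d ** 2 + r_p ** 2 + r_p * r_d) / 3.0


def equivalent_diameter(V: float, L: float) -> float:
    """Diameter of the cylinder with volume V and length L (m)."""
    if V <= 0 or L <= 0:
        raise ValueError("volume and length must be positive")
    return sqrt(4.0 * V / (pi * L))


def delta_d(
    D_scan: float, L_scan: float, D_ref: float, L_manual: float, H: float,
    dhat_scan_uses_manual_length: bool = True,
) -> float:
    """Height-normalized difference of the length-normalized diameters."""
    if min(D_scan, L_scan, D_ref, L_manual, H) <= 0:
        raise ValueError("all arguments must be positive")
    dhat_scan = D_scan / (L_manual if dhat_scan_uses_manual_length else L_scan)
    dhat_ref = D_ref / L_manual
    return (dhat_scan - dhat_ref) / H


@dataclass
class SegmentResult:
    """All per-segment outputs of the pipeline plus comparison deltas.

    Volumes in m^3, lengths and diameters in m, mass in kg; the delta fields
    are filled by :func:`deltas`.  NaN marks a quantity that does not apply
    (e.g. no truncated-cone model for the axial segments).
    """

    label: str
    V_scan: float
    L_scan: float = np.nan
    M_scan: float = np.nan
    n_points: int = 0
    n_fill: int = 0
    mc_se: float = np.nan
    V_ref: float = np.nan
    V_cone: float = np.nan
    L_ref: float = np.nan
    L_manual: float = np.nan
    dV_scan_ref: float = np.nan
    dV_scan_cone: float = np.nan
    dL_scan_ref: float = np.nan
    dL_scan_manual: float = np.nan
    D_ref: float = np.nan
    D_scan: float = np.nan
    Dhat_ref: float = np.nan
    Dhat_scan: float = np.nan
    dD: float = np.nan
    M_norm_pct: float = np.nan


def deltas(res: SegmentResult, H: float, body_mass: float | None = None,
           dhat_scan_uses_manual_length: bool = True) -> SegmentResult:
    """Fill every derivable delta/normalized field of a SegmentResult."""
    if H <= 0:
        raise ValueError("subject height must be positive")
    if np.isfinite(res.V_ref):
        res.dV_scan_ref = res.V_scan - res.V_ref
    if np.isfinite(res.V_cone):
        res.dV_scan_cone = res.V_scan - res.V_cone
    if np.isfinite(res.L_scan) and np.isfinite(res.L_ref):
        res.dL_scan_ref = (res.L_scan - res.L_ref) / H
    if np.isfinite(res.L_scan) and np.isfinite(res.L_manual):
        res.dL_scan_manual = (res.L_scan - res.L_manual) / H
    if np.isfinite(res.L_manual) and np.isfinite(res.V_ref) and res.L_manual > 0:
        res.D_ref = equivalent_diameter(res.V_ref, res.L_manual)
        res.Dhat_ref = res.D_ref / res.L_manual
    if np.isfinite(res.L_scan) and res.V_scan > 0 and res.L_scan > 0:
        res.D_scan = equivalent_diameter(res.V_scan, res.L_scan)
        if np.isfinite(res.L_manual):
            res.Dhat_scan = res.D_scan / (
                res.L_manual if dhat_scan_uses_manual_length else res.L_scan
            )
    if np.isfinite(res.Dhat_scan) and np.isfinite(res.Dhat_ref):
        res.dD = (res.Dhat_scan - res.Dhat_ref) / H
    if body_mass and np.isfinite(res.M_scan):
        res.M_norm_pct = 100.0 * res.M_scan / body_mass
    return res


@dataclass
class BlandAltman:
    mean_diff: float
    sd: float
    loa_low: float
    loa_high: float
    n: int
    means: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def bland_altman(pairs) -> BlandAltman:
    """Agreement summary: mean difference and 1.96 SD limits of agreement."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 2:
        raise ValueError("need at least 2 (a, b) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    mean_diff = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltman(mean_diff, sd, mean_diff - 1.96 * sd, mean_diff + 1.96 * sd,
                       len(arr), means, diffs)
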