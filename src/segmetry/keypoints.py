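"""Biomechanically corrected skeleton from raw pose-estimator landmarks.

A 2D pose model (e.g. BlazePose) returns ~33 image-space landmarks, of which
13 are anatomically usable: a cranial reference plus left/right shoulder,
elbow, wrist, hip, knee and ankle.  This module maps those onto the numbered
keypoint scheme used throughout the pipeline (KP1..KP14), derives the neck
(KP2, shoulder midpoint) and mid-hip (KP15), and constructs three vertebral
keypoints from anthropometric proportions:

* KP19 (C7)      = KP2 + unit(KP1 - KP2) * |midBody| * 17%
* KP17 (mid-ASI) = KP15 + unit(midBody) * W_hip * 47%
* KP18 (T12)     = KP17 + midBody * 36%

with midBody = KP2 - KP15, the trunk axis pointing from mid-hip toward the
neck.  All three constructions are frame-agnostic: they operate on whatever
coordinates the keypoints carry (2D pixels or 3D metres), the caller being
responsible for unit consistency (the pipeline applies them after metric
conversion so that the hip width, in metres, is dimensionally sound).
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "RawPoseKeypoints",
    "BiomechKeypoints",
    "ManualMeasurements",
    "LimbMeasurement",
    "select_keypoints",
    "compute_midpoints",
    "compute_corrected_keypoints",
    "MissingLandmarkError",
    "DegenerateSkeletonError",
]

# Fraction of |midBody| above the neck locating C7.
C7_FRACTION = 0.17
# Fraction of the hip width above mid-hip locating the mid-ASI point.
ASI_FRACTION = 0.47
# Fraction of midBody above mid-ASI locating T12.
T12_FRACTION = 0.36

#: Default pose-landmark -> keypoint-id mapping (config-overridable).  The
#: nose is the cranial reference: it is the only head landmark among the 13
#: that yields the upward direction needed for the C7 construction.
DEFAULT_LANDMARK_MAP: dict[str, str] = {
    "nose": "KP1",
    "left_shoulder": "KP3",
    "left_elbow": "KP4",
    "left_wrist": "KP5",
    "right_shoulder": "KP6",
    "right_elbow": "KP7",
    "right_wrist": "KP8",
    "left_hip": "KP9",
    "left_knee": "KP10",
    "left_ankle": "KP11",
    "right_hip": "KP12",
    "right_knee": "KP13",
    "right_ankle": "KP14",
}

REQUIRED_LANDMARKS = tuple(DEFAULT_LANDMARK_MAP)


class MissingLandmarkError(KeyError):
    pass


class DegenerateSkeletonError(ValueError):
    pass


@dataclass
class RawPoseKeypoints:
    """Raw pose-model output: landmark name -> (u, v, visibility)."""

    landmarks: dict[str, tuple[float, float, float]]
    image_size: tuple[int, int] | None = None  # (width, height) px

    def __post_init__(self) -> None:
        for name, (u, v, vis) in self.landmarks.items():
            if not 0.0 <= vis <= 1.0:
                raise ValueError(f"visibility of {name!r} outside [0, 1]: {vis}")

    @classmethod
    def load(cls, path) -> "RawPoseKeypoints":
        """Read the flat ``name -> [u, v, (visibility)]`` JSON schema."""
        with open(path) as fh:
            data = json.load(fh)
        size = data.pop("image_size", None)
        lm = {}
        for name, val in data.items():
            u, v = float(val[0]), float(val[1])
            vis = float(val[2]) if len(val) > 2 else 1.0
            lm[name] = (u, v, vis)
        return cls(lm, tuple(size) if size else None)

    def save(self, path) -> None:
        data: dict = {k: list(v) for k, v in self.landmarks.items()}
        if self.image_size:
            data["image_size"] = list(self.image_size)
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


@dataclass
class BiomechKeypoints:
    """Named keypoints KP1..KP15, KP17..KP19 in a tagged frame.

    KP16 is intentionally absent from the scheme (it has no published
    definition and no consumer downstream).
    """

    kp: dict[str, np.ndarray]
    frame: str = "pixel"
    low_visibility: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.kp = {k: np.asarray(v, dtype=float) for k, v in self.kp.items()}

    def __getitem__(self, key: str) -> np.ndarray:
        return self.kp[key]

    def __contains__(self, key: str) -> bool:
        return key in self.kp

    @property
    def mid_body(self) -> np.ndarray:
        """Trunk axis: mid-hip -> neck."""
        return self.kp["KP2"] - self.kp["KP15"]

    def transformed(self, T, frame: str | None = None) -> "BiomechKeypoints":
        new = {k: T.apply(v) for k, v in self.kp.items()}
        return replace(self, kp=new, frame=frame or self.frame)

    @classmethod
    def load(cls, path, frame: str = "pixel") -> "BiomechKeypoints":
        with open(path) as fh:
            data = json.load(fh)
        frame = data.pop("frame", frame)
        return cls({k: np.asarray(v, float) for k, v in data.items()}, frame=frame)

    def save(self, path) -> None:
        data: dict = {k: [float(x) for x in v] for k, v in self.kp.items()}
        data["frame"] = self.frame
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


@dataclass
class LimbMeasurement:
    """Length plus proximal/distal circumferences of one limb segment (m)."""

    L: float
    O_p: float
    O_d: float


@dataclass
class ManualMeasurements:
    """Tape/compass measurements of one subject (all metres, mass in kg).

    ``limbs`` is keyed ``"{segment}_{side}"`` with segment in
    {arm, forearm, thigh, shank} and side in {left, right}.
    """

    H_subject: float
    M_subject: float
    L_head: float
    O_head: float
    limbs: dict[str, LimbMeasurement]
    L_trunk: float
    D_shoulders: float
    W_sternum: float
    O_chest: float
    O_sternum: float
    L_abdomen: float
    W_T10: float
    O_T10: float
    D_asi: float
    O_asi: float
    W_hip: float
    W_troch: float
    D_asi_troch: float
    L_hand: float
    W_hand: float
    L_foot: float
    W_foot: float
    H_foot: float
    O_ankle: float

    def __post_init__(self) -> None:
        for name, val in vars(self).items():
            if name == "limbs":
                for key, lm in val.items():
                    if min(lm.L, lm.O_p, lm.O_d) <= 0:
                        raise ValueError(f"non-positive limb measurement for {key}")
            elif val <= 0:
                raise ValueError(f"non-positive measurement {name}={val}")
        # a closed circumference always exceeds the straight width it spans
        for o, w in (("O_T10", "W_T10"), ("O_asi", "W_hip"), ("O_sternum", "W_sternum")):
            if getattr(self, o) <= getattr(self, w):
                raise ValueError(f"{o} must exceed {w}")

    def limb(self, segment: str, side: str) -> LimbMeasurement:
        return self.limbs[f"{segment}_{side}"]

    @classmethod
    def load(cls, path) -> "ManualMeasurements":
        with open(path) as fh:
            data = json.load(fh)
        data["limbs"] = {k: LimbMeasurement(**v) for k, v in data["limbs"].items()}
        return cls(**data)

    def save(self, path) -> None:
        data = {k: v for k, v in vars(self).items() if k != "limbs"}
        data["limbs"] = {k: vars(v) for k, v in self.limbs.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


def select_keypoints(
    raw: RawPoseKeypoints,
    visibility_floor: float = 0.5,
    landmark_map: dict[str, str] | None = None,
) -> BiomechKeypoints:
    """Map the 13 required pose landmarks onto KP1..KP14 (pixel frame).

    Unmapped landmarks are discarded.  A missing required landmark is a hard
    error; a landmark below the visibility floor is kept but flagged.
    """
    lm_map = landmark_map or DEFAULT_LANDMARK_MAP
    kp: dict[str, np.ndarray] = {}
    low: set[str] = set()
    for name, kp_id in lm_map.items():
        if name not in raw.landmarks:
            raise MissingLandmarkError(f"required landmark absent: {name!r}")
        u, v, vis = raw.landmarks[name]
        if vis < visibility_floor:
            warnings.warn(f"landmark {name!r} visibility {vis:.2f} below floor", stacklevel=2)
            low.add(kp_id)
        if raw.image_size is not None:
            w, h = raw.image_size
            if not (0 <= u < w and 0 <= v < h):
                warnings.warn(f"landmark {name!r} outside image bounds", stacklevel=2)
                low.add(kp_id)
        kp[kp_id] = np.array([u, v], dtype=float)
    return BiomechKeypoints(kp, frame="pixel", low_visibility=low)


def compute_midpoints(kps: BiomechKeypoints) -> BiomechKeypoints:
    """Add the neck KP2 = (KP3 + KP6)/2 and mid-hip KP15 = (KP9 + KP12)/2."""
    for needed in ("KP3", "KP6", "KP9", "KP12"):
        if needed not in kps:
            raise MissingLandmarkError(f"keypoint {needed} required for midpoints")
    new = dict(kps.kp)
    new["KP2"] = 0.5 * (kps["KP3"] + kps["KP6"])
    new["KP15"] = 0.5 * (kps["KP9"] + kps["KP12"])
    return replace(kps, kp=new)


def compute_corrected_keypoints(
    kps: BiomechKeypoints, mm: ManualMeasurements
) -> BiomechKeypoints:
    """Add the vertebral keypoints KP19 (C7), KP17 (mid-ASI) and KP18 (T12)."""
    for needed in ("KP1", "KP2", "KP15"):
        if needed not in kps:
            raise MissingLandmarkError(f"keypoint {needed} required for correction")
    kp1, kp2, kp15 = kps["KP1"], kps["KP2"], kps["KP15"]
    mid_body = kp2 - kp15
    n_mid = np.linalg.norm(mid_body)
    head_dir = kp1 - kp2
    n_head = np.linalg.norm(head_dir)
    if n_mid < 1e-12 or n_head < 1e-12:
        raise DegenerateSkeletonError("coincident neck/hip or neck/head keypoints")
    new = dict(kps.kp)
    new["KP19"] = kp2 + head_dir / n_head * n_mid * C7_FRACTION
    new["KP17"] = kp15 + mid_body / n_mid * mm.W_hip * ASI_FRACTION
    new["KP18"] = new["KP17"] + mid_body * T12_FRACTION
    return replace(kps, kp=new)
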