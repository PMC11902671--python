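"""Schema-validated pipeline configuration (YAML-loadable, unknown keys rejected)."""
from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .filtering import FilterConfig
from .segmentation import SegmentationConfig

__all__ = ["PipelineConfig", "FilterParams", "SegmentationParams", "MonteCarloParams"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FilterParams(_Strict):
    """Filtering defaults sized for a consumer ToF camera ~1.5 m above the
    bed (mm-level depth noise after warm-up).  ``low_noise()`` narrows the
    plane threshold for quantization-limited input such as rendered
    phantoms; the plane inlier threshold should always be a few times the
    post-smoothing depth noise."""

    crop_half_extent: tuple[float, float] | None = (1.21, 1.21)
    xy_padding: float | tuple[float, float] = 0.45
    z_padding: float = 0.40
    ransac_distance: float = 0.01
    ransac_iterations: int = 200
    min_inlier_fraction: float = 0.2
    outlier_k: int = 20
    outlier_std_ratio: float = 6.0
    denoise_radius: float = 0.02
    denoise_min_neighbors: int = 5
    smooth_k: int = 9
    trim_tol: float = 0.002
    trim_k: int = 25
    pca_fill_n: int = 1_000_000

    @classmethod
    def low_noise(cls) -> "FilterParams":
        """Settings for quantization-limited depth (sub-mm noise)."""
        return cls(ransac_distance=0.002)

    @classmethod
    def noisy(cls) -> "FilterParams":
        """Settings for several-mm depth noise: wider plane threshold and a
        stronger median window."""
        return cls(ransac_distance=0.01, smooth_k=15)

    def build(self, seed: int) -> FilterConfig:
        return FilterConfig(seed=seed, **self.model_dump())


class SegmentationParams(_Strict):
    width_margin: float = 1.15
    axial_width_margin: float = 1.05
    shoulder_width_factor: float = 1.1
    shoulder_chamfer: float = 0.02
    head_offset: float | None = None
    hand_offset: float | None = None
    foot_offset: float | None = None
    extremity_offset_margin: float = 1.05
    cut_inset: float = 0.004
    segment_trim_tol: float = 0.002
    segment_trim_k: int = 15
    edge_radius: float = 0.03
    gap_fill_levels: int = 5
    gap_fill_segments: tuple[str, ...] = ("shoulders", "thorax", "abdomen", "pelvis")
    alpha_overrides: dict[str, float] = Field(default_factory=dict)

    def build(self) -> SegmentationConfig:
        return SegmentationConfig(**self.model_dump())


class MonteCarloParams(_Strict):
    n_points: int = 1_000_000
    alpha_convention: str = "inverse"  # printed alphas as probe radius 1/a


class PipelineConfig(_Strict):
    """Top-level configuration binding all stages together."""

    # input files (a direct cloud may replace depth + intrinsics)
    keypoints_path: str | None = None
    depth_path: str | None = None
    intrinsics_path: str | None = None
    cloud_path: str | None = None
    measurements_path: str | None = None
    table_path: str | None = None
    out_dir: str = "."
    subject_id: str = "subject"

    seed: int = 0
    visibility_floor: float = 0.5
    dhat_scan_uses_manual_length: bool = True
    min_segment_points: int = 50

    filter: FilterParams = Field(default_factory=FilterParams)
    segmentation: SegmentationParams = Field(default_factory=SegmentationParams)
    monte_carlo: MonteCarloParams = Field(default_factory=MonteCarloParams)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))
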