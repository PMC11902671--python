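"""Shared fixtures: phantom renders and pipeline runs reused across modules."""
from __future__ import annotations

import numpy as np
import pytest

from segmetry.config import FilterParams, PipelineConfig
from segmetry.keypoints import LimbMeasurement, ManualMeasurements
from segmetry.phantom import (
    default_spec, generate_phantom, phantom_cloud, phantom_manual_measurements,
)
from segmetry.pipeline import process


def make_measurements(**overrides) -> ManualMeasurements:
    """A minimal valid set of manual measurements for unit tests."""
    limbs = {
        f"{part}_{side}": LimbMeasurement(L=L, O_p=op, O_d=od)
        for side in ("left", "right")
        for part, L, op, od in (
            ("arm", 0.28, 0.28, 0.25), ("forearm", 0.26, 0.25, 0.18),
            ("thigh", 0.45, 0.47, 0.35), ("shank", 0.43, 0.33, 0.22),
        )
    }
    base = dict(
        H_subject=1.75, M_subject=70.0, L_head=0.22, O_head=0.57, limbs=limbs,
        L_trunk=0.30, D_shoulders=0.38, W_sternum=0.28, O_chest=0.95,
        O_sternum=0.90, L_abdomen=0.17, W_T10=0.28, O_T10=0.85,
        D_asi=0.24, O_asi=0.95, W_hip=0.34, W_troch=0.20, D_asi_troch=0.10,
        L_hand=0.19, W_hand=0.09, L_foot=0.25, W_foot=0.09, H_foot=0.07,
        O_ankle=0.24,
    )
    base.update(overrides)
    return ManualMeasurements(**base)


@pytest.fixture(scope="session")
def mm_basic():
    return make_measurements()


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom: (spec, render, measurements, labelled cloud)."""
    spec = default_spec()
    render = generate_phantom(spec)
    return spec, render, phantom_manual_measurements(spec), phantom_cloud(render)


@pytest.fixture(scope="session")
def clean_run(clean_phantom):
    """Full pipeline output on the noise-free phantom (labels threaded through)."""
    spec, render, mm, pc = clean_phantom
    cfg = PipelineConfig(seed=1, filter=FilterParams.low_noise())
    out = process(render.truth.raw_keypoints, render.depth, render.intrinsics,
                  mm, cfg, cloud=pc)
    return spec, render, mm, pc, out


@pytest.fixture(scope="session")
def noisy_run():
    """Full pipeline output on the noisy (3 mm sigma, 10% dropout) phantom."""
    spec = default_spec(noise_sigma=0.003, dropout=0.10)
    render = generate_phantom(spec)
    mm = phantom_manual_measurements(spec)
    pc = phantom_cloud(render)
    cfg = PipelineConfig(seed=1, filter=FilterParams.noisy())
    out = process(render.truth.raw_keypoints, render.depth, render.intrinsics,
                  mm, cfg, cloud=pc)
    return spec, render, mm, pc, out


def volume_errors_pct(render, results) -> dict[str, float]:
    """Per-segment relative volume error (%) of a pipeline result table."""
    truth = render.truth.segments.set_index("label")
    df = results.set_index("label")
    return {
        lab: 100.0 * (df.loc[lab, "V_scan_dm3"] - truth.loc[lab, "volume_m3"] * 1e3)
        / (truth.loc[lab, "volume_m3"] * 1e3)
        for lab in truth.index
    }


LIMBS = ("left_arm", "right_arm", "left_forearm", "right_forearm",
         "left_thigh", "right_thigh", "left_shank", "right_shank")
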