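"""Shared fixtures: small synthetic scenes reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from phantomqa import DetectionParams, SceneConfig, detect_wells, render_rud
from phantomqa.scene import DistortionField, GridSpec, IlluminationField


def small_config(**overrides) -> SceneConfig:
    """A fast 20 mm / 11x11-well scene rendered at 0.1 mm/px (256 px)."""
    defaults = dict(
        grid=GridSpec(well_diameter_mm=1.0, pitch_mm=2.0, extent_mm=20.0),
        image_shape=(256, 256),
        mm_per_pixel=0.1,
        psf_sigma_px=1.0,
        background_offset=200.0,
    )
    defaults.update(overrides)
    return SceneConfig(**defaults)


def detection_params(config: SceneConfig, **overrides) -> DetectionParams:
    defaults = dict(
        mm_per_pixel=config.mm_per_pixel,
        nominal_well_diameter_mm=config.grid.well_diameter_mm,
    )
    defaults.update(overrides)
    return DetectionParams(**defaults)


def radial_map_oracle(k1: float, k2: float, shape: tuple[int, int]):
    """Independent implementation of the Brown radial map for test oracles."""
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    r_norm = 0.5 * np.hypot(w, h)

    def forward(xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        dx, dy = xy[:, 0] - cx, xy[:, 1] - cy
        rn2 = (dx**2 + dy**2) / r_norm**2
        s = 1.0 + k1 * rn2 + k2 * rn2**2
        return np.column_stack([cx + dx * s, cy + dy * s])

    return forward


@pytest.fixture(scope="session")
def default_rud():
    """The full default dot-grid scene (2601 wells, 1024 px) plus detections."""
    cfg = SceneConfig()
    img, truth = render_rud(cfg)
    wells = detect_wells(img, detection_params(cfg))
    return cfg, img, truth, wells


@pytest.fixture(scope="session")
def small_rud():
    """Small clean scene plus detections (121 wells)."""
    cfg = small_config()
    img, truth = render_rud(cfg)
    wells = detect_wells(img, detection_params(cfg))
    return cfg, img, truth, wells
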