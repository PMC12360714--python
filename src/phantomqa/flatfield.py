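"""Flat-field correction from a fluorescence uniformity profile.

The correction multiplies each pixel by the inverse of the normalized
uniformity profile, so a region imaged at 50% relative efficiency is
doubled. The gain is clamped at ``1 / floor`` to bound amplification where
the profile approaches zero (the unilluminated frame edge); clamped pixels
are counted so downstream artifact analyses stay honest.

Because the profile is derived from *fluorescent* signal, it corrects
signal and additive background alike: a spatially constant background b at
local efficiency I becomes b / I > b after correction, so nonfluorescent
background is amplified toward the frame edge. This overshoot is a real
property of single-component flat-fielding, not a defect of the
implementation, and :func:`evaluate_flatness` quantifies it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .errors import FrameMismatchError, InvalidConfigError
from .uniformity import UniformityProfile, UniformitySamples, fit_surface

__all__ = ["CorrectionMap", "FlatnessReport", "build_correction", "apply_correction", "evaluate_flatness"]


@dataclass
class CorrectionMap:
    """Per-pixel inverse-profile gain, defined on the profile's valid region."""

    gain: np.ndarray  # (H, W); 1.0 outside the valid region
    valid_mask: np.ndarray  # (H, W) bool
    floor: float
    n_clamped: int
    profile_method: str


def build_correction(
    profile: UniformityProfile,
    floor: float = 0.05,
    image_shape: tuple[int, int] | None = None,
    *,
    edge_fill_px: float = 0.0,
) -> CorrectionMap:
    """Gain map = 1 / normalized profile, clamped at 1 / floor.

    The profile's decimated evaluation grid is bilinearly upsampled to the
    full pixel frame. Pixels outside the valid region get unit gain and a
    cleared mask bit; pixels whose profile value falls below ``floor`` are
    clamped and counted. ``edge_fill_px`` extends the valid region outward
    by that many pixels using the nearest valid profile value — useful so
    the outer halves of wells sitting on the hull boundary are corrected
    consistently with their inner halves.
    """
    if floor <= 0:
        raise InvalidConfigError("floor must be positive")
    shape = image_shape or profile.image_shape
    h, w = shape
    interp = RegularGridInterpolator(
        (profile.ys, profile.xs), profile.values, bounds_error=False, fill_value=np.nan
    )
    yy, xx = np.mgrid[0:h, 0:w]
    vals = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(h, w)
    valid = np.isfinite(vals)
    if not np.any(valid):
        raise InvalidConfigError("profile valid region is empty over this frame")
    if edge_fill_px > 0:
        from scipy.ndimage import distance_transform_edt

        dist, (iy, ix) = distance_transform_edt(~valid, return_indices=True)
        fill = (dist > 0) & (dist <= edge_fill_px)
        vals[fill] = vals[iy[fill], ix[fill]]
        valid = valid | fill
    clamped = valid & (vals < floor)
    vals = np.clip(vals, floor, 1.0)
    gain = np.ones((h, w), dtype=np.float64)
    gain[valid] = 1.0 / vals[valid]
    return CorrectionMap(
        gain=gain,
        valid_mask=valid,
        floor=floor,
        n_clamped=int(np.count_nonzero(clamped)),
        profile_method=profile.method,
    )


def apply_correction(image: np.ndarray, cmap: CorrectionMap) -> np.ndarray:
    """Pixelwise product of the image with the gain map.

    Pixels outside the valid region pass through unchanged (their gain is
    1); the map's ``valid_mask`` identifies them. Operates on raw float
    counts; re-quantization happens only at export.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != cmap.gain.shape:
        raise FrameMismatchError(f"image {image.shape} vs correction map {cmap.gain.shape}")
    return image * cmap.gain


@dataclass
class FlatnessReport:
    """Flatness of a refit uniformity surface after correction."""

    minimum: float  # min of the normalized refit surface (max is 1)
    maximum: float
    quantiles: dict[float, float]
    profile: UniformityProfile

    @property
    def flat_within(self) -> float:
        """Fraction of maximum within which the whole surface lies."""
        return self.minimum


def evaluate_flatness(samples: UniformitySamples, smoothing: float | str = "auto") -> FlatnessReport:
    """Refit corrected well samples with the b-spline method and report
    the min/max and quantile spread of the normalized surface.

    A perfect correction yields minimum = maximum = 1; an uncorrected
    nonuniform scene yields a minimum far below 1.
    """
    profile = fit_surface(samples, method="bspline", smoothing=smoothing)
    vals = profile.values[np.isfinite(profile.values)]
    qs = (0.01, 0.05, 0.50, 0.95, 0.99)
    return FlatnessReport(
        minimum=float(vals.min()),
        maximum=float(vals.max()),
        quantiles={q: float(np.quantile(vals, q)) for q in qs},
        profile=profile,
    )
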