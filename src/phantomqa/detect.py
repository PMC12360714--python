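"""Fluorescent-well detection: threshold, connected components, centroids.

This is the shared front end of the uniformity and distortion analyses: it
turns a phantom image into a list of :class:`DetectedWell` records (sub-pixel
centroid, mean intensity over the component, area), filtered by area and by
distance to the image border.

Coordinate convention: 0-based, origin at the top-left pixel center, x to
the right (columns), y downward (rows).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure
from skimage.filters import threshold_otsu

from .errors import OutOfBoundsError
from .imgio import bit_depth_max

__all__ = [
    "DetectedWell",
    "DetectionParams",
    "detect_wells",
    "measure_disk_roi",
    "wells_to_dataframe",
    "write_wells_csv",
]


@dataclass(frozen=True)
class DetectedWell:
    """One fluorescent dot: the atomic measurement of every analysis."""

    x: float
    y: float
    mean_intensity: float
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    saturated: bool = False
    source_image: str = ""

    @property
    def centroid(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass(frozen=True)
class DetectionParams:
    """Thresholding and filtering choices for well detection.

    ``threshold_method`` is Otsu by default (parameter-free and robust to
    overall gain); ``fixed`` uses ``threshold_value`` counts and
    ``quantile`` uses the ``quantile`` image quantile. ``min_area`` defaults
    to 25% of the nominal well footprint when the pixel scale and nominal
    well diameter are known, else 5 px. Components whose bounding box comes
    within ``border_margin`` px of the frame edge are discarded (their
    centroids are biased).

    ``intensity_mode`` selects how a well's mean intensity is measured:
    ``centroid_disk`` (default) averages a half-diameter disk ROI centered
    on the centroid, which sits on the well plateau and is insensitive to
    how much blurred edge clears the threshold; ``component`` averages the
    thresholded connected component itself.
    """

    threshold_method: str = "otsu"
    threshold_value: float | None = None
    quantile: float = 0.99
    min_area: int | None = None
    max_area: int | None = None
    border_margin: int = 2
    centroid_mode: str = "intensity_weighted"  # or "geometric"
    intensity_mode: str = "centroid_disk"  # or "component"
    mm_per_pixel: float | None = None
    nominal_well_diameter_mm: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed", "quantile"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold requires threshold_value")
        if self.centroid_mode not in ("intensity_weighted", "geometric"):
            raise ValueError(f"unknown centroid mode {self.centroid_mode!r}")
        if self.intensity_mode not in ("centroid_disk", "component"):
            raise ValueError(f"unknown intensity mode {self.intensity_mode!r}")
        if self.border_margin < 0:
            raise ValueError("border_margin must be >= 0")
        if self.min_area is not None and self.max_area is not None and not self.min_area < self.max_area:
            raise ValueError("min_area must be < max_area")

    def resolve_min_area(self) -> int:
        if self.min_area is not None:
            return self.min_area
        if self.mm_per_pixel and self.nominal_well_diameter_mm:
            r_px = 0.5 * self.nominal_well_diameter_mm / self.mm_per_pixel
            return max(int(0.25 * np.pi * r_px**2), 1)
        return 5


def _threshold(image: np.ndarray, params: DetectionParams) -> float:
    if params.threshold_method == "fixed":
        return float(params.threshold_value)  # type: ignore[arg-type]
    if params.threshold_method == "quantile":
        return float(np.quantile(image, params.quantile))
    return float(threshold_otsu(image))


def detect_wells(
    image: np.ndarray,
    params: DetectionParams | None = None,
    *,
    image_id: str = "",
    bit_depth: int | None = None,
) -> list[DetectedWell]:
    """Detect fluorescent wells as above-threshold connected components.

    Returns records sorted by (y, x). An empty image yields an empty list
    with a warning rather than an exception. Components containing any
    pixel at the bit-depth maximum are flagged ``saturated``.
    """
    params = params or DetectionParams()
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")

    thr = _threshold(image, params)
    mask = image > thr
    labels = measure.label(mask, connectivity=2)
    props = measure.regionprops(labels, intensity_image=image)

    min_area = params.resolve_min_area()
    max_area = params.max_area if params.max_area is not None else np.inf
    h, w = image.shape
    margin = params.border_margin
    sat_level = bit_depth_max(bit_depth) if bit_depth else np.inf

    wells: list[DetectedWell] = []
    for p in props:
        if not (min_area <= p.area <= max_area):
            continue
        r0, c0, r1, c1 = p.bbox
        if r0 < margin or c0 < margin or r1 > h - margin or c1 > w - margin:
            continue
        if params.centroid_mode == "intensity_weighted":
            # Weight by intensity in excess of the threshold: weights fall
            # continuously to zero at the component boundary, removing the
            # sub-pixel phase bias a hard truncation would introduce.
            coords = p.coords
            wts = image[coords[:, 0], coords[:, 1]] - thr
            cy, cx = (coords * wts[:, None]).sum(axis=0) / wts.sum()
        else:
            cy, cx = p.centroid
        if params.intensity_mode == "centroid_disk":
            # Half-diameter disk ROI at the centroid: the mean sits on the
            # well plateau, so it tracks local brightness faithfully where
            # a component mean would be biased by how much dim edge the
            # global threshold happens to include.
            if params.mm_per_pixel and params.nominal_well_diameter_mm:
                roi_r = 0.25 * params.nominal_well_diameter_mm / params.mm_per_pixel
            else:
                roi_r = 0.5 * float(np.sqrt(p.area / np.pi))
            try:
                mean_int, _, _ = measure_disk_roi(image, (float(cx), float(cy)), roi_r)
            except OutOfBoundsError:
                mean_int = float(p.intensity_mean)
        else:
            mean_int = float(p.intensity_mean)
        wells.append(
            DetectedWell(
                x=float(cx),
                y=float(cy),
                mean_intensity=mean_int,
                area=int(p.area),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                saturated=bool(p.intensity_max >= sat_level),
                source_image=image_id,
            )
        )
    if not wells:
        warnings.warn("no wells detected", stacklevel=2)
    wells.sort(key=lambda d: (d.y, d.x))
    return wells


def measure_disk_roi(image: np.ndarray, center: tuple[float, float], radius: float) -> tuple[float, float, int]:
    """Mean, SD, and pixel count over a circular ROI.

    The disk must lie fully inside the frame. A degenerate radius that
    captures no pixel center falls back to the single nearest pixel.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    cx, cy = center
    if cx - radius < -0.5 or cx + radius > w - 0.5 or cy - radius < -0.5 or cy + radius > h - 0.5:
        raise OutOfBoundsError(f"disk ROI at {center} with radius {radius} clipped by the frame")
    x0, x1 = int(np.floor(cx - radius)), int(np.ceil(cx + radius))
    y0, y1 = int(np.floor(cy - radius)), int(np.ceil(cy + radius))
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w - 1), min(y1, h - 1)
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = (xs - cx) ** 2 + (ys - cy) ** 2 <= radius**2
    if not np.any(inside):
        ix, iy = int(np.clip(round(cx), 0, w - 1)), int(np.clip(round(cy), 0, h - 1))
        vals = image[iy : iy + 1, ix : ix + 1].ravel()
    else:
        vals = image[y0 : y1 + 1, x0 : x1 + 1][inside]
    return float(vals.mean()), float(vals.std()), int(vals.size)


def wells_to_dataframe(wells: list[DetectedWell]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": [d.source_image for d in wells],
            "x_px": [d.x for d in wells],
            "y_px": [d.y for d in wells],
            "mean_intensity": [d.mean_intensity for d in wells],
            "area_px": [d.area for d in wells],
            "saturated": [d.saturated for d in wells],
        }
    )


def write_wells_csv(wells: list[DetectedWell], path: str | os.PathLike) -> None:
    wells_to_dataframe(wells).to_csv(path, index=False, float_format="%.6g")
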