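"""Synthetic phantom scenes with exact ground truth.

Renders the three physical targets used to characterize a fluorescence
imaging system:

* a dot-grid uniformity/distortion target — a square lattice of small,
  equally fluorescent wells (default 1 mm wells on a 2 mm pitch over a
  100 x 100 mm area, 2601 wells);
* a 9-well dilution-series target whose well intensities follow a power law
  of fluorophore concentration;
* a pair of large fluorescent cylinders for ROI-based flat-field checks.

Every render is driven by a :class:`SceneConfig` and returns both the image
and a ground-truth table (true well centers pre/post distortion, the local
illumination efficiency, and the true signal amplitude), so every analysis
stage downstream can be tested against known answers.

Physical model: well signal is multiplicative in the illumination/collection
efficiency field evaluated at the well center, the background offset is
additive and spatially constant, the optical blur is an isotropic Gaussian
PSF, and noise is either Gaussian or signal-proportional-variance Gaussian
("poisson_like"). Geometric distortion is a Brown-style radial polynomial
composed with a projective keystone map from a tilted object plane.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .errors import DegenerateSceneError, InvalidConfigError

__all__ = [
    "GridSpec",
    "IlluminationField",
    "DistortionField",
    "SceneConfig",
    "GroundTruth",
    "render_rud",
    "render_rcs",
    "render_cylinders",
    "DEFAULT_RCS_CONCENTRATIONS",
]

#: Default dilution series (nM) for the 9-well concentration target. The
#: physical target spans 0 (control) to 1000 nM; this roughly log-spaced
#: series is the package's fixture default.
DEFAULT_RCS_CONCENTRATIONS: tuple[float, ...] = (0.0, 1.0, 3.0, 10.0, 30.0, 60.0, 100.0, 300.0, 1000.0)


# ---------------------------------------------------------------------------
# Geometry of the dot grid
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Square lattice of fluorescent wells on the dot-grid target."""

    well_diameter_mm: float = 1.0
    pitch_mm: float = 2.0
    extent_mm: float = 100.0

    def __post_init__(self) -> None:
        if not (self.pitch_mm > self.well_diameter_mm > 0):
            raise InvalidConfigError(
                f"require pitch ({self.pitch_mm}) > well diameter ({self.well_diameter_mm}) > 0"
            )
        if self.extent_mm <= 0:
            raise InvalidConfigError("extent_mm must be positive")

    @property
    def wells_per_axis(self) -> int:
        return int(np.floor(self.extent_mm / self.pitch_mm)) + 1

    @property
    def total_wells(self) -> int:
        return self.wells_per_axis**2

    def lattice_mm(self) -> np.ndarray:
        """(N, 2) well centers in mm, centered on the target origin."""
        n = self.wells_per_axis
        axis = (np.arange(n) - (n - 1) / 2.0) * self.pitch_mm
        xx, yy = np.meshgrid(axis, axis)
        return np.column_stack([xx.ravel(), yy.ravel()])

    def lattice_indices(self) -> np.ndarray:
        n = self.wells_per_axis
        jj, ii = np.meshgrid(np.arange(n), np.arange(n))
        return np.column_stack([ii.ravel(), jj.ravel()])  # (row, col)


# ---------------------------------------------------------------------------
# Illumination / collection-efficiency field
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IlluminationField:
    """Smooth relative excitation x collection efficiency over the frame.

    Evaluates in image pixel coordinates to a strictly positive value,
    normalized so its maximum over the frame is 1. Kinds:

    ``uniform``
        constant 1.
    ``radial_gaussian``
        ``exp(-r^2 / (2 sigma^2))`` about ``center_frac`` of the frame, with
        ``sigma_frac`` in units of image width.
    ``separable_polynomial``
        ``px(x) * py(y)`` with polynomial coefficients over normalized
        [-1, 1] coordinates (``coeffs_x``/``coeffs_y``, highest degree first).
    ``tabulated``
        bilinear interpolation of a coarse ``values`` grid spanning the frame.
    """

    kind: str = "uniform"
    params: dict = field(default_factory=dict)

    _KINDS = ("uniform", "radial_gaussian", "separable_polynomial", "tabulated")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise InvalidConfigError(f"unknown illumination kind {self.kind!r}")

    def _raw(self, x: np.ndarray, y: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        h, w = shape
        if self.kind == "uniform":
            return np.ones_like(np.asarray(x, dtype=float))
        if self.kind == "radial_gaussian":
            cfx, cfy = self.params.get("center_frac", (0.5, 0.5))
            sigma = self.params.get("sigma_frac", 0.36) * w
            cx, cy = cfx * (w - 1), cfy * (h - 1)
            r2 = (np.asarray(x, float) - cx) ** 2 + (np.asarray(y, float) - cy) ** 2
            return np.exp(-r2 / (2.0 * sigma**2))
        if self.kind == "separable_polynomial":
            px = np.asarray(self.params.get("coeffs_x", [1.0]), dtype=float)
            py = np.asarray(self.params.get("coeffs_y", [1.0]), dtype=float)
            xn = 2.0 * np.asarray(x, float) / max(w - 1, 1) - 1.0
            yn = 2.0 * np.asarray(y, float) / max(h - 1, 1) - 1.0
            return np.polyval(px, xn) * np.polyval(py, yn)
        # tabulated
        values = np.asarray(self.params["values"], dtype=float)
        gy = np.linspace(0, h - 1, values.shape[0])
        gx = np.linspace(0, w - 1, values.shape[1])
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator((gy, gx), values, bounds_error=False, fill_value=None)
        pts = np.column_stack([np.asarray(y, float).ravel(), np.asarray(x, float).ravel()])
        return interp(pts).reshape(np.asarray(x).shape)

    def _norm_const(self, shape: tuple[int, int]) -> float:
        h, w = shape
        gx, gy = np.meshgrid(np.linspace(0, w - 1, 129), np.linspace(0, h - 1, 129))
        raw = self._raw(gx, gy, shape)
        m = float(np.max(raw))
        if not np.isfinite(m) or m <= 0 or np.min(raw) <= 0:
            raise InvalidConfigError("illumination field must be strictly positive over the frame")
        return m

    def evaluate(self, x: np.ndarray, y: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Relative efficiency in (0, 1] at pixel coordinates (x, y)."""
        out = self._raw(np.asarray(x, float), np.asarray(y, float), shape) / self._norm_const(shape)
        return np.minimum(out, 1.0)


# ---------------------------------------------------------------------------
# Geometric distortion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistortionField:
    """Brown-style radial distortion composed with a keystone projection.

    Radial: ``r' = r (1 + k1 rn^2 + k2 rn^4)`` with ``rn`` the radius
    normalized by half the image diagonal; ``k1 < 0`` is barrel, ``k1 > 0``
    pincushion. Keystone: the object plane is tilted by ``tilt_deg`` about
    the horizontal axis through the principal point and reprojected with an
    effective focal length of one image diagonal; ``tilt_deg = 0`` and
    ``k1 = k2 = 0`` is the identity map.
    """

    k1: float = 0.0
    k2: float = 0.0
    tilt_deg: float = 0.0
    center: tuple[float, float] | None = None  # principal point (x, y) px

    @property
    def is_identity(self) -> bool:
        return self.k1 == 0.0 and self.k2 == 0.0 and self.tilt_deg == 0.0

    def _center(self, shape: tuple[int, int]) -> tuple[float, float]:
        h, w = shape
        if self.center is not None:
            return tuple(self.center)  # type: ignore[return-value]
        return ((w - 1) / 2.0, (h - 1) / 2.0)

    def validate(self, shape: tuple[int, int]) -> None:
        """Check the map is invertible (monotone radius) over the frame."""
        rn = np.linspace(0.0, 1.0, 512)
        deriv = 1.0 + 3.0 * self.k1 * rn**2 + 5.0 * self.k2 * rn**4
        if np.any(deriv <= 0):
            raise InvalidConfigError("radial distortion is not invertible over the field of view")
        h, w = shape
        f = float(np.hypot(w, h))
        if f + (-(h / 2.0)) * np.sin(np.radians(self.tilt_deg)) <= 0:
            raise InvalidConfigError("keystone tilt too extreme for the field of view")

    def map_points(self, xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Apply the forward distortion to (N, 2) pixel coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        h, w = shape
        cx, cy = self._center(shape)
        r_norm = 0.5 * float(np.hypot(w, h))
        x = xy[:, 0] - cx
        y = xy[:, 1] - cy
        rn2 = (x**2 + y**2) / r_norm**2
        scale = 1.0 + self.k1 * rn2 + self.k2 * rn2**2
        x1, y1 = x * scale, y * scale
        t = np.radians(self.tilt_deg)
        f = 2.0 * r_norm  # effective focal length: one image diagonal
        denom = f + y1 * np.sin(t)
        x2 = x1 * f / denom
        y2 = y1 * np.cos(t) * f / denom
        return np.column_stack([x2 + cx, y2 + cy])


# ---------------------------------------------------------------------------
# Scene configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SceneConfig:
    """Full ground-truth description of a synthetic phantom image.

    Intensities are in detector counts. ``mm_per_pixel`` sets the object
    scale; ``target_offset_mm``/``target_rotation_deg`` place the phantom
    within the field of view (rotation about the target center, applied
    before the offset). With a fixed ``seed`` the render is bit-identical.
    """

    grid: GridSpec = field(default_factory=GridSpec)
    illumination: IlluminationField = field(default_factory=IlluminationField)
    distortion: DistortionField = field(default_factory=DistortionField)
    image_shape: tuple[int, int] = (1024, 1024)  # (H, W)
    mm_per_pixel: float = 0.1
    peak_intensity: float = 30000.0
    background_offset: float = 500.0
    psf_sigma_px: float = 1.5
    noise_model: str = "none"  # none | gaussian | poisson_like
    noise_strength: float = 0.0
    seed: int = 0
    target_offset_mm: tuple[float, float] = (0.0, 0.0)
    target_rotation_deg: float = 0.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.mm_per_pixel <= 0:
            raise InvalidConfigError("mm_per_pixel must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson_like"):
            raise InvalidConfigError(f"unknown noise model {self.noise_model!r}")
        if self.peak_intensity <= 0 or self.background_offset < 0:
            raise InvalidConfigError("peak_intensity must be > 0 and background_offset >= 0")
        if min(self.image_shape) < 8:
            raise InvalidConfigError("image_shape too small")

    def replace(self, **kwargs) -> "SceneConfig":
        return dataclasses.replace(self, **kwargs)

    # -- plain-text round trip -------------------------------------------

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "illumination": {"kind": self.illumination.kind, "params": dict(self.illumination.params)},
            "distortion": dataclasses.asdict(self.distortion),
            "image_shape": list(self.image_shape),
            "mm_per_pixel": self.mm_per_pixel,
            "peak_intensity": self.peak_intensity,
            "background_offset": self.background_offset,
            "psf_sigma_px": self.psf_sigma_px,
            "noise_model": self.noise_model,
            "noise_strength": self.noise_strength,
            "seed": self.seed,
            "target_offset_mm": list(self.target_offset_mm),
            "target_rotation_deg": self.target_rotation_deg,
            "bit_depth": self.bit_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        grid = GridSpec(**d.pop("grid", {}))
        illum = d.pop("illumination", {})
        illumination = IlluminationField(kind=illum.get("kind", "uniform"), params=illum.get("params", {}))
        dist = d.pop("distortion", {})
        if dist.get("center") is not None:
            dist["center"] = tuple(dist["center"])
        distortion = DistortionField(**dist)
        d["image_shape"] = tuple(d.get("image_shape", (1024, 1024)))
        d["target_offset_mm"] = tuple(d.get("target_offset_mm", (0.0, 0.0)))
        return cls(grid=grid, illumination=illumination, distortion=distortion, **d)

    def to_yaml(self, path: str | os.PathLike | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | os.PathLike) -> "SceneConfig":
        if os.path.exists(os.fspath(source)):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(io.StringIO(str(source)))
        return cls.from_dict(data)


@dataclass
class GroundTruth:
    """Per-well truth for a rendered scene (one row per rendered well)."""

    table: pd.DataFrame

    _COLUMNS = [
        "well_row",
        "well_col",
        "x_true_px",
        "y_true_px",
        "x_undist_px",
        "y_undist_px",
        "illum",
        "intensity_true",
    ]

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | os.PathLike) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "GroundTruth":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Rendering primitives
# ---------------------------------------------------------------------------

_SUPERSAMPLE = 4  # sub-pixel grid per axis for disk anti-aliasing


def _draw_disk(img: np.ndarray, cx: float, cy: float, radius: float, amplitude: float) -> None:
    """Accumulate an anti-aliased disk via 4x4 subpixel coverage sampling."""
    h, w = img.shape
    x0 = max(int(np.floor(cx - radius - 1)), 0)
    x1 = min(int(np.ceil(cx + radius + 1)), w - 1)
    y0 = max(int(np.floor(cy - radius - 1)), 0)
    y1 = min(int(np.ceil(cy + radius + 1)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    sub = (np.arange(_SUPERSAMPLE) + 0.5) / _SUPERSAMPLE - 0.5
    px = np.arange(x0, x1 + 1)
    py = np.arange(y0, y1 + 1)
    sx = (px[:, None] + sub[None, :]).ravel()  # (nx * S,)
    sy = (py[:, None] + sub[None, :]).ravel()
    in_x = (sx - cx) ** 2  # (nxS,)
    in_y = (sy - cy) ** 2
    inside = (in_y[:, None] + in_x[None, :]) <= radius**2
    cov = inside.reshape(len(py), _SUPERSAMPLE, len(px), _SUPERSAMPLE).mean(axis=(1, 3))
    img[y0 : y1 + 1, x0 : x1 + 1] += amplitude * cov


def _target_to_pixels(points_mm: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Rotate, offset, and scale target-frame mm coordinates to pixels."""
    h, w = config.image_shape
    th = np.radians(config.target_rotation_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    pts = points_mm @ rot.T + np.asarray(config.target_offset_mm, dtype=float)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    return pts / config.mm_per_pixel + np.array([cx, cy])


def _apply_noise(img: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise_model == "none" or config.noise_strength == 0:
        return img
    if config.noise_model == "gaussian":
        return img + rng.normal(0.0, config.noise_strength, img.shape)
    # poisson_like: gaussian with variance proportional to signal
    sd = config.noise_strength * np.sqrt(np.maximum(img, 0.0))
    return img + rng.normal(0.0, 1.0, img.shape) * sd


def _finalize(img: np.ndarray, config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    if config.psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, config.psf_sigma_px, mode="constant")
    img = img + config.background_offset
    return _apply_noise(img, config, rng)


def _render_disks(
    centers_px: np.ndarray,
    radius_px: float,
    amplitudes: np.ndarray,
    config: SceneConfig,
) -> np.ndarray:
    img = np.zeros(config.image_shape, dtype=np.float64)
    for (cx, cy), amp in zip(centers_px, amplitudes):
        _draw_disk(img, cx, cy, radius_px, amp)
    return img


def _inside_frame(centers_px: np.ndarray, radius_px: float, shape: tuple[int, int], margin: float = 1.0) -> np.ndarray:
    h, w = shape
    m = radius_px + margin
    return (
        (centers_px[:, 0] >= m)
        & (centers_px[:, 0] <= w - 1 - m)
        & (centers_px[:, 1] >= m)
        & (centers_px[:, 1] <= h - 1 - m)
    )


# ---------------------------------------------------------------------------
# Public render operations
# ---------------------------------------------------------------------------


def render_rud(config: SceneConfig) -> tuple[np.ndarray, GroundTruth]:
    """Render the dot-grid uniformity/distortion target.

    Returns the float image (counts) and the per-well ground truth. Wells
    whose footprint does not fit inside the frame are dropped from both the
    image and the truth table.
    """
    radius_px = 0.5 * config.grid.well_diameter_mm / config.mm_per_pixel
    pitch_px = config.grid.pitch_mm / config.mm_per_pixel
    if 2 * radius_px < 2.0:
        raise InvalidConfigError("well footprint under 2 pixels across; increase resolution")
    if pitch_px <= 2 * radius_px:
        raise InvalidConfigError("wells overlap: pitch must exceed diameter in pixels")
    config.distortion.validate(config.image_shape)

    lattice = config.grid.lattice_mm()
    indices = config.grid.lattice_indices()
    undist = _target_to_pixels(lattice, config)
    dist = config.distortion.map_points(undist, config.image_shape)

    keep = _inside_frame(dist, radius_px, config.image_shape)
    if not np.any(keep):
        raise DegenerateSceneError("no well fits inside the image frame")
    undist, dist, indices = undist[keep], dist[keep], indices[keep]

    illum = config.illumination.evaluate(dist[:, 0], dist[:, 1], config.image_shape)
    amplitudes = config.peak_intensity * illum

    img = _render_disks(dist, radius_px, amplitudes, config)
    rng = np.random.default_rng(config.seed)
    img = _finalize(img, config, rng)

    truth = GroundTruth(
        pd.DataFrame(
            {
                "well_row": indices[:, 0],
                "well_col": indices[:, 1],
                "x_true_px": dist[:, 0],
                "y_true_px": dist[:, 1],
                "x_undist_px": undist[:, 0],
                "y_undist_px": undist[:, 1],
                "illum": illum,
                "intensity_true": amplitudes,
            }
        )
    )
    return img, truth


def rcs_layout_mm(pitch_mm: float = 15.0) -> np.ndarray:
    """(9, 2) centers in mm of the 3x3 dilution-target wells (row-major)."""
    axis = (np.arange(3) - 1.0) * pitch_mm
    xx, yy = np.meshgrid(axis, axis)
    return np.column_stack([xx.ravel(), yy.ravel()])


def render_rcs(
    concentrations: Sequence[float],
    config: SceneConfig,
    *,
    m_true: float = 1.0,
    well_diameter_mm: float = 10.0,
    pitch_mm: float = 15.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render the 9-well dilution-series target.

    ``concentrations`` is the row-major 3x3 arrangement in nM; exactly one
    well must be the 0 nM control. Signal amplitude of each well is
    ``peak_intensity * (c / c_max)^m_true`` scaled by the illumination at
    the (distorted) well center; the background offset is additive.
    """
    conc = np.asarray(list(concentrations), dtype=float)
    if conc.shape != (9,):
        raise InvalidConfigError("exactly 9 concentrations required (3x3 layout)")
    if np.count_nonzero(conc == 0.0) != 1:
        raise InvalidConfigError("exactly one control well (0 nM) required")
    if np.any(conc < 0):
        raise InvalidConfigError("concentrations must be non-negative")
    config.distortion.validate(config.image_shape)

    radius_px = 0.5 * well_diameter_mm / config.mm_per_pixel
    centers_mm = rcs_layout_mm(pitch_mm)
    undist = _target_to_pixels(centers_mm, config)
    dist = config.distortion.map_points(undist, config.image_shape)
    if not np.all(_inside_frame(dist, radius_px, config.image_shape)):
        raise InvalidConfigError("dilution-target wells fall outside the frame")

    cmax = conc.max()
    with np.errstate(divide="ignore"):
        rel = np.where(conc > 0, (conc / cmax) ** m_true, 0.0)
    illum = config.illumination.evaluate(dist[:, 0], dist[:, 1], config.image_shape)
    amplitudes = config.peak_intensity * rel * illum

    img = _render_disks(dist, radius_px, amplitudes, config)
    rng = np.random.default_rng(config.seed)
    img = _finalize(img, config, rng)

    rows, cols = np.divmod(np.arange(9), 3)
    table = pd.DataFrame(
        {
            "well_row": rows,
            "well_col": cols,
            "x_true_px": dist[:, 0],
            "y_true_px": dist[:, 1],
            "x_undist_px": undist[:, 0],
            "y_undist_px": undist[:, 1],
            "illum": illum,
            "intensity_true": amplitudes,
        }
    )
    table["concentration_nM"] = conc
    table["well_diameter_px"] = 2.0 * radius_px
    return img, GroundTruth(table)


def render_cylinders(
    concentration_pair: tuple[float, float],
    position_mm: tuple[float, float],
    config: SceneConfig,
    *,
    diameter_mm: float = 10.0,
    separation_mm: float = 12.0,
    reference_concentration: float = 100.0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render two fluorescent cylinders side by side at ``position_mm``.

    Signal scales linearly with concentration, normalized so that
    ``reference_concentration`` maps to ``peak_intensity``; the cylinders
    are separated along x by ``separation_mm`` (center to center) about
    the stated position.
    """
    c_a, c_b = concentration_pair
    if separation_mm < diameter_mm:
        raise InvalidConfigError("cylinders overlap: separation below diameter")
    config.distortion.validate(config.image_shape)
    radius_px = 0.5 * diameter_mm / config.mm_per_pixel
    centers_mm = np.array(
        [
            [position_mm[0] - separation_mm / 2.0, position_mm[1]],
            [position_mm[0] + separation_mm / 2.0, position_mm[1]],
        ]
    )
    # Cylinders are placed directly in the field of view (not on the grid
    # target), so the target offset/rotation does not apply.
    h, w = config.image_shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    undist = centers_mm / config.mm_per_pixel + np.array([cx, cy])
    dist = config.distortion.map_points(undist, config.image_shape)
    if not np.all(_inside_frame(dist, radius_px, config.image_shape)):
        raise InvalidConfigError("cylinder disks fall outside the frame")

    conc = np.array([c_a, c_b], dtype=float)
    illum = config.illumination.evaluate(dist[:, 0], dist[:, 1], config.image_shape)
    amplitudes = config.peak_intensity * (conc / reference_concentration) * illum

    img = _render_disks(dist, radius_px, amplitudes, config)
    rng = np.random.default_rng(config.seed)
    img = _finalize(img, config, rng)

    table = pd.DataFrame(
        {
            "well_row": [0, 0],
            "well_col": [0, 1],
            "x_true_px": dist[:, 0],
            "y_true_px": dist[:, 1],
            "x_undist_px": undist[:, 0],
            "y_undist_px": undist[:, 1],
            "illum": illum,
            "intensity_true": amplitudes,
        }
    )
    table["concentration_nM"] = conc
    table["radius_px"] = radius_px
    return img, GroundTruth(table)
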