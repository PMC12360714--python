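"""Fluorescence-uniformity surfaces from detected wells.

A uniformity profile is a smooth surface fitted to the (x, y, intensity)
samples of the detected wells, normalized so its fitted maximum is 1, and
restricted to the convex hull of the samples (extrapolated spline behavior
at the frame edge is unreliable). Two fit methods are offered:

* ``bspline`` — bicubic smoothing spline (FITPACK); smoothing selected by
  k-fold cross-validation by default. Produces a smoothed representation.
* ``rbf`` — thin-plate-spline radial basis interpolation with a small ridge
  term; slower and noisier but preserves high-frequency structure (e.g. a
  sharp dip at the edge of a structured illumination pattern) that the
  b-spline smooths away.

Multiple images of the moving target in the fixed camera frame can be
pooled ("stitched") before fitting; the target moves, the camera does not,
so no registration is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator, RegularGridInterpolator, SmoothBivariateSpline
from scipy.spatial import Delaunay, cKDTree

from .detect import DetectedWell
from .errors import FitError, FrameMismatchError

__all__ = [
    "UniformitySamples",
    "UniformityProfile",
    "IsoMapSpec",
    "IsoMapResult",
    "pool_samples",
    "fit_surface",
    "iso_map",
    "line_profiles",
]


@dataclass(frozen=True)
class UniformitySamples:
    """Pooled (x, y, intensity) well samples in one camera pixel frame."""

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray
    image_shape: tuple[int, int]
    n_images: int = 1

    def __post_init__(self) -> None:
        h, w = self.image_shape
        if np.any(self.intensity <= 0):
            raise ValueError("sample intensities must be positive")
        if np.any((self.x < 0) | (self.x > w - 1) | (self.y < 0) | (self.y > h - 1)):
            raise ValueError("sample coordinates outside the image frame")

    def __len__(self) -> int:
        return len(self.x)


def pool_samples(
    well_lists: list[list[DetectedWell]],
    image_shape: tuple[int, int],
    *,
    merge_radius_px: float = 1.0,
) -> UniformitySamples:
    """Pool detections from one or more images of the same camera frame.

    All images must share ``image_shape``. Samples from different images
    that land within ``merge_radius_px`` of each other are treated as the
    same physical well re-imaged and averaged (position and intensity), so
    pooling an image with itself is idempotent.
    """
    if not well_lists or all(len(ws) == 0 for ws in well_lists):
        raise ValueError("no well samples to pool")
    xs, ys, zs = [], [], []
    for ws in well_lists:
        for d in ws:
            xs.append(d.x)
            ys.append(d.y)
            zs.append(d.mean_intensity)
    x = np.asarray(xs)
    y = np.asarray(ys)
    z = np.asarray(zs)

    # Union-find merge of samples closer than merge_radius_px.
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    parent = np.arange(len(pts))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in tree.query_pairs(merge_radius_px):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    roots = np.array([find(i) for i in range(len(pts))])
    df = pd.DataFrame({"root": roots, "x": x, "y": y, "z": z})
    merged = df.groupby("root", sort=False).mean()
    return UniformitySamples(
        x=merged["x"].to_numpy(),
        y=merged["y"].to_numpy(),
        intensity=merged["z"].to_numpy(),
        image_shape=tuple(image_shape),
        n_images=len(well_lists),
    )


def check_same_frame(shapes: list[tuple[int, int]]) -> tuple[int, int]:
    """All images must live in the same camera pixel frame."""
    unique = set(map(tuple, shapes))
    if len(unique) != 1:
        raise FrameMismatchError(f"images have mixed dimensions: {sorted(unique)}")
    return next(iter(unique))


# ---------------------------------------------------------------------------
# Surface fitting
# ---------------------------------------------------------------------------


@dataclass
class UniformityProfile:
    """Fitted, max-normalized uniformity surface over the field of view.

    ``values`` holds the normalized surface on the ``(ys, xs)`` evaluation
    lattice, clipped to [0, 1], NaN outside the valid region (the convex
    hull of the samples). ``norm_const`` is the fitted maximum in counts.
    """

    method: str
    xs: np.ndarray  # 1D grid of x pixel coordinates
    ys: np.ndarray  # 1D grid of y pixel coordinates
    values: np.ndarray  # (len(ys), len(xs)) normalized, NaN outside hull
    mask: np.ndarray  # bool valid-region mask on the grid
    norm_const: float
    image_shape: tuple[int, int]
    _hull: Delaunay | None = None
    _fitter: object | None = None  # raw-count evaluator

    def _raw_eval(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        if isinstance(self._fitter, SmoothBivariateSpline):
            return self._fitter.ev(x, y)
        if self._fitter is not None:
            pts = np.column_stack([np.ravel(x), np.ravel(y)])
            return np.asarray(self._fitter(pts)).reshape(np.shape(x))
        # Grid-only profile (e.g. reloaded from CSV): bilinear interpolation.
        interp = RegularGridInterpolator(
            (self.ys, self.xs), np.nan_to_num(self.values * self.norm_const), bounds_error=False, fill_value=np.nan
        )
        pts = np.column_stack([np.ravel(y), np.ravel(x)])
        return interp(pts).reshape(np.shape(x))

    def evaluate(self, x: np.ndarray, y: np.ndarray, *, extrapolate: bool = False) -> np.ndarray:
        """Normalized surface at arbitrary pixel coordinates.

        Outside the valid region the value is NaN unless ``extrapolate``
        is set (edge behavior of both fits is unreliable there).
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        vals = np.clip(self._raw_eval(x, y) / self.norm_const, 0.0, 1.0)
        if not extrapolate and self._hull is not None:
            pts = np.column_stack([np.ravel(x), np.ravel(y)])
            outside = self._hull.find_simplex(pts) < 0
            vals = np.where(outside.reshape(np.shape(x)), np.nan, vals)
        return vals

    def to_csv(self, path, meta_path=None) -> None:
        """Write the normalized surface grid as CSV plus a metadata sidecar."""
        import json

        pd.DataFrame(self.values).to_csv(path, index=False, header=False, float_format="%.6g")
        if meta_path is not None:
            meta = {
                "method": self.method,
                "norm_const": self.norm_const,
                "xs": [float(self.xs[0]), float(self.xs[-1]), len(self.xs)],
                "ys": [float(self.ys[0]), float(self.ys[-1]), len(self.ys)],
                "image_shape": list(self.image_shape),
            }
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=1)

    @classmethod
    def from_csv(cls, path, meta_path) -> "UniformityProfile":
        import json

        values = pd.read_csv(path, header=None).to_numpy(dtype=float)
        with open(meta_path) as fh:
            meta = json.load(fh)
        xs = np.linspace(meta["xs"][0], meta["xs"][1], int(meta["xs"][2]))
        ys = np.linspace(meta["ys"][0], meta["ys"][1], int(meta["ys"][2]))
        mask = np.isfinite(values)
        return cls(
            method=meta["method"],
            xs=xs,
            ys=ys,
            values=values,
            mask=mask,
            norm_const=float(meta["norm_const"]),
            image_shape=tuple(meta["image_shape"]),
        )


def _try_bspline(x, y, z, s) -> SmoothBivariateSpline | None:
    """Fit a bicubic FITPACK spline, rejecting numerically failed fits.

    FITPACK signals trouble at small smoothing via an ``ier`` warning while
    still returning a (garbage) surface, so both warnings and exceptions
    count as failure.
    """
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            spl = SmoothBivariateSpline(x, y, z, kx=3, ky=3, s=s)
        if any("ier" in str(w.message) for w in caught):
            return None
        return spl
    except Exception:
        return None


def _cv_smoothing_bspline(x, y, z, candidates, n_folds: int = 3) -> float:
    """Pick FITPACK smoothing by k-fold cross-validated prediction RMSE."""
    rng = np.random.default_rng(12345)  # fixed: model selection, not simulation
    idx = rng.permutation(len(x))
    folds = np.array_split(idx, n_folds)
    best_s, best_err = candidates[-1], np.inf
    for s in candidates:
        errs = []
        for k in range(n_folds):
            test = folds[k]
            train = np.concatenate([folds[j] for j in range(n_folds) if j != k])
            spl = _try_bspline(x[train], y[train], z[train], s)
            if spl is None:
                errs = []
                break
            errs.append(np.mean((spl.ev(x[test], y[test]) - z[test]) ** 2))
        if errs:
            err = float(np.mean(errs))
            if err < best_err:
                best_err, best_s = err, s
    return best_s


def fit_surface(
    samples: UniformitySamples,
    method: str = "bspline",
    smoothing: float | str = "auto",
    *,
    grid_shape: tuple[int, int] = (129, 129),
) -> UniformityProfile:
    """Fit a smooth surface to well samples and normalize to its maximum.

    ``smoothing`` is the FITPACK ``s`` for the b-spline (``"auto"`` selects
    it by cross-validation) or the ridge term of the RBF (``"auto"`` uses a
    small near-interpolating value). The normalization constant is the
    maximum of the *fitted* surface over the valid region, so isolated
    noisy samples do not set the scale.
    """
    if method not in ("bspline", "rbf"):
        raise ValueError(f"unknown fit method {method!r}")
    x, y, z = samples.x, samples.y, samples.intensity
    if len(x) < 16:
        raise FitError(f"need at least 16 samples, got {len(x)}")
    pts = np.column_stack([x, y])
    spread = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if spread[-1] < 1e-6 * max(spread[0], 1.0):
        raise FitError("sample geometry is rank deficient (collinear samples)")

    if method == "bspline":
        if smoothing == "auto":
            zvar = float(np.var(z)) or 1.0
            # FITPACK's s is an absolute residual budget, so it scales with
            # the sample count; select it by CV on a subsample when the
            # pool is large, then rescale to the full set.
            n_cv = min(len(z), 3000)
            if n_cv < len(z):
                rng = np.random.default_rng(2024)
                sub = rng.choice(len(z), n_cv, replace=False)
                xc, yc, zc = x[sub], y[sub], z[sub]
            else:
                xc, yc, zc = x, y, z
            candidates = n_cv * zvar * np.logspace(-7, 0, 6)
            s = _cv_smoothing_bspline(xc, yc, zc, list(candidates)) * (len(z) / n_cv)
        else:
            s = float(smoothing)
        fitter: object | None = _try_bspline(x, y, z, s)
        while fitter is None:
            # Escalate smoothing until FITPACK produces a sound surface.
            s = 10.0 * s if s > 0 else float(len(z))
            if s > 1e3 * len(z) * (float(np.var(z)) or 1.0):
                raise FitError("b-spline fit failed at every smoothing level")
            fitter = _try_bspline(x, y, z, s)
    else:
        zscale = float(np.max(z))
        smooth = 1e-6 * len(z) if smoothing == "auto" else float(smoothing)
        neighbors = None if len(z) <= 2000 else 64
        rbf = RBFInterpolator(
            pts, z / zscale, kernel="thin_plate_spline", smoothing=smooth, neighbors=neighbors
        )
        fitter = _RBFEvaluator(rbf, zscale)

    hull = Delaunay(pts)
    gy, gx = grid_shape
    xs = np.linspace(x.min(), x.max(), gx)
    ys = np.linspace(y.min(), y.max(), gy)
    gxx, gyy = np.meshgrid(xs, ys)
    if isinstance(fitter, SmoothBivariateSpline):
        raw = fitter.ev(gxx.ravel(), gyy.ravel()).reshape(gyy.shape)
    else:
        raw = fitter(np.column_stack([gxx.ravel(), gyy.ravel()])).reshape(gyy.shape)
    mask = hull.find_simplex(np.column_stack([gxx.ravel(), gyy.ravel()])).reshape(gyy.shape) >= 0

    if np.any(raw[mask] < 0):
        warnings.warn("negative fitted surface values clipped to 0", stacklevel=2)
        raw = np.maximum(raw, 0.0)
    norm = float(np.max(raw[mask]))
    if norm <= 0:
        raise FitError("fitted surface is non-positive over the valid region")
    values = np.where(mask, np.clip(raw / norm, 0.0, 1.0), np.nan)
    return UniformityProfile(
        method=method,
        xs=xs,
        ys=ys,
        values=values,
        mask=mask,
        norm_const=norm,
        image_shape=samples.image_shape,
        _hull=hull,
        _fitter=fitter,
    )


class _RBFEvaluator:
    """RBF fitted on rescaled intensities; undoes the scale on evaluation."""

    def __init__(self, rbf: RBFInterpolator, zscale: float):
        self.rbf = rbf
        self.zscale = zscale

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.rbf(pts) * self.zscale


# ---------------------------------------------------------------------------
# Interrogation: iso-maps and line profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IsoMapSpec:
    """Fractions of maximum at which to contour the uniformity surface."""

    thresholds: tuple[float, ...] = (0.60, 0.80, 0.90, 0.95)

    def __post_init__(self) -> None:
        t = self.thresholds
        if not all(0 < a < 1 for a in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly increasing and inside (0, 1)")


@dataclass
class IsoMapResult:
    thresholds: tuple[float, ...]
    masks: dict[float, np.ndarray]
    fractions: dict[float, float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": list(self.thresholds), "fraction_above": [self.fractions[t] for t in self.thresholds]}
        )


def iso_map(profile: UniformityProfile, spec: IsoMapSpec | None = None) -> IsoMapResult:
    """Masks of the valid region at or above each fraction of maximum.

    Masks are nested (higher threshold implies lower), and each fraction is
    the share of the valid region at or above that threshold.
    """
    spec = spec or IsoMapSpec()
    valid = profile.mask & np.isfinite(profile.values)
    n_valid = int(np.count_nonzero(valid))
    masks, fractions = {}, {}
    for t in spec.thresholds:
        m = valid & (profile.values >= t)
        masks[t] = m
        fractions[t] = float(np.count_nonzero(m) / n_valid) if n_valid else float("nan")
    return IsoMapResult(spec.thresholds, masks, fractions)


def line_profiles(
    profile: UniformityProfile,
    axis: str = "horizontal",
    positions: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> dict[float, pd.DataFrame]:
    """Normalized-intensity curves along rows or columns of the frame.

    ``positions`` are fractions of the frame (quarters by default). For a
    horizontal profile the curve runs along x at y = position * (H - 1).
    Points outside the valid region are NaN; a position whose entire curve
    is invalid yields an empty frame with a warning.
    """
    if axis not in ("horizontal", "vertical"):
        raise ValueError("axis must be 'horizontal' or 'vertical'")
    if not all(0 < p < 1 for p in positions):
        raise ValueError("positions must be in (0, 1)")
    h, w = profile.image_shape
    out: dict[float, pd.DataFrame] = {}
    for p in positions:
        if axis == "horizontal":
            coords = np.linspace(profile.xs[0], profile.xs[-1], len(profile.xs))
            vals = profile.evaluate(coords, np.full_like(coords, p * (h - 1)))
        else:
            coords = np.linspace(profile.ys[0], profile.ys[-1], len(profile.ys))
            vals = profile.evaluate(np.full_like(coords, p * (w - 1)), coords)
        if not np.any(np.isfinite(vals)):
            warnings.warn(f"line profile at position {p} lies entirely outside the valid region", stacklevel=2)
            out[p] = pd.DataFrame({"coord_px": [], "value": []})
        else:
            out[p] = pd.DataFrame({"coord_px": coords, "value": vals})
    return out
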