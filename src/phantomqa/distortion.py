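"""Local geometric distortion from a dot-grid target.

A regular reference grid is estimated from the wells near the image center
(where distortion is assumed negligible, as in ISO-style dot-target
methods), wells are matched to grid points, and the local distortion of
each well is

    distortion(%) = 100 * (actual - expected) / expected

where *actual* is the distance from the image center to the measured well
centroid and *expected* the distance from the image center to the matched
reference-grid point. Negative values at increasing radius indicate barrel
distortion, positive pincushion; a left/right or top/bottom asymmetry in
the 2D distortion map is the signature of keystone (tilted-plane)
distortion.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .detect import DetectedWell
from .errors import InsufficientCenterError, PhantomQAError

__all__ = [
    "ReferenceGrid",
    "Correspondence",
    "MatchResult",
    "DistortionRecord",
    "DistortionReport",
    "build_reference_grid",
    "match_wells",
    "compute_distortion",
    "keystone_asymmetry",
    "distortion_percent",
    "image_center",
]


def image_center(image_shape: tuple[int, int]) -> tuple[float, float]:
    """Sub-pixel image center: ((W-1)/2, (H-1)/2) in (x, y)."""
    h, w = image_shape
    return ((w - 1) / 2.0, (h - 1) / 2.0)


def distortion_percent(actual: float, expected: float) -> float:
    """Local distortion in percent from actual and expected center distances."""
    if expected <= 0:
        raise ValueError("expected distance must be positive")
    return 100.0 * (actual - expected) / expected


@dataclass(frozen=True)
class ReferenceGrid:
    """Ideal lattice anchored at the well nearest the image center."""

    anchor: tuple[float, float]  # pixel position of the central lattice point
    basis: np.ndarray  # (2, 2): rows are the two lattice basis vectors (px)
    index_range: tuple[tuple[int, int], tuple[int, int]]  # ((imin, imax), (jmin, jmax))
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        b1, b2 = self.basis
        cross = abs(b1[0] * b2[1] - b1[1] * b2[0])
        n1, n2 = np.linalg.norm(b1), np.linalg.norm(b2)
        if cross < 1e-6 * n1 * n2:
            raise PhantomQAError("reference-grid basis vectors are parallel")
        if not (0.75 <= n1 / n2 <= 1.25):
            raise PhantomQAError("reference-grid basis lengths differ by more than 25% (not a square lattice)")

    @property
    def pitch_px(self) -> float:
        return float(np.mean([np.linalg.norm(b) for b in self.basis]))

    def predict(self, ij: np.ndarray) -> np.ndarray:
        """Pixel positions of lattice indices (N, 2) -> (N, 2)."""
        ij = np.atleast_2d(np.asarray(ij, dtype=float))
        return np.asarray(self.anchor) + ij @ self.basis

    def lattice_coords(self, xy: np.ndarray) -> np.ndarray:
        """Continuous lattice coordinates of pixel positions."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return np.linalg.solve(self.basis.T, (xy - np.asarray(self.anchor)).T).T


def _fold_angle(angles: np.ndarray) -> float:
    """Mean lattice orientation of displacement angles, folded mod 90 deg."""
    # Multiply by 4 so that all four lattice directions coincide on the circle.
    c = np.mean(np.cos(4 * angles))
    s = np.mean(np.sin(4 * angles))
    return float(np.arctan2(s, c) / 4.0)


def build_reference_grid(
    wells: list[DetectedWell],
    image_shape: tuple[int, int],
    *,
    central_window_frac: float = 0.2,
    min_central_wells: int = 9,
) -> ReferenceGrid:
    """Estimate the ideal lattice from wells near the image center.

    The central window is a disk of diameter ``central_window_frac`` of the
    image diagonal. Orientation and pitch are first estimated from
    nearest-neighbor displacements of the central wells, then refined by a
    least-squares lattice fit anchored at the well nearest the center; the
    scale is finally re-estimated from only the first two lattice rings
    around the anchor, where residual lens distortion is negligible.
    """
    pos = np.array([[d.x, d.y] for d in wells], dtype=float)
    if len(pos) < min_central_wells:
        raise InsufficientCenterError(f"need at least {min_central_wells} wells, got {len(pos)}")
    cx, cy = image_center(image_shape)
    diag = float(np.hypot(*image_shape))
    dist_c = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    central = dist_c <= 0.5 * central_window_frac * diag
    if np.count_nonzero(central) < min_central_wells:
        raise InsufficientCenterError(
            f"only {np.count_nonzero(central)} wells within the central window; "
            f"need at least {min_central_wells}"
        )
    cpos = pos[central]
    anchor = tuple(pos[np.argmin(dist_c)])

    # Initial pitch and orientation from central nearest-neighbor vectors.
    tree = cKDTree(cpos)
    dd, ii = tree.query(cpos, k=min(5, len(cpos)))
    pitch0 = float(np.median(dd[:, 1]))
    vecs = []
    for a in range(len(cpos)):
        for b, d in zip(ii[a, 1:], dd[a, 1:]):
            if 0.7 * pitch0 <= d <= 1.3 * pitch0:
                vecs.append(cpos[b] - cpos[a])
    vecs = np.asarray(vecs)
    if len(vecs) < 4:
        raise InsufficientCenterError("too few neighbor pairs near the center to orient the lattice")
    theta = _fold_angle(np.arctan2(vecs[:, 1], vecs[:, 0]))
    b1 = pitch0 * np.array([np.cos(theta), np.sin(theta)])
    b2 = pitch0 * np.array([-np.sin(theta), np.cos(theta)])
    basis = np.vstack([b1, b2])

    # Least-squares lattice fit over the central wells (anchor held fixed).
    for _ in range(2):
        lat = np.linalg.solve(basis.T, (cpos - anchor).T).T
        ij = np.rint(lat)
        nonzero = np.any(ij != 0, axis=1)
        if np.count_nonzero(nonzero) < 4:
            break
        a_mat = ij[nonzero]
        rhs = cpos[nonzero] - anchor
        basis, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)

    # Scale refinement on the innermost rings (|i|^2 + |j|^2 <= 2).
    lat = np.linalg.solve(basis.T, (cpos - anchor).T).T
    ij = np.rint(lat)
    ring = (np.sum(ij**2, axis=1) <= 2.01) & np.any(ij != 0, axis=1)
    if np.count_nonzero(ring) >= 4:
        pred = ij[ring] @ basis
        meas = cpos[ring] - anchor
        scale = float(np.mean(np.linalg.norm(meas, axis=1) / np.linalg.norm(pred, axis=1)))
        basis = basis * scale

    # Index range covering all detections, padded because distortion can
    # pull the outermost ring inward by more than half a pitch.
    pad = 2
    lat_all = np.linalg.solve(basis.T, (pos - anchor).T).T
    ij_all = np.rint(lat_all).astype(int)
    irange = (int(ij_all[:, 0].min()) - pad, int(ij_all[:, 0].max()) + pad)
    jrange = (int(ij_all[:, 1].min()) - pad, int(ij_all[:, 1].max()) + pad)
    return ReferenceGrid(anchor=anchor, basis=basis, index_range=(irange, jrange), image_shape=tuple(image_shape))


@dataclass(frozen=True)
class Correspondence:
    well: DetectedWell
    index: tuple[int, int]
    reference_xy: tuple[float, float]


@dataclass
class MatchResult:
    correspondences: list[Correspondence]
    unmatched_wells: list[DetectedWell]
    grid: ReferenceGrid


def match_wells(
    wells: list[DetectedWell],
    grid: ReferenceGrid,
    tolerance: float = 0.5,
) -> MatchResult:
    """Match wells to reference-grid points, growing outward from the center.

    ``tolerance`` is a fraction of the lattice pitch. Because distortion is
    smooth, each lattice point's predicted position is corrected by the mean
    offset of its already-matched neighbors before the nearest-well search;
    this keeps correspondences unambiguous even when the cumulative
    displacement of outer wells exceeds half a pitch. Wells more than the
    tolerance away from every (corrected) grid point — e.g. spurious
    detections between lattice sites — are reported unmatched.
    """
    pos = np.array([[d.x, d.y] for d in wells], dtype=float)
    tree = cKDTree(pos)
    tol_px = tolerance * grid.pitch_px
    (imin, imax), (jmin, jmax) = grid.index_range

    matched: dict[tuple[int, int], int] = {}
    offsets: dict[tuple[int, int], np.ndarray] = {}
    claimed: set[int] = set()

    # Seed at the anchor (lattice index (0, 0)).
    d0, i0 = tree.query(np.asarray(grid.anchor))
    if d0 > tol_px:
        return MatchResult([], list(wells), grid)
    matched[(0, 0)] = int(i0)
    offsets[(0, 0)] = pos[i0] - np.asarray(grid.anchor)
    claimed.add(int(i0))

    from collections import deque

    queue: deque[tuple[int, int]] = deque([(0, 0)])
    visited: set[tuple[int, int]] = {(0, 0)}
    while queue:
        ci, cj = queue.popleft()
        for ni, nj in ((ci + 1, cj), (ci - 1, cj), (ci, cj + 1), (ci, cj - 1)):
            if (ni, nj) in visited or not (imin <= ni <= imax and jmin <= nj <= jmax):
                continue
            visited.add((ni, nj))
            neigh = [
                offsets[(ni + di, nj + dj)]
                for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
                if (ni + di, nj + dj) in offsets
            ]
            correction = np.mean(neigh, axis=0) if neigh else np.zeros(2)
            predicted = grid.predict([(ni, nj)])[0] + correction
            dists, idxs = tree.query(predicted, k=min(3, len(pos)))
            dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
            hit = None
            for d, idx in zip(dists, idxs):
                if d <= tol_px and int(idx) not in claimed:
                    hit = int(idx)
                    break
            if hit is not None:
                matched[(ni, nj)] = hit
                offsets[(ni, nj)] = pos[hit] - grid.predict([(ni, nj)])[0]
                claimed.add(hit)
            queue.append((ni, nj))

    correspondences = [
        Correspondence(well=wells[w], index=ij, reference_xy=tuple(grid.predict([ij])[0]))
        for ij, w in sorted(matched.items())
    ]
    unmatched = [wells[k] for k in range(len(wells)) if k not in claimed]
    return MatchResult(correspondences, unmatched, grid)


@dataclass(frozen=True)
class DistortionRecord:
    x: float
    y: float
    actual_distance: float
    expected_distance: float
    distortion_pct: float
    index: tuple[int, int]
    image_id: str = ""


@dataclass
class DistortionReport:
    """All matched-well distortion records plus summary statistics."""

    records: pd.DataFrame
    max_abs_distortion: float
    sign: str  # barrel | pincushion | none

    def radial_data(self) -> pd.DataFrame:
        """Distortion vs actual distance from the image center."""
        return self.records[["actual_dist_px", "distortion_pct"]].sort_values("actual_dist_px")

    def to_csv(self, path: str | os.PathLike) -> None:
        self.records.to_csv(path, index=False, float_format="%.6g")


def compute_distortion(
    match: MatchResult,
    image_shape: tuple[int, int] | None = None,
    *,
    image_id: str = "",
) -> DistortionReport:
    """Per-well local distortion against the reference grid.

    The central well (expected distance 0) carries no distortion value and
    is excluded. The overall sign classification (barrel vs pincushion) is
    the mean distortion sign of the outer half of the radial range.
    """
    shape = image_shape or match.grid.image_shape
    cx, cy = image_center(shape)
    rows = []
    for c in match.correspondences:
        actual = float(np.hypot(c.well.x - cx, c.well.y - cy))
        expected = float(np.hypot(c.reference_xy[0] - cx, c.reference_xy[1] - cy))
        if expected < 1e-9:
            continue
        rows.append(
            {
                "x_px": c.well.x,
                "y_px": c.well.y,
                "actual_dist_px": actual,
                "expected_dist_px": expected,
                "distortion_pct": distortion_percent(actual, expected),
                "well_i": c.index[0],
                "well_j": c.index[1],
                "image_id": image_id or c.well.source_image,
            }
        )
    if not rows:
        raise PhantomQAError("no non-central correspondences: distortion undefined")
    df = pd.DataFrame(rows)
    max_abs = float(df["distortion_pct"].abs().max())
    outer = df[df["expected_dist_px"] >= 0.5 * df["expected_dist_px"].max()]
    mean_outer = float(outer["distortion_pct"].mean())
    if mean_outer < -0.02:
        sign = "barrel"
    elif mean_outer > 0.02:
        sign = "pincushion"
    else:
        sign = "none"
    return DistortionReport(records=df, max_abs_distortion=max_abs, sign=sign)


def keystone_asymmetry(report: DistortionReport, image_shape: tuple[int, int]) -> dict[str, float]:
    """Left/right and top/bottom mean-distortion differentials.

    Both differentials are near zero for radially symmetric distortion; a
    tilted object plane produces a sign split across one axis (one side
    positive, the other negative), and flipping the tilt flips the signs.
    """
    cx, cy = image_center(image_shape)
    df = report.records
    halves = {
        "left": df[df["x_px"] < cx]["distortion_pct"],
        "right": df[df["x_px"] > cx]["distortion_pct"],
        "top": df[df["y_px"] < cy]["distortion_pct"],
        "bottom": df[df["y_px"] > cy]["distortion_pct"],
    }
    means = {k: (float(v.mean()) if len(v) else float("nan")) for k, v in halves.items()}
    return {
        "left_mean_pct": means["left"],
        "right_mean_pct": means["right"],
        "top_mean_pct": means["top"],
        "bottom_mean_pct": means["bottom"],
        "left_right_differential_pct": means["left"] - means["right"],
        "top_bottom_differential_pct": means["top"] - means["bottom"],
    }
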