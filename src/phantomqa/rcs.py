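"""Concentration-linearity analysis of the 9-well dilution-series target.

The target holds nine wells spanning a fluorophore dilution series
including one 0 nM control. Each well's mean intensity y is measured in a
circular ROI of half the well diameter, baselined by subtracting the
control mean, normalized to the maximum, and fitted to the power law

    y = 10^C * x^m

by ordinary least squares in log10-log10 space. The slope m is the
linearity measure; an ideal system gives m = 1. Wells whose baselined
intensity is non-positive (e.g. when flat-field correction amplifies the
control above a low-concentration well) cannot enter the log fit and are
excluded with a recorded reason.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .detect import measure_disk_roi
from .errors import FitError, InvalidConfigError
from .flatfield import CorrectionMap, apply_correction
from .scene import GroundTruth, SceneConfig, render_rcs

__all__ = ["RCSWell", "RCSFit", "extract_rcs_wells", "fit_linearity", "linearity_experiment"]


@dataclass(frozen=True)
class RCSWell:
    """One dilution-series well: concentration and ROI statistics."""

    concentration: float  # nM
    roi_mean: float  # counts
    roi_sd: float = 0.0
    n_pixels: int = 0
    x: float = float("nan")
    y: float = float("nan")


@dataclass
class RCSFit:
    """Power-law fit y = 10^C * x^m of normalized baselined intensities."""

    C: float
    m: float
    r_squared: float
    n_included: int
    excluded: list[tuple[float, str]]  # (concentration, reason)
    table: pd.DataFrame  # per-well concentration, baselined, normalized, included


def extract_rcs_wells(
    image: np.ndarray,
    centers_px: np.ndarray,
    diameters_px: np.ndarray | float,
    concentrations: np.ndarray,
) -> list[RCSWell]:
    """Measure the nine wells with half-diameter circular ROIs.

    The ROI radius is a quarter of the well diameter (i.e. the ROI diameter
    is half the well diameter, scaling from 10 mm wells down to 1 mm dots).
    ROIs clipped by the frame raise an error.
    """
    centers = np.atleast_2d(np.asarray(centers_px, dtype=float))
    conc = np.asarray(concentrations, dtype=float)
    if len(centers) != 9 or len(conc) != 9:
        raise InvalidConfigError("the dilution target has exactly 9 wells")
    if np.count_nonzero(conc == 0.0) != 1:
        raise InvalidConfigError("exactly one control well (0 nM) required")
    diam = np.broadcast_to(np.asarray(diameters_px, dtype=float), (9,))
    wells = []
    for (cx, cy), d, c in zip(centers, diam, conc):
        mean, sd, n = measure_disk_roi(image, (cx, cy), d / 4.0)
        wells.append(RCSWell(concentration=float(c), roi_mean=mean, roi_sd=sd, n_pixels=n, x=cx, y=cy))
    return wells


def fit_linearity(wells: list[RCSWell]) -> RCSFit:
    """Baseline, normalize, and fit the log-log concentration response.

    Baselining subtracts the control (0 nM) ROI mean from every well, so a
    spatially constant offset added to all wells cancels exactly.
    Normalization divides by the maximum baselined value among *included*
    wells (exclusions are applied first). The fit is an unweighted
    least-squares line in (log10 x, log10 normalized y).
    """
    conc = np.array([w.concentration for w in wells])
    if np.count_nonzero(conc == 0.0) != 1:
        raise InvalidConfigError("exactly one control well (0 nM) required")
    control = next(w for w in wells if w.concentration == 0.0)
    baselined = np.array([w.roi_mean - control.roi_mean for w in wells])

    excluded: list[tuple[float, str]] = []
    include = np.zeros(len(wells), dtype=bool)
    for k, w in enumerate(wells):
        if w.concentration == 0.0:
            excluded.append((0.0, "control well"))
        elif baselined[k] <= 0:
            excluded.append((w.concentration, "non-positive baselined intensity"))
        else:
            include[k] = True
    n_inc = int(np.count_nonzero(include))
    if n_inc < 3:
        raise FitError(
            f"only {n_inc} usable wells after baselining; exclusions: {excluded}"
        )
    norm = baselined[include].max()
    normalized = np.where(include, baselined / norm, np.nan)

    lx = np.log10(conc[include])
    ly = np.log10(normalized[include])
    m, C = np.polyfit(lx, ly, 1)
    resid = ly - (C + m * lx)
    ss_tot = float(np.sum((ly - ly.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0

    table = pd.DataFrame(
        {
            "concentration_nM": conc,
            "roi_mean": [w.roi_mean for w in wells],
            "baselined": baselined,
            "normalized": normalized,
            "included": include,
        }
    )
    return RCSFit(C=float(C), m=float(m), r_squared=r2, n_included=n_inc, excluded=excluded, table=table)


def _wells_from_truth(image: np.ndarray, truth: GroundTruth) -> list[RCSWell]:
    t = truth.table
    centers = t[["x_true_px", "y_true_px"]].to_numpy()
    return extract_rcs_wells(
        image, centers, t["well_diameter_px"].to_numpy(), t["concentration_nM"].to_numpy()
    )


def linearity_experiment(
    config: SceneConfig,
    concentrations,
    placements: list[tuple[str, tuple[float, float], float]],
    correction: CorrectionMap | None,
    *,
    m_true: float = 1.0,
    well_diameter_mm: float = 10.0,
    pitch_mm: float = 15.0,
) -> pd.DataFrame:
    """Fit linearity for several target placements, pre and post correction.

    ``placements`` is a list of ``(label, offset_mm, rotation_deg)``. For
    each, the dilution target is rendered at that position/orientation,
    analyzed raw, then (if ``correction`` is given) flat-field corrected
    and re-analyzed. Per-placement failures are recorded in the table and
    do not abort the remaining placements.
    """
    rows = []
    for label, offset, rot in placements:
        cfg = config.replace(target_offset_mm=tuple(offset), target_rotation_deg=rot)
        row: dict = {"label": label, "offset_x_mm": offset[0], "offset_y_mm": offset[1], "rotation_deg": rot}
        try:
            img, truth = render_rcs(
                concentrations, cfg, m_true=m_true, well_diameter_mm=well_diameter_mm, pitch_mm=pitch_mm
            )
            pre = fit_linearity(_wells_from_truth(img, truth))
            row.update(m_pre=pre.m, r2_pre=pre.r_squared, n_excluded_pre=len(pre.excluded) - 1)
            if correction is not None:
                corrected = apply_correction(img, correction)
                post = fit_linearity(_wells_from_truth(corrected, truth))
                row.update(m_post=post.m, r2_post=post.r_squared, n_excluded_post=len(post.excluded) - 1)
        except Exception as exc:  # keep other placements alive
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
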