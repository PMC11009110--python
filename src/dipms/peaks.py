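"""Elution peak analysis: FWHM areas, stoichiometry, occupancy, apparent MW.

A protein peak is a local maximum of the 0-1 rescaled elution profile with a
minimal height above background of 0.2 and a minimal width of three
fractions (counted at half maximum). Peak bounds are the half-maximum
crossings, located by linear interpolation between fractions; the peak area
is the trapezoid integral of the profile between those bounds.

Co-apexing peaks of several proteins form a peak group; within a group the
protein with the smallest FWHM area is the stoichiometric unit and every
member's stoichiometry is its area divided by that minimum. A peak's
occupancy is its area divided by the protein's total signal across the whole
fractionation dimension. Apparent molecular weights come from a log-linear
calibration against native MW standards run on the same gel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "Peak",
    "PeakGroup",
    "CalibrationCurve",
    "pick_peaks",
    "peak_metrics",
    "group_peaks",
    "stoichiometry",
    "occupancy",
    "mw_calibration",
    "apparent_mw",
    "trapezoid_between",
]


@dataclass
class Peak:
    """One elution peak in 1-based fraction coordinates."""

    protein_id: str
    apex_fraction: float
    left: float = np.nan     # half-maximum bounds (real-valued fractions)
    right: float = np.nan
    height: float = np.nan   # on the 0-1 rescaled scale
    fwhm_area: float = np.nan


@dataclass
class PeakGroup:
    """Co-apexing peaks of several proteins sharing one assembly."""

    peaks: list[Peak]
    apex_fraction: float
    apparent_mw_kda: float | None = None
    stoichiometry: dict = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return [p.protein_id for p in self.peaks]


@dataclass
class CalibrationCurve:
    """Least-squares fit of log10(MW/kDa) against fraction index."""

    slope: float
    intercept: float
    residuals: np.ndarray
    fraction_range: tuple[float, float]


def _interp_crossing(x0: float, y0: float, x1: float, y1: float, level: float) -> float:
    if y1 == y0:
        return x0
    return x0 + (level - y0) * (x1 - x0) / (y1 - y0)


def pick_peaks(
    profile: np.ndarray,
    fractions: np.ndarray | None = None,
    min_width: int = 3,
    min_height: float = 0.2,
    protein_id: str = "",
) -> list[Peak]:
    """Detect peaks in a 0-1 rescaled profile.

    A local maximum qualifies when its height is >= ``min_height`` and at
    least ``min_width`` consecutive fractions around the apex sit at or above
    half of the apex height. Bounds are the interpolated half-maximum
    crossings, clipped at the profile ends.
    """
    y = np.nan_to_num(np.asarray(profile, dtype=float), nan=0.0)
    if fractions is None:
        fractions = np.arange(1, len(y) + 1)
    fractions = np.asarray(fractions, dtype=float)
    apex_idx, props = signal.find_peaks(y, height=min_height, plateau_size=(1, None))
    # plateau apexes: use the plateau midpoint
    mids = ((props["left_edges"] + props["right_edges"]) // 2).astype(int)
    peaks: list[Peak] = []
    for k, apex in enumerate(mids):
        height = y[apex]
        half = height / 2.0
        # run of consecutive samples >= half containing the apex
        lo = apex
        while lo > 0 and y[lo - 1] >= half:
            lo -= 1
        hi = apex
        while hi < len(y) - 1 and y[hi + 1] >= half:
            hi += 1
        if hi - lo + 1 < min_width:
            continue
        if lo > 0:
            left = _interp_crossing(fractions[lo - 1], y[lo - 1], fractions[lo], y[lo], half)
        else:
            left = fractions[0]
        if hi < len(y) - 1:
            right = _interp_crossing(fractions[hi], y[hi], fractions[hi + 1], y[hi + 1], half)
        else:
            right = fractions[-1]
        peaks.append(
            Peak(
                protein_id=protein_id,
                apex_fraction=float(fractions[apex]),
                left=float(left),
                right=float(right),
                height=float(height),
            )
        )
    return peaks


def trapezoid_between(
    profile: np.ndarray,
    lo: float,
    hi: float,
    fractions: np.ndarray | None = None,
) -> float:
    """Trapezoid integral of a piecewise-linear profile over [lo, hi].

    ``lo`` and ``hi`` are real-valued fraction coordinates; partial end
    segments are included exactly.
    """
    y = np.nan_to_num(np.asarray(profile, dtype=float), nan=0.0)
    if fractions is None:
        fractions = np.arange(1, len(y) + 1)
    fractions = np.asarray(fractions, dtype=float)
    lo = max(lo, fractions[0])
    hi = min(hi, fractions[-1])
    if hi <= lo:
        return 0.0
    interior = fractions[(fractions > lo) & (fractions < hi)]
    xs = np.concatenate([[lo], interior, [hi]])
    ys = np.interp(xs, fractions, y)
    return float(np.trapezoid(ys, xs))


def peak_metrics(
    profile: np.ndarray,
    peak: Peak,
    fractions: np.ndarray | None = None,
) -> Peak:
    """Fill in the FWHM trapezoid area of a peak on the given profile.

    The profile may be on the raw intensity scale (areas then carry raw
    intensity x fraction units); bounds outside the profile are clipped with
    a warning.
    """
    y = np.asarray(profile, dtype=float)
    if fractions is None:
        fractions = np.arange(1, len(y) + 1)
    fractions = np.asarray(fractions, dtype=float)
    lo, hi = peak.left, peak.right
    if lo < fractions[0] or hi > fractions[-1]:
        warnings.warn("peak bounds outside the profile: clipping")
    area = trapezoid_between(y, lo, hi, fractions)
    return Peak(
        protein_id=peak.protein_id,
        apex_fraction=peak.apex_fraction,
        left=max(lo, float(fractions[0])),
        right=min(hi, float(fractions[-1])),
        height=peak.height,
        fwhm_area=area,
    )


def group_peaks(peaks: list[Peak], apex_tolerance: float = 1.0) -> list[PeakGroup]:
    """Group co-apexing peaks of different proteins.

    Peaks are sorted by apex and greedily clustered: a peak joins the current
    group when its apex lies within ``apex_tolerance`` fractions of the
    group's first apex; one peak per protein per group.
    """
    groups: list[PeakGroup] = []
    for peak in sorted(peaks, key=lambda p: (p.apex_fraction, p.protein_id)):
        placed = False
        for g in groups:
            if (
                abs(peak.apex_fraction - g.peaks[0].apex_fraction) <= apex_tolerance
                and peak.protein_id not in g.members
            ):
                g.peaks.append(peak)
                placed = True
                break
        if not placed:
            groups.append(PeakGroup(peaks=[peak], apex_fraction=peak.apex_fraction))
    for g in groups:
        g.apex_fraction = float(np.mean([p.apex_fraction for p in g.peaks]))
    return groups


def stoichiometry(group: PeakGroup) -> dict[str, float]:
    """Subunit ratios relative to the lowest-area member (the unit).

    ratio_i = area_i / min(area); the minimum-area member gets exactly 1.0.
    Zero-area members are excluded with a warning.
    """
    areas = {}
    for p in group.peaks:
        if not p.fwhm_area > 0:
            warnings.warn(f"zero-area member {p.protein_id} excluded from stoichiometry")
            continue
        areas[p.protein_id] = p.fwhm_area
    if len(areas) < 2:
        raise ValueError("stoichiometry requires >= 2 members with positive areas")
    unit = min(areas.values())
    ratios = {pid: a / unit for pid, a in areas.items()}
    group.stoichiometry = ratios
    return ratios


def occupancy(
    profile: np.ndarray,
    peak_bounds: tuple[float, float],
    fractions: np.ndarray | None = None,
) -> float:
    """Share of a protein's total elution signal inside one peak.

    Trapezoid area between the bounds divided by the trapezoid area over the
    entire fractionation dimension (raw intensity scale recommended).
    """
    y = np.nan_to_num(np.asarray(profile, dtype=float), nan=0.0)
    if fractions is None:
        fractions = np.arange(1, len(y) + 1)
    fractions = np.asarray(fractions, dtype=float)
    total = trapezoid_between(y, fractions[0], fractions[-1], fractions)
    if not total > 0:
        raise ValueError("occupancy undefined for a signal-free profile")
    lo, hi = peak_bounds
    return trapezoid_between(y, lo, hi, fractions) / total


def mw_calibration(standards) -> CalibrationCurve:
    """Fit log10(MW) against fraction index from native MW standards.

    ``standards`` is a sequence of (fraction, kDa) points; at least two with
    distinct fractions are required. Returns the fitted line plus residuals.
    """
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (fraction, kDa) standards")
    frac, mw = pts[:, 0], pts[:, 1]
    if len(np.unique(frac)) != len(frac):
        raise ValueError("duplicate standard fractions")
    if np.any(mw <= 0):
        raise ValueError("molecular weights must be positive")
    slope, intercept = np.polyfit(frac, np.log10(mw), 1)
    fitted = slope * frac + intercept
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        residuals=np.log10(mw) - fitted,
        fraction_range=(float(frac.min()), float(frac.max())),
    )


def apparent_mw(curve: CalibrationCurve, fraction: float) -> float:
    """Apparent molecular weight (kDa) at a fraction; warns on extrapolation."""
    lo, hi = curve.fraction_range
    if not (lo <= fraction <= hi):
        warnings.warn(
            f"fraction {fraction} outside the calibrated range [{lo}, {hi}]: extrapolating"
        )
    return float(10 ** (curve.slope * fraction + curve.intercept))
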