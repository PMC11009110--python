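"""Profile conditioning: imputation, Fourier smoothing, rescaling, resampling.

Every protein profile is brought to a fixed-length, 0-1 scaled representation
before feature engineering: missing values are filled from neighbouring
fractions, the trace is low-pass filtered with a discrete Fourier transform,
rescaled by its maximum and linearly interpolated onto a 72-point grid so
experiments with different fraction counts share one classifier input size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from dipms.profiles import ProteinProfileMatrix

__all__ = [
    "PreprocessConfig",
    "impute_missing",
    "fourier_smooth",
    "rescale01",
    "resample_profile",
    "preprocess_profile",
    "preprocess_matrix",
]


@dataclass
class PreprocessConfig:
    """Parameters of the profile-conditioning pipeline.

    target_length:
        Fixed classifier input grid (72 fractions).
    smooth_keep_fraction:
        Fraction of low-frequency DFT coefficient pairs kept by the low-pass
        filter; 0.2 keeps ~14 of 72 pairs, wide enough for peaks spanning
        three or more fractions while suppressing single-fraction spikes.
    impute_edges:
        How to fill missing runs touching the profile ends: ``"zero"``
        (absence at the gel extremes is treated as true absence) or
        ``"nearest"``.
    """

    target_length: int = 72
    smooth_keep_fraction: float = 0.2
    impute_edges: str = "zero"

    def __post_init__(self) -> None:
        if self.target_length < 4:
            raise ValueError("target_length must be >= 4")
        if not (0 < self.smooth_keep_fraction <= 1):
            raise ValueError("smooth_keep_fraction must lie in (0, 1]")
        if self.impute_edges not in ("zero", "nearest"):
            raise ValueError("impute_edges must be 'zero' or 'nearest'")


def impute_missing(profile: np.ndarray, impute_edges: str = "zero") -> np.ndarray:
    """Fill missing (NaN) values from neighbouring fractions.

    A single internal gap becomes the average of its two neighbours; longer
    internal runs are filled by linear interpolation between the flanking
    observed values. Edge runs are filled with zero (default) or the nearest
    observed value. Observed values are never altered.
    """
    x = np.asarray(profile, dtype=float).copy()
    observed = ~np.isnan(x)
    if not observed.any():
        raise ValueError("cannot impute an all-missing profile")
    if observed.all():
        return x
    idx = np.arange(len(x))
    x[~observed] = np.interp(idx[~observed], idx[observed], x[observed])
    first, last = idx[observed][0], idx[observed][-1]
    if impute_edges == "zero":
        x[:first] = 0.0
        x[last + 1:] = 0.0
    # 'nearest' is what np.interp already did for out-of-range points
    return x


def fourier_smooth(profile: np.ndarray, keep_fraction: float = 0.2) -> np.ndarray:
    """Low-pass smooth a profile via the one-dimensional DFT.

    Keeps the DC component plus the ``ceil(keep_fraction * n)`` lowest
    nonzero-frequency coefficient pairs and reconstructs; negative
    reconstruction values are clipped to zero. ``keep_fraction = 1`` is the
    identity up to round-trip tolerance.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    x = np.asarray(profile, dtype=float)
    if len(x) < 4:
        raise ValueError("profile must have length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValueError("profile must be finite (impute first)")
    n = len(x)
    keep = math.ceil(keep_fraction * n)
    coeffs = np.fft.rfft(x)
    coeffs[keep + 1:] = 0.0
    return np.clip(np.fft.irfft(coeffs, n), 0.0, None)


def rescale01(profile: np.ndarray) -> np.ndarray:
    """Scale a non-negative profile by its maximum (max -> 1, zeros stay 0)."""
    x = np.asarray(profile, dtype=float)
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("rescale01 requires non-negative input")
    peak = np.nanmax(x) if len(x) else 0.0
    if not peak > 0:
        warnings.warn("all-zero profile: rescale01 is the identity")
        return x.copy()
    return x / peak


def resample_profile(profile: np.ndarray, target_length: int = 72) -> np.ndarray:
    """Linearly interpolate a profile onto a uniform grid of fixed length.

    Endpoints are preserved exactly; a linear ramp stays a linear ramp.
    """
    x = np.asarray(profile, dtype=float)
    if len(x) < 2:
        raise ValueError("resampling requires at least two fractions")
    if target_length < 2:
        raise ValueError("target_length must be >= 2")
    grid = np.linspace(0, len(x) - 1, target_length)
    return np.interp(grid, np.arange(len(x)), x)


def preprocess_profile(profile: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Impute, smooth, rescale and resample one profile to classifier form."""
    config = config or PreprocessConfig()
    x = impute_missing(profile, config.impute_edges)
    x = fourier_smooth(x, config.smooth_keep_fraction)
    x = rescale01(x)
    return resample_profile(x, config.target_length)


def preprocess_matrix(
    matrix: ProteinProfileMatrix, config: PreprocessConfig | None = None
) -> ProteinProfileMatrix:
    """Apply :func:`preprocess_profile` to every protein of a matrix.

    Proteins whose profile is entirely missing are dropped with a warning.
    """
    config = config or PreprocessConfig()
    ids, rows = [], []
    for pid, profile in zip(matrix.protein_ids, matrix.intensities):
        if np.isnan(profile).all() or not np.nansum(profile) > 0:
            warnings.warn(f"dropping signal-free protein {pid}")
            continue
        ids.append(pid)
        rows.append(preprocess_profile(profile, config))
    return ProteinProfileMatrix(
        np.asarray(ids, dtype=object),
        np.vstack(rows) if rows else np.empty((0, config.target_length)),
        matrix.replicate_id,
        np.arange(1, config.target_length + 1),
    )
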