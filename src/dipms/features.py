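"""Pair enumeration and coelution feature engineering.

Candidate protein pairs are the nonnegatively correlating pairs of a profile
matrix. Each pair is described by a 2n-dimensional vector concatenating

1. a sliding-window Pearson correlation (window ``w`` = 6 fractions,
   centered, truncated at the edges), and
2. the fraction-wise absolute intensity difference,

giving 144 features on the standard 72-fraction grid. Both families are
symmetric under swapping the pair order, so prediction is orientation-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dipms.profiles import ProteinProfileMatrix

__all__ = [
    "FeatureConfig",
    "candidate_pairs",
    "sliding_window_correlation",
    "fractionwise_difference",
    "build_feature_vector",
    "build_feature_matrix",
    "pearson",
]


@dataclass
class FeatureConfig:
    """Feature-engineering parameters.

    window_w:
        Width of the sliding correlation window in fractions.
    n:
        Profile length after resampling; the feature vector has length 2n.
    window_mode:
        ``"centered"`` (default) or ``"trailing"`` window placement.
    signal_floor:
        Windows where either profile stays below this level (on the 0-1
        scale) carry no elution signal; their correlation is reported as a
        neutral 0 rather than the correlation of residual noise.
    """

    window_w: int = 6
    n: int = 72
    window_mode: str = "centered"
    signal_floor: float = 0.05

    def __post_init__(self) -> None:
        if not (2 <= self.window_w <= self.n):
            raise ValueError("window_w must satisfy 2 <= w <= n")
        if self.window_mode not in ("centered", "trailing"):
            raise ValueError("window_mode must be 'centered' or 'trailing'")

    @property
    def n_features(self) -> int:
        return 2 * self.n


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation with zero-variance inputs mapped to 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    da, db = a - a.mean(), b - b.mean()
    na, nb = np.linalg.norm(da), np.linalg.norm(db)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(da, db) / (na * nb))


def candidate_pairs(matrix: ProteinProfileMatrix) -> list[tuple[str, str]]:
    """Unordered protein pairs with nonnegative global Pearson correlation.

    Zero-variance (constant) profiles correlate with nothing; their pairs are
    treated as correlation 0 and retained, with a warning.
    """
    if len(matrix.protein_ids) < 2:
        raise ValueError("need at least two proteins to form pairs")
    x = np.nan_to_num(matrix.intensities, nan=0.0)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    flat = norms == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant profile(s): correlations set to 0, pairs retained"
        )
    unit = centered / np.where(flat, 1.0, norms)[:, None]
    corr = unit @ unit.T
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    ids = matrix.protein_ids
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if corr[i, j] >= 0:
                pairs.append((str(ids[i]), str(ids[j])))
    return pairs


def _window_bounds(i: int, n: int, w: int, mode: str) -> tuple[int, int]:
    if mode == "trailing":
        return max(0, i - w + 1), i + 1
    lo = i - (w - 1) // 2
    hi = i + w // 2 + 1
    return max(0, lo), min(n, hi)


def _batch_windowed_corr(
    A: np.ndarray, B: np.ndarray, w: int, mode: str, signal_floor: float = 0.0
) -> np.ndarray:
    """Sliding-window Pearson correlation for many pairs at once.

    ``A`` and ``B`` are (m, n) arrays of profiles; returns an (m, n) array.
    Windows with zero variance in either profile yield 0, as do windows
    where either profile stays below ``signal_floor`` (no elution signal,
    only residual noise).
    """
    m, n = A.shape
    out = np.empty((m, n))
    for i in range(n):
        lo, hi = _window_bounds(i, n, w, mode)
        a = A[:, lo:hi]
        b = B[:, lo:hi]
        da = a - a.mean(axis=1, keepdims=True)
        db = b - b.mean(axis=1, keepdims=True)
        na = np.linalg.norm(da, axis=1)
        nb = np.linalg.norm(db, axis=1)
        denom = na * nb
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.einsum("ij,ij->i", da, db) / denom
        informative = (denom > 0) & (a.max(axis=1) >= signal_floor) & (
            b.max(axis=1) >= signal_floor
        )
        out[:, i] = np.where(informative, r, 0.0)
    return np.clip(out, -1.0, 1.0)


def sliding_window_correlation(
    a: np.ndarray,
    b: np.ndarray,
    w: int = 6,
    mode: str = "centered",
    signal_floor: float = 0.0,
) -> np.ndarray:
    """Per-fraction Pearson correlation over a sliding window of width ``w``.

    The window is centered on each fraction and truncated at the profile
    edges, so the output has the same length as the input.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if w > len(a):
        raise ValueError("window must not exceed the profile length")
    return _batch_windowed_corr(a[None, :], b[None, :], w, mode, signal_floor)[0]


def fractionwise_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Element-wise absolute intensity difference |a_i - b_i|."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    return np.abs(a - b)


def build_feature_vector(
    a: np.ndarray, b: np.ndarray, config: FeatureConfig | None = None
) -> np.ndarray:
    """Concatenate [sliding-window correlation || fraction-wise difference].

    Length is 2n; the vector is invariant under swapping ``a`` and ``b``.
    """
    config = config or FeatureConfig()
    swc = sliding_window_correlation(
        a, b, config.window_w, config.window_mode, config.signal_floor
    )
    diff = fractionwise_difference(a, b)
    return np.concatenate([swc, diff])


def build_feature_matrix(
    matrix: ProteinProfileMatrix,
    pairs: list[tuple[str, str]],
    config: FeatureConfig | None = None,
) -> np.ndarray:
    """Feature vectors for a list of pairs, one row per pair (m, 2n)."""
    config = config or FeatureConfig()
    index = {str(pid): i for i, pid in enumerate(matrix.protein_ids)}
    rows_a = np.array([index[a] for a, _ in pairs], dtype=int)
    rows_b = np.array([index[b] for _, b in pairs], dtype=int)
    A = np.nan_to_num(matrix.intensities[rows_a], nan=0.0)
    B = np.nan_to_num(matrix.intensities[rows_b], nan=0.0)
    swc = _batch_windowed_corr(
        A, B, config.window_w, config.window_mode, config.signal_floor
    )
    diff = np.abs(A - B)
    return np.hstack([swc, diff])
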