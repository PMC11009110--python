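"""Peptide-level I/O and quality filtering for fraction-resolved coelution data.

The entry point of the pipeline is a long table of peptide quantities per gel
fraction exported from a DIA search engine. Three conservative filters turn it
into per-replicate protein coelution profiles:

1. consecutive-detection ("stretch") filtering removes isolated single-fraction
   identifications at the protein level;
2. sibling-peptide correlation filtering drops peptides that do not coelute
   with the other peptides of the same protein;
3. top-N quantification infers the protein profile from the N most intense
   proteotypic peptides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PeptideQuantTable",
    "ProteinProfileMatrix",
    "read_peptide_table",
    "write_peptide_table",
    "stretch_filter",
    "sibling_correlation_filter",
    "infer_protein_profiles",
    "split_replicates",
    "read_protein_matrix",
    "write_protein_matrix",
]

META_COLUMNS = ["protein_id", "peptide_id", "proteotypic", "replicate"]


def _fraction_columns(n: int) -> list[str]:
    return [f"frac_{i:04d}" for i in range(1, n + 1)]


@dataclass
class PeptideQuantTable:
    """Long-form peptide quantities: one row per (protein, peptide, replicate).

    Parameters
    ----------
    meta:
        DataFrame with columns ``protein_id``, ``peptide_id``, ``proteotypic``
        (bool), ``replicate`` and optionally ``low_evidence`` (bool, set by
        :func:`sibling_correlation_filter` for single-peptide proteins).
    intensities:
        ``(n_rows, n_fractions)`` float array aligned with ``meta`` rows.
        ``NaN`` encodes a missing (undetected) value; zeros are treated as
        absent signal.
    fractions:
        1-based gel-slice indices, one per column.
    """

    meta: pd.DataFrame
    intensities: np.ndarray
    fractions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")
        if self.fractions is None:
            self.fractions = np.arange(1, self.intensities.shape[1] + 1)
        self.fractions = np.asarray(self.fractions, dtype=int)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValueError(f"missing required metadata columns: {missing}")
        if len(self.meta) != self.intensities.shape[0]:
            raise ValueError("meta and intensities row counts differ")
        if self.intensities.shape[1] != len(self.fractions):
            raise ValueError("fraction count and intensity columns differ")
        if self.n_fractions < 2 and len(self.meta):
            raise ValueError("at least two fractions are required")
        key = self.meta[["protein_id", "peptide_id", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (protein, peptide, replicate) row: {dup}")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("negative intensities are not allowed")

    @property
    def n_fractions(self) -> int:
        return self.intensities.shape[1]

    @property
    def replicates(self) -> list:
        return sorted(self.meta["replicate"].unique().tolist())

    def copy(self) -> "PeptideQuantTable":
        return PeptideQuantTable(
            self.meta.copy().reset_index(drop=True),
            self.intensities.copy(),
            self.fractions.copy(),
        )

    def subset(self, row_mask: np.ndarray) -> "PeptideQuantTable":
        return PeptideQuantTable(
            self.meta.loc[row_mask].reset_index(drop=True),
            self.intensities[np.asarray(row_mask)],
            self.fractions.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = [c for c in self.meta.columns if c in META_COLUMNS + ["low_evidence"]]
        wide = self.meta[cols].copy()
        for j, name in enumerate(_fraction_columns(self.n_fractions)):
            wide[name] = self.intensities[:, j]
        return wide


@dataclass
class ProteinProfileMatrix:
    """Protein x fraction intensity matrix for one replicate.

    ``NaN`` entries are missing values awaiting imputation; all observed
    values are non-negative.
    """

    protein_ids: np.ndarray
    intensities: np.ndarray
    replicate_id: str = "rep1"
    fractions: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.protein_ids = np.asarray(self.protein_ids, dtype=object)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")
        if self.fractions is None:
            self.fractions = np.arange(1, self.intensities.shape[1] + 1)
        self.fractions = np.asarray(self.fractions, dtype=int)
        if len(self.protein_ids) != self.intensities.shape[0]:
            raise ValueError("protein_ids and intensity rows differ")
        if len(set(self.protein_ids)) != len(self.protein_ids):
            raise ValueError("duplicate protein_ids")
        with np.errstate(invalid="ignore"):
            if np.any(self.intensities < 0):
                raise ValueError("negative intensities are not allowed")

    @property
    def n_fractions(self) -> int:
        return self.intensities.shape[1]

    def profile(self, protein_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.protein_ids == protein_id)
        if len(idx) == 0:
            raise KeyError(protein_id)
        return self.intensities[idx[0]]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peptide_table(path, delimiter: str = "\t", column_map: dict | None = None) -> PeptideQuantTable:
    """Read a peptide quantity TSV into a :class:`PeptideQuantTable`.

    The file must carry ``protein_id``, ``peptide_id``, ``proteotypic`` and
    ``replicate`` columns plus ``frac_NNNN`` fraction columns, ordered by
    slice index. ``column_map`` renames nonstandard headers, e.g.
    ``{"PG.ProteinAccessions": "protein_id"}``.
    """
    df = pd.read_csv(path, sep=delimiter)
    if column_map:
        df = df.rename(columns=column_map)
    for col in META_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"required column '{col}' not found in {path}")
    frac_cols = sorted(
        (c for c in df.columns if c.startswith("frac_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if len(frac_cols) < 2:
        raise ValueError(f"no fraction columns (frac_NNNN) found in {path}")
    meta = df[[c for c in df.columns if c in META_COLUMNS + ["low_evidence"]]].copy()
    meta["proteotypic"] = meta["proteotypic"].astype(bool)
    intensities = df[frac_cols].to_numpy(dtype=float)
    fractions = np.array([int(c.split("_")[1]) for c in frac_cols])
    return PeptideQuantTable(meta.reset_index(drop=True), intensities, fractions)


def write_peptide_table(table: PeptideQuantTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="")


def write_protein_matrix(matrix: ProteinProfileMatrix, path) -> None:
    """Write a protein profile matrix as TSV (lossless round trip)."""
    df = pd.DataFrame({"protein_id": matrix.protein_ids})
    df["replicate"] = matrix.replicate_id
    for j, f in enumerate(matrix.fractions):
        df[f"frac_{f:04d}"] = matrix.intensities[:, j]
    df.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def read_protein_matrix(path, delimiter: str = "\t") -> ProteinProfileMatrix:
    df = pd.read_csv(path, sep=delimiter)
    if "protein_id" not in df.columns:
        raise ValueError(f"required column 'protein_id' not found in {path}")
    frac_cols = sorted(
        (c for c in df.columns if c.startswith("frac_")),
        key=lambda c: int(c.split("_")[1]),
    )
    intensities = df[frac_cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = np.argwhere(intensities < 0)
    if len(bad):
        # +2: header line plus 1-based numbering
        raise ValueError(
            f"negative intensity at line {bad[0][0] + 2} of {path}"
        )
    replicate = df["replicate"].iloc[0] if "replicate" in df.columns and len(df) else "rep1"
    fractions = np.array([int(c.split("_")[1]) for c in frac_cols])
    return ProteinProfileMatrix(
        df["protein_id"].to_numpy(dtype=object), intensities, replicate, fractions
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def _present(values: np.ndarray) -> np.ndarray:
    """Detection mask: a value is present when observed and strictly positive."""
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(values, nan=0.0) > 0


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open (start, stop) index ranges of consecutive True entries."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def stretch_filter(
    table: PeptideQuantTable,
    min_consecutive: int = 2,
    per_peptide: bool = False,
) -> PeptideQuantTable:
    """Zero out detections that are not part of a consecutive-fraction run.

    Detection is assessed at the protein level (default): a fraction counts as
    detected if any sibling peptide carries signal there. Fractions outside a
    run of at least ``min_consecutive`` detected fractions are set to zero for
    every peptide of that protein. ``per_peptide=True`` applies the same rule
    independently to each peptide row instead.
    """
    if min_consecutive < 1:
        raise ValueError("min_consecutive must be >= 1")
    out = table.copy()
    if len(out.meta) == 0 or min_consecutive == 1:
        return out
    if per_peptide:
        groups = [np.array([i]) for i in range(len(out.meta))]
    else:
        groups = [
            np.asarray(idx)
            for idx in out.meta.groupby(["protein_id", "replicate"], sort=False).indices.values()
        ]
    for rows in groups:
        present = _present(out.intensities[rows]).any(axis=0)
        keep = np.zeros_like(present)
        for start, stop in _runs_of_true(present):
            if stop - start >= min_consecutive:
                keep[start:stop] = True
        drop = present & ~keep
        if drop.any():
            block = out.intensities[rows]
            block[:, drop] = 0.0
            out.intensities[rows] = block
    return out


def _mean_sibling_correlation(vectors: np.ndarray) -> np.ndarray:
    """Mean Pearson correlation of each peptide against its siblings.

    Missing values are treated as zero signal; zero-variance vectors
    contribute a correlation of 0.
    """
    x = np.nan_to_num(vectors, nan=0.0)
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    corr[norms == 0, :] = 0.0
    corr[:, norms == 0] = 0.0
    np.fill_diagonal(corr, 0.0)
    k = len(vectors)
    return corr.sum(axis=1) / max(k - 1, 1)


def sibling_correlation_filter(table: PeptideQuantTable, cutoff: float = 0.2) -> PeptideQuantTable:
    """Iteratively remove peptides that do not coelute with their siblings.

    Within each (protein, replicate) group the peptide with the lowest mean
    Pearson correlation to its siblings is removed while that mean falls below
    ``cutoff``, recomputing after each removal (ties broken by peptide
    sequence). The last peptide of a protein is never removed; proteins left
    with a single peptide are flagged ``low_evidence``.
    """
    if not (-1.0 <= cutoff <= 1.0):
        raise ValueError("cutoff must lie in [-1, 1]")
    out = table.copy()
    if "low_evidence" not in out.meta.columns:
        out.meta["low_evidence"] = False
    keep_mask = np.ones(len(out.meta), dtype=bool)
    for (_, _), idx in out.meta.groupby(["protein_id", "replicate"], sort=False).indices.items():
        rows = np.asarray(idx)
        alive = list(rows)
        while len(alive) >= 2:
            mean_corr = _mean_sibling_correlation(out.intensities[alive])
            worst = np.min(mean_corr)
            if worst >= cutoff:
                break
            candidates = [alive[i] for i in np.flatnonzero(mean_corr == worst)]
            victim = min(candidates, key=lambda r: out.meta.at[r, "peptide_id"])
            alive.remove(victim)
            keep_mask[victim] = False
        if len(alive) == 1:
            out.meta.loc[alive, "low_evidence"] = True
    return out.subset(keep_mask)


def infer_protein_profiles(table: PeptideQuantTable, top_n: int = 2) -> ProteinProfileMatrix:
    """Infer protein profiles from the top-N most intense proteotypic peptides.

    Peptides are ranked by total intensity across fractions (ties broken
    lexicographically by sequence); the top ``top_n`` are summed fraction-wise.
    Fractions where every contributing peptide is missing stay missing.
    The table must contain a single replicate; use :func:`split_replicates`
    for multi-replicate tables.
    """
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if len(table.meta) == 0:
        warnings.warn("empty peptide table: returning empty protein matrix")
        return ProteinProfileMatrix(
            np.array([], dtype=object),
            np.empty((0, table.n_fractions)),
            "rep1",
            table.fractions,
        )
    reps = table.replicates
    if len(reps) > 1:
        raise ValueError(
            f"table contains {len(reps)} replicates; split with split_replicates() first"
        )
    proteo = table.meta["proteotypic"].to_numpy(dtype=bool)
    ids, profiles = [], []
    for pid, idx in table.meta.groupby("protein_id", sort=True).indices.items():
        rows = np.asarray(idx)[proteo[np.asarray(idx)]]
        if len(rows) == 0:
            continue
        totals = np.nansum(np.nan_to_num(table.intensities[rows], nan=0.0), axis=1)
        order = sorted(
            range(len(rows)),
            key=lambda i: (-totals[i], table.meta.at[rows[i], "peptide_id"]),
        )
        chosen = rows[np.asarray(order[:top_n])]
        block = table.intensities[chosen]
        all_missing = np.isnan(block).all(axis=0)
        summed = np.nansum(np.nan_to_num(block, nan=0.0), axis=0)
        summed = np.where(all_missing, np.nan, summed)
        ids.append(pid)
        profiles.append(summed)
    replicate = reps[0] if reps else "rep1"
    return ProteinProfileMatrix(
        np.asarray(ids, dtype=object),
        np.vstack(profiles) if profiles else np.empty((0, table.n_fractions)),
        str(replicate),
        table.fractions,
    )


def split_replicates(table: PeptideQuantTable) -> dict[str, PeptideQuantTable]:
    """Split a multi-replicate table into one table per replicate."""
    return {
        str(rep): table.subset((table.meta["replicate"] == rep).to_numpy())
        for rep in table.replicates
    }
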