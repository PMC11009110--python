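"""Target-decoy FDR control for predicted coelution interactions.

Decoy pairs — one per protein, drawn from pairs absent from the target set —
are pushed through the same feature and prediction pipeline as targets.
Decoy probabilities calibrate empirical p-values, which an adaptive step-up
rule converts to q-values:

    q_k = min_{i >= k} ( m * pi0 / i * P_(i) )

where m is the number of putative discoveries, P_(i) the sorted p-values and
pi0 the prior probability that a putative discovery is false. With pi0 = 1
this is exactly the Benjamini-Hochberg step-up. Replicate probabilities are
combined with a weighted noisy-OR under an independence assumption.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "generate_decoys",
    "empirical_pvalues",
    "estimate_pi0",
    "adaptive_fdr",
    "combine_replicates",
    "make_score_table",
    "filter_network",
]


def generate_decoys(
    protein_ids,
    target_pairs,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """One decoy pair per protein, sampled from pairs absent from the targets.

    Decoys are mutually distinct and disjoint from the target set; proteins
    with no eligible partner are skipped with a warning. Fully seeded.
    """
    ids = sorted(str(p) for p in protein_ids)
    targets = {frozenset(p) for p in target_pairs}
    rng = np.random.default_rng(seed)
    decoys: list[tuple[str, str]] = []
    used: set[frozenset] = set()
    for pid in ids:
        partners = [
            q
            for q in ids
            if q != pid
            and frozenset((pid, q)) not in targets
            and frozenset((pid, q)) not in used
        ]
        if not partners:
            warnings.warn(f"no eligible decoy partner for {pid}; skipped")
            continue
        mate = partners[rng.integers(len(partners))]
        pair = tuple(sorted((pid, mate)))
        decoys.append(pair)
        used.add(frozenset(pair))
    return decoys


def empirical_pvalues(target_probs: np.ndarray, decoy_probs: np.ndarray) -> np.ndarray:
    """Convert classifier probabilities to decoy-calibrated empirical p-values.

    p(t) = (1 + #{decoys >= t}) / (1 + #decoys), the add-one rank rule, which
    keeps p strictly positive for finite decoy sets and monotone nonincreasing
    in the score.
    """
    decoy_probs = np.asarray(decoy_probs, dtype=float)
    if decoy_probs.size == 0:
        raise ValueError("empirical p-values require at least one decoy")
    target_probs = np.asarray(target_probs, dtype=float)
    sorted_decoys = np.sort(decoy_probs)
    # count of decoys >= t  ==  D - (number strictly below t)
    below = np.searchsorted(sorted_decoys, target_probs, side="left")
    n_ge = decoy_probs.size - below
    return (1.0 + n_ge) / (1.0 + decoy_probs.size)


def estimate_pi0(
    target_probs: np.ndarray,
    decoy_probs: np.ndarray,
    floor: float = 0.05,
) -> float:
    """Estimate pi0 as the decoy fraction exceeding the median target score.

    Clipped to [floor, 1]. A score-rich experiment (decoys well below the
    targets) yields a small pi0, sharpening the step-up rule.
    """
    decoy_probs = np.asarray(decoy_probs, dtype=float)
    target_probs = np.asarray(target_probs, dtype=float)
    if decoy_probs.size == 0 or target_probs.size == 0:
        return 1.0
    med = np.median(target_probs)
    pi0 = float(np.mean(decoy_probs > med))
    return float(np.clip(pi0, floor, 1.0))


def adaptive_fdr(p_values: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Adaptive step-up q-values, returned in the input order.

    q_k = min_{i >= k} (m * pi0 / i * P_(i)), clipped to <= 1; with pi0 = 1
    this reproduces Benjamini-Hochberg.
    """
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = m * pi0 * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def combine_replicates(probabilities, weights=None) -> float:
    """Weighted noisy-OR combination of per-replicate probabilities.

    combined = 1 - prod_r (1 - w_r * p_r), with uniform unit weights by
    default; monotone in every p_r and bounded by [0, 1].
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one replicate probability")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape:
            raise ValueError("weights must match probabilities in shape")
        if np.any((w < 0) | (w > 1)):
            raise ValueError("weights must lie in [0, 1]")
    return float(1.0 - np.prod(1.0 - w * p))


def make_score_table(
    target_pairs: list[tuple[str, str]],
    target_probs_per_rep: np.ndarray,
    decoy_pairs: list[tuple[str, str]],
    decoy_probs_per_rep: np.ndarray,
    weights=None,
    pi0: float | None = None,
) -> pd.DataFrame:
    """Assemble the scored-pair table: combined probability, p-value, q-value.

    ``*_probs_per_rep`` are (n_pairs, n_replicates) arrays; NaN marks a pair
    unscored in a replicate (left out of its combination). Per-replicate
    probabilities are combined first; one decoy-calibrated empirical p-value
    is then computed per combined target score and converted to q-values with
    the adaptive step-up rule (pi0 estimated from the decoys when not given).
    """
    tp = np.atleast_2d(np.asarray(target_probs_per_rep, dtype=float))
    dp = np.atleast_2d(np.asarray(decoy_probs_per_rep, dtype=float))
    n_rep = tp.shape[1]

    def _combine(row: np.ndarray) -> float:
        seen = ~np.isnan(row)
        if not seen.any():
            return 0.0
        w = None if weights is None else np.asarray(weights, dtype=float)[seen]
        return combine_replicates(row[seen], w)

    combined_t = np.array([_combine(row) for row in tp])
    combined_d = np.array([_combine(row) for row in dp])
    if pi0 is None:
        pi0 = estimate_pi0(combined_t, combined_d)
    pvals = empirical_pvalues(combined_t, combined_d)
    qvals = adaptive_fdr(pvals, pi0)
    d_pvals = empirical_pvalues(combined_d, combined_d)

    def _rows(pairs, probs, combined, pv, qv, is_decoy):
        recs = []
        for i, (a, b) in enumerate(pairs):
            rec = {"protein_a": a, "protein_b": b}
            for r in range(n_rep):
                rec[f"p_rep{r + 1}"] = probs[i, r]
            rec.update(
                combined_p=combined[i],
                empirical_p=pv[i],
                q_value=qv[i],
                is_decoy=is_decoy,
            )
            recs.append(rec)
        return recs

    records = _rows(target_pairs, tp, combined_t, pvals, qvals, False)
    records += _rows(decoy_pairs, dp, combined_d, d_pvals, np.ones(len(decoy_pairs)), True)
    table = pd.DataFrame.from_records(records)
    table.attrs["pi0"] = pi0
    # deterministic ranking: by descending combined probability, ties by pair id
    table = table.sort_values(
        ["combined_p", "protein_a", "protein_b"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return table


def filter_network(
    table: pd.DataFrame,
    fdr_alpha: float = 0.10,
    confidence_cut: float = 0.9,
) -> pd.DataFrame:
    """Retain target pairs at q <= fdr_alpha; tag high-confidence pairs.

    Decoys are removed from the output; pairs whose combined probability is
    >= ``confidence_cut`` are flagged ``high_confidence``.
    """
    out = table.loc[~table["is_decoy"].astype(bool)].copy()
    out = out.loc[out["q_value"] <= fdr_alpha].copy()
    out["high_confidence"] = out["combined_p"] >= confidence_cut
    return out.reset_index(drop=True)
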