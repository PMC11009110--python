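"""Complex inference and the end-to-end pipeline.

Two deconvolution modes turn the filtered interaction network into protein
complexes: a hypothesis mode that superimposes known complex definitions on
the retained edges, and a fully data-driven mode using Markov clustering
(MCL) on the probability-weighted network. ``run_pipeline`` composes every
stage — peptide filtering, profile conditioning, feature engineering,
prediction, target-decoy FDR, W-score filtering, complex inference and peak
analysis — and records all parameters and seeds in a run manifest.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

import dipms.fdr as fdr_mod
import dipms.peaks as peaks_mod
from dipms.wscore import bootstrap_threshold as _bootstrap_threshold
from dipms.wscore import build_adjacency as _build_adjacency
from dipms.features import FeatureConfig, build_feature_matrix, candidate_pairs
from dipms.model import CoelutionClassifier
from dipms.preprocess import PreprocessConfig, fourier_smooth, impute_missing, \
    preprocess_matrix, rescale01
from dipms.profiles import PeptideQuantTable, infer_protein_profiles, read_peptide_table, \
    sibling_correlation_filter, stretch_filter

__all__ = [
    "ComplexReport",
    "markov_cluster",
    "mcl_mode",
    "hypothesis_mode",
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
]


@dataclass
class ComplexReport:
    """One inferred (or recovered) complex."""

    complex_id: str
    members: list[str]
    mode: str                       # 'hypothesis' | 'mcl'
    completeness: float | None      # hypothesis mode only
    n_edges: int
    peak_group_ids: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Markov clustering
# ---------------------------------------------------------------------------

def markov_cluster(
    adjacency: np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 200,
    prune: float = 1e-6,
    tol: float = 1e-8,
) -> list[set[int]]:
    """Markov clustering of a weighted adjacency matrix.

    Implements the canonical flow simulation: add self-loops, column-
    normalize, then alternate expansion (matrix power) and inflation
    (element-wise power + renormalization) with pruning of vanishing entries
    until the matrix is stable. Clusters are read off the attractor rows;
    overlapping attractor supports are merged so the result is a partition
    of the clustered nodes. Deterministic for a fixed inflation.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    A = np.asarray(adjacency, dtype=float)
    n = A.shape[0]
    if n == 0:
        return []
    M = A.copy()
    np.fill_diagonal(M, 1.0)  # self-loops stabilize convergence
    M = M / M.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        last = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune] = 0.0
        colsum = M.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        M = M / colsum
        if np.abs(M - last).max() < tol:
            break
    # one cluster per distinct attractor support; attractors of the same
    # cluster share a support and are deduplicated, while a node claimed by
    # several distinct supports (e.g. a subunit shared between assemblies)
    # goes to the support holding the most flow, keeping the result a
    # partition of the clustered nodes
    attractors = np.flatnonzero(np.diag(M) > tol)
    if len(attractors) == 0:
        return []
    support_tol = max(tol, prune) * 10
    supports: dict[frozenset, np.ndarray] = {}
    for a in attractors:
        key = frozenset(np.flatnonzero(M[a] > support_tol).tolist())
        if key:
            flow = supports.get(key)
            supports[key] = M[a] if flow is None else np.maximum(flow, M[a])
    keys = sorted(supports, key=lambda k: sorted(k))
    flows = np.vstack([supports[k] for k in keys])
    clusters: list[set[int]] = [set() for _ in keys]
    for node in sorted(set().union(*keys)):
        candidates = [i for i, k in enumerate(keys) if node in k]
        best = max(candidates, key=lambda i: flows[i, node])
        clusters[best].add(node)
    return [c for c in clusters if c]


def mcl_mode(network: nx.Graph, inflation: float = 2.0) -> list[ComplexReport]:
    """Data-driven complex inference by MCL on the weighted PPI network.

    Edge weights are combined probabilities in [0, 1]; singleton clusters are
    discarded.
    """
    if network.number_of_nodes() == 0:
        return []
    nodes = sorted(network.nodes())
    A = nx.to_numpy_array(network, nodelist=nodes, weight="weight")
    clusters = markov_cluster(A, inflation=inflation)
    reports = []
    k = 0
    for cluster in sorted(clusters, key=lambda c: sorted(nodes[i] for i in c)):
        members = sorted(nodes[i] for i in cluster)
        if len(members) < 2:
            continue
        k += 1
        sub = network.subgraph(members)
        reports.append(
            ComplexReport(
                complex_id=f"mcl_{k:03d}",
                members=members,
                mode="mcl",
                completeness=None,
                n_edges=sub.number_of_edges(),
            )
        )
    return reports


def hypothesis_mode(
    network: nx.Graph,
    reference_complexes: dict[str, list[str]],
) -> list[ComplexReport]:
    """Superimpose known complex definitions on the retained network.

    For each reference complex, a member is recovered when it has at least
    one retained edge to another member. Completeness is the recovered
    members over the reference members present in the profiled universe;
    complexes with fewer than two recovered members are omitted.
    """
    if not reference_complexes:
        raise ValueError("hypothesis mode requires at least one reference complex")
    universe = set(network.nodes())
    reports = []
    for name, members in reference_complexes.items():
        present = [m for m in members if m in universe]
        if len(present) < 2:
            continue
        sub = network.subgraph(present)
        recovered = sorted(m for m in present if sub.degree(m) > 0)
        if len(recovered) < 2:
            continue
        reports.append(
            ComplexReport(
                complex_id=name,
                members=recovered,
                mode="hypothesis",
                completeness=len(recovered) / len(present),
                n_edges=sub.number_of_edges(),
            )
        )
    return reports


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All tunables of the end-to-end run, recorded in the manifest."""

    stretch_min_consecutive: int = 2
    sibling_corr_cutoff: float = 0.2
    top_n_peptides: int = 2
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    fdr_alpha: float = 0.10
    confidence_cut: float = 0.9
    bootstrap_n: int = 1000
    bootstrap_quantile: float = 0.95
    mode: str = "mcl"               # 'mcl' | 'hypothesis'
    inflation: float = 2.0
    reference_complexes: dict | None = None
    peak_min_width: int = 3
    peak_min_height: float = 0.2
    apex_tolerance: float = 1.0
    mw_standards: list | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    score_table: pd.DataFrame
    network: nx.Graph
    complexes: list[ComplexReport]
    peak_table: pd.DataFrame
    peak_groups: dict[str, list[peaks_mod.PeakGroup]]
    manifest: dict


def _load_tables(peptide_tables) -> list[PeptideQuantTable]:
    out = []
    for item in peptide_tables:
        if isinstance(item, PeptideQuantTable):
            out.append(item)
        else:
            out.append(read_peptide_table(item))
    return out


def run_pipeline(
    peptide_tables,
    model: CoelutionClassifier,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage from peptide tables (one per replicate) to complexes.

    ``peptide_tables`` is a list of :class:`PeptideQuantTable` or file paths,
    one per replicate. Every stage's parameters and seeds are recorded in the
    returned manifest.
    """
    config = config or PipelineConfig()
    manifest: dict = {"stages": []}

    def log(stage: str, **params) -> None:
        manifest["stages"].append({"stage": stage, **params})

    # 1. peptide filtering and protein inference
    tables = _load_tables(peptide_tables)
    if not tables:
        raise ValueError("stage profile_io: need at least one replicate table")
    raw_matrices = []
    for t in tables:
        t = stretch_filter(t, config.stretch_min_consecutive)
        t = sibling_correlation_filter(t, config.sibling_corr_cutoff)
        raw_matrices.append(infer_protein_profiles(t, config.top_n_peptides))
    log(
        "profile_io",
        n_replicates=len(tables),
        stretch_min_consecutive=config.stretch_min_consecutive,
        sibling_corr_cutoff=config.sibling_corr_cutoff,
        top_n_peptides=config.top_n_peptides,
    )

    # 2. profile conditioning
    prep = [preprocess_matrix(m, config.preprocess) for m in raw_matrices]
    log("preprocessing", **asdict(config.preprocess))

    # 3. candidate pairs and features (target set = union over replicates)
    target_set: set[frozenset] = set()
    for m in prep:
        if len(m.protein_ids) >= 2:
            target_set |= {frozenset(p) for p in candidate_pairs(m)}
    target_pairs = sorted(tuple(sorted(p)) for p in target_set)
    universe = sorted({str(p) for m in prep for p in m.protein_ids})
    log(
        "pair_features",
        n_target_pairs=len(target_pairs),
        window_w=config.features.window_w,
        n=config.features.n,
    )

    # 4. decoy generation
    decoy_pairs = fdr_mod.generate_decoys(universe, target_pairs, seed=config.seed)
    log("decoys", n_decoys=len(decoy_pairs), seed=config.seed)

    # 5. per-replicate prediction
    def _predict(pairs):
        probs = np.full((len(pairs), len(prep)), np.nan)
        for r, m in enumerate(prep):
            have = set(str(p) for p in m.protein_ids)
            rows = [i for i, (a, b) in enumerate(pairs) if a in have and b in have]
            if not rows:
                continue
            feats = build_feature_matrix(m, [pairs[i] for i in rows], config.features)
            probs[np.asarray(rows), r] = model.predict(feats)
        return probs

    target_probs = _predict(target_pairs)
    decoy_probs = _predict(decoy_pairs)
    log("predict", model_seed=model.config.seed, n_features=model.config.n_features)

    # 6. FDR scoring
    table = fdr_mod.make_score_table(target_pairs, target_probs, decoy_pairs, decoy_probs)
    table["fdr_pass"] = (~table["is_decoy"].astype(bool)) & (table["q_value"] <= config.fdr_alpha)
    filtered = fdr_mod.filter_network(table, config.fdr_alpha, config.confidence_cut)
    log("fdr_scoring", fdr_alpha=config.fdr_alpha, confidence_cut=config.confidence_cut,
        pi0=float(table.attrs["pi0"]), n_passing=int(len(filtered)))

    # 7. W scoring and bootstrap thresholding
    adjacency, fdr_flags = _build_adjacency(table, universe)
    threshold, retained, wresult = _bootstrap_threshold(
        adjacency,
        fdr_flags,
        n_boot=config.bootstrap_n,
        quantile=config.bootstrap_quantile,
        seed=config.seed,
    )
    # the FDR-filtered network is the positive PPI set; the bootstrap-retained
    # W scores mark the further-pruned, specificity-filtered edges
    network = nx.Graph()
    network.add_nodes_from(universe)
    idx = adjacency.index
    n_specific = 0
    for _, row in filtered.iterrows():
        a, b = row["protein_a"], row["protein_b"]
        i, j = idx[a], idx[b]
        specific = bool(retained[i, j] or retained[j, i])
        n_specific += specific
        network.add_edge(
            a, b,
            weight=adjacency.matrix[i, j],
            w_score=float(max(wresult.W[i, j], wresult.W[j, i])),
            w_retained=specific,
        )
    log("wscore_network", bootstrap_n=config.bootstrap_n,
        bootstrap_quantile=config.bootstrap_quantile, threshold=threshold,
        n_edges=network.number_of_edges(), n_w_retained=int(n_specific),
        seed=config.seed)

    # 8. complex inference
    if config.mode == "hypothesis":
        if not config.reference_complexes:
            raise ValueError("stage complex_inference: hypothesis mode needs reference complexes")
        complexes = hypothesis_mode(network, config.reference_complexes)
    else:
        complexes = mcl_mode(network, config.inflation)
    log("complex_inference", mode=config.mode, inflation=config.inflation,
        n_complexes=len(complexes))

    # 9. peak analysis on the smoothed raw-scale profiles, per replicate;
    # stoichiometry ratios are taken within subunits of a common complex
    curve = peaks_mod.mw_calibration(config.mw_standards) if config.mw_standards else None
    membership: dict[str, str] = {}
    for report in complexes:
        for member in report.members:
            membership.setdefault(member, report.complex_id)
    peak_rows = []
    peak_groups: dict[str, list[peaks_mod.PeakGroup]] = {}
    for m in raw_matrices:
        all_peaks = []
        for pid, profile in zip(m.protein_ids, m.intensities):
            if not np.nansum(profile) > 0:
                continue
            raw = impute_missing(profile, config.preprocess.impute_edges)
            raw = fourier_smooth(raw, config.preprocess.smooth_keep_fraction)
            scaled = rescale01(raw)
            for peak in peaks_mod.pick_peaks(
                scaled, m.fractions, config.peak_min_width, config.peak_min_height, str(pid)
            ):
                peak = peaks_mod.peak_metrics(raw, peak, m.fractions)
                all_peaks.append((peak, raw))
        groups = peaks_mod.group_peaks([p for p, _ in all_peaks], config.apex_tolerance)
        profiles = {id(p): raw for p, raw in all_peaks}
        for gi, g in enumerate(groups):
            by_complex: dict[str, list[peaks_mod.Peak]] = {}
            for p in g.peaks:
                cid = membership.get(p.protein_id)
                if cid is not None and p.fwhm_area > 0:
                    by_complex.setdefault(cid, []).append(p)
            ratios: dict[str, float] = {}
            for cid, members in by_complex.items():
                if len(members) >= 2:
                    sub = peaks_mod.PeakGroup(peaks=members, apex_fraction=g.apex_fraction)
                    ratios.update(peaks_mod.stoichiometry(sub))
            g.stoichiometry = ratios
            if curve is not None:
                g.apparent_mw_kda = peaks_mod.apparent_mw(curve, g.apex_fraction)
            for p in g.peaks:
                occ = peaks_mod.occupancy(profiles[id(p)], (p.left, p.right), m.fractions)
                peak_rows.append(
                    {
                        "replicate": m.replicate_id,
                        "protein": p.protein_id,
                        "apex_fraction": p.apex_fraction,
                        "left": p.left,
                        "right": p.right,
                        "height": p.height,
                        "fwhm_area": p.fwhm_area,
                        "apparent_mw_kda": g.apparent_mw_kda,
                        "peak_group": gi,
                        "complex_id": membership.get(p.protein_id),
                        "stoichiometry": ratios.get(p.protein_id, np.nan),
                        "occupancy": occ,
                    }
                )
        peak_groups[m.replicate_id] = groups
    peak_table = pd.DataFrame(peak_rows)
    log("peaks_stoichiometry", min_width=config.peak_min_width,
        min_height=config.peak_min_height, apex_tolerance=config.apex_tolerance,
        calibrated=curve is not None)

    manifest["seed"] = config.seed
    manifest["mode"] = config.mode
    return PipelineResult(
        score_table=table,
        network=network,
        complexes=complexes,
        peak_table=peak_table,
        peak_groups=peak_groups,
        manifest=manifest,
    )
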