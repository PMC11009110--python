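"""Seeded synthetic coelution experiments with ground truth.

The generator emulates the data model of a fractionated AP experiment:
protein complexes elute as Gaussian peaks over the gel-slice dimension, each
subunit's amplitude scaled by its copy number; proteins shared between
assemblies show one apex per assembly; peptides report the protein profile
through a multiplicative log-normal ionization factor and per-fraction
log-normal noise, with Bernoulli dropout and an instrument detection limit;
contaminants contribute flat nonspecific background or ragged scattered
detections. Every replicate re-draws noise and dropout against the same
planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dipms.features import FeatureConfig, build_feature_matrix, pearson
from dipms.model import make_labels
from dipms.preprocess import PreprocessConfig, preprocess_matrix
from dipms.profiles import PeptideQuantTable, infer_protein_profiles, \
    sibling_correlation_filter, stretch_filter

__all__ = [
    "ComplexSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_experiment",
    "make_training_corpus",
    "default_training_configs",
]


@dataclass
class ComplexSpec:
    """A planted complex: members, elution apex, peak width, copy numbers."""

    name: str
    members: list[str]
    apex: float
    sigma: float
    stoichiometry: dict[str, float] = field(default_factory=dict)

    def copies(self, member: str) -> float:
        return self.stoichiometry.get(member, 1.0)


@dataclass
class SimulationConfig:
    """Study conditions of a synthetic coelution experiment.

    Defaults describe a mid-size experiment: 60 gel fractions, four planted
    complexes of 3-6 subunits with Gaussian elution peaks (sigma 1.5-2.5
    fractions, apexes spaced at least 3 sigma apart), one subunit shared
    between two assemblies, 3-6 peptides per protein, 20% multiplicative
    noise (CV), 10% missingness, five contaminants and three replicates.
    """

    n_fractions: int = 60
    n_complexes: int = 4
    complex_size_range: tuple[int, int] = (3, 6)
    sigma_range: tuple[float, float] = (1.5, 2.5)
    stoich_choices: tuple[float, ...] = (1.0, 1.0, 1.0, 2.0)
    n_shared_subunits: int = 1
    peptides_per_protein: tuple[int, int] = (3, 6)
    noise_cv: float = 0.2
    batch_cv: float = 0.0
    missing_rate: float = 0.1
    n_contaminants: int = 5
    contaminant_kind: str = "mixed"   # 'mixed' | 'flat' | 'ragged'
    n_replicates: int = 3
    peptide_flyability_cv: float = 0.05
    frac_nonproteotypic: float = 0.05
    base_intensity: float = 1e6
    detection_limit: float = 1e4
    complexes: list[ComplexSpec] | None = None   # explicit plant overrides
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.missing_rate, self.frac_nonproteotypic):
            if not (0 <= rate <= 1):
                raise ValueError("rates must lie in [0, 1]")
        if self.sigma_range[0] < 1:
            raise ValueError("sigma must be >= 1 fraction")
        if self.n_fractions < 8:
            raise ValueError("need at least 8 fractions")


@dataclass
class GroundTruth:
    """Planted structure of a simulated experiment."""

    complexes: dict[str, list[str]]
    co_complex_pairs: set[frozenset]
    apexes: dict[str, list[float]]
    stoichiometry: dict[tuple[str, str], float]   # (complex, protein) -> copies
    contaminants: set[str]


def _plan_complexes(config: SimulationConfig, rng: np.random.Generator) -> list[ComplexSpec]:
    if config.complexes is not None:
        return config.complexes
    lo, hi = config.complex_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_complexes)
    if sizes.sum() > 26 * 26:
        raise ValueError("complex plan exceeds the protein pool")
    # apexes on an even grid with jitter; grid spacing >= 3 sigma_max
    sigma_max = config.sigma_range[1]
    margin = 3 * sigma_max
    span = config.n_fractions - 2 * margin
    if span <= 0 or (config.n_complexes > 1 and span / (config.n_complexes - 1) < 3 * sigma_max):
        raise ValueError("too many complexes for the fraction range (apex spacing < 3 sigma)")
    if config.n_complexes == 1:
        grid = np.array([config.n_fractions / 2])
    else:
        grid = np.linspace(margin, config.n_fractions - margin, config.n_complexes)
    jitter = rng.uniform(-0.5, 0.5, size=config.n_complexes)
    specs = []
    pid = 0
    for c, size in enumerate(sizes):
        members = [f"P{pid + k:03d}" for k in range(size)]
        pid += size
        stoich = {m: float(rng.choice(config.stoich_choices)) for m in members}
        specs.append(
            ComplexSpec(
                name=f"cpx_{c + 1:02d}",
                members=members,
                apex=float(grid[c] + jitter[c]),
                sigma=float(rng.uniform(*config.sigma_range)),
                stoichiometry=stoich,
            )
        )
    # shared subunits: move a member of one complex into a second one
    for s in range(min(config.n_shared_subunits, len(specs) - 1)):
        donor, host = specs[s], specs[(s + 1) % len(specs)]
        shared = donor.members[0]
        if shared not in host.members:
            host.members.append(shared)
            host.stoichiometry[shared] = float(rng.choice(config.stoich_choices))
    return specs


def _gaussian(grid: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - apex) / sigma) ** 2)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[dict[str, PeptideQuantTable], GroundTruth]:
    """Simulate one experiment: a peptide table per replicate plus the truth."""
    rng = np.random.default_rng(config.seed)
    specs = _plan_complexes(config, rng)
    grid = np.arange(1, config.n_fractions + 1, dtype=float)

    # true protein profiles: sum over assemblies of copies x Gaussian
    protein_profiles: dict[str, np.ndarray] = {}
    apexes: dict[str, list[float]] = {}
    stoich_truth: dict[tuple[str, str], float] = {}
    for spec in specs:
        shape = _gaussian(grid, spec.apex, spec.sigma)
        for m in spec.members:
            contribution = spec.copies(m) * config.base_intensity * shape
            protein_profiles[m] = protein_profiles.get(m, 0.0) + contribution
            apexes.setdefault(m, []).append(spec.apex)
            stoich_truth[(spec.name, m)] = spec.copies(m)

    contaminants: set[str] = set()
    for c in range(config.n_contaminants):
        pid = f"C{c:03d}"
        contaminants.add(pid)
        level = rng.uniform(0.05, 0.3) * config.base_intensity
        flat = {"mixed": c % 2 == 0, "flat": True, "ragged": False}[config.contaminant_kind]
        if flat:
            # flat nonspecific background across the whole separation range
            profile = np.full(config.n_fractions, level)
        else:
            # ragged: scattered single-fraction detections
            profile = np.zeros(config.n_fractions)
            hits = rng.choice(config.n_fractions, size=config.n_fractions // 3, replace=False)
            profile[hits] = level * rng.uniform(0.5, 1.5, size=len(hits))
        protein_profiles[pid] = profile
        apexes.setdefault(pid, [])

    # peptide plan is shared across replicates (same peptides, same flyability)
    noise_sigma = np.sqrt(np.log(1 + config.noise_cv**2))
    fly_sigma = np.sqrt(np.log(1 + config.peptide_flyability_cv**2))
    peptide_plan = []
    for pid in sorted(protein_profiles):
        k = int(rng.integers(*config.peptides_per_protein, endpoint=True))
        for j in range(k):
            fly = float(rng.lognormal(0.0, fly_sigma))
            proteotypic = bool(rng.random() >= config.frac_nonproteotypic)
            peptide_plan.append((pid, f"{pid}_pep{j:02d}", fly, proteotypic))

    batch_sigma = np.sqrt(np.log(1 + config.batch_cv**2))
    tables: dict[str, PeptideQuantTable] = {}
    for r in range(1, config.n_replicates + 1):
        rep = f"rep{r}"
        # per-fraction batch factor shared by every protein of the replicate
        # (loading, digestion and instrument-response variation per slice)
        batch = rng.lognormal(0.0, batch_sigma, size=config.n_fractions) \
            if config.batch_cv > 0 else np.ones(config.n_fractions)
        meta_rows, rows = [], []
        for pid, pep_id, fly, proteotypic in peptide_plan:
            base = protein_profiles[pid] * fly
            noise = rng.lognormal(0.0, noise_sigma, size=config.n_fractions) \
                if config.noise_cv > 0 else 1.0
            values = base * noise * batch
            values[values < config.detection_limit] = np.nan
            if config.missing_rate > 0:
                drop = rng.random(config.n_fractions) < config.missing_rate
                values = np.where(drop, np.nan, values)
            meta_rows.append(
                {"protein_id": pid, "peptide_id": pep_id,
                 "proteotypic": proteotypic, "replicate": rep}
            )
            rows.append(values)
        tables[rep] = PeptideQuantTable(
            pd.DataFrame(meta_rows), np.vstack(rows), np.arange(1, config.n_fractions + 1)
        )

    pairs: set[frozenset] = set()
    for spec in specs:
        for i, a in enumerate(spec.members):
            for b in spec.members[i + 1:]:
                if a != b:
                    pairs.add(frozenset((a, b)))
    truth = GroundTruth(
        complexes={s.name: list(s.members) for s in specs},
        co_complex_pairs=pairs,
        apexes=apexes,
        stoichiometry=stoich_truth,
        contaminants=contaminants,
    )
    return tables, truth


def default_training_configs(seed: int = 0) -> list[SimulationConfig]:
    """Standard mixed corpus: experiments of 40-90 fractions, sizes scaled.

    Emulates training on heterogeneous separation depths; the number of
    planted complexes grows with the fraction count so the apex-spacing rule
    (>= 3 sigma) stays satisfiable.
    """
    configs = []
    sigma_ranges = ((1.5, 2.0), (2.0, 2.5))
    for i, n in enumerate((40, 50, 60, 60, 72, 72, 84, 90, 90, 100)):
        configs.append(
            SimulationConfig(
                n_fractions=n,
                n_complexes=max(3, n // 9),
                sigma_range=sigma_ranges[i % 2],
                n_shared_subunits=2,
                n_contaminants=12,
                batch_cv=0.12 if i % 2 else 0.0,
                seed=seed + 101 * i,
            )
        )
    return configs


def make_training_corpus(
    configs: list[SimulationConfig],
    feature_config: FeatureConfig | None = None,
    preprocess_config: PreprocessConfig | None = None,
    neg_corr_band: tuple[float, float] = (-0.3, 0.3),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, str]], dict]:
    """Simulate, preprocess and label a balanced training corpus.

    Each configuration (they may differ in fraction count, noise, size) is
    simulated, run through the standard peptide filters and conditioned to
    the 72-point grid; all protein pairs are featurized, labeled positive
    when the pair shares a planted complex, and negatives are drawn from
    weakly correlating non-pairs (global Pearson within ``neg_corr_band``),
    balanced against the positives. Returns (X, y, pairs, provenance).
    """
    feature_config = feature_config or FeatureConfig()
    preprocess_config = preprocess_config or PreprocessConfig()
    X_parts, y_parts, pair_parts, corr_parts = [], [], [], []
    provenance = {"n_configs": len(configs), "seed": seed, "per_config": []}
    for ci, config in enumerate(configs):
        tables, truth = simulate_experiment(config)
        for ri, (rep, table) in enumerate(sorted(tables.items())):
            t = stretch_filter(table)
            t = sibling_correlation_filter(t)
            matrix = infer_protein_profiles(t)
            prep = preprocess_matrix(matrix, preprocess_config)
            ids = [str(p) for p in prep.protein_ids]
            all_pairs = [
                (ids[i], ids[j])
                for i in range(len(ids))
                for j in range(i + 1, len(ids))
            ]
            corrs = np.array(
                [
                    pearson(prep.profile(a), prep.profile(b))
                    for a, b in all_pairs
                ]
            )
            # planted contaminant pairs are known non-interactors and enter
            # the negative pool at any correlation (they teach the classifier
            # that structureless co-fluctuation is not coelution)
            cont = truth.contaminants
            known_neg = {
                frozenset((a, b))
                for a, b in all_pairs
                if a in cont and b in cont
            }
            try:
                idx, labels = make_labels(
                    all_pairs, truth.co_complex_pairs, corrs,
                    neg_corr_band, seed=seed + 1000 * ci + ri,
                    reference_negatives=known_neg,
                )
            except ValueError:
                continue  # too few eligible negatives in this replicate
            chosen = [all_pairs[i] for i in idx]
            feats = build_feature_matrix(prep, chosen, feature_config)
            X_parts.append(feats)
            y_parts.append(labels)
            pair_parts.extend(chosen)
            corr_parts.append(corrs[idx])
            provenance["per_config"].append(
                {"config": ci, "replicate": rep,
                 "n_pos": int(labels.sum()), "n_neg": int(len(labels) - labels.sum())}
            )
    if not X_parts:
        raise ValueError("no labeled pairs could be generated from the given configs")
    X = np.vstack(X_parts)
    y = np.concatenate(y_parts)
    provenance["global_pearson"] = np.concatenate(corr_parts)
    return X, y, pair_parts, provenance
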