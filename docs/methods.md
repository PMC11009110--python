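# Methods

This note documents the statistical model behind `dipms`, the defaults and
why they are set as they are, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
problem left room.

## Data model

The unit of input is a peptide-level quantitative matrix from one replicate
of a fractionated affinity-purification experiment: one row per (protein,
peptide), one column per gel slice, intensities missing where a peptide was
not detected. The analysis assumes that subunits of an intact complex
comigrate — their profiles share apex position and shape — while
nonspecific background does not track any single assembly.

## Peptide filtering

Three conservative filters precede everything else.

- **Stretch filter** (`min_consecutive = 2`): a fraction counts as detected
  for a protein when any sibling peptide carries signal there; detections
  outside a run of ≥ 2 consecutive fractions are zeroed. Detection is
  judged at the protein level because single-peptide dropout should not
  erase a fraction covered by a sibling; a `per_peptide` flag switches to
  row-wise filtering. Zeroing (rather than row removal) keeps the table
  shape stable; a zero after filtering means "confidently absent".
- **Sibling correlation filter** (cutoff 0.2 on the mean Pearson
  correlation against sibling peptides): applied iteratively — the worst
  peptide is removed and the means recomputed — because a single
  badly-behaved peptide drags down the mean of every well-behaved sibling;
  one-shot filtering would delete whole proteins whose peptides are
  individually fine. The last peptide of a protein is never removed;
  single-peptide proteins are kept with a `low_evidence` flag so downstream
  consumers can drop them, since silently deleting them would remove baits
  detected only in sparse regions.
- **Top-2 quantification**: protein profiles are the fraction-wise sum of
  the two highest-total-intensity proteotypic peptides (ties broken
  lexicographically for determinism). Nonproteotypic peptides are excluded
  throughout.

## Profile conditioning

Profiles are imputed, smoothed, rescaled and resampled, in that order.
Imputation precedes smoothing because the DFT needs complete vectors.
Internal gaps are filled by linear interpolation between the flanking
observed values (the single-gap case reduces to the two-neighbour
average); edge gaps default to zero because absence at the gel extremes is
true absence, with a `nearest` option.

Smoothing keeps the DC component plus the `ceil(keep_fraction · n)` lowest
nonzero-frequency DFT coefficient pairs and clips negative reconstruction
values. The default `keep_fraction = 0.2` keeps ~14 of 72 pairs: wide
enough that a peak spanning three fractions (the minimal peak width used in
peak calling) survives, narrow enough to suppress single-fraction spikes.

Rescaling divides by the profile maximum rather than min–max scaling, so
the zero baseline is preserved — the 0.2 peak-height rule below assumes a
zero background. Resampling linearly interpolates onto a fixed 72-point
grid so experiments with any fraction count share one classifier geometry;
72 is the fixed input size of the classifier.

## Pair features

Candidate pairs are those with nonnegative global Pearson correlation
(constant profiles are treated as correlation 0 and kept, with a warning,
rather than silently dropped). Each pair is described by 2n features:

1. sliding-window Pearson correlation, window w = 6 centered on each
   fraction and truncated at the edges (so the printed 2n count holds for
   any n); zero-variance windows map to a neutral 0;
2. the fraction-wise absolute intensity difference (absolute, so the
   vector is invariant under swapping the pair).

Windows where either profile stays below `signal_floor = 0.05` on the 0–1
scale are also mapped to 0. Without this, the ~85% of windows that carry
no elution signal report the correlation of smoothing residue — ringing
left by the low-pass filter — which has magnitudes up to 1 and no
information; empirically a classifier trained on such features keys on
corpus-specific ringing structure and misjudges cleanly separated peak
pairs. The floor makes the correlation family report "no evidence" exactly
where there is none.

## Classifier

A feed-forward network: input 144 → three hidden layers of 72 ReLU units
with 30% inverted dropout → one sigmoid unit. Training: Adam (learning
rate 0.001, β₁ = 0.9, β₂ = 0.999), binary cross-entropy on labels smoothed
by 0.1, 80/20 train/test split, the training portion split 70/30 into
train/validation, up to 256 epochs at batch size 64, early stopping with
patience 10 and restoration of the weights with the lowest validation
loss. One master seed drives the splits, negative sampling, weight
initialization and batch shuffling, so a run is exactly repeatable. The
forward/backward passes and the Adam update are written in numpy; the
parameter count of the default architecture is 21,025.

Labels for synthetic corpora: positives are planted co-complex pairs;
negatives are sampled from pairs with global correlation in [−0.3, 0.3]
that are not positives, balanced 1:1 against the positives. Pairs of
planted contaminants are additionally eligible as negatives at *any*
correlation and are taken into the negative quota first: they are the only
abundant source of "correlated but structureless" examples, and without
them the correlation band structurally excludes exactly the junk pairs the
classifier must learn to reject (a model trained on band-only negatives
extrapolates "more alignment = more positive" onto flat profiles, which
destroys the null calibration of the FDR stage).

## Target–decoy FDR

One decoy pair per protein is drawn (seeded) from pairs absent from the
target set; decoys flow through the identical feature and prediction path.
Per-replicate probabilities are combined first — weighted noisy-OR,
`1 − Π(1 − w·p)`, weights defaulting to 1 — and one empirical p-value is
computed per combined target score with the add-one rank rule
`p = (1 + #{decoys ≥ t}) / (1 + #decoys)`, which cannot reach zero on a
finite decoy set. (The alternative — per-replicate p-values combined
afterwards — multiplies the decoy-set granularity into the combination and
was not taken.) q-values follow the adaptive step-up rule
`q_k = min_{i≥k} (m·π₀/i · P_(i))`, which is exactly Benjamini–Hochberg at
π₀ = 1 (asserted against `statsmodels` in the tests). π₀ is estimated as
the fraction of decoys above the median target score, floored at 0.05 and
capped at 1 — an intentionally crude estimator, exposed in the API, that
adapts the rule when the decoy distribution sits clearly below the targets.
The network keeps pairs with q ≤ 0.10; pairs with combined probability
≥ 0.9 are flagged high-confidence.

**Limitation.** Decoy calibration assumes decoys resemble false targets.
In a degenerate experiment consisting entirely of *identical-class*
structureless profiles (e.g. all flat background), every junk pair scores
at the classifier's floor, the decoy distribution collapses to a point,
and any target epsilon above it obtains the minimal p-value — the realized
false-discovery proportion is then far above the nominal level. Mixed
profile classes (as in any real experiment, and in the generator's default
contaminant model) restore the spread and the calibration: on 20 seeded
no-complex experiments the realized proportion of targets passing q ≤ 0.10
is ~1–5%, within the binomial bound of the nominal 10%.

## Specificity (W) score and bootstrap

Combined probabilities are arranged as a symmetric protein × protein
matrix read as in-silico purifications (columns = baits). Per column,

    W = X_j · (n/n₀) · sqrt( Σᵢ (X_ji − µ)² + µ²·n₁ )

with n the column size, n₀ the entries below 0.5, n₁ the entries above 0.5
that also pass the target FDR, µ the column mean. Entries at exactly 0.5
count in neither n₀ nor n₁; an all-positive column (n₀ = 0) uses a
pseudo-count of 1 with a warning. The vectorized implementation is tested
to 1e−10 against a scalar double-loop oracle.

The retention threshold is the 95th percentile of a bootstrap null: each
replicate resamples every column's (probability, FDR-flag) entries with
replacement and recomputes W, pooled over 1,000 replicates. Edges with
W ≥ threshold are flagged `w_retained` on the output network.

Complex inference runs on the FDR-filtered network (q ≤ 0.10), with the
W-retained flags carried as edge annotations rather than as a gate. On
small dense benchmarks, a large fraction of a bait's column can be true
signal; the per-column resampling null then contains the signal itself and
the threshold rises into the true-edge range, so gating recovery on it
would measure background size, not evidence. The specificity-pruned edge
list remains available for users who want the stricter network.

## Complex inference

- **MCL mode**: canonical Markov clustering (expansion 2, inflation 2.0 —
  the standard default, exposed in config; pruning 1e−6) on the
  probability-weighted network, implemented directly in numpy and verified
  in the tests against an independent per-element flow-simulation
  transcription. Clusters are read from attractor rows; identical supports
  are deduplicated and a node claimed by several distinct supports goes to
  the one holding the most flow, so the result is a partition. Singletons
  are discarded. A subunit genuinely shared between two assemblies is
  assigned to one of them — flow-based partitions cannot express overlap.
- **Hypothesis mode**: each reference complex (name + member accessions)
  is superimposed on the network; a member is recovered if it keeps ≥ 1
  retained edge to another member; completeness is recovered members over
  members present in the profiled universe; complexes with < 2 recovered
  members are omitted. No ranking statistic is attached — completeness and
  edge support are reported as-is.

## Peak analysis

Peaks are picked on the smoothed, 0–1 rescaled profile: local maxima with
height ≥ 0.2 (background is 0 on this scale; no baseline subtraction) and
≥ 3 consecutive fractions at or above half maximum (the run containing the
apex). This width definition rejects 1- and 2-fraction bumps and accepts a
0/0.5/1/0.5/0 triangle, whose half-maximum run is exactly 3. Peak bounds
are the half-maximum crossings located by linear interpolation between
fractions, clipped at the profile ends.

Areas integrate the piecewise-linear profile exactly between the bounds
(partial end segments included), on the raw intensity scale. Stoichiometry
ratios divide each member's FWHM area by the group minimum — the
lowest-area member is the stoichiometric unit — and are therefore
scale-invariant; the pipeline computes them within peak-group members that
share an inferred complex, because co-apexing non-members (contaminants)
would otherwise capture the unit slot. Occupancy is the peak area over the
trapezoid area of the whole profile, computed on the raw scale. Apparent
molecular weights come from a least-squares fit of log₁₀(MW) against
fraction index over the native standards; predictions outside the
calibrated fraction range warn about extrapolation.

Co-apex grouping is automated (apexes within ±1 fraction, greedy in apex
order, one peak per protein per group); manual bounds can be passed
directly to `peak_metrics`/`occupancy`.

## Synthetic experiments

`simulate_experiment` plants complexes as Gaussian elution peaks: a
subunit's noiseless profile is the sum over its assemblies of
copies × amplitude × Gaussian(apex, σ), sampled at the fraction grid.
Default study conditions: 60 fractions, four complexes of 3–6 subunits,
σ ∈ [1.5, 2.5] fractions with apexes spaced ≥ 3σ (so planted peaks satisfy
the ≥ 3-fraction width rule), one subunit shared between two assemblies,
3–6 peptides per protein, log-normal multiplicative peptide noise with
CV 0.2, Bernoulli missingness 0.1, a detection limit of 1% of the base
intensity, five contaminants (alternating flat background and ragged
scattered detections) and three replicates re-drawing noise against the
same truth. Peptide ionization-efficiency factors are log-normal with
CV 0.05 — deliberately narrow, so top-2 protein intensities are comparable
across proteins, mirroring the premise under which intensity-based
stoichiometry is meaningful. An optional per-fraction batch factor shared
by all proteins of a replicate (log-normal; off by default) emulates
per-slice loading and instrument variation.

What the generator does *not* emulate: peak asymmetry and tailing, real
flyability variance (orders of magnitude in practice — absolute
stoichiometry from real data needs response calibration), correlated
peptide interference, isotope structure, or gel-migration physics. Passing
tests therefore demonstrate the correctness and calibration of the
*computation*, not instrument-level robustness.

`make_training_corpus` simulates a mixed set of configurations (40–100
fractions, both σ ranges, 12 contaminants, half the datasets with batch
structure), conditions everything to the 72-grid, and labels pairs as
described above. The breadth is intentional: resampling stretches or
compresses peak widths, and a corpus covering both directions is what
makes the classifier transfer across fraction counts.

## Problem sizes used in validation

The shipped validation runs use desk-scale problems chosen to exercise
every code path: a ~4,500-pair balanced corpus for training; 20 null
experiments of 30 noise proteins × 3 replicates for FDR calibration; a
recovery experiment of 9 planted complexes (hexamer with a 2-copy subunit,
two subcomplexes sharing a subunit, six background assemblies) plus 10
contaminants over 90 fractions; 10 single-replicate simulations for
stoichiometry recovery. Statistical granularity scales with experiment
size: with one decoy per protein, the smallest achievable p-value is
1/(#proteins + 1), so very small experiments cannot support a 10% FDR
cutoff regardless of signal — the recovery benchmark includes background
assemblies for exactly this reason.

## Known limitations

- The adaptive π₀ estimator is crude; a Storey-type estimator on the
  target p-value distribution would be better-behaved in low-signal
  regimes.
- Noisy-OR replicate combination rewards single-replicate flukes; a
  reproducibility-weighted combination would be stricter but is not what
  the combination rule specifies.
- MCL yields disjoint complexes; moonlighting subunits are assigned to one
  assembly.
- The W bootstrap null is anti-conservative on dense matrices (see above).
- Overlapping elution peaks are not deconvolved; FWHM bounds of fused
  peaks merge.
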