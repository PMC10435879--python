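# Methods

## The analysis model

`leukosig` treats a cytometry cohort as a table of per-animal event counts
for gated blood leukocyte populations, annotated with a group label (a
no-tumor control group and one or more tumor-bearing groups) and an
experiment batch. The scientific question is which population counts
discriminate the groups well enough to serve as blood biomarkers of cancer
presence and type, and how well a small signature of them classifies.

The pipeline assumes:

* counts are positive and right-skewed, with roughly multiplicative group,
  batch and noise effects — hence log transforms throughout;
* batch effects are multiplicative and shared by all groups within an
  experiment, so dividing by the same-batch control mean removes them;
* samples are exchangeable within (group, batch); no repeated measures.

### Count normalization

Three deterministic stages, strictly ordered and tagged on the table:

1. `count × 5000 / beads` — counting beads are spiked at a known load
   (5000 Flow-Count Fluorospheres ≈ 5 µL of blood) and acquisition stops
   after ~2000 collected beads, so this converts events to absolute cells
   per ~5 µL.
2. division by the same-batch control-group mean per population ("nil
   normalization"); control animals then average exactly 1 per (batch,
   population).
3. multiplication by the grand mean of the bead-normalized control counts,
   pooled over all batches and unweighted by batch size, restoring a
   cells-per-volume scale. Zero counts propagate as zeros; normalized
   values stay real-valued.

### Screen normalization

Screen wells measure the median PE-channel fluorescence (MedFI-PE) of one
antibody per well for each (population, barcoded group). FMO wells define
the channel background per (population, group) and their arithmetic mean is
subtracted from every entry (BC-MedFI-PE). Tumor-group deltas against the
matched control group are scaled per (population, marker) by the largest
positive delta across tumor groups — falling back to the largest absolute
delta when no increase exists — and floor-clipped at −1. The divisor is the
largest *signed* delta deliberately: scaling by the absolute maximum would
make the −1 floor unreachable, whereas the signed divisor sends the
strongest increase to exactly +1 and lets stronger decreases saturate at
−1. A per-marker (across populations) divisor is available via
`per_population=False`.

Isotype QC subtracts the matched isotype-class control of the same
population from each entry and averages per marker; markers with negative
average specific signal are flagged (zero passes — exclusion is for
fluorescence *below* the isotype control, which indicates a technical
anomaly). The cumulative change S|I| sums |delta| in raw MedFI units over
populations and tumor groups. The top-fraction filter scores each marker by
its largest absolute raw delta and keeps the top `ceil(fraction·n)` with
ties at the cut retained; it scores raw deltas rather than scaled values
because max-scaling fixes every marker's peak |s| at 1 by construction.

### Ranking statistics

Per population and ordered (test, reference) group pair:

* `M = log2((mean_test+1)/(mean_ref+1))`, `A = log2((mean_test+mean_ref)/2 + 1)`.
  The +1 pseudocount mirrors the log10(Y+1) ANOVA transform and keeps
  zero-count populations finite.
* p-values from an additive two-factor OLS fit of log10(count+1) on group
  and batch (two-way ANOVA without interaction); each pairwise comparison
  is the contrast of the two group coefficients with the pooled residual
  variance. The design matrix is shared across populations, so all
  populations are solved in a single multi-RHS least-squares pass; a
  confounded design (a batch containing one group) is rejected. Zero
  residual variance (literally identical data) yields p = 1 for a zero
  contrast.
* all populations × comparisons form one multiple-testing family for the
  Benjamini–Krieger–Yekutieli two-stage step-up procedure: BH at
  q′ = q/(1+q) estimates the number of true nulls m0 = m − r1; if
  0 < r1 < m a second BH pass runs at q′·m/m0. Reported adjusted values
  satisfy `reject ⇔ adjusted ≤ q`. The procedure is *not* guaranteed to
  contain the plain BH rejection set at q (when stage 1 rejects nothing it
  stops), only the BH set at q′.
* `−Lg(p) = −log2(adjusted p)` (adjusted p floored at 1e−300).
* the overlap coefficient OV integrates min(f̂₁, f̂₂) of Gaussian KDEs of
  the two groups' per-animal counts on the linear scale: Silverman/nrd0
  bandwidths (0.9·min(sd, IQR/1.34)·n^(−1/5)) with a floor of 10⁻⁶ × pooled
  range for degenerate samples, a 512-point grid spanning the pooled range
  ±3 bandwidths, trapezoidal integration, result clamped to [0, 1]. KDE
  smoothing biases OV slightly upward (≈0.006 at n = 10⁴ for
  2σ-separated normals against the closed form 2Φ(−1)).
* `|LgFC|/OV = |M| / max(OV, 0.01)`; the 0.01 floor keeps disjoint
  distributions finite.
* direction calls: Up/Down require BKY significance *and* at least a
  2-fold mean change; otherwise NS.

Metrics are min–max scaled to [0, 1] per comparison — except −Lg(p), which
is scaled over the pooled values of all comparisons so the single smallest
adjusted p attains 1 — with constant columns mapped to 0. The cumulative
discriminating score sums, per population, the scaled −Lg(p) and scaled
|LgFC|/OV over all comparisons plus the two importance-rank scores
(n − rank)/(n − 1) from the random forest and the GBT. Populations are
grouped by hierarchical clustering (Euclidean distance, complete linkage by
default, configurable) of the scaled metric columns, cutting the tree to
exactly k = 9 clusters by default.

### Classification

The GBT engine is xgboost with 100 trees for prediction and 500 for
importance ranking, depth 6, learning rate 0.3, L2 regularization λ = 3,
subsample 1, exact tree construction, single-threaded for determinism. The
random forest uses 100/500 trees, depth 4, 5 features considered per node
and no splits below 5 samples. Importances become dense ranks 1..n with
lexicographic tie-breaks, so ranks are always a permutation.

Repeated holdout draws, per repeat, an unstratified random 66/34 split
without replacement (test size ceil(0.34·n)) from a canonically sorted
sample index (making results row-order invariant); a split whose training
part misses a class is redrawn and counted. Test predictions pool into one
confusion matrix; per repeat we record macro one-vs-rest AUC (over classes
with both outcomes present in the test set), classification accuracy, and
macro precision/recall/F1 over classes present (averaging is configurable).
Metrics are averaged per-repeat-then-mean. The learning curve re-evaluates
the top-k ranked features for k = n..1 under the same seed, so k = n
reproduces the full evaluation exactly. The final signature unions the
top-6 GBT-ranked populations with the top-2 cumulative-score populations,
order-preserving with duplicates collapsed (6–8 members). Classical
(Torgerson) MDS double-centres squared Euclidean distances of z-scored
selected columns and returns the first two principal coordinates; constant
features are dropped with a warning.

## The synthetic cohort generator

The generator encodes the study conditions the pipeline targets: 3 groups
(Nil, CT26, 4T1) × 3 experiment batches with 5 animals per group per batch
and one animal missing from the last 4T1 batch (15/15/14 total); 39 gated
populations with log-normal counts around per-population baselines spread
log-evenly from ~3000 down to ~20 cells per 5 µL (order-of-magnitude
choices — real per-population baselines are not tabulated anywhere and only
affect scale, not structure); planted fold changes up to 8-fold emulating
myeloid expansion and mild lymphoid contraction, with the two monocyte
subsets (Mo F+L+, Mo F+L−) carrying the distinguishing pattern; count CV
0.4 (σ_log = sqrt(ln(1+CV²))); multiplicative per-(batch, population)
log-normal batch effects with σ = 0.15; bead counts ~N(2000, 200) truncated
at 1. Screens draw per-(population, marker) backgrounds uniformly on
200–1500 MedFI units, add a constant FMO channel offset (120), isotype
binding (60), planted tumor-specific shifts (±200–800, including one
opposite-sign pair that exercises the −1 clip and two markers whose
background sits below the isotype offset to exercise QC), and Gaussian well
noise (SD 10). Everything is deterministic given the config seed.

Two designed experiment configs supplement the defaults:
`dominant_discriminator_config` plants one population with 4-/16-fold
changes (distinct in every pairwise comparison) over weak nuisance effects,
for cumulative-score recovery experiments; `monocyte_signature_config`
plants the two-subset signature structure with near-zero between-group
overlap (6-fold in both tumor groups vs 10-fold in one, CV 0.3), for
classification and selection-recovery experiments. Both default to
12-population cohorts so hundred-seed recovery studies run in about a
minute.

What the generator does *not* emulate: event-level data and gating error,
spectral spillover, correlated populations (counts are drawn independently
given group and batch, whereas real subsets are compositionally and
biologically correlated), heavy-tailed outliers, and batch-by-group
interactions. Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct and calibrated under its own
assumptions — not that those assumptions hold in any particular real
cohort.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: exhaustive FDR validation
over all ~8000 p-vectors of length ≤ 6 on a 10-point grid; overlap
convergence at n = 10⁴ per sample over 20 seeds; type-I calibration over
1000 null cohorts (12 populations × 2 comparisons pooled per cohort) and
power over 200 cohorts with a planted 4-fold effect at 15 animals/group,
CV 0.5; and 100-seed recovery experiments for the cumulative score and the
6+2 selection, with one 100-repeat holdout evaluation of the two-subset
signature.

## Known limitations

* The overlap coefficient inherits KDE boundary bias for counts near zero
  (densities leak below 0 on the linear scale); with strictly positive
  counts and the pooled-range grid this is negligible for ranking purposes.
* With per-cell max-scaling, every screened marker with any increase peaks
  at exactly +1 on the −1..1 scale; the scale encodes the *shape* of a
  marker's response across groups, not its magnitude (magnitude lives in
  the raw deltas and S|I|).
* GBT feature importances are gain-based and can split credit between
  highly correlated populations; the cumulative score mitigates this by
  mixing in per-population univariate statistics.
* The ANOVA path tests mean differences on the log scale with a pooled
  variance; severe variance heterogeneity between groups is not modelled.
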