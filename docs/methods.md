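# Methods

## Model

`crossmet` analyses crossover-design feature tables with a two-stage
model. First, the data matrix X (samples × features, preprocessed and
log-transformed) is split by **marginal group centering** on a chosen
design factor g (subject, week or day):

    residual_i = x_i − mean(x_j : g(j) = g(i)) + grand_mean
    removed_i  = mean(x_j : g(j) = g(i)) − grand_mean

The grand mean is kept in the residual so the intensity scale survives
for fold-change reporting. The split is exact (input = residual +
removed) and satisfies sum-of-squares additivity about the grand mean,
which the tests verify against a loop-based oracle. For the subject
factor this is the classical multilevel within-subject decomposition of
paired multivariate data. Centering of week/day can optionally be nested
within subject (`nested=True`); marginal centering is the default because
week and day effects are modeled as run-level phenomena (weather, sample
handling, batch position) common to all subjects.

Second, a **sparse PLS-DA** is fitted to the residual against a one- or
two-factor class encoding (e.g. phase, or phase × day interaction
labels). Each component's X-weight vector is obtained by NIPALS
iteration with hard thresholding: after every update the weight vector is
truncated to its `keepX` largest-magnitude entries (ties broken toward
the smaller feature index, for determinism) and renormalized; iteration
stops when the weight change drops below 1e-6 or after 500 rounds. X is
deflated by regression on the component scores, which makes score vectors
exactly orthogonal; Y is not deflated. With `keepX = p` the first
component equals the dominant singular vector of the X'Y cross-covariance
(checked against an SVD oracle to 1e-6). Class prediction uses the
regression coefficients B = W(P'W)⁻¹C' with the maximum predicted
one-hot score (`max_dist`, the default) or the nearest class centroid in
score space (`centroids_dist`).

**VIP** scores are the standard weighted mean of squared normalized
weights, weighted per component by the explained response sum of squares
q_h²·t_h't_h, and scaled so mean(VIP²) = 1 over features. The
conventional importance cut-off is VIP > 1.5.

**Tuning and performance.** keepX is chosen on a grid (default 50, 60,
70 per component) by repeated stratified M-fold cross-validation
(default 7 folds). Two criteria are available: mean held-out
misclassification per component, and a correlation criterion — the mean
Pearson correlation between held-out component scores (projected through
the fold model, sign-aligned via the weight vectors) and the full-data
model's scores on the same samples. The correlation criterion's exact
definition is an open design point in the field; this package documents
and uses the score-correlation form. Fit quality is reported as
cumulative R² (in-fit explained one-hot response variance using the
first h components) and Q² = 1 − PRESS/TSS from cross-validation,
plus overall and balanced error rates.

## Synthetic study generator

Because crossover raw data are rarely shareable, the generator is a
first-class module: log intensities are the exact sum of a per-feature
baseline N(7, 1) (natural-log scale, i.e. raw intensities ~ e⁷), a
between-subject offset N(0, σ_b²) per (subject, feature), a week offset
N(0, σ_w²) per (week, feature) shared by all subjects, a day offset
N(0, σ_d²) per (week, day, feature), analytical noise N(0, σ_e²), and a
treatment term ±effect·profile(day) on the affected features under
oleuropein. Defaults: 9 subjects × 2 weeks × (2 baseline + 5
administration) days = 126 samples; 500 features, 50 affected with random
sign; effect = 0.5 (fold change ≈ e^0.5 ≈ 1.65, in the range typically
reported for dietary interventions); σ_b = 1.0, σ_w = 0.3, σ_d = 0.2,
σ_e = 0.25. Under these defaults between-subject variation carries ~87%
of the total sum of squares while the treatment term carries ~1%, the
regime that motivates the multilevel step. The magnitudes of the week
and day components relative to the subject component are free parameters
of the generator, not literature claims.

The **reset profile** (default 1.0, 0.9, 0.7, 0.4, 0.1) scales the
treatment effect per administration day and emulates the observed
retraction of day-4/5 treated samples toward the placebo cluster
("metabolome reset", plausibly enzyme induction); a profile ending at 0
makes day-5 treated and placebo samples exactly equal in expectation,
which is asserted structurally on the generated components.

QC injections are the feature-wise mean of all study samples (a pooled
aliquot, computed before drift is applied, mirroring physical pooling
before acquisition), inserted as 5 leading, 1-every-10 and 5 trailing
injections. Drift multiplies each sample by 1 + slope·(injection − 1).
Missingness is MCAR or intensity-dependent (censoring weights decaying
quadratically with intensity rank); each feature keeps at least one
observed value so imputation stays defined, which biases the realized
rate by at most one cell per feature.

What the generator does **not** emulate: chromatographic peak shapes,
isotope patterns, correlated features (metabolites from shared pathways),
nonlinear or step-change drift, multi-batch structure, and
subject-by-treatment interaction (all subjects share one effect size).
Passing tests therefore demonstrate correctness of the algorithms under
the stated variance model, not robustness to every artifact of real
acquisitions.

## Preprocessing

Pipeline order: **QC-RLSC → PPCA imputation → quotient normalization →
log₁₀ + centering/scaling**. Drift is an acquisition artifact and is
corrected first, on the incomplete matrix (the loess fit per feature uses
the observed QC values); imputation precedes normalization so quotients
are computed over complete vectors.

- **QC-RLSC**: per feature, a tricube-weighted linear loess (span 0.75 by
  default, a standard choice) is fitted to QC intensity versus injection
  order, evaluated at every injection by linear interpolation with
  constant extrapolation beyond the outermost QCs, and each intensity is
  divided by the fitted curve scaled to the median fitted QC value. The
  loess fit is delegated to statsmodels. For linear drift the correction
  is exact up to a per-feature constant (tested to 1e-6) because a
  locally weighted linear fit reproduces a line exactly and all study
  injections lie between the leading and trailing QCs. Features whose
  fitted curve touches zero are left uncorrected with a warning.
- **PPCA imputation**: probabilistic PCA fitted by EM, initialized from
  classical PCA on the mean-imputed matrix; each EM sweep re-estimates
  loadings and noise variance and replaces missing cells by their model
  expectation, until the relative change of the imputed cells falls below
  `tol` (default 1e-9) or `max_iter` (default 1000). Observed cells are
  never altered. On a noiseless rank-2 matrix with 10% deletions the
  deleted cells are recovered to better than 1e-6 relative. Imputed
  values are unconstrained model expectations, so the pipeline imputes on
  the log scale and exponentiates back to keep intensities positive. The
  EM iteration itself is deterministic; the seed argument is reserved for
  stochastic restarts.
- **Quotient normalization (PQN)**: the pseudo-reference is the
  feature-wise mean of a reference group (the pipeline uses baseline +
  placebo samples — the non-treated set); each sample is divided by the
  *median* of its feature-wise ratios to the reference (median rather
  than mean, for robustness — with 10% corrupted features the quotient is
  still exact). Re-normalizing an already normalized table is exactly
  idempotent only when samples are proportional to the reference profile;
  in general the pseudo-reference itself changes after the first pass and
  the second pass is a near-identity, not an exact one.
- **Consensus matching** of two peak lists: candidate pairs within both
  tolerances (|Δm/z|/m z ≤ ppm·1e-6, |Δrt| ≤ rt_tol) are assigned
  greedily one-to-one by ascending tolerance-normalized Euclidean
  distance, ties broken by smaller ppm then smaller index. Matched pairs
  are averaged into the merged list, so common + unique-A + unique-B
  equals the merged size (the Venn arithmetic). The greedy matcher is
  tested against an independent all-pairs brute-force implementation.

## Selection and validation

Two candidate-selection strategies operate on a fitted model: (1) the k
(default 10) largest-|weight| features per component, component-major,
duplicates skipped; (2) features whose correlation-circle coordinates
(correlations with components 1 and 2) have norm between an adjustable
inner radius — starting at 0.9 and shrinking by 0.1 steps — and the unit
circle (the outer boundary of the variable plot). Candidates are
validated by subject-paired two-sided t-tests on per-subject log-mean
intensities (the two-arm special case of a repeated-measures analysis;
with 9 subjects the power is moderate, roughly 60% of truly affected
features surviving FDR at the default effect size), with
Benjamini–Hochberg q-values over the tested set. Fold changes are
subject-averaged raw-scale O/P ratios ± SD over subjects; features with
mean ratio ≤ 1 are reported as the reciprocal with trend "down", so
every printed fold change is ≥ 1 and the arrow carries the direction.
An exact tie (|mean ratio − 1| ≤ 1e-12) resolves to "down" and is
flagged.

## Annotation

Monoisotopic masses come from the NIST isotope table shipped with
pyteomics (H 1.007825, C 12 exactly, N 14.003074, O 15.994915,
S 31.972071, P 30.973762); the proton mass is 1.00727646677 Da (hydrogen
atom minus electron). Supported adducts: [M+H]+, [M−H]−, [2M+H]+,
[2M−H]−. The dimer identity m/z([2M+H]+) − 2·m/z([M+H]+) = −m_proton
holds exactly by construction. RDB is computed on the ion formula
(neutral counts ×1 or ×2, ± one H), as C − H/2 + (N+P)/2 + 1, giving
half-integers for even-electron ions; elements outside CHNOPS are
rejected rather than guessed. ppm error is (observed −
theoretical)/theoretical × 1e6, with the sign convention fixed in that
direction. Published candidate tables sometimes print average masses or
inconsistent signs; only values consistent with monoisotopic arithmetic
are used as test anchors.

## Numerical choices and edge cases

- All randomness flows through `numpy.random.default_rng` seeds; fixed
  spec + seed reproduces tables, models and tuning results bit-for-bit.
- Weight-threshold ties and consensus-match ties break toward smaller
  indices; class labels are sorted lexicographically for the one-hot map.
- Stratified folds require every class to have at least `n_folds`
  members; otherwise an error is raised rather than silently merging
  folds.
- Zero is a valid measured intensity and is never conflated with
  missing; missing cells are empty on disk and NaN in memory.
- `keepx` larger than the feature count is clipped with a warning; a
  single-class fit, an all-missing feature, a non-positive drift
  multiplier and log of non-positive values are errors that name the
  offending object.
- Cross-validated error on null data is an unbiased chance estimate only
  on average: single draws vary by about ±0.1 at n ≈ 70–90, and strong
  feature selection at small n can push held-out error slightly above
  chance (the training-fold covariance of noise anti-correlates with the
  held-out fold). Calibration tests therefore average over replicate
  draws.

## Problem sizes

The test suite and the acceptance script run the simulation-based checks
at 126 samples × 200–500 features with 20 replicate seeds, and the
oracle equivalences at 50 × 50 — sizes at which every property above is
stable yet the whole suite completes in well under a minute.
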