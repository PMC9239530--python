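# Methods

`wsirs` re-implements, as a tested library, the computational chain that
links cell-level detections in H&E-stained breast-cancer whole-slide
images (WSIs) to the Oncotype DX Recurrence Score (RS): slide tiling and
cell-density features, rule-based nuclear grading, regression of RS on
Magee equation-2 variables plus image features, TAILORx risk
stratification with concordance analysis, and the detection/segmentation
evaluation metrics. Because no WSIs or detection tables are publicly
deposited for this kind of study, every stage runs on synthetic scenes
and cohorts with known generating processes; printed summary tables from
the clinical literature serve as exact worked examples for the
tabulation and scoring operations.

## Slide model and image features

Detections are point records (class `tumor`/`til`, center in pixels at
the 40x frame, optional nucleus contour). Slides scanned at 20x are
brought to the common frame by linear resizing with a factor of two per
axis (coordinates x2, areas x4; rasters by bilinear interpolation).
Tissue is defined on rasters as HSV saturation > 30 on the 8-bit scale.

The canvas is partitioned into half-open 1,024 x 1,024-px tiles; partial
right/bottom remainders are dropped so all tiles have equal area, which
the absolute-count features require. A tile is "tissue" when at least 5%
of its pixels are tissue (all tiles, when no raster is supplied). Cells
are binned by their centers; out-of-grid cells are tallied, never
silently lost, so per-class counts are conserved exactly.

The ten tissue tiles richest in tumor cells (ties broken by row-major
tile index; slides with fewer tiles use all of them, flagged short) give
three features each — tumor count n_t, TIL count n_l, and tumor
percentage n_t/(n_t+n_l) — and two slide-level features:

* **TIL number variance** V = Σᵢ(nᵢ − n̄)²/(m−1), the sample variance of
  the tiles' TIL counts (m = 10 normally; the m−1 divisor generalizes to
  short slides). The unsquared deviation sum is identically zero, so only
  the squared form defines a meaningful feature; the invariant suite
  checks both facts.
* **Aggregated nuclear grade** G. Each tumor nucleus is graded by the
  ratio r of its area to a reference TIL nucleus area of 304.7 px²:
  grade 1 for r < 2.5 (ratios below 1 clamp to 1), grade 2 for
  2.5 ≤ r ≤ 3.5, grade 3 for r > 3.5, with a 1e-9 relative tolerance so
  areas specified exactly at a boundary stay in the closed middle bin.
  Per-cell grades aggregate by a 10% cascade: G = 3 if ≥ 10% of cells
  are grade 3, else 2 if ≥ 10% are grade 2, else 1. Grading pools tumor
  cells from the selected top tiles only.

That yields 32 image features per slide (10 x 3 + V + G). "Nucleus size"
is interpreted as area in px²: published per-grade mean equivalent
diameters (≈26 px at grade 1) imply areas ≈543 px² and hence ratios
≈1.8 to the 304.7-px² reference — consistent with the grade-1 bin,
whereas a 304.7-px *diameter* would be anatomically absurd at 40x.

## Regression and risk evaluation

The eight-variable model regresses RS on the five Magee equation-2
variables (Nottingham grade/score, ER and PR H-scores with
H = percentage x intensity ∈ [0, 300], a binary HER2-equivocal dummy,
tumor size in cm) plus three image summaries (tumor count in the densest
tile, V, G). OLS (statsmodels) is the primary fit, with a rank check
that names collinear columns. LASSO (scikit-learn coordinate descent)
fits on z-scored features with an unpenalized intercept and reports
coefficients back on the original scale; the penalty is scikit-learn's
α in (1/2n)·RSS + α·‖β‖₁, chosen either directly or by seeded 5-fold
cross-validation with the one-standard-error rule. At α = 0 the
standardized problem is solved by plain least squares, which must (and
does, to 1e-6) agree with OLS through the independent
standardize/solve/back-transform path. Fit quality: R² = 1 − SSres/SStot,
adjusted R² = 1 − (1−R²)(n−1)/(n−p−1), and Pearson r with a two-sided
p-value from t = r√((n−2)/(1−r²)) on n−2 df. A feature-combination
search scores, by training adjusted R², every model using the first
x = 1..10 tile triplets with V and G toggled on/off, breaking ties
toward fewer features.

Predictions are left unclamped; stratification applies the TAILORx
categories directly: low for RS < 16, intermediate for 16 ≤ RS < 26,
high for RS ≥ 26 (the published strata are low ≤ 15, intermediate
16–25, high 26–100, so the high stratum starts at 26 and fractional
scores in the open gaps fall to the lower stratum). Observed-vs-predicted
strata are tabulated in a 3x3 matrix ordered high/intermediate/low;
concordance plus one- and two-step discordance partition unity exactly.
The chemotherapy recommendation rule — recommend iff RS ≥ 26, or age
≤ 50 with RS ≥ 16 — is a reconstruction of the trial-derived practice
rule, exposed as parameters rather than hard-coded; recommendation
agreement is a labeled 2x2 matrix with its off-diagonal discordant
count.

## Detection and segmentation evaluation

Point detections are matched greedily: candidate pairs within a 12-px
radius (about half the grade-1 equivalent nucleus diameter) sorted by
ascending distance, accepted when both endpoints are unused; remaining
ground truths are FN, remaining predictions FP, and precision, recall
and F1 follow the usual definitions. Contours are matched at an IOU
cutoff K by a sequential rule: ground truths scanned in index order,
each taking the free prediction with the largest IOU ≥ K (ties to the
lower prediction index); a prediction stays with the first ground truth
it was assigned to. Both matchers are verified against independent
brute-force oracles (exhaustive assignment for points on well-separated
perturbed sets; a naive re-simulation of the sequential rule for
contours). Matched pairs are summarized per grade and per
K ∈ {0.1, …, 0.9} by the mean symmetric Hausdorff distance — computed
on polygon boundaries densified to ≤ 1-px segments, bounding the
discretization error by half a segment — and by the ratio of mean HD to
the grade's mean equivalent diameter √(4·area/π), the latter averaged
over all ground-truth nuclei of the grade, matched or not.

## Synthetic data: what it emulates, and what it does not

`gen_scene` draws tumor-cluster centers uniformly, places Poisson
numbers of tumor cells (mean 150/cluster) with isotropic Gaussian spread
(SD 120 px), and overlays TILs from a uniform Poisson background
(40 cells/Mpx) whose intensity is multiplied by 6 inside a 100-px
annulus just outside each cluster's 2-SD radius — reproducing the
qualitative proximity of TIL-dense and tumor-dense regions at tumor
fronts, not any measured spatial statistic. Tumor nuclei are rotated
ellipses (axis ratio uniform in [0.7, 1]) whose polygon area is scaled
exactly to a ratio sampled strictly inside the grade's bin (grade-3
ratios capped at 6), so re-grading a stored area recovers the sampled
grade with probability 1. The default grade mix (0.01, 0.65, 0.34)
mirrors a typical slide-level grade distribution in RS-tested cohorts.
`perturb_detections` drops cells i.i.d. at the false-negative rate,
jitters survivors, and adds uniform spurious cells at the
false-positive rate, giving detection metrics known binomial
expectations. The optional renderer draws nuclei as filled dark
ellipses/disks on a pink background; it makes no attempt at H&E
texture, staining variability or scanner artifacts, so raster-based
results demonstrate machinery, not real-slide performance.

`gen_cohort` samples the eight variables from independent marginals
(categorical for grades, Bernoulli for HER2, range-anchored Beta with
matched mean for the continuous variables, concentration 4) shaped like
a routine ER+/HER2−/LN− training cohort: ER H-score range 80–300 with
mean 277, densest-tile tumor count 140–612 with mean 346, TIL variance
2.49–8,227.6 with mean 715, and so on. RS is intercept + Σβx + Gaussian
noise (default SD 5 RS units), kept both raw and rounded-clipped to
[0, 100]. No published coefficients exist for this variable set, so the
defaults are the package's own: signs follow clinical direction (higher
ER/PR lowering RS, size/grade raising it), the TIL-variance coefficient
is set so that coefficient x feature-mean ≈ 0.35 (the per-feature
product reported for training data in the source literature), and the
intercept centers mean RS near 16.6. Under these defaults an
eight-variable OLS on n = 150 attains Pearson r ≈ 0.5 — comparable to
reported validation-set correlations — but the cohort is i.i.d. and
linear by construction: passing tests show estimator and pipeline
correctness, not clinical validity. Independence between features also
means the feature-correlation matrix has no structure to recover; it is
exercised against a direct covariance-formula oracle instead.

Feature columns with a non-zero coefficient must not be constant:
structurally degenerate marginals (p ∈ {0, 1}, collapsed ranges) raise
a singular-design error, while chance-constant draws (rare binary
features in small cohorts) are redrawn deterministically from the same
seeded stream.

## Numerical and design choices

* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bitwise-identical scenes, perturbations and cohorts.
* Half-open tiles make binning a true partition; a cell at x = 1,024
  belongs to column 1.
* Tile-selection ties: row-major order, fixed, so feature vectors are
  reproducible across platforms.
* The greedy point matcher is order-independent given distinct
  distances; exact ties break by (gt index, prediction index).
* Degenerate inputs fail loudly: empty grade lists, fewer than two
  tiles for V, zero-area polygons, zero-variance responses and
  mismatched feature names all raise `ValueError`.
* Problem sizes in the test suite (4,096-px scenes, cohorts of
  125–2,000, 100-replicate recovery studies) were chosen so the whole
  suite completes in seconds while keeping binomial/SE margins at the
  3-sigma level.

## Known limitations

* The synthetic spatial model is a stand-in; no claim is made about TIL
  spatial statistics of real slides.
* The renderer and reference detector exist to exercise masking,
  detection evaluation and round-trips on rasters; the detector is a
  color/size blob finder and will fail on real H&E.
* Magee equation coefficients themselves are not reproduced (not
  published with this variable set); Ki-67-based variants and survival
  endpoints are out of scope.
* Published headline correlations (e.g. validation Pearson r ≈ 0.71 /
  0.50) depend on the study's slides and trained detector and are not
  reproducible from synthetic data; only table-derivable statistics are
  asserted exactly.
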