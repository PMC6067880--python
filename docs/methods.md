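# Methods

This note documents the analysis model implemented by `mooneyrsa`, the
assumptions of its synthetic-data generator, and the numerical and design
choices made where the method left room.

## Analysis model

### First-order representational geometry

For each subject and ROI the three condition matrices (`pre`, `post`,
`gray`; one row per image, one column per voxel) are stacked and every pair
of rows is correlated across voxels. The RDM entry is the correlation
distance 1 − r, giving a symmetric 99 × 99 matrix with zero diagonal and a
fixed block order [pre | post | gray]; within each block images are ordered
natural category first, then manmade, ascending id. Pearson correlation is
computed on the raw per-image patterns — correlation's own centering and
scaling is the only normalization applied, and rows with zero variance are
rejected with an error rather than silently patched.

Three scalar summaries drive the inferential contrasts:

* *distinctness*: mean of the strictly lower triangle of a within-condition
  block (the diagonal is identically zero and is never used);
* *identity similarity*: mean of a between-condition block diagonal of the
  RSM (= 1 − RDM), i.e. the same image's similarity to itself across
  conditions;
* *category information*: mean between-category dissimilarity minus mean
  within-category non-identical dissimilarity, within one condition block.

Differences are tested across subjects with two-sided paired Wilcoxon
signed-rank tests. Zero differences are dropped (classic Wilcoxon
treatment); the exact null distribution is used for n ≤ 25 when the absolute
differences are tie-free, otherwise the normal approximation with tie and
continuity corrections. When every subject's difference is exactly zero the
test is reported as W at its null center with p = 1 instead of erroring, so
degenerate inputs flow through group pipelines. FDR (Benjamini–Hochberg)
is applied across the ROIs entering one analysis family.

Because gray-scale and post-disambiguation presentations always come later
in a session than pre-disambiguation ones, a repetition confound is
controlled by a 2 × 2 repeated-measures ANOVA (condition × image set) on the
per-subject summaries computed separately for the *disambiguation set* (pre
not-recognized ∧ post recognized) and the *repetition set* (recognized at
both stages): a condition × set interaction indicates an effect of
disambiguation beyond repetition. Subjects with fewer than two images in
either set are excluded and logged.

### Second-order representational geometry

Group-average RDMs (elementwise mean across subjects, computed before any
rank transformation) are compared between ROIs with 1 − Spearman ρ over
their strictly-lower-triangle vectors — the full 99 × 99 triangle for the
across-conditions scope (a flag restricts to within-condition triangles),
or one 33 × 33 condition block for per-condition scopes. Rank correlation
makes the distance invariant to any strictly increasing transform of either
RDM. The resulting R × R matrix is embedded with 2-D non-metric MDS;
goodness-of-fit is reported as stress-1 (< 0.1 conventionally good) and as
r², the squared Pearson correlation between embedded pairwise Euclidean
distances and the original second-order distances.

### Dimensionality

The dimensionality of one within-condition RDM is the smallest k, tested in
ascending order over 2..10, whose non-metric MDS solution reaches r² > 0.90
against the original block. If no tested dimension reaches the threshold
the estimate is flagged "not reached" and excluded from network means with a
logged count — it is never silently reported as 10. Estimates are averaged
per network (keeping LOC and FG separate from the early-visual average) and
compared with a network × condition repeated-measures ANOVA.

### Preservation Index

On each subject's disambiguation-set images the pre × post block of the RSM
is Fisher-z transformed (r clipped to ±(1 − 1e−12) first, since same-image
cross-condition correlations reach 1 in noise-free synthetic limits) and

PI = mean(z(diagonal)) − mean(z(off-diagonal)).

The off-diagonal mean uses all n(n−1) off-diagonal cells of the
non-symmetric block, because s(pre_i, post_j) ≠ s(pre_j, post_i); using one
triangle would discard half the information. The normalized variant divides
the PI by the mean off-diagonal z and is therefore a ratio whose sign flips
when the baseline similarity is negative — it is tested with a Wilcoxon
signed-rank test rather than a t-test, since a ratio of normal variables is
not normal. Per-ROI one-sample t-tests (PI) and Wilcoxon tests (normalized
PI) are FDR-corrected within each family; network comparisons use one-way
repeated-measures ANOVAs at a 5-level grouping (Visual, LOC, FG, FPN, DMN)
and a 3-level grouping (FPN-parietal, FPN-frontal, DMN). The image subset
defaults to the recognition-based disambiguation set; a verbal-report-based
subset can be passed instead.

### Statistics

Repeated-measures ANOVAs (one or two within factors) are computed through
pingouin with uncorrected-sphericity degrees of freedom
(df = (a−1, (a−1)(n−1))); a Greenhouse–Geisser-corrected p is available
from the backend but is not the default. Effect sizes are partial
η² = SS_effect/(SS_effect + SS_error) for F tests — recomputable from the
statistic alone as F·df₁/(F·df₁ + df₂), an identity the test suite checks to
1e−10 against the SS-based value — and Cohen's d = t/√n = mean(diff)/sd(diff)
for paired and one-sample t tests. Post-hoc pairwise comparisons are
Bonferroni-corrected by the number of comparisons performed within the
effect. Constant data (zero range up to float noise) short-circuits to
F = 0, η² = 0 rather than dividing zero by zero.

## Synthetic-data generator

The generator produces cohorts with the statistical structure the analyses
assume. Per ROI with latent dimension k and v voxels:

* **Gray prototypes** are 33 points in a k-dimensional latent space, mapped
  to voxel space by a random orthonormal map scaled by √(v/k) so every
  component has unit per-voxel variance; category centroids are separated by
  κ (`category_separation`) along the first latent axis.
* **Pre patterns** mix an image-specific Mooney component (correlated
  `mooney_gray_overlap` = 0.3 with the prototype in latent space, and
  restricted to the leading ⌈k/2⌉ latent dimensions — unrecognized two-tone
  images span fewer feature axes, so estimated dimensionality rises after
  disambiguation) with a component shared by all images at weight γ
  (`pre_clustering` = 0.6), which collapses pre patterns together.
* **Post patterns** are λ·prototype + (1−λ)·pre-component + noise. λ is
  `prior_shift` = 0.8 for images that are hard to recognize pre
  (`prior_shift_easy` = 0.4 for easy ones), encoding the finding that the
  prior reshapes the code most for images rescued by disambiguation;
  setting both equal removes the condition × set interaction, which is how
  the type-I calibration tests construct their null.
* **Networks** sit on a 1-D cortical hierarchy (Visual 0 → LOC → FG →
  FPN-parietal → FPN-frontal → DMN 1). Each network's latent geometry is a
  smoothly varying mixture of two common geometries plus a network-specific
  part (`network_distinctness` = 0.45), and ROIs within a network share
  leading latent dimensions (`network_coupling` = 0.6). This yields
  second-order distances that grow with hierarchy separation and embed
  nearly perfectly in two dimensions, as real representational formats do.
* **Noise** is additive i.i.d. Gaussian per voxel, σ = 0.5 in the arbitrary
  pattern units (correlation distance is scale-invariant, so no calibration
  to BOLD amplitudes is attempted). σ was fixed once so that within-condition
  blocks reach the r² > 0.90 criterion inside the tested 2..10 range, as the
  study's data did, while group contrasts remain comfortably detectable at
  n = 19.
* **Behavior** is a two-component easy/hard mixture over images
  (frac easy = 0.42, p(recognize) 0.85 vs 0.12 pre, 0.86 post), which
  reproduces both the bimodal per-image recognition distribution and the
  ~43% pre / ~86% post group rates; a per-subject logit offset
  (sd = 0.5) generates realistic between-subject spread, and verbal-report
  accuracy is the recognition probability scaled by 0.8 pre (1.0 post).
  Images are treated as exchangeable within category: nothing is known
  about the real images' pairwise perceptual similarity, so none is
  modeled.

What the generator does **not** emulate: hemodynamics or temporal structure
(patterns are drawn directly, as GLM-style beta estimates), spatial
autocorrelation between voxels, session or run effects, and any non-Gaussian
noise. Passing tests therefore demonstrate the correctness and calibration
of the analysis chain under the assumed generative structure, not the
reproducibility of any particular empirical effect size in real fMRI data.

## Numerical choices

* **Non-metric MDS** uses scikit-learn's SMACOF with the stress-1
  criterion. The first start initializes from classical (Torgerson)
  scaling, which on these inputs converges within a few iterations to lower
  stress than the best of many random starts at a fraction of the cost; the
  default is therefore a single deterministic classical start
  (`restarts=1`), with additional seeded random restarts available as
  insurance against local minima. Convergence: eps = 1e−6 on normalized
  stress, max 300 iterations. r² against a constant-distance target
  (equilateral inputs) is defined as 1 when the embedding is equidistant
  too, since such configurations are exactly embeddable.
* **Fisher z** clips |r| to 1 − 1e−12 with a warning rather than failing.
* **FDR families** are one family per analysis across the ROIs entering it
  (each contrast, each condition's category test, each PI test family);
  family ids are recorded in every output row.
* **Determinism**: every random draw flows from a single integer seed
  (NumPy `default_rng`; behavior uses a spawned stream so pattern draws are
  unaffected by behavioral settings), and two runs with the same config
  produce byte-identical artifacts — the test suite checks this end to end.
* **Problem sizes**: the test-suite cohorts use 5–8 subjects and 3–6 small
  ROIs; power and calibration suites use 200 effect cohorts and 500 null
  cohorts of 19 subjects × 1 ROI, and the acceptance script runs the full
  19-subject × 10-ROI default configuration.

## Known limitations

* Correlation distance is the only dissimilarity implemented (no Euclidean,
  Mahalanobis or cross-validated distances), matching the analysis it
  implements.
* The rm-ANOVA assumes complete, balanced designs; unbalanced input is an
  error, not a mixed-model fallback.
* Exactly-3-of-6 pre-recognition responses are deliberately unclassified
  and excluded from both image sets; post-not-recognized images are
  excluded from all set-based analyses.
* The dimensionality criterion inherits the MDS fit's stochastic floor:
  with very noisy RDMs the r² threshold may be unreachable within 2..10,
  which is reported as "not reached" rather than extrapolated.
* Verbal scoring is exact string matching (case- and whitespace-normalized)
  against the answer key; no fuzzy matching is attempted because it could
  not be validated against a ground truth.
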