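# Methods

## Problem and pipeline

The package classifies subjects as diabetic-analog vs. control from a
pre-cropped tongue photograph plus three covariates (gender, age, BMI).
The pipeline is: body/coating segmentation → per-region color and texture
features → stratified 80/20 split → SMOTE balancing of the training set →
symmetric min–max scaling → PCA → GA-tuned RBF SVM → evaluation against
k-NN, Gaussian Naive Bayes, and a backpropagation network. All stochastic
stages derive from a single seed; a run is byte-reproducible.

## Segmentation

Body and coating differ chiefly in chrominance: the body is red-dominant,
the coating whitish/yellow. Segmentation therefore operates on a
chrominance map — CIELAB a\* by default (HSI hue and raw R−G are
selectable) — restricted to the tongue mask.

**Division.** The tongue's bounding box is quadtree-split until a block is
homogeneous or has side ≤ `min_block_size` (default 4 px). Homogeneity is
`std ≤ homogeneity_tol` (default 6 chrominance units) **and**
`range ≤ 2·homogeneity_tol`; the range clause matters because a single
contaminant pixel in a large block barely moves the std but doubles the
range. Minimal blocks that are still inhomogeneous are split into single
pixels, so region boundaries can be resolved at pixel granularity.

**Merging.** Adjacent regions (4-connectivity) are merged greedily in
raster order of region creation, ties broken by lower region index. A merge
is accepted when the merged std **and** the difference of the two region
means are both ≤ `homogeneity_tol`. The mean-difference clause is this
package's addition to the classic merged-std rule: absorbing a tiny region
into a huge one changes the merged std by only Δ²/n, so std alone lets big
regions swallow boundary pixels of the other class.

**Thresholding.** Each tongue pixel carries its region's mean chrominance;
Otsu's criterion is evaluated exactly over the distinct region means
(candidate thresholds at midpoints of consecutive distinct values, no
histogram binning, so the threshold lands mid-gap between modes rather than
at a bin edge). Regions are labeled by their side of the threshold. Regions
whose mean lies within `homogeneity_tol` of the threshold, or whose
internal std exceeds it, are re-labeled pixel by pixel against the same
threshold — the fallback for thin coating, where body and coating colors
overlap. A final cleanup flips any pixel lying more than `homogeneity_tol`
beyond the threshold on the side opposite its label. The body label goes to
the side with the higher mean a\* (red body vs. pale coating), so labels
follow color, not geometry: swapping the fixture colors swaps the masks.

**Degenerate inputs.** The histogram is declared unimodal — and the whole
tongue labeled body, with a warning — when the Otsu split separates the two
sides by less than `homogeneity_tol`, or when the smaller side holds < 1%
of tongue pixels (a handful of outliers is not a coating). The minimum
detectable coating is therefore about 1% of the tongue area.

## Color features

Region color is computed **mean-then-transform**: pixel RGB is averaged
over the region mask, and the single mean color is converted to HSI and
CIELAB. This matches reporting one parameter set per region; the
alternative (transform each pixel, then average) is deliberately not the
default since hue is angular and averages badly.

* HSI uses the arccos hue formulation, reflected to (180°, 360°) when
  B > G; H ∈ [0°, 360°), S, I ∈ [0, 1]. Achromatic colors (including
  black) take H = 0, S = 0 by convention.
* CIELAB assumes sRGB gamma and primaries with D65 white (the acquisition
  illuminant's color temperature is near D65), using the classic published
  6-decimal sRGB→XYZ matrix and the CIE 1976 piecewise cube-root.

An empty coating (no region found) yields NaN features, imputed later with
training-set means — keeping dimensionality fixed without discarding
subjects.

## Texture features

Gray level is rounded BT.601 luminance (0.299R + 0.587G + 0.114B). For a
displacement δ, `p(i)` is the normalized histogram of |g(x) − g(x+δ)| over
pixel pairs fully inside the region mask. Statistics: CON = Σ i²p(i),
ASM = Σ p(i)², ENT = −Σ p(i) log₂ p(i) (bits; base configurable),
MEAN = Σ i·p(i). Defaults use δ ∈ {(1,0), (0,1)} averaged, computed per
region; both choices are configurable since neither is canonical. All four
statistics are invariant to adding a constant gray offset.

## Preprocessing

* **SMOTE** (k = 5 neighbors): synthetic minority samples
  `x + u(x_nn − x)`, u ~ U(0,1), x_nn among the k nearest minority
  neighbors. Distances are computed on a [0,1] min–max-scaled copy so no
  feature dominates; interpolation is on raw features. A non-integer
  oversampling rate r (e.g. 296 → 531, r ≈ 1.794) is hit exactly: each
  minority point contributes ⌊r⌋−1 extra synthetics and a seeded random
  subset contributes one more. The 0/1 gender code is rounded after
  interpolation (a documented distortion). SMOTE is applied to training
  data only, never to test rows.
* **Scaling**: per-feature affine map of the training range to [−1, 1];
  constant features map to 0; test values extrapolate without clipping.
* **PCA**: full SVD on training data; keep the smallest k whose cumulative
  explained-variance ratio ≥ `retain` (default 0.95). With fewer samples
  than features, k is capped at the data rank with a warning.

The full feature vector has 29 columns: 3 covariates, 2 regions × 9 color,
2 regions × 4 texture. Subsets are configurable.

## GA-SVM

The chromosome is (log₂c, log₂g), bounded to log₂c ∈ [−5, 15],
log₂g ∈ [−15, 3] (common practice for RBF grids). Fitness is mean held-out
accuracy of stratified 10-fold CV; folds are fixed per run by first putting
rows in a canonical lexicographic order and then shuffling with the seed,
which makes fitness invariant to the row order of the training table.
Operators: tournament selection (size 2), uniform crossover (probability
0.7), per-gene Gaussian mutation (probability 0.1, σ = 0.5 log₂ units)
clipped to bounds, elitism of the single best individual. Population 20,
100 generations. Fitness evaluations are cached per chromosome; elitism
plus caching make the best-so-far curve non-decreasing, reproducing the
characteristic rise-then-plateau fitness trace. The final model is a
single RBF SVM refit on all training data with the best (c, g); the
quadratic program is solved by scikit-learn's LIBSVM binding — the search,
CV harness and plumbing are this package's.

## Evaluation

Positive class = diabetic-analog (label 1). Sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). ROC thresholds at every distinct score (ties
stepped simultaneously); AUC by trapezoid rule, which equals the
tie-corrected Mann–Whitney pair statistic (asserted in tests to 1e−12).
The negative-class curve (the mirrored display convention for two-curve ROC
plots) is reported alongside. Baselines: k-NN (k = 5, score =
positive-neighbor fraction), Gaussian Naive Bayes (posterior), BP-NN (one
hidden layer of 10 logistic units, SGD, score = output activation). These
hyperparameters are conventional defaults, all configurable. The 80/20
split is stratified with per-stratum training count `round(0.8·n)`; a
single seeded split is the default.

## Synthetic data

`make_tongue_image` renders an elliptical tongue inscribed in the frame;
the coating is a concentric ellipse scaled by √coating_fraction and shifted
into the upper half (kept fully inside the tongue, so the coating is
connected and its area fraction is within a few percent of the request;
fractions 0 and 1 are exact). Pixels are the region mean color plus a
shared-channel Gaussian gray texture (`texture_amplitude`, default σ = 6)
plus per-channel Gaussian noise (`noise_sigma`, default σ = 3), clipped to
[0, 255]. Default colors: body (180, 120, 120) reddish, coating
(210, 200, 170) pale yellow — a\* ≈ 23.5 vs. −1.4, a clear chrominance
separation.

`make_cohort` adds per-subject color jitter (σ = 5 per channel), a
class color shift (default (+12, −10, −4), applied to the diabetic-analog
class), coating fractions uniform in [0.25, 0.45], and covariates whose
distributions mirror the study groups (diabetic age ~ N(58.35, 12.99),
53.7% male; control age ~ N(62.37, 8.13), 36.0% male; BMI given a mild
class shift). `make_feature_dataset` draws two isotropic unit-variance
Gaussian classes a configurable distance apart, with the 296/531 imbalance
as default counts.

**What this does not emulate:** real lighting and color-temperature
variation, specular highlights, non-elliptical tongue shapes, fissures and
papillae structure, multi-patch or graded coatings, and correlated
camera noise. Passing tests therefore demonstrate correctness of the
algorithms and the pipeline's statistical machinery — not clinical
performance; the synthetic classes are far cleaner than patients, so
headline synthetic accuracies (≈0.9–1.0) exceed what heterogeneous
clinical data can support.

## Problem sizes and numerics

Tests and the acceptance script run at desk scale by design: 120-subject
cohorts at 96×128 px for end-to-end runs (≈10 s), n = 300 for the
GA-vs-grid-search comparison (the GA's distinct-evaluation cache keeps a
20×100 search near 400 actual CV evaluations), and 16×16 images for the
brute-force texture oracles. Degenerate cases are handled explicitly:
empty coating masks (NaN → train-mean imputation), constant features
(scale to 0), rank-deficient PCA (cap + warn), unimodal chrominance
(all-body + warn), black pixels (H = S = 0). Seeded `numpy.random.
default_rng` streams drive every stochastic component; no global RNG state
is used.

## Known limitations

* Segmentation assumes exactly two chrominance populations; gray/black
  coatings, which overlap the body in a\*, would need a different channel
  (config `chroma_channel`).
* SMOTE's gender rounding slightly biases synthetic minority covariates.
* The BP-NN baseline's SGD training can hit its iteration cap on hard
  data; it reports whatever it converged to (sklearn emits a convergence
  warning).
* The GA does not adapt operator rates; for the two-gene search space this
  is adequate, and the grid-search cross-check in the acceptance suite
  bounds any optimality gap at 0.02 CV accuracy on the synthetic task.
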