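# Methods

## The phantom model

Each head phantom is a composition of smooth implicit solids evaluated on a
voxel grid: an ellipsoidal brain (semi-axes 0.66/0.61/0.57 of the grid
half-width) with a white-matter core at 80% of the brain radius, a central
ventricle cavity, two mirrored spherical "hippocampus" inclusions at
gray-matter intensity, and a spherical skull band (0.68–0.80 of the
half-width). Compartment edges are sigmoidal in normalized radius (width
0.035), so fractional radius changes move intensity mass even when they are
smaller than a voxel — this is what makes a 10% atrophy effect expressible
on a 16³ grid. Intensity modes before noise: background 0, ventricle 0.15,
gray 0.7, white 1.0, skull 1.3.

Class effects apply to patients only:

* **atrophy** *a*: brain and hippocampus radii × (1 − a), ventricle radii
  × (1 + a);
* **texture** *t*: gray intensity moves toward white so the gray–white gap
  is × (1 − t);
* **contour shortcut** *s*: intensities in the 1-voxel shell just inside
  the mask boundary × (1 + s) — an explicit, dose-controllable version of
  the edge artifact that skull-stripping creates implicitly.

Every image additionally gets a small random rigid jitter (±4° rotation,
±3% shift and radius jitter) applied *before* class effects, truncated
additive Gaussian noise (default SD 0.02), and an additive per-site tissue
offset (SD 0.01). Ages are Gaussian per class with a configurable mean
offset (default +2 years for patients, SD 6) so the matching stage has real
work; sex is Bernoulli(1/2). All randomness derives from
`(seed, subject_id, image_index)` via hashed seed sequences, so cohorts are
bit-reproducible and independent of generation order.

**What the generator does not emulate:** MRI physics (bias fields, Rician
noise, partial-volume mixtures), cortical folding, registration error, and
any site effect beyond a global intensity offset. Passing tests therefore
demonstrate that the *pipeline* behaves as specified under controlled
signal decompositions — not that any conclusion transfers to a particular
real scanner or cohort.

## Preprocessing

The white-matter peak is the center of the highest-count bin of the
196-bin within-mask intensity histogram, with candidate bins restricted to
intensities above the midpoint of the in-mask range so the gray-matter mode
can never win. The histogram range is [min, max] of in-mask intensities.
Normalization divides by the peak (idempotent up to one bin width).
Binarization thresholds at a fraction of the WM peak with ties going to
foreground. The eight configurations are built by binarizing the
*normalized aligned* image first and masking afterwards, so each
skull-stripped variant equals its aligned counterpart restricted to the
mask.

## Cohort handling

Propensity scores come from a logistic regression of class on age and sex
(constant covariate columns are dropped; if nothing varies, all logits are
equal). Matching is greedy 1:1 nearest neighbor on the logit, cases in
descending logit order, without replacement, optional caliper, no caliper
by default. Splits are drawn per class over subjects weighted by image
count: a seeded shuffle is cut at the boundaries nearest the cumulative
70% / 85% image fractions, which keeps proportions within one subject's
images of the target and guarantees all images of a subject share a
subset. Session schedules enumerate samplings × initializations; the seed
lists depend only on the split seed, so different preprocessing
configurations receive identical (sampling, init) pairs and their sessions
can be compared pairwise.

## Classifier and training

The network is implemented directly on NumPy in float32: im2col + GEMM
convolutions with same-padding (symmetric for stride 1, right-padded for
stride 2 so even sizes halve exactly), He-normal initialization, ReLU
activations, and a softmax head trained with cross-entropy and Adam
(lr 1e-3, β₁ 0.9, β₂ 0.999). The non-positive-bias constraint is realized
by projection — biases are clamped to ≤ 0 after every optimizer step —
which also keeps the relevance decomposition clean (see below). Fixed
epoch budget, final-epoch weights, no early stopping. A non-finite loss
aborts the session and marks it non-converged; the convergence screen
additionally requires final validation accuracy ≥ 0.60 (chance is 0.5 on
balanced classes). Determinism is best-effort: identical seeds on the same
BLAS give identical runs; acceptance-style checks use multi-seed majorities
rather than bitwise equality.

AUC is the Mann–Whitney pair-count statistic (ties count half), verified
against an independent implementation in the tests. Session metrics are
aggregated as mean, sample SD, and the normal-approximation interval
mean ± 1.96·SD.

## Relevance propagation

LRP starts at the pre-softmax logit of the explained class (the predicted
class unless fixed) and applies the αβ-rule (default α = 1, β = 0) through
dense and convolutional layers on their affine pre-activations; ReLU and
flatten pass relevance unchanged. Inputs to every layer are non-negative
(image intensities and ReLU outputs), which the implementation exploits.
Bias relevance is absorbed rather than redistributed; with all biases ≤ 0
the absorbed amount is non-negative, so the input relevance sum is bounded
by the starting logit and equals it exactly for bias-free networks
(stabilizer ε = 1e-9; zero-denominator neurons propagate nothing). A
consequence of starting at the raw logit: when the winning logit is ≤ 0
(possible early in training), the map is degenerate and is dropped from
relevance summaries.

Windowing builds a 196-bin histogram of relevance values and accumulates
bin relevance sums from the top bin downward until the requested fraction
(default 40%; 10% for IoU and the boundary share) of total relevance is
covered; the threshold is the lower edge of the last included bin.

## Similarity, statistics, clustering

Heatmaps are min-max normalized before comparison. RMSE is reported ×100
(on normalized maps the raw value lives in [0, 1]). MSSIM uses uniform 7³
windows, dynamic range 1. EMD treats both maps as unit-mass distributions
and averages the exact 1-D Wasserstein-1 distances of the three axis
marginals, in voxel units — chosen over full 3-D transport for exactness
and speed; it retains the translation sensitivity that makes the metric
informative. Comparisons run on session mean heatmaps per aligned session
pair; constant or degenerate maps are skipped.

The exact McNemar test conditions on the discordant count n and doubles
the smaller binomial tail, capped at 1 (p = 1 when n = 0). Each test
carries its finite support of attainable p-values; the step-down Holm
procedure counts, at every step, only remaining tests whose minimal
attainable p could fall under the current threshold (Tarone's adjustment),
making the correction less conservative for small n without losing
family-wise error control — verified by a 500-replicate null simulation.
Sensitivity/specificity comparisons restrict the paired table to true
patients / true controls respectively; missing or non-converged session
pairs shrink the family.

Relevance maps are mean-pooled to 8³, connected in a symmetrized 10-NN
graph with Gaussian weights (bandwidth = median neighbor distance, weight
1 when all maps coincide), and clustered via the symmetric normalized
Laplacian. The cluster count is at least the number of near-zero
eigenvalues; otherwise the largest eigengap among candidates k ∈ [2, 8]
whose k-th eigenvalue is below 0.5 — the smallness condition is what keeps
a single well-connected cluster from being split. Labels come from seeded
k-means on row-normalized leading eigenvectors; the 2-D embedding is
seeded t-SNE and is visualization-only.

The boundary relevance share intersects the top-10% relevance mask with a
2-voxel shell around the brain-mask boundary (boundary = mask minus its
erosion, dilated twice); shell, interior and exterior partition the grid,
so the three shares sum to 1. Uniform maps select all voxels (no threshold
exists), giving the shell's voxel fraction — a useful null reference.

## Problem sizes

The committed analysis and acceptance profiles use 16³ grids, 30 subjects
per class × 1 image, 2×2 or 1×1 schedules, and 12 training epochs — sized
so the entire audit runs in minutes on one CPU while every qualitative
contrast (shape suffices; contour attracts relevance; zero effect stays at
chance) is preserved. The paper-faithful geometry (160×240×256, 10×3
schedule, 30 epochs) is fully expressible through the same configs; the
architecture check instantiates it symbolically (319,626 parameters)
rather than training it.

## Known limitations

* Explaining the raw logit yields degenerate (all-non-positive) maps for
  weakly trained sessions; such maps are excluded from summaries rather
  than rescaled.
* At 16³ the skull band and gray rim are 1–2 voxels thick; compartment
  statistics are partial-volume diluted, which the tests account for by
  using medians and direction-plus-margin assertions.
* Axis-marginal EMD is a lower bound on true 3-D transport cost; identical
  marginals with different joint structure would read as distance 0.
* The desk-scale cohorts make classification easy (AUC near 1 at atrophy
  0.1); the pipeline measures *which* cue is used, not realistic absolute
  performance.
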