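# Methods

This note documents the models and procedures implemented in `popgeom`, the
choices made where the underlying methodology is genuinely open, and what
the synthetic validation does and does not establish.

## Data model

A `ResponseTensor` holds nonnegative trial-averaged activity of shape
`neurons × sequences × time` with per-sequence metadata (base class, variant,
drift direction). Conventions: directions are degrees, counter-clockwise,
0° = rightward drift, on a uniform grid of `n_directions` points; time bins
are uniform with the first bin starting at stimulus onset (bin centers at
`(i + ½)·bin_width` s); activity units are arbitrary but must be finite and
≥ 0 (validated on construction, with the offending index reported).

On disk, tensors are stored either as HDF5 (bit-exact round trip) or as a
human-inspectable CSV bundle (long-format activity table + sequence metadata
table + JSON sidecar).

## Decoding analyses

**Analysis units.** The default grouping averages within-class variants,
giving `classes × directions` units (48 under the default ensemble); the
per-sequence grouping (88 units) is retained as an option.

**Manifold.** Each unit's feature vector is its time-averaged population
activity. PCA subtracts the grand mean across units and applies no
per-neuron variance scaling: activity-magnitude structure (e.g. a
non-selective intensity component) is part of what the embedding should
show. Component signs follow a largest-loading-positive convention so
outputs are deterministic; zero-variance input maps every unit to the origin
with zero explained variance rather than NaN.

**Trajectories.** The trajectory PCA is fitted on the pooled (unit, time)
point cloud, not on time averages, so trajectories and the manifold live in
different but affinely related spaces. Because the projection is affine, the
time average of a trajectory equals the projection of the unit's
time-averaged activity — `DecodingResults.project_units` exposes the fitted
projection so this identity can be used and tested.

**Classification.** `nearest-centroid-loo` is leave-one-unit-out nearest
class centroid (Euclidean); ties resolve to the lowest class index so
degenerate inputs are deterministic. `linear-cv` is a stratified k-fold
ridge classifier. The choice of classifier behind a headline "accuracy"
number is often under-specified in the literature, so the scheme is an
explicit argument.

**Selectivity.** OSI and DSI use the circular-variance (vector-sum)
convention, `|Σ r_d e^{ikθ_d}| / Σ r_d` with k = 2 and 1 respectively,
computed on the time-and-variant-averaged tuning curve of the class of
maximal response. This convention is bounded in [0, 1] and needs no
null-direction choice; a zero-response neuron scores 0 on both.

## Encoding analyses

**Normalisation.** Each neuron's slab is scaled to peak 1
(`per-neuron-max`), so the embedding reflects response shape rather than
gain; all-zero neurons are flagged and excluded.

**Non-negative CP decomposition.** Hierarchical alternating least squares
(HALS) with column-wise nonnegative updates; the objective trace is recorded
and is non-increasing. Restart 0 uses a deterministic data-driven
initialisation (absolute leading singular vectors per unfolding), which
makes a single-restart decomposition permutation-equivariant in the neuron
axis; further restarts are seeded random, and the best (lowest relative
Frobenius error) run wins. Rank selection ("auto") uses an elbow rule:
the rank grows while each extra component reduces relative error by ≥ 5%,
and the last rank that cleared the bar is kept — so a component buying less
than 5% is never included. (Read literally, "smallest rank whose improvement
falls below 5%" would include that unhelpful component; we keep the elbow
intent instead.)

**Similarity graph.** Gaussian kernel on Euclidean distances between
row-normalised neuron loadings with a local bandwidth per neuron — its
distance to its k-th nearest neighbour: `W_ij = exp(−d²_ij/(σ_i σ_j))`. This
is a fully specified stand-in for adaptive-neighbourhood kernels used in
published encoding-manifold pipelines; duplicates (σ = 0) are floored at a
machine-scaled epsilon and reported.

**Diffusion embedding.** The affinity is row-normalised to a Markov matrix;
coordinates are `λ_m^t ψ_m` for the top nontrivial right eigenvectors
(computed through the symmetric conjugate, trivial λ = 1 constant vector
dropped, negative eigenvalues discarded, diffusion time t = 1 by default,
signs fixed largest-entry-positive). A disconnected graph is embedded per
component: the leading coordinates become centered component indicators —
exactly the λ = 1 eigenspace orthogonal to the constant, so components
separate by sign deterministically — followed by per-component diffusion
coordinates ordered by eigenvalue; component labels are reported.

**Topology statistics.** `n_components` counts connected components of the
symmetrised k-NN graph on the embedding; clusters come from seeded k-means
at the silhouette-optimal k; `gap_ratio` is the mean nearest
other-cluster distance over the mean nearest same-cluster distance (∞ when
clusters contain exact duplicates); `label_ari` is the adjusted Rand index
against reference labels.

## Tubularity

With class centroids `c_k(t)`, per-step between-spread
`b(t)` = mean pairwise centroid distance and within-spread `w(t)` = mean
point-to-own-centroid distance:

    S_tight = mean_t  b(t) / (b(t) + 2·w(t))

The factor 2 makes S_tight = 0.5 when centroid spacing equals twice the
within-bundle spread (tubes touching). Steps with `b(t) = 0` contribute 0;
zero-width separated tubes give exactly 1. The per-class breakdown uses the
same `b(t)` with class-restricted `w_c(t)`; because `w ↦ b/(b+2w)` is
nonlinear, the count-weighted mean of per-class values matches the pooled
score only approximately (tightly so when dispersions are comparable).

`S_cross` counts order exchanges: for each cross-class trajectory pair and
consecutive step, the difference of the two projections onto the axis
joining the two class centroids must strictly change sign. The flip is
required on both endpoint axes (each time point projected onto its own
instantaneous axis), which makes the count exactly time-reversal symmetric;
a degenerate (zero-length) axis at one endpoint defers to the other. Strict
sign change means an intersection landing exactly on a sample point (or an
exact tangency) is not counted — generic configurations are unaffected.
Normalising by (cross-class pairs × (T−1)) bounds the score in [0, 1]. Note
this is an *order-exchange* definition; counting geometric polyline
intersections or bundle-membership switches are alternative readings, and
the implementation is versioned so a different definition can be swapped in.

Both scores use Euclidean distances in the trajectory space as given
(default: the decoding-trajectory PCA space at its configured dimension,
recorded in the output) and are invariant to global rotation, translation
and uniform scaling.

**Comparison test.** `compare_scores` bootstraps trajectories with
replacement within class, independently in each set, and uses the centered
two-sided convention `p = (1 + #{|δ* − δ̂| ≥ |δ̂|})/(n_boot + 1)`, so
identical inputs give p = 1 exactly; the empirical type-I error at α = 0.05
over 200 null repetitions falls within [0.02, 0.09] (checked in the
acceptance suite). Bonferroni correction multiplies by the caller's number
of comparisons.

## Alignment battery

* **RSA**: RDM per system = 1 − Pearson across features between condition
  rows; score = Spearman correlation of the RDM upper triangles.
  Zero-variance conditions are dropped from both sides (warned).
* **CCA**: each side reduced to `pca_dim` principal components (default up
  to 10), canonical correlations via QR-orthonormalised bases with
  rank-deficient directions dropped; score = mean of the top
  `n_components` correlations.
* **LP**: k-fold cross-validated ridge; out-of-fold predictions pooled, then
  mean per-target-feature Pearson correlation. Directional: the report
  stores both directions and uses their mean. On pure-noise targets the
  score has a small negative bias (a known property of cross-validated
  correlation), well inside the null spread.
* **DSA**: each set reduced to its top-`rank` principal components of pooled
  points; a one-step linear operator `A` fitted by least squares over all
  transitions; dissimilarity = `min_Q ‖A_X − Q A_Y Qᵀ‖_F / max(‖A_X‖,
  ‖A_Y‖)` over orthogonal Q (both determinant components), solved by seeded
  multi-start (identity + a reflection + random orthogonal starts, 10 by
  default) with local refinement over a skew-symmetric parametrisation;
  score = 1 − min(1, dissim). No delay embedding beyond the rank-PCA is
  used.

The battery mean is the plain arithmetic mean of the four scores — they live
on different natural scales, but no weighting is specified by the metrics'
common usage, so none is invented.

## Synthetic data: the stated world

The default stimulus ensemble has 6 base classes — a grating class carrying
six spatial-frequency variants, plus five single-variant flow classes —
giving 11 variants × 8 directions = 88 unique sequences, which
variant-average to 48 analysis units. This is the unique simple
factorisation consistent with the four published counts (88 sequences, 6
classes, 8 directions, 48 manifold points); the exact split of variants
across classes is not published, so it is configurable.

Population responses are separable:
`gain · class-affinity · vonMises(direction; pref, κ) · profile(t)` plus
noise (truncated Gaussian or Poisson-like), clipped at zero. Default sizes:
20 neurons per class (120 total), κ ∈ [1, 4], gain ∈ [0.8, 1.2],
cross-class affinity 0.1, 20 bins of 50 ms, Gaussian noise SD 0.05 —
modest trial-averaged variability for a well-driven population. Temporal
profiles: transient (gamma-shaped pulse peaking at 15% of the trial),
sustained (saturating ramp, τ = 0.15 of the trial), periodic (rectified
sinusoid, 2 cycles per trial by default; integer cycles close trajectory
loops), ramp (linear), and nonselective (direction- and class-independent
rising intensity, τ = 0.3 — the "intensity arm" phenotype).

Trajectory bundles are center curves (straight, arc or loop) plus smooth
per-trajectory offsets (constant + three Fourier modes, normalised to unit
RMS and scaled by σ, so mean offset distance is exactly linear in σ at fixed
seed). Planted crossings are adjacent-lane transpositions of straight center
curves at scheduled times; each center-level event makes every cross-bundle
trajectory pair cross once, so the planted count is
`center events × n_traj²` (consistent with the X-configuration, where one
center intersection yields `n_traj²` pair crossings).

**What a green test does not establish.** The generator produces separable,
stationary-tuning responses with independent noise; real recordings (and
network activations) have correlated variability, adaptation, heterogeneous
latencies and non-separable spatiotemporal tuning. Recovery results (ARI,
accuracy, calibration bands) therefore certify the *pipeline*, not any
claim about a particular biological dataset or pretrained model — analysing
those requires their activity tensors, which are out of scope here.

## Degenerate inputs and numerical choices

* All-zero activity: decoding units coincide at the origin; classification
  falls back to the fixed class order (accuracy ≤ max prior); selectivity
  indices are 0; all-zero neurons are excluded from encoding manifolds.
* HALS dead components (zero Gram diagonal) are zeroed rather than divided.
* Eigen-spectra are clipped to (0, 1] after floating-point round-off;
  retained diffusion dimensions never include non-positive eigenvalues.
* The bootstrap p-value is never 0 (the +1 convention); `n_boot < 100`
  warns.
* Seeds: every stochastic routine takes an explicit integer seed; the
  pipeline derives per-stage seeds from one global seed via
  `SeedSequence([seed, stage_index])`, logged per stage.
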