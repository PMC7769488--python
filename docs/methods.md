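# Methods

`gaitfda` analyses sagittal-plane joint-angle curves (hip, knee, ankle, in
degrees) defined over the stride cycle, where 0% and 100% are consecutive
toe-off events of the same limb. Positive angles denote hip flexion, knee
flexion and ankle dorsiflexion relative to upright standing. This note
documents the models, the numerical choices behind them, and what the
synthetic-data generator does and does not emulate.

## Preprocessing

**Filtering.** "Fourth-order zero-lag Butterworth with 10 Hz cutoff" is
realized as a forward–backward pass of a 2nd-order Butterworth whose design
cutoff is raised by the dual-pass correction factor
`1 / (2^(1/2) − 1)^(1/4) ≈ 1.2465` (Winter's convention), so the combined
response is −3 dB at the nominal cutoff. The measured gain of the
implementation at the 10 Hz cutoff (fs = 250 Hz) is 0.710 and the gain at
50 Hz is 0.0022; both are verified against sinusoid projections in the tests.

**Toe-off detection.** Toe-off is the toe marker's lowest vertical point
followed by a sustained rise. A candidate local minimum qualifies if its
prominence is at least 10% of the signal range and the following 5 samples
(≈20 ms at 250 Hz) are strictly increasing; events closer than a 0.25 s
refractory window are merged keeping the deeper minimum. These three
thresholds are defaults exposed as function arguments; the qualitative
definition itself contains no numbers, and no force-plate gold standard is
available to tune them against.

**Segmentation and normalization.** `segment_strides` returns end-exclusive
segments `[e_k, e_{k+1})`. The stride-extraction path used before time
normalization appends the closing event frame (`include_end=True`) so that
the 0% and 100% grid points refer to the same gait event; without this the
last grid point would sit one frame short of the next toe-off and a
zero-noise trial could not reproduce its generating template at 100% of the
cycle. Each stride is interpolated onto the conventional 101-point grid
(0–100% inclusive) with a piecewise-cubic spline; cubic interpolation is
smooth for kinematic signals and avoids the ringing of global polynomial
fits. Runs whose signals contain a missing-sample gap longer than 10 frames
(or a gap touching the signal edge) are excluded; shorter gaps are linearly
bridged before filtering.

## Penalized spline smoothing (`fdsmooth`)

Curves are represented as `y(u) ≈ Σ c_j φ_j(u)` with either a clamped cubic
B-spline basis or a cyclic cubic basis (periodic B-splines, so value and
first two derivatives match across the 0/100% seam). Coefficients minimize
`‖y − Φc‖² + λ cᵀRc`, where `R` is the Gram matrix of second derivatives
computed exactly by per-span Gauss quadrature. Conventions that matter:

- Default basis size for SPM smoothing is 21 (≈ one basis function per 5% of
  cycle), enough to resolve the narrowest localized effects of interest
  (~12–15% of cycle) without interpolating noise. The SPM smoothing parameter
  default is λ = 0.01.
- The penalty is computed on the raw [0, 100] domain without rescaling, so λ
  values are interpreted on that scale. Smoothing parameters are only
  comparable between software packages up to the basis dimension and penalty
  normalization, which differ across implementations; the defaults here
  (0.01 for SPM smoothing; 0.1 / 0.18 for the hip–knee and knee–ankle
  couples) reproduce the intended behaviour — light smoothing that leaves
  localized features intact — rather than any external package's numerics.
- GCV uses the Craven–Wahba per-curve score `(RSS/n)/(1 − tr(S)/n)²`,
  averaged across curves, with ties broken toward the larger λ. At λ = 0 the
  fit switches from the normal equations to a direct least-squares solve with
  one step of iterative refinement, since squaring the design's condition
  number at the interpolation limit (n_basis = n points) otherwise costs
  ~7 digits of accuracy.

## SPM permutation t-tests (`spm`)

Two curve sets are compared pointwise with the two-sample pooled-variance t
statistic (classic SPM convention; Welch available via a flag). Grid points
with exactly zero variance yield t = 0 with a warning. The comparison is
unpaired, pooling all runs per condition across participants: the curve sets
mix participants with unequal run counts after exclusions, which an unpaired
test accommodates. Labels are shuffled at the run (curve) level.

Family-wise error over the trajectory is controlled with the max-statistic
permutation null: for each relabelling the maximum of |t| over the grid is
recorded. When the number of distinct relabellings is ≤ `n_perm`
(default 1000) all are enumerated; otherwise `n_perm` random relabellings
are drawn and the observed statistic joins the reference set (the +1
finite-sample correction, which guarantees validity). The critical threshold
is the `⌈(1−α)·N⌉`-th order statistic of the N reference values. Clusters are
maximal runs of grid points with |t| strictly above the threshold; each
cluster's p-value is the fraction of reference max statistics at least as
large as the cluster's own maximum. Under these conventions the realized
type-I rate measured over 500 null datasets (10 curves per group, 2° smooth
noise, 200 permutations) is ≈ 0.05, and a planted knee bump of twice the
noise SD at 66–81% of the cycle is localized in ≈ 99% of replicates at 20
curves per group.

## Cyclic-spline additive models (`gam`)

Per joint, stacked angle values are modelled as

    angle = β₀ + Σ_c β_c·1[condition = c] + f_c(pct) + b_run + ε,

with one cyclic cubic regression spline `f_c` per condition (sum-to-zero
constrained, so β₀ is the baseline's mean angle across the cycle and β_c are
mean-angle offsets), a random intercept per run, and Gaussian residuals.
Design choices:

- Run intercepts form a single exchangeable variance component; participant
  identity is carried as metadata for grouping (variability summaries per
  participant × condition) rather than as a nested variance component.
- Smoothing parameters (one λ per condition smooth) and the run-intercept
  variance are selected by REML through the mixed-model representation:
  `−2·l_r = (n−p)·log(2πσ̂²) + (n−p) + log|WᵀW+S| − log|S|₊` with
  `σ̂² = D_p/(n−p)`, optimized by L-BFGS-B on the log scale with 3 starts to
  guard against local optima. The constrained cyclic penalty is positive
  definite (the constant null space is removed by the constraint), so the
  log pseudo-determinant is an ordinary log-determinant per block.
- Reported residual variance uses the usual GAM scale `RSS/(n − EDF_total)`;
  coefficient covariances (hence SEs and t-values) use this scale times the
  inverse penalized information. EDF per smooth is the trace of its block of
  the influence matrix.
- Knot escalation refits with increasing knot counts and stops when deviance
  explained improves by less than 0.05 percentage points (the escalation rule
  states no tolerance; this one resolves angle curves to far below
  measurement noise).
- No approximate F/p-values are computed for smooth terms — estimates, SEs,
  t-values for parametric terms, EDFs, and the variance components are
  reported.

The implementation is cross-checked in the test suite against R mgcv fitting
the identical structure (`y ~ cond + s(pct, bs="cc", by=cond) + s(run,
bs="re")`, REML): parametric estimates agree to ~1e-6, standard errors and
the run-intercept SD to ~1%.

Between-run movement variability is the SD of the estimated (shrunken) run
intercepts within each participant × condition cell; singleton cells are
flagged with a missing SD.

## Bivariate functional PCA (`bfpca`)

Concurrent joint couples (hip–knee, knee–ankle) are smoothed with a shared
B-spline basis (λ defaults 0.1 and 0.18 respectively, overridable by GCV)
and stacked as coefficient pairs. Components are eigenfunctions of the
sample covariance in the inner product induced by the block-diagonal basis
Gram matrix, so "orthonormal" means orthonormal as functions. Both joints
enter unweighted since both are measured in degrees. Scores are projections
of centered fits onto the components; eigenvalues sum to the total
functional variance.

The leading two components are varimax-rotated for interpretability; the
rotation is computed on the component functions discretized to the 101-point
grid with both joints stacked, without Kaiser normalization (the functional
varimax convention; a flag could add Kaiser weighting but none is used by
default). Rotation preserves the spanned subspace, its total variance and
Gram-orthonormality; explained variance per rotated component is recomputed
from rotated score variances, and both raw (pre-rotation) and rotated
percentages are reported, since the two conventions genuinely differ.
Each component is canonically oriented so that its largest-magnitude grid
value is positive, removing the eigenvector sign ambiguity so that "+/−"
perturbation curves (mean ± 2 score-SDs times the component) are
reproducible.

## Synthetic data (`synthetic`)

Each generated stride is

    template(joint) + participant offset + condition effect + condition
    offset + run intercept + smooth periodic noise.

- **Templates** are fixed Fourier sums (≤ 3 harmonics) per joint, hard-coded
  for reproducibility without deposited data: one flexion–extension
  oscillation for the hip, two flexion peaks per cycle for the knee,
  alternating dorsi-/plantarflexion for the ankle, with amplitudes in the
  ranges typical of overground running.
- **Condition effects** are Gaussian bumps in %-cycle coordinates, wrapped
  periodically so bumps near 0/100% stay continuous — the minimal smooth,
  localized deviation consistent with reported condition differences, with
  no biomechanical model invented. Constant per-condition offsets are also
  available for mean-shift recovery studies.
- **Random effects** are constant vertical offsets per run and per
  participant (a run-level flexion–extension bias), matching what the
  additive model's random intercepts represent. The participant-offset SD is
  a free knob (default 2°) — no study value exists to calibrate it; condition
  contrasts are insensitive to it because designs are balanced.
- **Noise** is white noise circularly convolved with a periodic Gaussian
  kernel (SD 3% of cycle), rescaled to the requested marginal SD, so
  synthetic curves have realistic smoothness; raw white noise would make
  B-spline smoothing trivially dominant.

The defaults mirror the emulated study design: 14 participants, conditions
(BW, 1%, 3%, 5%) with BW baseline, 10 runs per condition (560 runs per
joint). The generator is a pure function of its configuration including the
seed, and the truth sidecar (config + realized random effects) is sufficient
to regenerate every curve exactly.

**What the generator does not emulate:** per-participant template *shape*
heterogeneity (only vertical offsets), phase/timing variability between
strides, amplitude-dependent noise, marker dropout patterns, and
non-sagittal mechanics. Passing recovery tests therefore demonstrates the
statistical machinery is correct under the assumed data-generating model,
not that real gait data satisfy those assumptions.

One subtlety in recovery studies: with i.i.d. run intercepts of SD 2° and
140 runs per condition, the sampling SD of a condition-mean contrast is
≈ 0.24°, so fixed condition offsets are only estimable up to the realized
mean of the drawn run intercepts. Recovery checks therefore compare offset
estimates against the *realized* estimand (generating offset plus realized
run-intercept mean difference), which the truth sidecar makes computable.

## Problem sizes and determinism

Statistical calibration checks use 500 null datasets (type-I error), 200
replicates (localization power), and 50 study-scale replicates (GAM
recovery); these sizes put Monte-Carlo standard errors well below the
margins being asserted while keeping a full test run to a few minutes.
All randomness flows through `numpy.random.default_rng` seeds carried in
configs; the orchestrated pipeline writes byte-identical CSVs when rerun
with the same config and seed, and its manifest records the seed and a
SHA-256 hash of the canonical config.

## Known limitations

- The toe-off detector is validated only against the package's own synthetic
  marker fixture; no force-plate reference exists here.
- The GAM fits per-condition smooths and reports their EDFs; software that
  fits a reference smooth plus difference smooths will report EDFs on a
  different (difference) scale even for the same fit quality.
- Smoothing-parameter values are not transferable across packages (basis
  dimension and penalty normalization differ); only behaviour is.
- The additive model assumes i.i.d. residuals within curves; smooth
  within-curve noise mildly inflates the apparent run-intercept variance
  (visible when the generating run SD is exactly zero).
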