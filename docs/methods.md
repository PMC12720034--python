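# Methods

This note documents the models, numerical choices and limitations of
`t2rp`.  It complements the API docstrings; nothing here is a measured
result — all numbers quoted as outcomes are computed by the test suite or
`scripts/acceptance.py`.

## Coordinate and data conventions

All volumes share one voxel grid indexed `(x, y, z)`: axis 0 left-right,
axis 1 cranio-caudal, axis 2 anterior-posterior.  Axis 2 is the **coronal
slice axis**: the emulated acquisition reconstructs 1.6 × 1.6 mm in-plane
with 8.8 mm coronal slices, so spacing defaults to `(1.6, 1.6, 8.8)` mm.
Slice-wise operations (the reference-region average, mask smoothing) act on
axis-2 planes; the six lung sub-volumes are bands along axis 1.  Both axes
are configurable.  Masks are 0/1 volumes; physical distances always use the
voxel spacing.

## T2 mapping

Mono-exponential decay is assumed: `S(TE) = S0 exp(-TE/T2)`.  Unweighted
ordinary least squares of `ln S` on TE is used — the simplest estimator
consistent with a "linear fit of the log-signal", with no noise-floor
subtraction and no multi-component or stimulated-echo modelling.

* **Noise floor (`min_signal`)**: echoes at or below 5× the estimated
  background noise SD are dropped per voxel.  Magnitude (Rician) data
  overestimate the true signal near the noise floor; at a 3× floor the
  late-echo bias pushes the median fitted T2 of a 40 ms / SNR 50 phantom to
  ~6% error, at 5× it stays below 5%.  The background SD is estimated from
  the eight grid-corner patches of the first echo (Rayleigh mean = σ√(π/2)).
* **Valid voxels**: a voxel needs ≥ 3 surviving echoes (2 when only two
  were acquired) and a strictly negative slope; otherwise it is excluded
  from `valid_mask` and pinned at `t2_cap` (default 2000 ms, guarding
  against absurd T2 in air).  How non-decaying voxels should be treated is
  genuinely open; flagging rather than guessing was chosen, and all region
  statistics use valid voxels only.
* On noiseless mono-exponential input the fit is exact to < 1e−10 relative
  error (asserted in the tests).

## Dose and geometry

EQD2 = D·(d + α/β)/(2 + α/β) with per-voxel per-fraction dose d = D/n and
α/β = 3 Gy; the conversion is the identity at 2 Gy/fraction.  V20 is
evaluated on the **EQD2** grid with a strict `> 20 Gy` comparison — the
source workflow converts doses to EQD2 before defining regions, though it
does not state this explicitly for V20; the threshold and comparison are
configurable.  The PTV is the GTV expanded by a physical 5 mm margin
(Euclidean distance transform with anisotropic sampling, so 8.8 mm slices
are never crossed by a 5 mm margin).

## Baseline correction

The lung must have exactly two face-connected components; each is split
into three cranio-caudal bands of equal slice extent (±1 slice, via
`array_split` over the occupied slices).  The reference band maximizes the
centroid-to-centroid physical distance to the GTV ("distance from the
target" is not otherwise specified); ties break to the lowest label.  The
reference mean averages **per-slice means with equal weight** over the
GTV-bearing coronal slices — the reading of "average over coronal slices"
that limits anterior-posterior (gravitational) T2 gradients — rather than
pooling voxels; a pooled variant would weight slices by voxel count.  If
the selected band has no valid voxels on those slices, the next-farthest
band is used (degenerate-geometry fallback).  The correction itself is an
exact affine shift; negative corrected values are meaningful and kept.

## Stratification

The classifier predicts RP when the parameter value is **≥ threshold**
(elevated corrected T2 indicates radiation-induced change).  The ROC sweep
runs over all distinct values with a +∞ sentinel; AUC is trapezoidal and
equals the Mann-Whitney U statistic divided by n₁n₀ (asserted exactly on
tie-free data).  Bootstrapping resamples patients with replacement,
unstratified, size preserved; replicates that lose a class are redrawn and
counted.  Each replicate's curve is evaluated on a fixed 101-point FPR grid
(vertical aggregation; duplicate-FPR vertices collapse to their upper
envelope before interpolation); the summary stores pointwise median and
2.5/97.5 percentile TPR bands — the CI is a pointwise band, not a band of
whole curves — and the median/CI of replicate AUCs.

The Mann-Whitney test is two-sided, exact when both groups have ≤ 12
tie-free observations, otherwise the tie-corrected normal approximation;
the all-tied degenerate case (SD = 0) returns p = 1 explicitly.

The Youden cut-off maximizes J = TPR_median − FPR over the grid (ties to
the smallest FPR).  Mapping the optimal FPR back to a threshold uses the
candidate threshold just above the (k+1)-th largest non-RP value (midpoint
to the next pooled value), choosing the candidate whose empirical FPR is
nearest the optimum: this reproduces the (1 − FPR) empirical quantile at
interior operating points, keeps sensitivity maximal at that FPR, and
yields a separating threshold under perfect separation, where a plain
quantile would misclassify the largest non-RP value.  The reported
sensitivity/specificity at the cut-off are read off the median curve, so
J = sens + spec − 1 holds exactly.

## Segmentation

Only RP patients with a CT–MRI follow-up gap of at most 28 days are
scored, using the cohort-wide PTV-parameter cut-off.  The ROI is V20 ∩
lung; thresholding uses ≥ on valid voxels.  Smoothing is 2D slice-wise on
coronal planes ("pixels" kernels imply 2D): 6×6 binary dilation then 3×3
erosion, even kernels anchored at floor(k/2).  Metric conventions: DSC = 1
and HD95 = 0 when both masks are empty; one-empty-mask cases give DSC 0 and
NaN ("missing") for undefined ratios rather than 0.  HD95 extracts
face-neighbour boundary voxels, computes directed nearest-surface distances
both ways in mm (KD-tree), pools them symmetrically and takes the 95th
percentile with linear interpolation; the alternative max-of-directed-95th
convention is not used.  SegAUC is the voxel-level ROC AUC of the corrected
T2 value against truth membership within the ROI — the score-based reading,
which unlike balanced accuracy of the binary mask is consistent with a
patient simultaneously showing high sensitivity, very low precision and
high SegAUC.

## Synthetic cohort

The generator provides the study conditions: 24 patients, prevalence 15/24
(11:4 grade-1:grade-2), five echoes at TE = 18/36/61/100/131 ms, and five
of the 15 RP patients with a > 28-day follow-up gap.  Anatomy is scaled to
the field of view (default 64 × 64 × 25 grid ≈ 102 × 102 × 220 mm): two
ellipsoidal lungs (~250 cm³ each), a 10 mm-radius GTV (~4 cm³, in the range
of the emulated cohort's median 9 cm³ tumors) placed with a random
cranio-caudal offset, PTV = GTV + 5 mm.  Doses follow a sigmoid falloff
(width 6 mm) from the GTV centroid, normalized so the PTV receives the
prescription and peaks at 1.25× it; fractionation schemes are allocated by
largest remainder from a table of typical hypofractionated lung schemes
(3×13.5 … 10×5 Gy).

Tissue T2 (no quantitative tissue priors exist for this setting, so the
defaults are tuned to the emulated cohort's *derived* group medians, not
fitted to tissue data):

* lung background 40 ± 3 ms (smooth Gaussian random field, ~8 mm
  correlation length), tumor +7 ms;
* a per-patient linear T2 gradient, SD 4 ms per half-FOV per axis —
  regional/gravitational variation that the distant-lung baseline cannot
  remove, and the main source of realistic parameter overlap between the
  groups;
* RP region: an ellipsoidal blob seeded on the PTV boundary toward the
  host-lung centroid (offset 0.8–2.2 PTV radii), volume log-uniform in
  40–160 cm³ (median ≈ 80 cm³, bracketing the emulated cohort's median
  84.6 cm³ RP volume), intersected with the lung; T2 elevation
  16 ms × lognormal(σ = 0.8) per-patient severity;
* non-RP patients receive a mild change of N(−2, 2.5) ms in a smaller
  high-dose blob (20–80 cm³), emulating fibrotic change / volume loss —
  this reproduces the slightly *negative* non-RP medians of the
  baseline-corrected parameters.

Signals are S₀ = 100 with Rician noise σ = 2 (SNR 50), implemented as
√((S+n₁)² + n₂²) with independent Gaussians — the standard magnitude-MRI
model; non-body voxels have S₀ = 0 and sit at the noise floor.  Dates are
synthetic; only the CT–MRI gap matters downstream.  With these defaults the
RP / non-RP medians of the PTV parameter land near 13 vs 2 ms and the
median bootstrap AUC across cohorts near 0.88 (asserted within [0.7, 0.95]
by the acceptance suite).

**What the phantom does not emulate** — and hence what passing tests do not
show about clinical data: registration error between CT and MRI (inputs are
intrinsically co-registered), respiratory motion, delineation uncertainty
of the ground-truth mask, partial-volume and susceptibility effects, and
tumor/fibrosis T2 heterogeneity.  Because the simulated RP region has a
sharp T2 boundary exactly matching its truth mask, segmentation metrics
(DSC ≈ 0.6, SegAUC ≈ 0.98 at default settings) are optimistic relative to a
clinical setting, where boundary raggedness and registration error dominate;
the stratification behaviour is the realistic part.

## Problem sizes and reproducibility

Default analyses run a 24-patient cohort on a 64 × 64 × 25 grid with 5000
bootstrap samples (seconds on one core); the test suite uses the same grid
for cohort-level checks and coarser 32–48³-scale grids for unit tests.  All
randomness flows from named seeds (`PhantomConfig.seed` spawns independent
per-patient streams via `SeedSequence`; the bootstrap has its own seed), so
every tabular output is byte-reproducible.  Configuration round-trips
through YAML; a run manifest records the seeds, a config hash and library
versions.

## Known limitations

* Unweighted log-linear fitting is biased at low SNR even with the 5σ
  floor; nonlinear (Rician-likelihood) fitting is out of scope.
* The six-band lung split assumes two connected lung components and fails
  loudly otherwise (no single-lung support).
* The Youden cut-off is derived from the median bootstrap curve of the PTV
  parameter only, mirroring the emulated workflow; no cross-validation or
  calibration of the clinical decision threshold is attempted.
* HD95 compares voxelized surfaces; sub-voxel surface positioning is not
  modelled, so values are quantized at the voxel scale (8.8 mm
  through-plane).
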