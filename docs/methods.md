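# Methods

`fundusmosaic` registers the two en-face SLO localizer images an OCT device
acquires per eye — one centered on the macula, one on the optic nerve head
(ONH) — into a single mosaic, using two independent methods plus a layer that
detects when either registration has failed.  This note documents the models,
the parameters that matter, the synthetic data the package is validated on,
and the numerical choices made where the design was open.

## Vessel-feature homography method

The primary method treats the retinal vasculature as the only structure
reliable enough to anchor a projective registration.

**Contrast decision and CLAHE.**  Poor-contrast exports concentrate their
histogram in a narrow dark band.  Per image, the least-median-of-squares
location of the intensity sample — the midpoint of the shortest intensity
interval containing ⌈n/2⌉ of the n pixels, i.e. the minimizer of
med_i (y_i − b)² over the location b — is compared against `th1` (default
120 on the 8-bit scale, about half the dynamic range).  At or below the
threshold, contrast-limited adaptive histogram equalization is applied
(8×8 tile grid, clip limit 0.01, bilinear inter-tile interpolation; grid
and clip are conventional defaults, configurable).  The decision is per
image: one image of a pair may be enhanced and the other not.

**Vesselness.**  At each scale σ ∈ {0.8, 1.6, 2.4, 3.2} px the image is
convolved with σ²-normalized second-derivative-of-Gaussian kernels; the
Hessian eigenvalues, ordered |λ₁| ≤ |λ₂|, give the blobness R_B = λ₁/λ₂
and structureness S = √(λ₁² + λ₂²), and

    V = 0                                               if λ₂ > 0
    V = exp(−R_B²/2β²) · (1 − exp(−S²/2c²))             otherwise

with β = 0.5 and c = 0.5·max(S), where max(S) is taken per scale so the
S-term is comparable across the ladder before the per-pixel maximum over
scales.  This form detects *bright* ridges, so the filter runs on the
intensity complement 1 − I (SLO vessels are dark).  The scale set extends
the customary initial σ = 0.8 by an arithmetic ladder covering vessel
calibers at 768² resolution.  The companion feature is the Euclidean
gradient magnitude of V (central differences).

**Segmentation and skeleton.**  Seeds come from the image's own feature
histograms: vessel seeds are pixels at or above the 0.92 quantile of
nonzero V, background seeds are pixels at or below the 0.50 quantile of V
with gradient magnitude at or below its median (inclusive comparisons so
degenerate zero-background maps still seed).  Two-class labels then
propagate to 8-neighbours: stage 1 grows only through territory whose
gradient magnitude is below the median (suppressing growth across edges),
stage 2 drops that constraint and contested pixels go to the class whose
current mean V is closer (ties to vessel; row-major sweeps; fixed point or
error after 100 sweeps).  The vessel mask is thinned to a one-pixel
8-connected skeleton; thinning preserves component topology.

**Descriptors, matching, MSAC.**  At every skeleton point whose 23×23
neighbourhood lies fully inside the frame, the raster-ordered block of V
values, scaled to unit Euclidean norm, is the descriptor (529-vector).
Matching is exhaustive SSD between unit vectors (SSD = 2 − 2⟨u,v⟩): each
reference descriptor proposes its nearest neighbour when SSD < `th2` = 1.0,
and proposals are accepted greedily in ascending SSD order, one-to-one.
The homography p_r = H·p_p (macula frame is the reference) is estimated by
MSAC over minimal 4-point samples solved by Hartley-normalized DLT, with
cost Σ min(residual², th3²), `th3` = 4.5 px, up to 2000 iterations with a
0.99-confidence early stop and a seeded RNG; the winner's inliers
(residual ≤ th3) are refit by least-squares DLT.  Greedy uniqueness and
Hartley normalization are our choices where the procedure was open; both
are standard.

**Mosaic and metrics.**  The ONH image is inverse-warped (bilinear) into
the macula frame on a union-bounding-box canvas; doubly covered pixels are
averaged so the overlap is visible.  Overlap is the number of overlapping
pixels relative to the pixel count of the source (moving, ONH) image,
computed by rasterizing the moving footprint in the reference frame.
Alignment metrics over matched inlier points: mean ± sd of |Δx| and |Δy|,
of the Euclidean distance D, the same per-point distances aggregated as the
RMS-error mean ± sd and max, and the pooled scalar √(mean ‖p_r − p_p‖²)
(`rms_pooled`).  With per-point aggregation the RMS mean equals the D mean
by construction; both are reported because users of the cross-table expect
both rows.

## NMI affine backend

The second method is a deliberately simple intensity-based backend.  The
ONH image starts shifted +50% of the fixed image's width (sign flipped for
known left eyes — the anatomical offset mirrors); because the NMI peak of
vascular images is only a few pixels wide while that initialization can be
tens of pixels off, an exhaustive translation sweep (±96 px in 8-px steps)
at the coarsest pyramid level locates the basin before optimization.
Powell's derivative-free method then maximizes Studholme's normalized
mutual information, NMI = (H(A) + H(B)) / H(A,B) ∈ [1,2], over the joint
histogram of the overlap region (64 bins at full resolution, halved per
pyramid level), across a 3-level pyramid (×4, ×2, ×1 downsampling) over
six parameters (tx, ty, rotation, shear, two scales), rescaled internally
so a unit step means ~1 px / ~1° / ~1%.  Iteration budgets are fixed per
level (1500/500/150 evaluations), making the backend fully deterministic.
A result outside |rotation| ≤ 30°, scales ∈ [0.7, 1.4] is a failure
signal.  The final objective value is recorded as the `similarity`
covariate and the 64-bin NMI as `nmi`; they differ only in binning.

## Failure detection

The vessel method self-reports: failure iff no matches were found or fewer
than 4 inliers remain (4 being the minimal homography sample).  The affine
backend instead feeds a 500-tree random forest fit on the covariates
(similarity, nmi, overlap_pct, tx, ty, rotation, skew) with registration
success as outcome; covariates with permutation importance above 10% of
the maximum are retained and the forest refit.  *failureAlert* is 1 minus
the fraction of trees voting success, computed by explicit per-tree votes.
*overlapdiff* — the absolute difference of the two methods' overlap
percentages for the same eye, in percentage points — cross-checks the
methods; pairs beyond 10 points (configurable) are flagged for inspection.
AUCs are computed from a plain maximum-likelihood logistic fit of failure
on the score(s); for a single monotone regressor this equals the rank AUC
of the raw scores, which is what the univariate path returns (a univariate
logistic is a monotone transform of its regressor).

## Synthetic data: what it emulates and what it does not

No public SLO mosaicing dataset exists, so validation uses a generator
whose defaults define the package's study conditions:

* a 1400² master scene: textured background (smooth field, fine
  2-px-scale micro-texture, radial vignette), bright elliptical disc, dark
  smooth macula, and a recursively bifurcating vessel tree (4 arcade roots
  near the disc, 6 levels, widths 5.5 → 1.5 px, dark Gaussian
  cross-sections);
* two 768² views: an integer crop centered on the fovea and a perturbed
  crop centered on the fovea→disc axis at the distance giving the
  requested overlap (default 0.5, attainable range [0.2, 0.9]); the
  default perturbation is a similarity (rotation ≤ 5°, scale 0.97–1.03),
  `projective` adds small perspective terms;
* per-view acquisition effects, drawn independently: vessel caliber and
  contrast re-rendered with smooth random fields (widths ×0.7–1.3,
  amplitude ±30%, emulating pulsation and tone-curve differences),
  defocus σ ∈ [0.5, 0.9] px, a smooth illumination field (±0.04), gamma
  jitter (log-sd 0.15), correlated speckle (sd 0.005) plus white noise
  (sd 0.01), and 8-bit quantization as in real TIFF exports.

Ground truth is exact: the homography is composed analytically from the
crop offsets and the perturbation, and the planted centerline
correspondences satisfy it to < 10⁻⁶ px.

What passing tests on this data do *not* show: clinical SLO pairs are two
independent acquisitions whose micro-texture does not repeat, so their
descriptors match far more sparsely (hundreds of matches out of thousands
of skeleton points) than here, where both views derive from one master
scene and typical pairs yield thousands of mutually consistent matches.
Corruptions strong enough to reproduce clinical match sparsity either
flood the quantile-seeded segmentation with noise ridges or destroy the
sub-2-px transform recovery, so the generator favors geometric fidelity
over match-count realism.  Pathology, optic-disc rim detail, and
nonplanar (curvature-induced) distortion are not simulated at all; the
projective model is exact here by construction, whereas on real eyes it is
an approximation.

## Problem sizes and numerics

The evaluation harness uses 50 similarity pairs (seeds 1–50 pattern) for
vessel-pipeline recovery, 10 translation-only pairs for the affine
backend, and 500-row covariate tables for the failure model — sizes at
which each quantity is stable to a few percent while a full run stays in
the minutes range on one core.  Degenerate inputs are handled as failure
signals, not crashes: featureless images (zero vesselness or < 50 vessel
seeds), < 4 matches or inliers, collinear MSAC samples, empty NMI overlap,
and implausible affine optima all produce a self-reported failure in the
pair's report.  Ties are fixed deterministically (leftmost shortest-half
window; vessel class on contested growth; stable sort in greedy matching),
and every stochastic step (MSAC, forest, generator) takes an explicit
seed, so identical inputs give identical reports.

## Known limitations

* Only pairwise (two-image) mosaics; no multi-image bundle.
* No photometric gain compensation in the mosaic beyond averaging.
* The affine backend's `similarity` is this backend's own objective value,
  not the output of any external registration toolkit.
* The importance-threshold covariate selection is a stand-in for nested
  variable-selection procedures; with strongly correlated covariates it
  may keep more variables than a redundancy-eliminating selector would.
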