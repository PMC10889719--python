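# Methods

trabekit rebuilds a three-dimensional tissue-class volume from stained serial
sections of a trabecular bone biopsy, registers it to a microCT volume of the
same specimen, measures the trabecular microarchitecture of both volumes with
an open morphometry engine, and quantifies their agreement with a standard
method-comparison battery.  This note records the models, algorithms and
numerical choices, what the synthetic phantom does and does not emulate, and
the known limitations.

## Reconstruction model

The biological object is a trephine bone-core biopsy from an augmented
(sinus-floor-grafted) site: a network of mineralized struts (native bone and
residual graft particles) embedded in non-mineralized tissue.  Serial
sections of the decalcified specimen are cut at approximately 5 µm, stained,
and scanned; the microCT volume of the same core (isotropic voxels, 11 µm in
the motivating protocol) provides the structural reference.

Reconstruction proceeds in stages, each with an in-plane similarity
transform `T(tx, ty) · R(θ) · S(s)` about the image centre as its currency
(sections are assumed rigid up to slight stretch; no elastic deformation is
modelled):

1. **Slide preparation** (`wsi_prep`).  Grayscale conversion, Canny edges
   (hysteresis 100/255 on a 0–255 scale), adaptive local thresholding
   (window 11, offset 2, inverted; Gaussian-weighted local mean by default,
   arithmetic mean selectable via `adaptive_kind`), pixelwise OR of the two
   maps, morphological closing (15 dilations then 15 erosions, 3×3 square),
   and connected-component extraction.  The component with the largest
   axis-aligned bounding box is the biopsy; its minimum-area rotated
   rectangle (angle normalized to (−90°, 90°] with width ≥ height) defines
   the upright rotation for coarse alignment, and its filled outline is the
   ROI polygon.  The erosion treats pixels beyond the canvas as foreground
   so that tight crop margins do not erode the closed band inward.  Exports
   resample bicubically; binary masks are re-thresholded at 128.  The output
   pixel pitch is the input pitch times the downsample factor.

2. **Stack pre-alignment** (`registration`).  Walking the stack from one
   end, each slide is compared against the previous `window` aligned slides
   with the keypoint matcher; the candidate with the most matches is the
   reference.  A similarity transform is estimated from the matched pairs by
   RANSAC and then refined by the sequential cross-entropy optimizer.
   Cumulative transforms are composed from raw-to-raw pairwise fits (the
   reference image itself is never resampled twice).

3. **Cross-modal matching** (`cross_modal`).  The CT volume is sliced in
   silico in the sectioning plane.  For each histology slide, the number of
   geometrically consistent keypoint matches (RANSAC similarity inliers;
   fewer than 6 counts as zero) against every CT slice forms a profile over
   z; spurious matches scatter in random directions — they would draw
   crossing lines between the image pair — so inlier counting keeps the
   off-partner background near zero while the true partner shows a dominant
   peak.  A Gaussian with constant baseline,
   `count(z) = A·exp(−(z−µ)²/2σ²) + b`, is least-squares fitted
   (initialized at amplitude max−median, mean argmax, width 2, baseline
   median); the rounded mean is the matched index.  A diverging fit
   (non-finite parameters, width exceeding the profile) falls back to the
   argmax and is flagged.  Each slide is then registered to its matched CT
   slice and its class mask is written at that z on the CT grid, so the
   reconstruction is born registered to the CT frame.  Planes without a
   slide are coded 255 (missing), optionally filled by nearest-plane
   replication.  When two slides claim one plane the higher profile peak
   wins and the loser demotes to its next-best index.  Matched indices are
   not forced monotone by default (`enforce_monotone` is available); order
   violations are recorded.

### Keypoint matcher contract

Any callable producing paired keypoints between two grayscale images can
serve as the matcher.  The shipped backend is classical: oriented
multi-scale FAST corners with binary BRIEF-style descriptors (skimage ORB;
800 keypoints, FAST threshold 0.02) matched with cross-checking and a 0.9
ratio test.  A transformer-based dense matcher can be plugged through the
same contract where its weights are available; nothing in the pipeline
depends on the backend beyond the `MatchResult` interface.

### Sequential cross-entropy optimizer

The refinement objective is the mean Bernoulli cross-entropy between the
intensity-normalized fixed image and the warped moving image over their
overlap, `−mean[f·log m + (1−f)·log(1−m)]` with intensities min-max
normalized to [0, 1] and clamped to [10⁻⁶, 1−10⁻⁶].  An overlap floor (25%
of the scored region) forbids degenerate escapes; an optional fixed-image
ROI mask restricts scoring to tissue, which matters when working images
carry uniform canvas margins.  Optimization is coordinate descent in the
order translation → rotation → scale (two cycles): translation by an
exhaustive coarse grid (8 px stride) refined per axis by bounded
golden-section search, rotation and scale by golden-section, with
tolerances 0.25 px / 0.05° / 0.001.  Separating the components avoids the
false joint optima that a simultaneous search falls into.  Each stage keeps
the incumbent when a probe is worse, so the objective is non-increasing by
construction.

Two empirical properties of this objective shaped the defaults.  First,
because the cross-entropy is minimized by the conditional mean rather than
by the sharpest prediction, any warp that blurs the moving image (rotation
interpolation, up-scaling) gains a small spurious advantage on noisy
images; left unchecked in a chained stack this compounds into systematic
scale inflation and rotation drift.  Both alignment stages therefore smooth
the two images (Gaussian, σ = 1 px) before scoring, and when a RANSAC seed
exists the refinement is confined to a trust region around it — during
pre-alignment ±4 px, ±1°, and scale within ±0.005 of the seed (keypoint
scale estimates are accurate and unbiased; the chain must not accumulate
the intensity bias), and during cross-modal registration ±8 px, ±5°, scale
±0.02 (per-slide, so nothing compounds).  Second, residual pre-alignment
drift is deliberately tolerated rather than fought: the cross-modal stage
registers every slide to its CT partner independently, which re-anchors the
stack slide by slide.

## Tissue segmentation

Slides are split into square tiles (512 px with 64 px overlap at the
published geometry; border tiles shift inward so all tiles are full size)
and a U-Net — contracting/expanding convolutional encoder–decoder with skip
concatenations, batch normalization after every 3×3 convolution, dropout
(rate 0.05) after each concatenation — classifies each pixel into bone,
graft, or non-mineralized tissue.  With 512-pixel input and four 2×2
poolings the bottleneck is 32×32.  Training uses Adam, class-weighted
categorical cross-entropy (inverse-frequency weights `N/(3·N_c)` from the
training masks), batch 16, and a plateau schedule that divides the rate by
10 (from 10⁻³ down to 10⁻⁵) after 30 stale epochs, in a five-fold
cross-validation; prediction ensembles the fold models, averages the
per-pixel softmax over models and tile overlaps, renormalizes, applies
bilateral filtering channel-wise (window 32 px, σ_color 64/255, σ_space 64;
bilateral rather than Gaussian because it removes isolated artifacts
without displacing tissue boundaries), renormalizes again and takes the
most probable class.  Argmax ties resolve by the fixed priority
bone > graft > non-mineralized.

The network is implemented in a small numpy layer framework written for
this package (forward and hand-derived backward passes, verified against
central-difference gradients in the test suite).  Channel widths are
configuration (`base_channels`, doubling per level) since only the depth
and tile geometry are architectural commitments.  Two presets exist: the
`paper` geometry above, and a `tiny` CPU preset (depth 2, base 8, 32 px
tiles with 8 px overlap, 20 epochs, batch 8) used by the test suite and the
demo pipeline.  No augmentation is applied by default.

## Phantom

The phantom makes every stage testable with exact ground truth:

* **Trabecular volume.**  Gaussian white noise filtered at a correlation
  length (default 44 µm at 11 µm voxels in the demo; tests use 33–66 µm
  depending on what they probe) and thresholded at the quantile that pins
  the mineralized fraction to the target BV/TV (30% by default, enforced
  within 0.5 percentage points by construction).  A second independent
  smooth field relabels a fraction (default 25%) of mineralized voxels as
  contiguous graft blobs.  A plate lattice, solid ball, and hollow-shell
  generator provide analytic geometry for morphometry oracles.
* **MicroCT rendering.**  Mineralized voxels map to intensity 1, the rest
  to 0; Gaussian blur (σ = 1 voxel) and additive Gaussian noise
  (SD 0.05) follow, clipped to [0, 1].  At this noise floor a global Otsu
  threshold recovers ≥ 98% of mineralized voxels, which anchors what
  "SNR floor" means in the tests.
* **Histology stack.**  Sections at a configurable thickness (5 µm
  physical default; the demo sections at the CT pitch so that slide and
  plane indices coincide) take the class map at z = ⌊depth/voxel⌋, are
  coloured with a fixed distinguishable palette (eosin-pink bone, violet
  graft, pale-pink soft tissue — a test fixture, not a stain-chemistry
  model), perturbed with Gaussian stain noise (SD 0.03), warped by a
  random similarity transform drawn uniformly within bounds (±10°, ±20 px,
  ±3% scale by default), and dropped independently with a configurable
  probability (modelling torn slides as uniform random removal).  All
  draws derive from one seed; the recorded transforms invert the applied
  jitter exactly.

What the phantom does **not** emulate: stain variability and chemistry,
section folding or tearing geometry (dropout is whole-slide), decalcification
artifacts, scanner optics, X-ray physics (beam hardening, partial volume
beyond Gaussian blur), or anisotropic in-plane resolution.  Passing tests
demonstrate that the algorithms recover known corruptions of the stated
kinds at realistic scales — not that the pipeline is validated on real
tissue.

## Morphometry

All parameters are computed on binary volumes (label rules `labels:bone`,
`labels:bone,graft` — the default, since graft is radiopaque and CT cannot
exclude it — or grayscale rules `otsu` / `fixed:t`).  Anisotropic volumes
are first resampled to isotropic voxels at the coarsest axis pitch (nearest
neighbour); voxel anisotropy is a known driver of surface-parameter
disagreement, so the rule is explicit and configurable.

* **BV/TV, Po** by voxel counting (they sum to 100% exactly by shared
  counting).  TV is the prism volume; TS its box surface.
* **BS** by marching-cubes triangulation at isolevel 0.5 after a light
  Gaussian smoothing of the binary field (σ = 1 voxel).  The smoothing
  suppresses the voxel staircase, which otherwise overestimates curved
  surfaces by ~8%; on a radius-20 voxelized ball the smoothed mesh is
  within 1% of 4πr².  Flat faces are unmoved since the isolevel stays at
  0.5.
* **Tb.Th / Tb.Sp** by maximal-sphere local thickness: sphere radii come
  from the Euclidean distance transform minus half a voxel (the phase
  boundary lies between voxel centres), processed in descending half-voxel
  bins; each bin's spheres cover their voxels via one distance-transform
  threshold.  Tb.Sp runs the same code on the complement, so
  separation-of-foreground equals thickness-of-background by construction.
  Spheres are bounded only by the observed opposite phase, not by the VOI
  face.  On an odd-width slab the result is exact; even widths quantize
  half a voxel low (a 10-voxel gap reads 9), the known center-sampling
  limit of the discrete transform.
* **Tb.N** = (BV/TV)/Tb.Th by default (model-free); the plate-model variant
  BS/TV/2 is selectable.
* **Tb.Pf and SMI** from one-voxel dilation differences:
  Tb.Pf = (S₁−S₂)/(V₁−V₂) and SMI = 6·S′·V/S² with S′ = (S₂−S₁)/voxel.
  Convex structures give positive Tb.Pf, well-connected concave lattices
  negative; SMI sits near 0 for plates, 3 for rods, 4 for spheres.
* **DA** from the mean-intercept-length fabric tensor: directed secants
  along 49 quasi-uniform directions (golden spiral), ray origins every
  2 voxels, intercepts counted as phase entries; `MIL(u)⁻² = uᵀMu` is
  least-squares fitted and DA = √(λ_max/λ_min) ≥ 1.  Isotropic random
  fields measure ≤ 1.3; parallel plates ≫ 3.
* **FD** by 3D box counting of the phase boundary over dyadic box sizes.
* **Obj.N, Po.N(cl), EuN** with 26-connected foreground and 6-connected
  background (standard duality): component counting, enclosed background
  components, and the 3D Euler characteristic
  χ = objects − tunnels + cavities.
* **Centroid and second moments** of the foreground in physical units.

Degenerate prisms (all pore or all bone) return defined values (BV/TV 0 or
100, zero surface, thickness undefined → NaN) rather than failing.  No
numeric parity with any proprietary morphometry implementation is claimed;
every formula above is the package's own commitment.

**Prism tiling.**  The shared ROI's bounding-box minimum corner (plus an
optional offset) anchors an axis-aligned grid of non-overlapping prisms
(512 × 512 × 230 µm by default; the demo uses 176 × 176 × 220 µm to get a
useful prism count from a small phantom).  Prism edges are converted to
voxels by ceiling, so a prism always spans at least the requested physical
size; only prisms fully inside the ROI are kept, and the identical grid is
applied to both volumes being compared.

## Method-comparison statistics

For each parameter, matched per-prism values from the two methods are
compared with:

* **Spearman rank correlation** (average ranks for ties; p from the
  t-approximation, two-sided; p < 0.05 flagged significant; no
  multiple-testing correction).  Constant input has no defined rank
  correlation and is reported missing.
* **Bland–Altman**: differences d = histology − microCT by default
  (configurable), bias = mean(d), 95% limits of agreement bias ± 1.96·sd(d),
  the D'Agostino–Pearson omnibus normality test of d, a one-sample t-test
  of zero bias, and OLS of d on the pair means with the slope's standard
  error and p (zero-slope test).  Zero-variance differences collapse the
  limits onto the bias and flag the record degenerate.
* **Mountain plot**: the empirical CDF of d folded at the median (1−p above
  0.5), peaking at 0.5 at the median, with the central 95% interval from
  the 2.5th/97.5th percentiles.

These computations delegate to scipy.stats; the package's contribution is
the battery, its orientation conventions, and the folded-CDF construction.

## Pipeline and problem sizes

`trabekit demo` (equivalently `pipeline.run` with the default
configuration) generates a 40 × 96 × 128-voxel phantom at 11 µm (the
non-square in-plane aspect keeps the upright-rotation convention stable
across jittered slides), renders CT, sections 40 slides at the CT pitch
with standard jitter, and runs preparation, pre-alignment (window 3),
tiny-preset segmentation trained on 75 tiles from 4 slides, cross-modal
assembly (z-search window 8 around the previous match, full-stack rescan on
a window miss, missing planes filled by nearest-plane replication), and
per-prism morphometry of the Otsu-binarized CT against the bone+graft
reconstruction.  The shared prism grid is restricted to the region where
the reconstruction carries evidence on every plane (voxels a jittered slide
never covered are coded missing, not pore — counting them as pore would
dilute BV/TV with an artifact of the slide footprint), followed by the
agreement battery for BV/TV, BS/TV, Tb.Pf, Tb.Th and Tb.Sp.  These sizes
are chosen so the whole demonstration runs in minutes on one CPU core while
every stage still faces its intended difficulty (jitter at the stated
bounds, SNR-floor noise, class imbalance); the same code paths accept
full-scale inputs.  Each run writes a manifest with per-stage status,
wall-clock seconds, output checksums (SHA-256) and warnings (fallbacks,
collisions, flagged fits), including on failure.

## Known limitations

* Affine-only: no elastic section deformation is modelled or corrected.
* The classical matcher needs visible in-plane texture; featureless or
  heavily smoothed sections defeat it where a learned dense matcher might
  not.
* Slice matching assumes the sectioning plane is the given CT cut plane;
  no search over plane orientation is performed.
* The even-width half-voxel quantization of Tb.Th/Tb.Sp above.
* Out-of-plane placement writes each slide to its single matched CT plane
  (nearest-z); no sub-plane interpolation between sections.
* Pre-alignment drift grows as a random walk along very long stacks; the
  cross-modal stage re-anchors it, but a stack without a reference volume
  retains the drift envelope.
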