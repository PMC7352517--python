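# Methods

This note documents the models, estimators and numerical choices behind
`stromascan`, what the synthetic-data generators do and do not emulate, and
the known limitations.

## Coordinate and angle conventions

Images are (row, col) arrays with the origin at the top-left; physical
coordinates are x = col·pixel_size (rightward) and y = row·pixel_size
(downward). Headings are measured from +x toward +y in degrees; a step in
−y is 270°. Fiber and stress-fiber orientations are *axial* quantities
(θ and θ+180° are the same state): every circular statistic doubles the
angles, operates on the circle, and halves the result, so e.g. the mean
direction of {10°, 170°} is 0°, not 90°.

## Fiber phantoms

`generate_fiber_image` renders each fiber as a centerline with a Gaussian
cross-section whose FWHM is the fiber width. Orientations are sampled by
the standard axial-data construction: 2θ ~ von Mises(2θ₀, κ), halved.
κ = 0 gives an isotropic mesh; κ = 10 (the aligned presets) gives a
doubled-angle mean resultant length of ≈ 0.95. Crimped (wavy) fibers
follow y′ = A·sin(2πs/λ + φ) in the fiber frame, with a random phase φ per
fiber; the ground-truth table records the local tangent angle at every
rendered point. Centerline mass is deposited bilinearly at quarter-pixel
steps and blurred to the target width, scaled to a peak intensity, offset
by a background level, and corrupted by Poisson noise (default; photon-
limited detection) or additive Gaussian noise.

Class presets (400×400 px at 0.5 µm/px — one 200×200 µm pattern tile):

| class      | κ  | width (µm) | crimp | emulates |
|------------|----|------------|-------|----------|
| normal     | 0  | 1.5        | none  | mesh-like random straight fibers |
| benign     | 0  | 3.0        | none  | thicker, more fibrotic random fibers |
| high_risk  | 10 | 1.5        | none  | strongly aligned straight fibers |
| high_grade | 10 | 1.5        | A=2 µm, λ=25 µm | aligned, wavy (crimped) fibers |

Per-class widths, densities and crimp wavelengths are plausible values for
ovarian stroma chosen once for the phantoms; they are not calibrated
against tissue measurements. The phantoms reproduce fiber *geometry* only:
no speckle, depth attenuation, or other SHG image statistics, and no 3D
structure (the 10 µm pattern height is metadata). Tests passing on these
phantoms therefore validate the estimators on images whose geometry and
noise are known, not the biology of any particular tissue.

## Blueprint discretization and the fidelity score

`discretize_fibers` enhances bright curvilinear structures with the
Sato tubeness filter (largest-magnitude negative Hessian eigenvalue
response, maximum over scales; default scales 0.5/1.0/2.0 µm), thresholds
the response with Otsu's parameter-free rule, and removes objects below a
minimum area (default 1 µm²). The graded map carries the original
intensities on the mask, median-background-subtracted and rescaled to
[0, 1]; it doubles as the scan plan's per-pixel shutter open fraction
because laser exposure maps linearly to crosslinked protein concentration.
Thresholding the tubeness response rather than the raw image makes the
mask invariant to global intensity rescaling.

`simulate_fabrication` blurs the graded map with a Gaussian PSF. The
specified FWHM is the total system resolution, so only blur in excess of
the pixel sampling is applied (σ² = (FWHM² − px²)/(8 ln 2)); a PSF at
exactly the pixel size is an identity. Poisson noise is parameterized by
the peak signal-to-noise ratio (peak counts = SNR²).

`fidelity_score` applies one and the same operator to both sides —
median-background subtraction, rescale to [0, 1], Otsu segmentation — and
reports three numbers: the Dice overlap of the two masks (×100), the
Pearson correlation of the normalized intensities on the mask union, and
their arithmetic mean as the combined percentage. Using the identical
operator on both sides makes the spatial term symmetric and guarantees a
blueprint scores exactly 100 against itself; reporting the components
separately keeps the combination transparent, since "colocalization of
spatial overlap and grayscale intensity" does not by itself fix a single
formula.

## Persistent-random-walk simulation and fitting

The trajectory generator integrates a stationary Ornstein–Uhlenbeck
velocity process: per-component variance µ/P, correlation time P, exact
discrete update at substep δ = dt/50 (decay e^(−δ/P), innovation variance
(µ/P)(1 − e^(−2δ/P))), initial velocity drawn from the stationary law so
the process is stationary from frame 0, and trapezoidal position
integration. This avoids the bias of an Euler scheme; the ensemble MSD of
500 simulated tracks matches the Fürth closed form within 5% at every
retained lag (the Monte-Carlo error scales as 1/√n_cells). Defaults mirror
the experimental sampling: 30-min frames over 72 h (145 frames).

Contact guidance (`guidance_strength` g ∈ [0, 1]) rotates the velocity
toward the local fiber axis — the signed axial difference, capped at the
difference itself — applied per substep at a rate whose compound over one
frame equals g. Applying the bias continuously matters: a single per-frame
rotation washes out within the frame whenever P ≲ dt and fails to produce
the intended persistence gain. The rotation is scaled by the local
structure-tensor coherence (cells only sense an axis where the matrix is
locally oriented) and field look-ups wrap periodically, matching the tiled
scaffold layout. With guidance the Fürth formula no longer holds; guided
ensembles are used only for qualitative trend checks (fitted µ̂ increases
with g; step headings cluster on the fiber axis). At desk-scale ensembles
the per-step increments between adjacent guidance levels are comparable to
the Monte-Carlo spread of µ̂, so strict orderings are asserted where the
effect is isolated (a fully coherent axis, paired seeds); across
independently seeded pipeline conditions only the extreme contrast is
asserted.

The MSD estimator is the overlapping-pair time average per track, combined
across tracks weighted by pair counts — the lowest-variance standard
choice. Lags are truncated at 1/3 of the track duration, where the
time-averaged estimator is reliable; in the recovery simulations this
keeps the µ̂ bias below 5%. Tracks shorter than 10 frames are excluded.
The fit is unweighted nonlinear least squares on (µ, P) with positivity
bounds (an optional 1/n_pairs weighting is available); µ is initialized
from the slope of the last half of the curve divided by 2n_d and P from
the first lag, with bounded restarts on failure. P is bounded above by 10×
the largest lag; `identifiable_P` is false when the estimate reaches a
bound, exceeds the largest lag (a plateau outside the observation window
carries no information), or has a standard error larger than itself.
Ensemble fitting is the default; a per-track mode quantifies cell-to-cell
variability.

## Orientation analysis

The local orientation field is the structure tensor at a Gaussian
integration scale σ (default 1.5 µm): the fiber axis is the eigenvector of
the smaller eigenvalue (axis of least intensity variation), and coherence
(λ₁−λ₂)/(λ₁+λ₂) grades how oriented each neighborhood is. A constant
image is returned flagged as degenerate with zero coherence. This replaces
curvelet-based fiber extraction; for angular distributions the two agree in
what they measure, and the structure tensor is parameter-light.

Angular distributions are weighted histograms on [0°, 180°) — default 36
bins of 5°, balancing resolution against counting noise — weighted by
coherence (default), intensity, or uniformly. The alignment index is the
mean resultant length of the doubled bin-center angles: 0 for uniform, 1
for perfectly aligned; for a doubled-angle von Mises sample it estimates
the Bessel ratio I₁(κ)/I₀(κ).

Watson's U² is computed from the ranked combined sample of doubled angles;
the p-value comes from random label permutations (default 999), exact
under exchangeability at any sample size, with p = (1 + #{U* ≥ U})/(B+1).
The statistic is invariant under common rotations of both samples.

Pearson correlation between two binned distributions requires identical
bin edges (no silent rebinning). Note that under the null of two
independent samples the correlation between 36-bin histograms has standard
deviation ≈ 1/√35 ≈ 0.17 *independent of the sample size* — individual
|r| values up to ≈ 0.35 arise by chance, which matters when interpreting
correlations between single pairs of distributions.

## Morphometry

Circularity is 4πA/p² (1 for a circle), clipped at 1. The perimeter uses
the four-direction Crofton line-intercept estimator, which is nearly
unbiased for smooth shapes: a rasterized r = 100 px circle scores 0.9995,
and a 4:1 ellipse lands within 1% of the Ramanujan-perimeter value.
Marching-squares contour length overestimates smooth perimeters by ≈ 5%
(biasing the circle's circularity to 0.90) and pixel-edge counting is far
worse, so neither is used. Orientation and aspect ratio come from second
central moments. The cell-vs-fiber alignment angle is the axial difference
between the cell's major axis and the fiber axis folded into [0°, 90°];
lower is more aligned.

Focal-adhesion detection band-passes the image with a difference of
Gaussians (σ, 1.6σ), subtracts the band-pass response of the cell mask
itself scaled by the in-cell background level (otherwise the intensity
step at the cell boundary seeds spurious detections), and thresholds at
mean + 3·sd of the in-mask background response with the background
statistics obtained by iterative sigma clipping. Components are filtered
to [0.25, 20] µm² by default with a 1 µm² minimum in the detector
(adhesions below ~1 µm² are not reliably separable from correlated noise
at these settings); merged near-coincident puncta are split at local
maxima of the band-pass response. On the 50-spot phantom at peak
SNR 10 this yields recall and precision ≥ 0.95 with ground-truth matching
at 2σ.

CTCF is the integrated intensity over the cell minus cell area × mean
background intensity, with a caller-supplied background region (mirroring
manual ROI practice; no automatic background estimation). It is exactly
invariant to constant offsets. The on/off-pattern ratio divides the two
cells' CTCF per unit area.

## Group statistics and the pipeline

Condition comparisons run one-way ANOVA followed by all pairwise t-tests —
Welch's unequal-variance variant by default, with a pooled option — and no
multiplicity correction by default; a Holm step-down correction is
available and recommended when many pairs are compared. Significance is
reported at α = 0.05.

A pipeline run is a pure function of its configuration: per-class child
seeds are spawned from the run seed, the metrics JSON contains no
timestamps or paths, and re-running the same config is byte-identical.
Timings and stage parameters go to the log. Default test and example
problem sizes (400×400 px single-tile images, tens to hundreds of cells,
50 fitting replicates) were chosen so the full suite runs in a couple of
minutes on one CPU while keeping Monte-Carlo tolerances meaningful.

## Known limitations

- The phantoms are 2D and geometric; conclusions about estimator accuracy
  do not automatically transfer to real SHG/fluorescence images with
  depth-dependent attenuation, speckle, or segmentation errors.
- The guidance mechanism is a minimal qualitative model of contact
  guidance, not a mechanistic one; its parameters have no direct
  biophysical calibration, and fitted (µ, P) under guidance describe an
  effective, not a generative, PRW.
- Fidelity scoring assumes pre-registered, equally sampled grids; no
  registration search is performed.
- The Watson U² permutation p-value is stochastic; at 999 permutations its
  resolution is 0.001 and its own Monte-Carlo error dominates below
  p ≈ 0.01.
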