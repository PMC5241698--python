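# Methods

This note records the models behind `smlmkit`, the defaults and why they
were chosen, and what the simulation-based tests do and do not demonstrate
about real data.

## Acquisition-time model

A frame contains a Poisson number of activations with mean *a·A_S*, where
*A_S* is the labelled area and *a* the activation density per unit area per
frame.  An activation yields a usable localization only if no second
activation falls inside its exclusion area *E(x)* — the intersection of a
disc of radius *r* (the minimum separation the fitting algorithm
tolerates) with the labelled structure.  By the Poisson void probability
that happens with probability exp(−aE), so the frames needed to accumulate
a density *Q* of good localizations are

    T(Q, a, E) = Q / (a·exp(−a·E)),

minimised at a\* = 1/E with T_min = e·Q·E.  The exclusion area follows the
local dimensionality *D* of the structure at scale *r*:

| D | structure | E |
|---|-----------|---|
| 2 | extended patch | π r² |
| 1 | filament of width w | 2 w r |
| 0 | point w₁ × w₂ | w₁ w₂ (independent of r) |

The 1D value uses the rectangle approximation (disc diameter × width); the
exact strip∩disc area is available through the Monte-Carlo oracle
`intersection_area_numeric`, which agrees with 2wr to <2% whenever strand
length ≥ 10r and width ≤ r/10.  E = 0 (the limit of a vanishing structure)
is reported as a flagged degenerate case: T = Q/a then decreases without
bound and no finite optimum exists.

Internal units are nm, nm² and per-nm²-per-frame throughout; the CLI prints
μm-scaled values alongside.  The default target density Q = 1/25 nm⁻² (one
localization per 5×5 nm reconstruction cell) is the density-limited
surrogate for a ~10 nm-scale reconstruction.

## Blinking and camera simulator

Photoswitching is a per-frame four-state Markov chain (inactive, active,
dark, bleached).  The defaults model the live-cell large-pool regime: a
huge reservoir of tagged fluorophores of which a small subset activates per
frame (`p_act`, the main experimental control), mean on-time of two frames
(active→inactive 0.5/frame), dark state disabled and bleaching negligible
on the acquisition timescale.  All transition probabilities are exposed for
fixed-cell work.  An emitter switching on mid-frame contributes a uniform
random fraction of the frame's photon budget, so the localizer and
classifier see the sub-full-brightness events real data contain.

Optics: pixel-integrated Gaussian PSF with σ = 0.21·λ/NA (≈73 nm at
λ = 488 nm, NA 1.4 — the standard Airy-core approximation), pixel size
110 nm, and 450 detected photons for a full-frame activation.  The
pixel integration uses the error-function integral per pixel, so total
flux is exact regardless of sub-pixel position.

Camera: photoelectrons are Poisson (QE 0.9 by default), the EM register is
Gamma(k = n_pe, θ = gain) — the standard EMCCD output model — with gain
100, 1 count RMS Gaussian read noise and a baseline offset of 100 counts.
The acquisition-level entry point adds a uniform diffuse background of
2 photons/pixel/frame as a stand-in for cellular autofluorescence; the
frame renderer itself defaults to none so flux checks stay exact.

Canonical structures: an 8×8 nm 0D point, an 8×3520 nm 1D strand, a
3520×3520 nm 2D plane and four 30 nm-radius vesicles at offsets (0,0),
(200,200), (200,400), (400,600) nm.  Tagging density is 0.5 nm⁻² except on
the 2D plane fixture, where 0.01 nm⁻² keeps the emitter pool tractable
(~10⁵ emitters) while still being ~400× larger than the number of
activations per sequence, preserving the large-pool assumption.  Fixture
activation probabilities default to the value that puts the measured
activation density at the theoretical optimum 1/E (E evaluated at
r = 440 nm), so "n× optimum" conditions are one multiplier away.

## Reference localizer

The bundled localizer is a documented stand-in, not a re-implementation of
any published tool: difference-of-Gaussians detection (σ 1.0/2.5 px) with
a noise floor estimated from the lower half of the band-pass distribution
(a global MAD would inflate with scene density and throttle detection in
exactly the crowded frames the classifier needs to see), 3 px minimum peak
distance, and an elliptical pixel-integrated-Gaussian least-squares fit in
an 11×11 window.  Width/asymmetry rejection keeps fits with
σ ∈ [0.7, 1.5]× the optical σ and |σx−σy|/σ ≤ 0.6.  Reported uncertainty is
the standard shot-noise + pixelation + background precision estimate,
doubled in variance under EM gain (excess noise factor).

The two-emitter separation sweep classifies each separation as merged (≤1
fit), biased (2 fits, midpoint bias > 2 nm) or accurate, noise-free by
default so the boundaries are deterministic.  For the default optics this
fitter merges below ~340 nm and is accurate above ~380 nm; these are
properties of *this* algorithm — published single-emitter fitters at the
same optics show the same three-regime structure but with boundaries in
the 400–600 nm range, which is why the exclusion radius fed to the
planning theory should be measured per algorithm (the sweep's conservative
recommendation) rather than assumed.

## Quality classification

Feature vector per localization: the 21×21-pixel patch around the fit in
its own frame plus the same patch in the previous and next frames (1323
pixels), each patch bilinearly shifted so the localization sits at the
centre of the middle pixel and rotated so the Sobel gradient of the
σ=1 px-smoothed patch at the centre pixel points up (this canonicalises the
direction of the dominant neighbour), followed by the fitter's numeric
outputs (width, brightness, background, uncertainty) and two
neighbour-presence flags — 1329 dimensions.  Each element is replaced by
the natural log of its magnitude (ε = 10⁻⁶ of the median nonzero
magnitude keeps zeros finite), a Gaussian window (σ = 5 px) then
down-weights rim pixels, and a PCA fitted on *this acquisition's*
covariance compresses to 20 dimensions.

Two deliberate choices here:

* **Window after log.** A multiplicative window applied to raw counts
  becomes an additive per-pixel constant after the log and cancels exactly
  out of the covariance matrix — it would not influence the PCA at all.
  Applying it to the log values genuinely reduces rim-pixel variance, which
  is the window's purpose.
* **Per-acquisition PCA.** The basis is refitted for every dataset so the
  retained directions track that dataset's variability; models refuse to
  classify features reduced with a different basis (fingerprint check).

The classifier is a 300-tree random forest (bootstrap, 5 candidate
dimensions per split, majority vote) trained on ~300 localizations drawn
by time-stratified sampling so the labelled set spans the acquisition.
Classes are weighted inversely to their training frequency: on dense data
the background class is a few percent of detections (~5 of 300 labels) and
would otherwise never be predicted.  For simulated data a ground-truth
oracle substitutes for the human labeller: a localization is *too dense*
if ≥2 emitters were active within 500 nm of it in its frame, *good* if
exactly one emitter lies within 250 nm and the position error is below 3×
the reported uncertainty, *background* otherwise.  When feeding the
classifier, the localizer's width gate is left open (`keep_rejected=True`):
the published workflow classifies the algorithm's raw output, and the
obviously distorted fits are exactly what the classifier should learn.

**Measured performance and limitation.**  On the overlap-rich 2D-plane
benchmark (activation density ≈ 2× optimum, 300 training labels), held-out
three-class balanced accuracy against the oracle is ≈0.5.  Diagnostics in
the test suite show the patch content *does* carry the signal (a forest on
the full raw vectors reaches ≈0.9 two-class accuracy); the bottleneck is
the 20-dimensional covariance-PCA representation, whose leading directions
are dominated by the crowd of unrelated neighbour blobs, combined with the
small label budget — and the background class is intrinsically rare on a
uniformly labelled plane, capping the three-class balanced average.  The
pipeline is nevertheless effective at its qualitative job: on the
four-vesicle benchmark essentially all bridge artefacts between vesicles
are classified as misfits while on-structure localizations survive.

## Evaluation

Reconstructions are 10 nm-pixel 2D histograms.  FRC splits the
localizations at random into halves, renders both on a common square grid,
correlates per one-Fourier-pixel ring and averages the curve over 20
independent splits; resolution is the inverse frequency of the first
crossing of the fixed 1/7 threshold (linearly interpolated), and a curve
that never crosses is reported as unresolved rather than numeric.  Sample
area is estimated from a thresholded (any-nonzero by default)
reconstruction with 8-connected components smaller than 10 pixels removed —
a reproducible replacement for hand annotation.  Frame subsampling trims
the first and last 5% of the sequence (burst-in and drift-out) and then
samples uniformly at random, which prevents consecutive-frame repeats of
one emitter from inflating short-sequence FRC.  Frames-to-target
extrapolation is linear: frames = Q·area/rate, assuming the observed
per-frame rate is maintained.

The density-ladder experiment runs the 1D and 2D fixtures at activation
multipliers (1/8, 1/4, 1/2, 1, 2)× the theoretical optimum, 200 frames and
three seeds per condition.  The ladder deliberately stops at 2× the
optimum: this is the regime where overlap failures are *silent* (merged
fits still masquerade as localizations); far above it the reference
fitter's detection visibly collapses and the apparent rate drops — an
overt failure outside the phenomenon the ladder probes.  Expected
signatures, asserted by the acceptance tests: frames-to-target using all
localizations falls or plateaus with density, using oracle-good
localizations it has an interior minimum, and the 2D structure needs >10×
the frames of the 1D structure at each optimum.

## What the synthetic tests do not show

The simulator has no drift, no sCMOS-style structured noise, no dipole or
aberrated PSFs, no 3D (astigmatic) encoding and spatially uniform labelling
and background; live-cell motion blur is absent.  Oracle labels use exact
ground truth, so they cannot reproduce limitations that stem from human
perception — in particular, the published observation that bridges between
structures ~200 nm apart survive classification because the *labeller*
cannot resolve them is absent here: with ground-truth labels those bridges
are removed as reliably as well-separated ones.  Quantities tied to a
specific published fitter (exclusion radii of 400–600 nm, a ~440 nm
minimum separation) are algorithm-specific; this package measures its own
fitter's values and exposes the sweep so users can measure theirs.
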