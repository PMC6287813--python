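# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `kymokin`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Physical picture and conventions

A rod-shaped protein (the motivating case is skeletal tropomyosin, a
coiled-coil dimer spanning seven actin monomers) polymerises head-to-tail
along each of the two grooves of an actin filament. A kymograph of a single
labelled filament therefore takes three intensity levels: background,
single-bound (one groove decorated) and double-bound (both grooves). The
analysis reduces each level boundary to a transition-time curve over filament
position,

* association: τ(x) = first frame at which position x is at or above the
  level (binding spreads outward from a nucleation, so a nucleation is a
  local *minimum* of τ and a meeting of two same-side strands a local
  *maximum*);
* dissociation: τ(x) = last bound frame (a dissociation initiation point is
  a local minimum / domain edge, the vanishing point of a shrinking domain
  a local maximum).

Displays that plot time downward invert the apparent min/max sense; the
package fixes event semantics by the physics, not by plot orientation.
Positions are 0-based pixels, frames 0-based per acquisition; a concatenated
recording carries the index of the first dissociation frame and one frame
interval per phase (association is often recorded at 10 Hz, dissociation at
1 Hz, so event times in seconds always use the per-phase interval).

## Boundary detection

Each threshold level is binarised and cleaned: 2-D median filter
(`median_window`, default 3×3 in (position, frame)), then morphological
erosion, hole in-fill and re-dilation with a user-defined structuring
element (default disk of radius 2; radius 0 disables the step). τ(x) is read
off the cleaned mask per position. Undefined values are NaN, never sentinel
numbers. The cleanup order (median first, then erode/fill/dilate) is
configurable in code but fixed in this package as stated.

Two caveats drove the defaults used in the tests:

* Opening with a disk rounds wedge apices, biasing extremum *times* by up
  to the element radius. For data with flip probabilities far below 1 per
  pixel (noise sd ≤ ~1/5 of the level step) the median filter alone is the
  appropriate cleanup, and the event-recovery studies use radius 0.
* On noiseless data all cleanup is disabled (window (1,1), radius 0), which
  makes detection exact: τ equals the first threshold crossing.

Thresholds are explicit in every run for reproducibility; `auto_thresholds`
provides 3-class Otsu starting values only (a two-level kymograph yields a
degenerate high cut, flagged with a warning).

### Double-step cross-validation

Independently of thresholding, each pixel's intensity profile is fitted with
two step transitions of identical magnitude, f(t) = b + m[t≥t₁] + m[t≥t₂]
(m subtracted for dissociation). The search over integer pairs t₁ ≤ t₂ is
exhaustive and vectorised; for each pair, b and m have closed-form
least-squares solutions, so the global optimum is exact, O(T²) per pixel.
Ties are broken toward the smallest t₁ then t₂ (a constant profile returns
m = 0 with t₁ = t₂ = 0). On noiseless three-level kymographs the fitted
(t₁, t₂) coincide exactly with the thresholded (τ₁, τ₂) wherever both levels
occur — the package's oracle-equivalence test. Region statistics
(`region_stats`) recompute the two step magnitudes *without* the equality
constraint; their percent difference |s₁−s₂|/mean(s₁,s₂)·100 is the natural
check that the two levels really are two equal quanta of one fluorophore
layer.

## Editing and crossings

Manual curation is replaced by a scripted API: cut a segment at a vertex,
join two segment ends (within a tolerance, default 5 px/frames), delete,
assign a side label (A/B), and mask a position range containing fixed
fluorescent debris (horizontal lines in the kymograph). Every operation is
appended to an edit log; replaying the log on the raw detection reproduces
the edited state exactly, which makes curation auditable. Candidate
crossings — strands elongating past each other on opposite filament sides —
are proposed automatically where a local maximum of τ₁ coincides with a
local minimum of τ₂ (within 2 px / 3 frames by default), ranked by gradient
continuity: a genuine crossing continues with a similar slope on both sides
of the point.

## Events

Extrema are detected per segment after a moving-median smoothing (window 3
positions) with prominence ≥ 2 frames and separation ≥ 2 px by default
(3/3 in the recovery studies); the reported vertex is the raw extremum
nearest the smoothed peak. Nucleations of the second groove inside an
already-bound region appear on the *inner* boundary, so both levels are
searched; inner minima and outer maxima explained by a crossing candidate
are excluded. Terminal vertices are not nucleation candidates (a strand
present from frame 0 is flagged left-censored instead); segment ends are
DIP candidates during dissociation, and a domain still bound in the last
recorded frame yields no DEP (right-censoring). A meeting point is
annotated as unresolvable at optical scale: two strands meet either in
register or leaving a 1–6-monomer gap (≤ ~16.5 nm at 2.75 nm monomer rise),
far below a 92 nm pixel.

## Rates

A rate is the least-squares slope of boundary position versus time between
a nucleation and its neighbouring stop points (nearest meeting in either
direction, else the segment end), one record per growth direction, weighted
by the position extent of the fitted span. Signs follow the position axis;
a user-declared polarity flag (which kymograph end is barbed) maps them to
toward-barbed / toward-pointed — polarity is metadata because inferring it
requires the actin channel, outside this package's scope. The weighted
average uses extent weights (long, well-constrained spans dominate);
uniform weighting is available. Concentration dependence uses the exact
through-origin form slope = Σcᵢrᵢ/Σcᵢ², with an optional low-concentration
exclusion window for flow systems where the feed concentration lags the
channel concentration. Accurate per-side rates on kymographs with crossings
require side-assigned (edited) segments; on raw two-level detections a
meeting of the first-bound side is located through the inner boundary,
which bounds the fitted span but can still mix sides near crossings.

## Minimum measurable rate

Pixelation and the PSF impose a floor on measurable boundary speeds.
Movies of a 1-pixel-wide filament elongating at known rates A (length
accumulated as a real number, rendered by rounding; one end tethered) are
blurred with a Gaussian PSF (σ = 2.5 px) and degraded with camera noise,
then pushed through the same kymograph → boundary → segment-fit pipeline
as experimental data. The measured rate M of a movie is the mean |LS slope|
of the detected tip trace over sliding windows spanning k frame intervals
(k = 1…10; sliding windows keep the estimator unbiased when pixel-advance
events are periodic). The first/last few frames of the trace are dropped
because the median filter and morphology see past the recording ends there.
The cutoff model

    M = R_cutoff + (A − R_cutoff) · H(A − R_cutoff)

is fitted by exact piecewise least squares: within a fixed membership split
the optimal R is the mean of the below-cutoff M values, so enumerating
splits of the A-sorted pairs finds the global optimum deterministically.

Because the effective noise amplitude of a camera/label combination is not
known a priori, the calibration is run over a grid of read-noise levels
(2–30% of the blurred single-filament peak). At the reference level of 5%,
40 log-spaced rates in [10⁻⁴, 0.1] px/frame and 400-frame movies give a
pooled R_cutoff ≈ 1.1–1.5×10⁻² px/frame.

**Known limitation.** With temporally uncorrelated (white) camera noise the
detected edge flickers in short pulses, and the per-window |slope| floor
scales roughly like k⁻⁰·⁸ across segment lengths k = 1…10, so the
*per-segment-length* cutoff estimates spread by far more than the pooled
value. A segment-length-independent floor requires edge excursions whose
dwell time exceeds the longest fit window (≫10 frames), i.e. temporally
correlated disturbances (slow drift, breathing of the illumination or
focus) that this generator deliberately does not include. The acceptance
suite therefore reports the pooled cutoff and its per-segment-length
spread, and the spread check is expected to fail under white noise — a
property of the noise model, not of the fitting code, whose noiseless
recovery is within 2–4% at every k.

## Nucleation kinetics

The at-risk set for nucleation at frame i is the available sites: filament
pixels neither occupied nor adjacent (±1 pixel) to an occupied pixel —
neighbours are elongation, not nucleation, sites. With dᵢ nucleations *at*
frame i, the survival estimator S(t) = Π_{i<t}(1 − dᵢ/nᵢ) steps down at
event frames and is right-censored at the recording end; it estimates the
probability that a given available site has not yet nucleated. S is fitted
by exp(−t/t_nuc) by deterministic 1-D least squares on the step values at
the step times (left-edge convention; bounded search on log t_nuc seeded by
a log-linear regression). A curve with no events raises an error carrying
the identifiable lower bound rather than a number. Estimators from
filaments recorded under the same conditions are pooled by summing dᵢ and
nᵢ per frame, which requires the full per-frame at-risk series to be kept
on every curve. When side labels exist, availability is computed per side
and the two curves pooled; otherwise the merged occupancy is used — the
conservative choice, since merged occupancy under-counts the true per-side
at-risk set and both-side events then inflate the apparent hazard.

## Registration

Association and dissociation stacks are aligned on one frame pair (by
default the last association and first dissociation frame — the two most
similar states), assuming no distortion: rotation about the image centre
plus translation, minimising the mean-squared intensity difference (both
frames image the same labelled species, so a same-modality metric is
appropriate). The optimiser is a regular-step gradient descent written for
exact contract control: central-difference gradient, unit-normalised
descent direction, step halved on gradient-direction reversal or on a
failed trial, only improving steps accepted (so the accepted-metric
sequence is non-increasing by construction), stopping at min_step (10⁻⁴ px)
or the iteration cap. A 3-level coarse-to-fine pyramid extends the capture
range to at least ±10 px and ±5°; recovery on noiseless synthetic frames is
better than 0.02 px and 0.01°. If no step improves on the identity, the
identity is returned with a warning. Resampling is bilinear with a declared
fill value; integer translations reproduce array shifts exactly, and the
identity transform is returned bit-identical without resampling.

## Synthetic data: what it emulates, and what it does not

The lattice generator reproduces the statistical structure the analysis
relies on: Bernoulli nucleation per available site per frame on two
independent sides, bidirectional elongation at a configurable rate
(fractional advance, rendered by rounding — the same pixelation convention
as the movies), meeting when same-side strands become adjacent, stochastic
end-retraction during dissociation, three exact intensity levels plus
optional position-axis blur and Gaussian noise, and complete ground truth
(occupancy, τ curves, all event types). Defaults describe a realistic
acquisition: 92 nm pixels, 1 Hz, level step 10 arbitrary units over
background 5, noise sd = level step/10 for "moderate noise" studies.

Not emulated: curved or fluctuating filaments, photobleaching, two-colour
channels, diffusing or transiently binding molecules, intra-phase drift,
and temporally correlated noise. Passing tests therefore demonstrate the
correctness and calibration of the *algorithms* under the stated
conditions, not robustness to every experimental pathology; boundaries on
real data remain parallel to (not identical with) the true molecular edge
because of the PSF.

## Numerical and interface decisions

* Undefined τ is NaN throughout; serialisations (JSON/CSV) use null/empty.
* The double-step search covers t ∈ {0,…,T−1} for both transitions; a pair
  with zero regressor variance falls back to m = 0, b = mean.
* `fit_cutoff` prefers membership-consistent splits (A_{s−1} < R ≤ A_s) and
  raises when the optimum sits outside the sampled rate range
  (unidentifiable plateau).
* Event times are reported in frames internally and converted with the
  per-phase interval at the interface; positions optionally in nm.
* All stochastic components draw from one seeded generator per simulation;
  identical configuration + seed reproduces outputs bit-for-bit, and the
  pipeline writes a manifest (config hash, seed, stage counts) sufficient
  to regenerate every file byte-identically.
* Images are stored as multi-page TIFF with YAML sidecars for physical
  metadata; metadata is never defaulted silently — a stack without pixel
  size or frame interval is an error.
* Test problem sizes (400-frame movies, 40-rate calibration grids,
  100-filament recovery studies) were chosen so the full suite runs in
  about half a minute while keeping every estimate's sampling error well
  inside the asserted tolerances.
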