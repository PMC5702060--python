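# Methods

`puffmapper` detects Ca²⁺ puffs — transient, µm-scale Ca²⁺ release events
produced by small clusters of IP₃ receptors — in TIRF-microscopy image
stacks, assigns them to immobile release sites, and extrapolates the total
number of sites per cell from short stimulations that each reveal only a
fraction of them. This note documents the signal model, the detection and
clustering rules, the estimators, the synthetic-data generator used for
validation, and the numerical choices made where the design was open.

## Detection model

The detector assumes a puff rises to its peak within one inter-frame
interval (40 ms at 25 Hz) and decays over a few hundred milliseconds, so
puffs appear as large positive excursions in the frame-to-frame difference
of the normalised fluorescence. The preprocessing chain per cell:

1. **Background correction.** For every frame, the mean intensity over an
   extracellular rectangular ROI is subtracted from every pixel. Small
   negative values are permitted.
2. **Masking.** Extracellular pixels are set to zero; each cell is
   processed independently. In-mask pixels whose baseline F₀ works out
   non-positive (possible after background subtraction) are removed from
   the effective mask with a warning rather than failing the cell.
3. **Smoothing.** A 2×2 box mean, applied per frame only, aids candidate
   seeding. A true 2×2 window has no centre; the output is anchored at the
   window's top-left pixel with replicate padding at the bottom/right
   edges. Only candidate seeding uses the smoothed stack — every
   measurement is made on the unsmoothed data.
4. **Normalisation.** F₀ is the per-pixel mean of the 50 pre-stimulus
   frames (the stimulus frame index is config-supplied, not inferred);
   F/F₀ is formed inside the mask.
5. **Differencing.** ΔF[n] = F/F₀[n+1] − F/F₀[n]. Difference frame *n*
   therefore carries the rise that occurs at stack frame *n+1*.
6. **Global-rise removal.** ΔΔF subtracts, per frame, the in-mask mean of
   ΔF from every in-mask pixel. This cancels the slowly creeping global
   F/F₀ rise that precedes a regenerative wave; each ΔΔF frame has zero
   in-mask mean by construction. Because a puff occupies a small fraction
   of the cell (~0.2%), its own contribution to the frame mean attenuates
   its ΔΔF peak by only that fraction.
7. **Thresholds.** Per pixel, the temporal mean µ (≈0) and standard
   deviation of ΔΔF give T1 = µ + 3.4·s.d. and T2 = µ + 2.45·s.d. The
   statistics are computed over difference frames *before* the detected
   wave onset: an explosive wave inflates the s.d. and would suppress
   detection everywhere. (Sample s.d., ddof = 1.)

### Candidate selection

In each difference frame, every in-mask pixel above T1 is a potential puff
centre. Pixels are visited in descending ΔΔF order (ties broken by
(row, col) for reproducibility). Each seed centres a 5×5 matrix in which
pixels above T2 score 1; the matrix is accepted when at least 18 of the 25
score — an empirically conservative criterion that makes false positives
on plain noise essentially impossible (the independent-noise tail
probability per matrix is below 10⁻³⁰, and spatial correlation introduced
by 2×2 smoothing still leaves it negligible). A seed whose matrix would
share any pixel with an already-accepted matrix is skipped, so accepted
footprints are disjoint. Where the matrix is clipped by the image or mask
edge the criterion rescales proportionally, ceil(18/25 × available
pixels), rather than leaving a blind 2-pixel rim. Accepted candidates are
ranked by supra-T2 count, ties by signal mass (the ΣΔΔF of their supra-T2
pixels).

### Boundary expansion

Each candidate's rectangular extent starts as a 3×3 box on the seed and
grows in two passes: first columns (left, then right) while the adjacent
column contains at least one supra-T2 pixel, then rows (up, then down)
while the adjacent row is at least 10% supra-T2; the second pass repeats
the sweep outward (columns then rows), adding lines while the next line is
strictly more than 10% supra-T2. Lines added in pass one are never
removed — the second pass is read as a continuation of outward expansion,
not a filter that could shrink the rectangle. Expansion clips at image
edges. Candidates whose centre already lies inside an expanded rectangle
of the same frame are not expanded again.

### Temporal merging

A puff that stays above threshold for several frames would otherwise be
counted once per frame. Region centroids (ΔΔF-weighted, supra-T2 pixels)
in consecutive difference frames within 0.96 µm of each other are merged
into one event; a single frame below threshold ends the event. The event's
onset is its first frame; its rectangle is that of the member frame with
the greatest candidate signal mass.

### Measurement

All measurements use the unsmoothed stack. Amplitude is the maximum ΔΔF
inside the rectangle across the event's frame span. Signal mass is ΣΔΔF
over rectangle pixels ≥ T2 at the peak frame (the event-level choice;
whether the original summed one frame or the whole event is not
documented). The rectangle at the peak frame is fitted with an elliptical
2D Gaussian plus constant offset (trust-region least squares, moment-based
initialisation); if the optimiser fails, intensity-moment estimates are
used and flagged. Reported radii use the 1/e² convention, radius = 2σ, so
the generator's default σ = 0.55 µm corresponds to a ~1.1 µm radius and
~2.2 µm mean diameter, matching the scale of measured puffs; the ellipse
area is π·r_major·r_minor. Half-maximal duration is measured on the
rectangle-mean F/F₀ trace — ΔΔF is derivative-like and has no meaningful
half-max width — as the linearly interpolated time above half of the peak
excess over a 5-frame local pre-event baseline, never less than one frame
interval.

### Wave-onset detection

Analysis must stop when a regenerative wave floods the cell. Onset is the
first frame at which the cell-mean F/F₀ exceeds the pre-stimulus mean by
max(10 baseline s.d., 0.3) for 5 consecutive frames. The absolute floor
(0.3 F/F₀ units, config `wave_min_rise`) is needed because spatial
averaging makes the baseline s.d. of the mean trace orders of magnitude
smaller than the creeping rise the ΔΔF correction is designed to
tolerate; without it, slow drift would be mistaken for the wave. A wave is
a ≥3 F/F₀ event, so the floor discriminates cleanly. Detections at or
after onset are discarded, and threshold statistics use only pre-wave
difference frames.

## Site mapping

Puff centroids are amalgamated into sites greedily: the unassigned puff of
greatest signal mass (ties: earlier onset, then lexicographic centroid)
seeds a site at its centroid; unassigned puffs within 0.96 µm (6 pixels at
160 nm) are absorbed; the centre is then redefined as the centre of the
region enclosing the member centroids and absorption repeats until stable,
after which the site is frozen. "Centre of the enclosing region" is taken
as the axis-aligned bounding-box midpoint of the member centroids (the
literal reading of a bounding region); the centroid mean is available via
`site_recentre="mean"`. Termination is guaranteed because membership only
grows. Sites with one puff are classed low-activity, several puffs
high-activity.

Site lists from different stimulations are matched greedily by ascending
centre distance within the same 0.96 µm radius, each site used at most
once — deterministic and near-optimal for well-separated sites.

## Site-number estimators

- **Capture–recapture** (default): N̂ = n₂ / f, where n₂ is the number of
  sites seen during the second challenge and f the fraction of those also
  seen during the first. This is the form used for the headline estimate (17/0.26 ≈
  65) and equals the Lincoln–Petersen form n₁n₂/overlap when n₁ ≈ n₂; both
  forms are provided. The per-cell ratio has a positive small-sample bias
  of order 10% when the expected overlap is below ~10 sites (Jensen's
  inequality on 1/overlap); applied to cohort means, as in the source
  analysis, it is essentially unbiased.
- **Zero-truncated Poisson**: per-site puff counts over a window are
  modelled as Poisson(µ) conditioned on ≥1 — a site is only seen if it
  fires. µ̂ solves µ/(1−e^(−µ)) = mean observed count by bracketed root
  finding (Brent, xtol 1e-10; the bracket (0, mean] always contains the
  root when the mean exceeds 1), and N̂ = observed sites / (1 − e^(−µ̂)).
  All-singleton counts put the mean at the truncation boundary, where N is
  unidentifiable; this is an error, not a value.

Quantitative comparisons between stimulations use, by default, the last
2 s (50 frames) before wave onset or stimulus end — matching records whose
usable length is set by the unpredictable wave — with a full-record option
for density and discovery-curve analyses.

## Synthetic movies

The generator emulates the acquisition the detector was designed for:
16-bit single-channel stacks at 40 ms/frame and 160 nm/pixel, a
star-convex cell footprint of a few hundred µm², immobile sites scattered
uniformly on the footprint with a 2 µm minimum spacing, per-site puff
onsets as a homogeneous Poisson process during stimulation, and, per
pixel inside the cell,

    F(t) = F_rest · [ramp(t) + Σ_puffs a · G(x, y; σ) · g(t) + wave(t)]

with G an isotropic Gaussian (σ = 0.55 µm default), g a one-frame rise
(configurable to 2 for robustness tests) followed by exp(−t/τ) decay
(τ = 0.25 s default), ramp a spatially uniform multiplicative drift, and
an optional saturating radial wave front (amplitude 3 F/F₀, 15 µm/s)
after a configurable onset frame. Extracellular pixels hold a lower
resting level (default 100 vs 1000 counts in-cell — background subtraction
and F/F₀ require the two levels to differ). i.i.d. Gaussian noise
(default s.d. 50 counts) is added everywhere. Defaults for puff amplitude
(1.0 ± 0.3 ΔF/F₀, floored at 0.3) sit in the range typically measured for puffs and give in-window SNR ≈ 14 at the default noise.

What the generator does **not** emulate: Poisson shot noise and camera
gain structure (additive Gaussian noise was chosen for analytic
tractability), photobleaching, dye saturation and buffering kinetics,
axial structure of the ~62 nm evanescent field, cell motion, and
anisotropic or site-specific puff shapes (a per-puff σ is the only shape
knob). Passing the recovery tests therefore demonstrates correctness of
the algorithmic chain under the stated signal model, not performance on
every real-world artefact.

## Problem sizes used in the validation suite

The end-to-end recovery experiment simulates 20 cells (176×176 pixels,
300 frames, 65 planted sites, two challenges each) with per-site firing at
0.155 s⁻¹, chosen so that a 2-s analysis window detects ~17 sites per
challenge with ~26% overlap — the regime of the experiment the estimator
is taken from. At that regime the cohort estimate has an intrinsic
standard deviation of ~7 sites, so recovery is
asserted within 15%. False-positive suppression runs twenty 512×512×250
pure-noise movies at the default noise level; detection uses float32
derived stacks for these large inputs (float64 elsewhere).

## Known limitations

- The second expansion pass never shrinks the rectangle; if the original
  intended a filter, rectangles here are conservative supersets.
- Signal mass is summed at the peak frame only.
- The greedy site amalgamation is order-dependent by design (mass
  ranking); it reproduces the documented procedure rather than optimising
  any clustering objective, and chains of puffs spaced just under the
  merge radius can bridge nearby sites.
- The capture–recapture estimator assumes equal, independent per-site
  detection probability across challenges; heterogeneous firing rates
  bias it downward (eager sites dominate both samples).
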