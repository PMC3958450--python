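# Methods

This note documents the models, estimators, parameter choices, and numerical
decisions behind `odyn`, and what the synthetic benchmarks do and do not
demonstrate about real microscopy.

## Imaging model and calibration

All analyses operate on a single selected plane of a calibrated time series
(`Movie`: T×Y×X intensities, µm/pixel, s/frame). Defaults mirror the
emulated acquisition: 0.09 µm/pixel, 109 s/frame, 8-bit intensities,
≥8 frames (≈16 min). Where a z-stack exists, the analysis plane is chosen
once per series by maximizing the variance of the Laplacian (a standard
autofocus score), replacing visual selection for reproducibility; an
explicit index override is available. Rectangular ROIs are configured in
a YAML file — 0-based, (row, column), half-open — mirroring the practice of
selecting a few perinuclear regions by hand; there is no interactive UI.

## Segmentation

Two routes, selected by `segmentation.mode`, reflect two very different
morphologies; attempts to unify them are known to fail, so none is made.

**MidGrey + medial axis** (fragmented morphologies). A pixel is foreground
iff its intensity strictly exceeds `(local_min + local_max)/2 − offset`,
extrema over a disk of radius 15 px, reflect padding. Ties go to background,
making constant images empty. The textbook rule marks ~half of all pixels in
object-free noise (the local mid-grey sits at the noise median), so the
pipeline adds a contrast guard: neighbourhoods with `max − min <
min_contrast` (default 40 of 255) are background. Components smaller than
`min_area_px` (default 9 px ≈ a 3×3 speck, below the optical resolution at
0.09 µm/px) are removed. The medial-axis transform produces the skeleton;
note that scikit-image's `medial_axis` breaks thinning ties randomly, so it
is called with a fixed seed to keep identical masks giving identical
skeletons.

**Hessian ridge tracing** (tubular networks). The frame is normalized to
[0, 1] and filtered with the Sato tubeness operator at the tubule scale
(default σ = 1.5 px ≈ half the tubule FWHM); the response is thresholded at
an absolute 0.08, cleaned, and skeletonized. Unlike the semi-automatic
tracing it replaces, no user seed points exist; endpoint placement is
validated only against synthetic ground truth.

**Skeleton to centerline.** Skeleton spurs shorter than 4 px are pruned
(repeatedly, endpoint→junction walks). Each component is reduced to its
longest geodesic path (double-sweep Dijkstra over the 8-connected pixel
graph with axial/diagonal weights 1/√2 — exact on trees, which pruned
tubule skeletons are). Branched objects therefore contribute their
longest path, treating tubule-like objects as paths.

**Length measurement.** The contractual operator `measure_length` sums pixel
steps (1 axial, √2 diagonal) × pixel size; a single pixel has length 0 and
the measure is invariant under path reversal and axis-aligned rotation.

The *pipeline's* per-object length adds three refinements, all motivated by
one fact: the dynamic-range statistic compares lengths *across frames*, and
a raw pixel skeleton quantizes each endpoint to the grid, which on a 20–30 px
fragment injects ±1–2 px of frame-to-frame jitter — comparable to the whole
true signal at 15% dynamic range.

1. *Path smoothing.* Coordinates are moving-average smoothed (window 5)
   before integration, removing the staircase overestimate of 8-connected
   chains (angle-dependent, up to ~8%). The smoothed endpoints sit a
   fraction of a pixel inside the discrete tips but move continuously as the
   object translates.
2. *Sub-pixel tip completion.* From each smoothed endpoint the intensity is
   sampled (cubic interpolation) along the outward tangent after re-centring
   the origin on the ridge (intensity-weighted centroid across the tube);
   the tip is where the profile crosses half-maximum, the local maximum
   being a median over a short on-path stretch rather than one noisy pixel.
   Subtracting the perpendicular half-maximum half-width converts the
   tip-to-tip measure into an axis length.
3. *Cap-retreat correction.* Under a Gaussian PSF the half-maximum level set
   of a convex cap retreats inward by ≈ σ²κ/2 (level-set motion under
   Gaussian smoothing; κ ≈ 1/half-width at the cap). σ is estimated from
   the measured edge slope at the crossing. Because tubule diameter and PSF
   are uniform within a cell, both the half-width and this correction are
   pooled (median) over all objects in a frame, which removes most of their
   estimation variance.

With these, noise-free synthetic benchmarks recover object counts exactly
and individual lengths to within ~5% (test contract: 10%), and the residual
per-frame length noise is ~0.2 px — low enough that a 15% length oscillation
on 2-µm fragments is recovered as 15–17%.

## Tracking

Centerline centroids (unweighted pixel means) are linked frame to frame by
optimal bipartite assignment (Hungarian) on squared displacement, with
matches beyond `max_disp_px` forbidden and unmatched objects carrying the
conventional `max_disp_px²` penalty — equivalent to the Crocker–Grier
minimization at these instance sizes, and verified in tests against
exhaustive enumeration. Tracks stay open for `memory_frames` missed frames
(gap closing), then close; new objects start new tracks; every record
belongs to exactly one track. Exact cost ties break toward the lowest
previous-object index via an infinitesimal (1e-9) perturbation of the
non-match cost. The defaults `max_disp_px = 20` (≈1.8 µm/frame) and
`memory_frames = 2` are declared, not inferred — the original description
gives only qualitative guidance ("maximum distance … adjusted accordingly",
reappearance "after being lost in few time steps") — and both are config
keys. Tracks shorter than 3 records are excluded from dynamics summaries
(and counted), not deleted.

## Dynamics statistics

Per track: mean length; dynamic range `100·(max−min)/mean` of the length
series; net displacement (first→last centroid); path length (summed steps);
directionality = confinement ratio net/path ∈ [0, 1]. The published gloss of
the dynamic-range statistic ("varied from half the average size to twice as
long" ↔ "100%") is not internally consistent with any single ratio, so the
(max−min)/mean definition is fixed here and the synthetic presets express
their truth in the same statistic, making recovery well-posed. The
directionality formula is likewise unstated in the source; the confinement
ratio is the most common single-number choice for organelle motion. A
strictly stationary track gets directionality 0 by convention. Condition
summaries use median and IQR — robust to heterogeneous track lengths.

## Synthetic movies

Objects are smooth planar curves (AR(1) curvature, bending radius ≥ ~50 px)
placed without overlap (bounded retries, failure reported), rasterized at
0.09 µm/px with 4× supersampled coverage (so sub-pixel tip positions appear
as partial-coverage shading rather than whole-pixel jumps), dilated to a
0.30 µm tubule, blurred with a σ = 0.12 µm Gaussian PSF (≈ the diffraction
limit of the emulated 63×/1.4 NA acquisition), scaled onto a background of
16 with signal 170, noised (additive Gaussian σ = 3 counts by default;
optional Poisson), and clipped to 8 bits.

Lengths: each object draws a base (time-averaged) length uniformly from the
preset band — 5.5–9.5 µm for `control_mito`, 1.4–2.75 µm for `mutant_mito`
— and oscillates as a random-phase sinusoid over the series, centred and
rescaled so the *sampled* series realizes `(max−min)/mean` exactly equal to
the preset amplitude (1.0 control, 0.15 mutant). The waveform is not
contractual; only the amplitude statistic is. Growth and shrinkage happen
symmetrically about the curve midpoint, and the whole object additionally
random-walks by 0.08 (control) / 0.03 (mutant) µm/frame. Note a geometric
consequence: with amplitude 1.0 the *instantaneous* control lengths
necessarily leave the 5–10 µm band (a series whose range equals its mean
cannot fit inside it); the band constrains the time-averaged size, and for
the mutant (amplitude 0.15) instantaneous lengths do stay within 1–3 µm.
Fission is modelled as an optional split event (rate per object per frame;
both shipped presets use 0, since the source counts no events); fusion of
distinct objects is not simulated.

What the generator does *not* emulate: out-of-focus light and z-drift,
intensity heterogeneity along a tubule, object crossings and true network
topology (objects are placed disjoint), photobleaching over the series, and
camera gain structure. Passing recovery tests therefore demonstrates the
correctness and stability of the measurement chain under realistic geometry,
sampling, and noise — not robustness to every artefact of real microscopy.

## FRAP

Curves are ROI mean intensities versus time (2-min sampling in the emulated
protocol). The bleach is the largest single-step drop, required to exceed
50% of the running prebleach mean. Percent recovery at time t is
`100·(F(t) − F0)/(F_pre − F0)` with `F_pre` the prebleach mean and `F0` the
single bleach-index sample — fixed, not fitted, because the protocol empties
the region — using linear interpolation between samples (15 min falls
between the 14- and 16-min scans; the chord-vs-curve gap is < 0.1 point at
these curvatures). The fit estimates `F∞` and `τ` by least squares over the
post-bleach samples with deterministic initialization (`F∞` ← last sample,
`τ` ← half the post-bleach span); the mobile fraction is reported clipped to
[0, 1] with the raw value retained. No acquisition-photobleaching or
reference-ROI normalization is applied by default (the emulated protocol
used low-intensity monitoring and applied none). Synthetic presets:
`control_frap` (Mf 0.95, τ 300 s) and `mutant_frap` (Mf 0.55, τ 360 s),
sampled every 120 s for 30 min with three prebleach samples, 90% bleach
depth, and 2% multiplicative Gaussian noise — the true recoveries at 15 min
are 90.3% and 50.5%. Estimator calibration (tested): bias < 0.02 and SD
< 0.05 over 50 noisy replicates at Mf ∈ {0.5, 0.9}.

## Puncta

Spots are detected by multi-scale LoG (σ ∈ [1, 3] px, 5 scales). The
response threshold is *absolute* in the intensity units of the input
(default 10 counts for 8-bit-like data, roughly a tenth of the faintest spot
of interest): normalizing a field to its own min/max would stretch the noise
floor of a spot-free image into detections. Detected blobs must additionally
exceed `median + k·MAD` of the image (default k = 3) — the robust analogue
of "larger and brighter than background". Spots are assigned to the labelled
cell containing their centre; background spots are discarded but counted.
Positivity is `count > 5`, exactly; the autophagy index is the mean count
per cell; condition contrasts are index ratios. Cell segmentation is out of
scope — labels come from the generator or an external source, as the original
counting was manual. Synthetic fields place cells as disjoint disks
(radius 20 px) on a jittered grid; spot counts are drawn from a configurable
distribution (e.g. Poisson(4) vs Poisson(10) with 200 cells per condition,
matching the emulated experiment's scale); spots keep ≥ 4σ mutual separation
where packable, relaxing gradually to 3σ for rare dense cells, so detection
recovers per-cell counts exactly for ≥ 98% of cells at the default SNR.

## Problem sizes and determinism

Shipped movie presets use 512×512 frames with 6 (control) / 14 (mutant)
objects and 8 frames — a field comparable to one cell's perinuclear region;
benchmark movies in the test suite use 256–384 px variants of the same
presets to keep the suite fast. A full mito pipeline run takes ~5–15 s per
movie on one CPU; the acceptance script (two movies, six extra frames, 40
FRAP series, two 200-cell fields) completes in well under a minute. Every
stochastic step takes an explicit seed, and identical configuration + seed
reproduces bit-identical outputs (the one upstream source of hidden
randomness, `medial_axis` tie-breaking, is pinned).

## Known limitations

- The two segmentation modes must be chosen by the user per condition; no
  automatic morphology classifier is provided (deliberately, matching the
  two-method design).
- Dynamic-range recovery carries a small positive bias (~1 point at the
  15% level) from residual per-frame measurement noise entering a max−min
  statistic; it is characterized by the amplitude-recovery tests.
- The tracker links objects; it does not build fission/fusion lineages, so
  split events appear as new tracks.
- FRAP analysis assumes a single-exponential recovery and does not convert
  τ into a diffusion coefficient.
- 3-D (volumetric) segmentation is out of scope; analysis is on one plane.
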