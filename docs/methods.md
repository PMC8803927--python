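# Methods

This note documents the models, algorithms and numerical choices behind
`qpicell`, in the spirit of a methods section: what is computed, under
which assumptions, and where the open design decisions were made.

## Imaging model

The forward model is a double-beam interference microscope with an
incoherent (LED) source at λ = 530 nm. A cell introduces an optical path
difference

    OPD(x, y) = α · σ(x, y) + B(x, y) + c_t,

where σ is the dry-mass surface density (pg µm⁻²), α the average specific
refractive increment of cellular dry matter (default 0.18 µm³ pg⁻¹ — the
standard literature value; biomolecular α values cluster tightly enough
that the conversion is nearly substance-independent), B a smooth static
instrument aberration (modelled as a degree-2 polynomial in normalized
field coordinates), and c_t a per-frame global offset from reference-arm
drift. Four interferograms are acquired per time point with reference
phase steps δ_k:

    I_k = A + B_f · cos(2π·OPD/λ + δ_k) + ε,   ε ~ N(0, s²).

**Step schedule.** The two-difference arctangent
φ = atan2(I₃ − I₁, I₀ − I₂) is closed-form exact only for quarter-wave
steps δ_k = k·π/2. The generator and the reconstructor therefore use the
quarter-wave schedule by default; the schedule is an explicit parameter of
both, and a non-quarter-wave schedule is rejected with an error rather
than silently mis-reconstructed (generalized-step algorithms such as
Carré's are out of scope). A common offset δ₀ is allowed and removed.

**Unwrapping.** Thick cells exceed λ/2 of OPD and wrap. Sensor noise
flips pixels near the wrap contour across the branch cut, which derails
path-following unwrappers, so the reliability-guided unwrap (scikit-image)
is run on a complex-smoothed copy of the field (Gaussian σ = 1.5 px on
e^{iφ}) to obtain an integer wrap-count map, which is then applied to the
raw phase. Raw pixel values are preserved exactly (mod 2π). Fields whose
wrapped range is below π are passed through unchanged.

**Zero-modulation pixels** (both image differences ≈ 0) carry no phase
information; they are filled by nearest-neighbour interpolation, flagged,
and counted in the log.

## Background reconstruction

Cells occupy a given pixel only transiently, so a pixel's most frequent
OPD value over time estimates the cell-free background there.

1. *Frame fluctuations*: each frame's provisional background (its lowest
   50% of values — cells only add OPD) is histogrammed with bins anchored
   at the frame median; the modal value (mean of samples within one bin
   width of the fullest bin) is subtracted. Median-anchored bins make the
   estimate identical across frames that differ only by a shift,
   avoiding half-bin quantization jumps between frames.
2. *Temporal mode*: per pixel, histogram bins of width 4× the robust
   noise SD (1.4826·MAD of frame differences / √2) are scanned; a bin
   holding ≥ f_min = 25% of the frames is *dominant*, and the
   lowest-valued dominant bin is taken as background (again refined by
   the mean of samples within one bin width). Choosing the lowest rather
   than the fullest dominant bin makes the estimate robust to cells that
   hover over a pixel for most of the movie with stable elevated values.
   Pixels with no dominant bin — covered by cells throughout — are
   flagged for inpainting.
3. *Smoothness screening*: the aberration surface is smooth by
   assumption, so surviving pixels deviating from their 7×7 local median
   by more than 4 bin widths are treated as contaminated and added to
   the inpainting mask.
4. *Inpainting*: gap pixels receive w·L + (1 − w)·G, where L is the
   harmonic (Laplace) extension of the gap-boundary values (sparse
   direct solve), G a global degree-2 polynomial fitted to trusted
   pixels, and w = exp(−d/d₀) with d the distance to the gap boundary
   and d₀ = 20 px. Near the boundary the fill follows local values;
   deep inside it relaxes to the global trend. Any degree ≤ 1 background
   is reproduced exactly by both components; a gap touching all four
   borders falls back to the polynomial alone.

After subtraction, the cell-free background is clean enough to threshold
at 1% of the maximum cell signal.

## Segmentation and tracking

The mask is `gaussian(σ=1 px)(image) > 0.01 · max`, 8-connected
components ≥ 20 µm². All statistics are computed on *raw* values inside
the mask: object mass is the signed sum (preserving the physically
meaningful negative values in the thinnest periphery), centroids are
weighted by the positive part of the signal — signed weights could place
a centroid outside the object, violating the containment invariant.
Touching cells form clusters and are tracked as single objects; there is
no splitting logic.

Tracking links each object to the nearest object of similar mass in the
next frame: candidate pairs are sorted by centroid distance and accepted
greedily when the distance is ≤ 30 µm per elapsed frame and the relative
mass difference ≤ 35%. Unmatched objects seed new tracks; tracks
unmatched for more than 2 frames close. When two tracks converge on one
object the heavier keeps it and the lighter closes with a logged merge
event. The greedy-with-gate rule is deliberate (it is the stated
tracking principle of this instrument class); a brute-force optimal
assignment is used in the tests as an independent oracle, not in the
implementation.

## Metrics

* **Growth**: OLS on ln(mass) vs time (h); Td = ln 2/slope, with slope
  standard error and r². Non-positive masses are excluded; < 3 points
  yields no fit; negative slopes report shrinkage.
* **Speed**: step speed = centroid displacement × 60/Δt_min (so 1 µm per
  5-min step is exactly 12 µm h⁻¹); gap-spanning steps are excluded.
  Summaries report both the pooled-step mean (SEM over steps) and the
  per-cell mean (SEM over cells), since the two weightings differ.
* **Protrusion/retraction**: P = mask_{t+1} \ mask_t, R = mask_t \
  mask_{t+1}. Protrusion mass integrates the *new* frame's density over
  P, retraction mass the *old* frame's over R; both divide by Δt_min to
  give per-minute rates. The pixel identity area(t) + |P| − |R| =
  area(t+1) holds exactly by construction and is asserted in the tests.
  Dynamic polarity is the distance between the P and R centroids — area
  (unweighted) centroids by default, with mass-weighted variants behind
  a flag, since the choice is not dictated by the measurement principle.
  The per-pixel protrusion maximum is reported in femtograms.

## Directional statistics

A trajectory's direction is defined at the first crossing of a 70 µm
horizon from its start, with linear interpolation inside the crossing
step; cells never reaching the horizon are excluded (chemotaxis is
undefined for non-motile cells). The Rayleigh test uses R̄ = |Σe^{iθ}|/n,
Z = nR̄², and the standard series approximation for p (clipped to (0, 1];
accurate over the n = 10–200 range used here). The 95% CI of the mean
direction uses the von Mises circular standard error 1/√(nR̄κ̂) with the
standard piecewise approximation for κ̂(R̄).

Population contrasts use a two-level nested ANOVA for unbalanced data:
the response is each cell's mean step-displacement component along the
gradient (the cell, nested in its movie, is the sampling unit), and the
population mean square is tested against the between-movie
within-population mean square. A population with a single movie is
rejected — that error stratum would be undefined. In balanced designs
this F is identical to a one-way ANOVA on movie means, which the tests
use as an independent oracle.

The in-vivo incidence comparison is a Pearson χ² on the 2×2 table,
χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)), df = 1, with Yates correction
available behind a flag (off by default, matching the uncorrected
convention for these sample sizes).

## Invasion assay

Holes in the red monolayer are pixels whose (Gaussian-smoothed) red
signal falls below 50% of the median-smoothed first-frame baseline, as
connected components ≥ 50 µm²; optional per-frame renormalization to the
baseline median absorbs global photobleaching. Pre-existing near-zero
baseline regions cannot "open" and are excluded from scoring. Green
cells are segmented with a stack-global Otsu threshold and tracked with
the same linker, the integrated fluorescence standing in for mass. A
cell invades when, at any frame, holes cover ≥ 30% of its footprint —
partial overlap suffices because the hole opens *under* the cell. The
invading fraction is computed over tracked cells with ≥ 3 time points;
with no such cell it is NaN (flagged), never 0. Treatments are compared
on movie-level fractions (the movie is the experimental unit), with a
one-way ANOVA against the reference group. The 50% and 30% thresholds
are explicit configuration; the defaults are validated against scripted
synthetic movies where ground truth is known exactly.

## Synthetic-data generator: what it does and does not emulate

The generator reproduces the statistical structure the pipeline relies
on: positive compact dry-mass objects, exponential growth (mass schedule
m₀·2^{tΔt/Td}, exact by renormalization), persistent random-walk motion
(heading increments of variance 2Δt/P give directional autocorrelation
e^{−t/P}; every step has length v·Δt exactly), chemotactic drift as a
biased mixture of steps, a smooth low-order background, frame-offset
jitter, sinusoidal fringe formation and additive Gaussian sensor noise.
Defaults mirror the instrument setting: 634 × 483 µm field, 530 nm,
10-min QPI lapse, 15-min invasion lapse, 1308 µm invasion camera field.

Cell blobs are Gaussians truncated at 2.5σ and renormalized so the
integral equals the scheduled mass exactly. The tight truncation models
the compact edge of an adherent cell: the rim density is ~4% of the
peak, so the entire object lies above a 1%-of-peak segmentation contour
and mass-conservation checks are meaningful to sub-percent accuracy. (At
a 4σ truncation ~2% of a Gaussian's mass would sit below any such
contour — a property of the Gaussian tail, not of the measurement
chain.) Invasion scenes place green cells with a minimum 60 µm
separation so each is individually trackable, matching the subconfluent
seeding of the assay.

Not emulated: diffraction and the instrument PSF, shot noise and camera
gain, halo/shade-off effects, coherence gating, cell division, shape
changes beyond rigid translation of the blob, and cell–cell repulsion.
Passing tests therefore demonstrate correctness of the *computational*
chain under the stated statistical structure, not robustness to every
optical artifact of real data.

## Problem sizes and numerical notes

The reference test scene is 512 × 390 px × 30 frames with three cells —
large enough to exercise wrapping, background inpainting and tracking,
small enough that the full pipeline runs in seconds. The Rayleigh
calibration uses 10,000 uniform samples of n = 60; the invasion power
analysis mirrors the published design (17 movies per arm, ~90 cells per
movie, true fractions 0.21 vs 0.03) over 200 replicates at the
statistics level. All randomness flows from explicit integer seeds;
identical spec + seed yields bit-identical synthetic data, and pipeline
re-runs write byte-identical CSVs.

Known limitations: clusters are not split, so masses of touching cells
pool; the temporal-mode background requires cells to vacate most pixels
for at least a quarter of the frames (a nearly confluent, static movie
degrades to the inpainting path); doubling-time estimates from a few
hours of growth carry the expected large relative uncertainty; and the
nested ANOVA treats movies as exchangeable random draws within a
population.
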