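# Methods

`patchquant` measures how fast fission-yeast cells assemble endocytic actin
patches, in absolute molecule numbers, from confocal time-lapse movies of a
GFP-tagged patch marker (e.g. fimbrin).  This note records the models, the
defaults and why, the numerical choices, and what the synthetic-data tests
do and do not demonstrate.

## Image model and correction chain

A raw acquisition is a `(T, Z, Y, X)` stack: movies default to six
Z-sections 0.6 µm apart at 1-s intervals for 60 s; calibration images are
single-time-point stacks of 21 Z-sections.  All quantitative measurements
are made on Z-sum projections, which keep intensity proportional to total
fluorophore content.

**Flat-field / dark correction.** Each frame becomes
`(raw − dark) / normalized_flat`, where the flat is dark-subtracted and
scaled to peak 1, and the output is clipped below at zero.  Calibration
measurements instead correct the Z-sum projection once (with `n_z · dark`)
and skip the clip: clipping puts a half-normal pedestal on near-zero
pixels, which inflates dim strains' totals (per-section clipping acts
inside weakly expressing cells, projection-level clipping on the halo band
around every cell) and measurably bends the calibration line.  Without the
clip the measured response is linear in the true copy number to within
noise across 1e3–1e5 molecules per cell.

**Illumination model and crop.** The flat is summarized by a least-squares
axis-aligned elliptical 2-D Gaussian with offset (a rotation angle would be
unidentifiable at the instrument's near-isotropic, low-contrast falloff).
Poorly illuminated regions are removed by keeping the largest axis-aligned
rectangle in which the peak-normalized Gaussian stays above a configurable
fraction (default 0.5).  The rectangle — rather than an arbitrary mask —
keeps downstream arrays dense; it is found exactly with the
maximal-rectangle algorithm (per-row column heights + monotonic stack,
O(Y·X)), which the tests verify against exhaustive enumeration.

## Photobleaching correction

The brightness histogram of the first corrected, cropped projection frame
(Freedman–Diaconis bins) contains a background and an intracellular pixel
population, both roughly normal.  A two-term Gaussian is fitted to the full
histogram by least squares with Poisson (√count) weights; without the
weights the fit collapses onto the sharp background spike that zero-clipping
produces.  A one-term Gaussian fitted to the bins at or below the histogram
mode identifies which component is background.  Fits whose components are
closer than a quarter of the pooled SD, or where either component carries
under 2 % of the pixel mass, are rejected as a single population.

The segmentation threshold is the lowest bin edge at which, under the
fitted mixture, at least 95 % of the pixels at or above it are predicted
intracellular (cumulative purity from the weighted Gaussian survival
functions — monotone in the threshold and hence uniquely defined; a
pointwise per-bin reading would not be).  A frozen mask keeps pixels that
exceed the threshold in at least 8 of the first 10 frames.

The per-frame median brightness of the masked pixels is fitted with
`A (a1 e^{-k1 t} + a2 e^{-k2 t})`, unweighted least squares, no additive
offset (an offset trades off against k2 ≈ 0).  Initialization is
deterministic: a log-linear fit to the second half of the trace seeds the
slow constant, the log-linear fit of the positive early residual seeds the
fast one.  If the two-term fit does not improve the residual RMS of a
single exponential by at least 1 %, the single exponential is kept.  The
decay is normalized to 1 at t = 0 (`a1 + a2 = 1`, constants ordered
`k1 ≥ k2 ≥ 0`) and every frame is divided by its value — a per-frame scalar
division, so within-frame intensity ratios are untouched.

Known bias: the median of the masked pixels tracks the true decay exactly
for a symmetric brightness distribution, but the blurred cell boundary
skews the intracellular distribution, and the signal-dependent shot-noise
width then shifts the median by up to ~2–3 % over a movie.  The fitted rate
constants are still recovered within 10 % (median) at default noise, and the
residual trend after correction stays below 0.1 %/min.

## Calibration: fluorescence → molecules

Strains expressing GFP-tagged proteins at copy numbers known from
quantitative immunoblotting are imaged identically.  Cells are segmented on
the projection by Otsu threshold → hole filling → watershed on a smoothed
distance transform with h-maxima markers (the smoothing and the h-maxima,
h = 2 px, prevent a rod-shaped cell's flat distance ridge from being split
into fragments); regions outside 500–5,000 px or touching the border are
discarded.  Footprints are expanded 4 px into the background
(`expand_labels`, never into a neighbour) before integrating — the PSF
pushes ~9 % of a cell's light past the threshold boundary, and without the
expansion that loss propagates directly into the slope.  The modal pixel
value of the non-cell region times the footprint area is subtracted, then
the nonfluorescent strain's mean corrects for autofluorescence (negative
results clip to zero and are flagged).

The curve regresses per-strain mean intensity on known molecules — one
point per strain, not pooled single cells — by ordinary least squares with
a free intercept; conversion of a query intensity subtracts the intercept
and divides by the slope.  A through-origin variant is available since
autofluorescence is already subtracted.  Patch intensities, which are
locally background-subtracted, are converted with the slope alone.

## Tracking and screening

Patches are detected per frame as local maxima of the scale-normalized
Laplacian-of-Gaussian response (σ = 1.5 px).  Detection runs on the
temporal-median-subtracted projection: after bleach correction the cell
background is static, so subtracting the per-pixel temporal median removes
cytoplasm and cell-edge structure and leaves only transient objects — this
is what keeps the accepted-track false-positive count at zero.  The default
prominence threshold is 12 robust (MAD) SDs of the response — deliberately
wide because shot noise makes the in-cell response variance several times
the frame-wide MAD, so a narrower margin admits in-cell noise maxima, while
real patches clear 12 MAD from a few percent of peak.  Intensity is
integrated in a disk of radius 3σ (divided by the enclosed-energy fraction
`1 − e^{-k²/2}` ≈ 0.989 so totals are unbiased), against a per-track
background map: the per-pixel median of the frames when that track is
inactive.  This avoids both the bias of a constant annulus background near
cell boundaries and the pollution of a global temporal median by the patch
itself; annulus photometry remains the fallback for tracks active most of
the movie.

Detections are linked greedily to the nearest active track end (≤ 3 px per
elapsed frame, gaps of ≤ 1 frame bridged by linear interpolation and
flagged); patch density in these movies is low enough that optimal
assignment would change nothing, and the linker is isolated so it could be
swapped.  Screening automates the rejection rules that are applied manually
in practice: a track starting on frame 0 above 25 % of its own peak
(assembly start missed), ending on the last frame above 25 % of peak
(disassembly end missed), approaching another track within 5 px
(overlapping patches), or shorter than 5 frames (not a real event) is
rejected, with the reason recorded.  All fractions and radii are
configurable.

## Temporal super-resolution realignment

Individual events start at arbitrary sub-frame phases, so frame-indexed
averaging blurs the mean time course.  Each track gets a continuous time
offset, estimated by alternating minimization: offsets initialize at the
track's peak sample; the reference is the offset-corrected mean on a 0.1-s
grid (linear interpolation — at 1-s sampling, higher orders risk ringing at
the peak); each offset is then re-fitted by minimizing the mean squared
difference to the reference over a bounded search (coarse scan ± two frame
intervals, then bounded scalar minimization), iterating until the largest
offset change is below 0.01 s or 50 iterations (a warning carries the last
state; the translation gauge is pinned by fixing the mean offset).  Only
time offsets are fitted — amplitudes are averaged raw.  The mean ± SD is
reported where at least three tracks contribute.

Linear interpolation of a 1-s-sampled triangle cannot reconstruct the
exact tip, so the aligned mean's peak underestimates the true peak by
~2 % at these event shapes; rates, fitted away from the tip, are unaffected.

## Rates

The aligned curve splits at its peak (located on a 3-point moving average)
into assembly and disassembly phases bounded below at 10 % of peak to
exclude baseline noise.  Within each phase a 3.7-s window slides at grid
resolution (38 positions of 0.1 s per window placement); every placement
gets a closed-form running-sum OLS line, and the window with the smallest
RMS residual wins, ties (within numerical tolerance — the closed-form
residual cancels catastrophically on near-perfect fits) going to the
earliest window.  "Most linear = minimum RMS residual" is this package's
operationalization; maximum R² or minimum curvature would be alternatives.
The same window duration serves both phases.  Replicate rates (one per
movie) are summarized as mean ± sample SD.

Growth rates of liquid cultures are the least-squares slope of log2(OD)
versus time over the first eight measurements, i.e. the log phase.

## Synthetic data: what it emulates, and what it does not

The generator renders elliptical cells (default semi-axes 18 × 10 px,
area ≈ 565 px) with uniform cytoplasmic autofluorescence (60 ADU per
Z-summed pixel), boundary blurred by a 1.5-px Gaussian, on a 2-D Gaussian
illumination field whose far corner defaults to 60 % of peak.  Patches are
2-D Gaussian spots (σ = 1.5 px) whose molecule count follows a triangular
profile — linear rise at the assembly rate to the peak, linear fall at the
disassembly rate — matching the linear phases the analysis fits and making
rate recovery exact in the noiseless limit; defaults are 50 molecules/s up
to 500 molecules with disassembly at 40 molecules/s (~22 s lifetime), at
10 ADU per molecule, with a 0.15 px/frame centroid random walk.
Photobleaching multiplies everything fluorescent by a double-exponential
decay (defaults a1 = 0.3, k1 = 0.1 s⁻¹, a2 = 0.7, k2 = 0.005 s⁻¹).  The
camera adds Poisson shot noise (gain 1 ADU/photon), Gaussian read noise
(2 ADU), and a 100 ADU offset, each switchable off.  Absolute ADU scales
are arbitrary — the instrument's gain is not modelled — so only ratios
carry meaning.

Not emulated: real cell shapes and internal structure, 3-D PSFs and
depth-dependent aberration, spatially varying bleaching, patch motility
(internalization movement), crowded fields where patches genuinely overlap,
and bright-field channels.  Passing tests therefore demonstrate that the
algorithms are implemented correctly and are unbiased under this noise
model — not that segmentation or screening thresholds transfer untouched to
real acquisitions, where they are expected to need the exposed knobs.

## Problem sizes

The validation suite runs at desk scale by choice: movies of 192–320 px
fields (20 cells / 20 patches for tracking; 4 cells for bleach recovery,
100 seeds), calibration at 448 px with 7 strains × 50 cells for the slope
and 100 seeds of 8-cell strains for the held-out bias, 12 movies for the
end-to-end rate recovery over assembly rates {25, 50, 100} molecules/s, and
200 seeds for growth rates.  The full-size default (512 px) runs identically,
just longer.

## Known limitations

* The mixture fit needs a visible intracellular mode: nearly empty fields
  (cells under ~10 % of the cropped area) or noiseless images raise
  degenerate-mixture errors rather than guessing.
* Temporal-median background subtraction assumes each patch occupies its
  site for less than half the movie; for short movies or very slow events
  pass `subtract_temporal_median=False` and rely on annulus photometry.
* The aligned mean underestimates sharp peaks by ~2 % (tip interpolation)
  and patch photometry carries a ~1–3 % low bias from the bleach-fit
  residual; both are documented above and bounded by the tests.
* Greedy linking can in principle swap identities in dense fields; the
  screening overlap rule rejects exactly those configurations.
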