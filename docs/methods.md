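# Methods

This note documents the models behind `retquant`, the parameters that
matter (with units and defaults), the numerical conventions, and what the
synthetic generators do and do not emulate.

## Retinal phantom

A phantom is a layered tissue volume on a `fast × slow × depth` grid over
a 1 × 1 mm field of view (default desk-scale grid 256 × 200 × 384 at
1.5 µm/pixel axially; full acquisition-scale 512 × 400 generation is
supported but not the default — runtimes, not fidelity, motivated the
half-scale default). Seven boundary surfaces are built from an ILM depth
(60 µm), a smooth random undulation common to the whole stack (amplitude
6 µm, correlation length ≈ 24 px), an optional planar tilt, and per-layer
thickness fields (means RNFL/GCL 33, IPL 37, INL 27, OPL 12, PRC 103, RPE
11 µm — total ≈ 223 µm, IRL ≈ 97 µm, typical murine values — each with a
2 µm smooth modulation).

Voxel amplitude is `reflectivity(layer) × m(r) × s + ε`, where

* reflectivity follows the usual contrast ordering (plexiform layers and
  RNFL bright, nuclear layers dark, RPE brightest);
* `m(r) = max(1 − a (r/r_corner)², 0.15)` is a radial signal falloff
  (default `a = 0.4`; set to 0 for flat-SNR experiments);
* `s` is multiplicative speckle: unit-mean Rayleigh, mixed with 1 by the
  `speckle_contrast` (1 = fully developed, 0 = noise-free);
* `ε` is additive Rayleigh noise with scale `noise_floor` (default 0.003).

Repeats share one speckle realization except inside vessels, where each
repeat's speckle is mixed with an independent draw at the configured
decorrelation level (0.9). The depolarization channel is 1 inside the
PRC/RPE-to-posterior-RPE band and 0 elsewhere, with a gap inside the ONH
disc (radius 75 µm) — a deliberately binary stand-in for the depolarizing
RPE contrast of polarization-sensitive systems.

Vessels are en-face masks per plexus (SVP in the RNFL/GCL slab, ICP down
to INL/OPL, DCP down to OPL/PRC; vessel voxels occupy the central 60 % of
the slab). Tubes are short random walks of capillary-scale radius
(3.5–8 µm) grown *space-filling*: each new tube starts in the currently
least-vascularised block of an 8 × 8 partition. Real capillary beds are
locally homogeneous — perfusion demands it — and independent uniform
seeding produces clumpy, unrealistic meshes whose density fluctuates by
percentage points between subregions. Tube length shrinks with the
remaining density deficit, so the realized density lands within a small,
grid-size-dependent granularity of the target (well inside the ±0.02
contract, and converging as the grid grows).

What the phantom does **not** emulate: axial point-spread blurring,
speckle spatial correlation, eye motion between B-scans, projection
(tail) artifacts of superficial vessels onto deeper slabs, graded
depolarization, or pathology. Passing tests therefore demonstrate the
correctness of the measurement chain under its stated assumptions, not
robustness to motion or projection artifacts in real data.

## Flattening and segmentation

The RPE depth of every A-scan is the depolarization-weighted centroid
depth, in-painted from nearest valid neighbours where no depolarizing
signal exists (ONH) and smoothed laterally (Gaussian, σ = 2 px). If more
than 30 % of A-scans lack signal the volume is rejected, emulating a
quality exclusion. Each A-scan is shifted by the fractional centroid
offset (linear interpolation) so the RPE sits at a common reference
depth; fractional shifting avoids the one-pixel staircase that integer
shifts would imprint on all later boundary estimates.

Boundaries are axial-gradient extrema of the (σ = 1 px) smoothed,
repeat-averaged intensity inside anatomically ordered search bands:

* the anterior and posterior RPE faces come from the depolarizing band
  directly, with sub-pixel threshold-crossing interpolation (the raw
  first/last above-half-maximum indices are biased by half a pixel);
* the ILM is the strongest positive gradient 140–320 µm above the RPE (a
  total-thickness prior);
* the four interior boundaries are signed gradient extrema within bands
  centered at fixed fractions of the ILM–RPE span (0.156, 0.330, 0.458,
  0.514; signs − − + −, i.e. bright→dark at RNFL/IPL and IPL/INL,
  dark→bright at INL/OPL, bright→dark at OPL/PRC), refined to sub-pixel
  by a parabola through the extremum.

Boundary maps are median-filtered laterally (window 15 px, clamped to the
grid) and projected onto the ordered set (each surface at least 0.5 px
below its predecessor). A gross inversion rate above 20 % before
smoothing raises a segmentation failure naming the offending boundary.
The ONH center is an explicit annotation everywhere; a
depolarization-gap centroid detector exists for convenience but is never
applied silently. The RPE "thickness" reported is the segmented thickness
of the depolarizing band.

Thickness maps follow from surface differences, so TOTAL = IRL + ORL and
the sublayer sums hold exactly by construction. The OPL is counted in the
ORL (with PRC and RPE); the IRL is RNFL/GCL + IPL + INL. Annulus
statistics use physical micrometers with pixel centers at
`index × spacing`, half-open membership `r_in ≤ r < r_out` (defaults
200/600 µm), and quadrants bounded by the two diagonals through the ONH
center with half-open angular intervals; sector names map image-frame
top/right/bottom/left to superior/nasal/inferior/temporal — true
anatomical orientation depends on eye laterality and is not resolved
here.

## OCTA and vessel density

Decorrelation: for each adjacent repeat pair, the Pearson correlation of
the two amplitude profiles in a centered 7-pixel axial window, averaged
over the `R − 1` pairs; the voxel value is `1 − ρ̄` clipped to [0, 1]
per pair (so the R-repeat result is exactly the mean of the pair
results). Static voxels (shared speckle) give ρ ≈ 1 and decorrelation
≈ 0; flow voxels with independent speckle give ρ ≈ 0 and decorrelation
≈ 1. Windowed correlation was chosen over per-voxel amplitude ratios
because the latter saturate near 0.2 for independent Rayleigh amplitudes
and would compress the flow/static contrast.

The noise floor is `mean + 2 SD` of the intensity in the signal-free band
above the shallowest ILM of the flattened volume. Zone SNR uses the
slab-averaged *structural* signal over the noise floor — an SNR of the
flow contrast itself would be self-referential; this is configurable.

Binarization: a pixel is vessel iff its mean structural signal is at
least 10× the noise floor AND it belongs to a vesselness-confirmed flow
region. The flow region is obtained by thresholding the lightly smoothed
(σ = 0.5 px) decorrelation map at Otsu's threshold and keeping only the
connected mass reachable from Frangi-vesselness seeds (scales 1–4 px,
Otsu cutoff on the vesselness histogram) via morphological
reconstruction. A plain vesselness threshold was measured to recover only
about half of the true vessel area on phantoms — ridge detectors are
centerline-weighted — whereas the reconstruction restores the full lumen
width while the vesselness seeding still rejects non-tubular responses.
The smoothing scale was set to null the dilation bias of this pipeline on
phantoms with known density. The 10-pixel border frame is zeroed, a disc
around the ONH is cut out (default radius 100 µm, matching the 200 µm
diameter removed in the thickness analysis; the choice is configurable),
and zones (diagonal quadrants × 100 µm rings, half-open) below the SNR
gate — 20× the floor for SVP and ICP, 15× for DCP — are excluded. Density
is the positive-pixel percentage among analysed pixels of included zones;
counts are unweighted even though pixels are anisotropic. If no zone
passes the gate the measurement is reported missing, not zero.

Resolution caveat: with capillary-scale vessels the binarization is
accurate at the default 256 × 200 sampling (≈ 4 × 5 µm/px) and degrades
on coarser grids where tubes become sub-pixel; density validation is
specified at 256 × 200.

## Morris water maze

Geometry: a 1 m diameter pool, an 8 cm diameter platform at mid-radius of
the NW quadrant (per the start-position schedule; the protocol text and
schedule disagree on the quadrant, and the schedule is followed — the
position is configurable), a 0.10 m wall zone, quadrants bounded by
axis-aligned lines through the pool center with half-open angular
membership, and a target zone equal to the platform footprint.

The swim model advances at 14 Hz. The heading relaxes toward a blend of
(i) drift toward the platform with weight
`w = gain · σ(day · (d₀ + k·ability) + c)` (gain 0.35, d₀ 0.25, k 0.35,
c −1.5 — logistic, increasing in ability × day, and average animals still
improve across training days), (ii) attraction toward the wall
(thigmotaxis weight 0.12), and (iii) the previous heading perturbed by
Gaussian noise (σ = 0.45 rad/frame); speed is Gaussian (0.18 ± 0.04 m/s)
and the position is clipped to the pool with specular reflection.
Floating is injected explicitly as Poisson episodes (0.6/min, 1.5–4 s) at
0.005 m/s, so the floating metric has ground truth. Training trials end
at platform contact (a sample inside the disc, no dwell requirement) or
at the 60 s cap; probe trials last exactly 60 s with the platform absent,
the drift scaled by 0.5 (partial memory expression) and suppressed within
1.5 platform radii until the animal swims 4 radii away — without this
search hysteresis a trained simulated animal parks on the remembered spot
and the crossing count explodes.

Metric conventions: each sample carries the duration to the next sample
(the last carries the mean interval), so irregular frame times are
handled; distance is truncated at the latency on training days
(configurable); floating is time inside maximal episodes with speed below
0.02 m/s sustained ≥ 1 s; thigmotaxis is time with
`r > pool radius − 0.10 m`. These thresholds mirror common tracking
defaults and are configurable.

Chance-level symmetry: with zero memory bias and zero thigmotaxis the
dynamics are rotationally symmetric, so balancing the probe start over
the four quadrants makes every quadrant's expected abidance exactly 25 %;
the validation suites use balanced starts. With the fixed SE probe start
of the schedule, a residual start-quadrant bias of a few percent over
60 s remains — a property of any finite-mixing swim, not a bug.

## Cohort generator

Thickness values follow
`baseline(layer) + group offset + group slope · (week − 12) + b_mouse +
b_eye + ε`, with `b_mouse ~ N(0, 5²)`, `b_eye ~ N(0, 0.8²)`,
`ε ~ N(0, 2²)` (µm), weeks {12, 20, 24, 36}, and 16 animals per
genotype × sex cell (64 total). Dropout removes 16 animals after week 12
and 21 after week 24 (stratified round-robin over the four groups),
leaving 48/48/27 — the published attrition pattern. Negative generated
values are clipped and counted.

The latent memory ability is `ρ · z + √(1 − ρ²) · η`, where `z` is the
animal's final-week, eye-averaged INL deviation standardised by its
*analytic* population SD and `η` is independent standard normal; the
population correlation with final INL therefore equals the configured ρ
exactly (defaults 0.87 for female transgenics, 0.10 male transgenics,
0.25 controls). Ability is defined for all animals, including those that
drop out. A per-animal body weight (sex-dependent mean) accompanies the
table for the weight–retina correlations.

## Statistics

The mixed-intercepts model is fit by REML through `statsmodels`' MixedLM
with a full group × week cell-mean fixed-effect design and a random
intercept per animal; eyes enter as repeated measures within mouse.
Estimated marginal means are then single coefficients and contrasts are
linear forms with t-based p-values on residual degrees of freedom
(`n_obs − n_animals − n_cells + 1`; Satterthwaite approximations are out
of scope). Two degenerate paths exist: data with zero within-cell
variance are solved exactly (cell means, zero variances), and
single-timepoint data — where the random intercept is unidentifiable —
raise an error unless `allow_degenerate=True`, which fits OLS with zero
random-intercept variance; in the balanced two-group case its contrast
reproduces the pooled t-test exactly. Week is categorical by default. No
multiplicity correction is applied anywhere (exploratory stance);
Benjamini–Hochberg is available but off.

Probe-day tests use pooled-variance unpaired t-tests (Welch behind a
flag), one-sample t-tests against the chance constants (25 % abidance,
1.5 crossings), and Cohen's *d* with (n−1)-weighted pooled SD.
Correlations report Pearson r with the two-sided t-based p (n − 2 df)
plus slope, intercept, R² = r² and MSE (1/n normalisation) from the least
squares line on the same pairs; eyes are averaged per mouse first, and
groups smaller than three mice are skipped with a reason.

Analytic power uses the plain Fisher z approximation,
`power = Φ(|atanh ρ|√(n−3) − z₁₋α/₂) + Φ(−|atanh ρ|√(n−3) − z₁₋α/₂)`.
This is the standard textbook formula (and the one consistent with a
power of 0.85 at ρ = 0.87, n = 8); it omits the `ρ/(2(n−1))` mean bias of
`atanh r`, so at moderate n it understates the exact test's power by
roughly 0.01 (e.g. ≈ 0.814 analytic vs ≈ 0.828 simulated at ρ = 0.5,
n = 30). Power is α at ρ = 0 and strictly increasing in |ρ| and n.

## Problem sizes and determinism

The validation suites use half-scale phantoms (256 × 200 × 224 for
density, 128 × 100 × 256 for thickness), 20 phantom seeds for density
recovery, 1000 balanced probe swims for the chance level, 100 simulated
cohorts of 200 animals for model recovery and 100,000 replicates for the
power Monte Carlo — sizes chosen as the package's own accuracy/runtime
trade-off. All generators take explicit integer seeds and are
bit-reproducible for a fixed seed; `scripts/acceptance.py` derives every
stream from its single `--seed`.

## Known limitations

* No projection-artifact removal between plexuses and no skeleton/length
  density — area density only.
* The binary depolarization band idealises RPE detection; real
  depolarization contrast is graded and noisy.
* Sector naming assumes a fixed image orientation; eye laterality is not
  resolved.
* The swim model is a single-attractor drift-diffusion caricature: no
  strategy switching, no inter-trial learning dynamics beyond the
  day-scaled drift, and its chance-level behaviour is exactly 25 % only
  under start-balanced designs.
* The Fisher z power formula carries the small-n bias noted above.
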