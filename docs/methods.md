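# Methods

This note documents the models, conventions and numerical choices behind
`qwamap`, in the spirit of a package methods appendix: what is computed, under
which assumptions, and what the synthetic validation does and does not show.

## Data model and conventions

A sample is a pair of tables. The per-cell table has one row per detected
xylem element with calendar year, calibrated centroid coordinates (μm), lumen
area (μm²), optional major/minor lumen axes, and the radial distance of the
centroid from the ring boundary (μm and % of ring width). The per-ring table
carries year, ring width and the manually measured analysed area of interest
(AOI). All lengths are μm and areas μm² internally; SI conversion happens only
inside the hydraulic formulas.

Conventions that matter downstream:

- The radial coordinate increases from pith to bark, and radial distance is
  measured from the **pith-side** ring boundary, so position 0 is the start
  of the earlywood and profiles run in growth direction.
- Ring and sector intervals are **half-open** `[start, start + width)`. A
  centroid exactly on a boundary belongs to the later ring/sector. This
  tiles the core without double counting and makes assignment deterministic.
- Radial distance refers to the **centroid**, the same positional quantity
  used for sector membership.
- Ring area is `core width × ring width` with a fixed 5 mm core width, so
  vessel number is not biased by method-dependent AOI extents; VD and RCA
  use the AOI itself.

## Classification and cut-offs

Elements with lumen area strictly above 500 μm² are vessels; at or below,
fibres. The same strict inequality applies to the comparability cut-off
(1000 μm² for diffuse-porous, 5000 μm² for ring-porous wood), which removes
the size range where acquisition methods disagree most about detection. The
no-cut-off, fibres-included variant of the thin section is kept as its own
"method" so the cost of the cut-off can itself be quantified. MLA convergence
analysis scans a cut-off grid and reports the smallest cut-off at which the
per-method mean-ring MLA values agree within a configurable tolerance
(default 5 % maximum pairwise relative difference — an explicit, configurable
criterion).

## Hydraulic quantities

The cell hydraulic diameter is ellipse-aware: with semi-axes a, b it is
`(32 a³ b³ / (a² + b²))^(1/4)` (the capillary with the same laminar
conductance as the elliptical tube), reducing to the circle diameter for
a = b; without axes, the equivalent-circle diameter `2√(A/π)`. The ring-level
`D_h = Σ d⁵ / Σ d⁴` weights each cell by its d⁴ conductance share, so it lies
between the smallest and largest cell diameter and never below the arithmetic
mean.

Sector conductance is Hagen–Poiseuille, `K_H = π Σ d⁴ / (128 η l)`, with
η = 0.001 Pa·s (water at 20 °C) and capillary length l = 1 m, making K_H a
per-metre conductance; any common choice of l cancels from between-method
comparisons. `K_s = K_H / box area` is reported in m² s⁻¹ MPa⁻¹ and is
independent of the sector width. Empty sectors have K_H = K_s = 0 — a
vessel-free sector genuinely conducts nothing — whereas the median lumen area
of an empty sector is *missing*, not zero.

## Sector boxes and density

Rings are tiled with fixed-width sector boxes (default 120 μm, matching the
diameter of larger vessels in diffuse-porous species; 450 μm for ring-porous
wood with its much larger earlywood vessels). The final partial sector is
kept with its true width and box area rather than dropped or padded: dropping
it would systematically discard latewood. Box area uses the tangential core
width (default 5 mm), consistent with the ring-area convention.

Anatomical density is `ρ = ρ_wall × (box − Σ lumen − cracks) / box` with
ρ_wall = 1.504 g cm⁻³ (density of wood cell-wall material). The expression is
evaluated as `ρ_wall × (1 − lumen fraction)` so the zero-lumen limit is
exactly ρ_wall in floating point. ρ is clipped to [0, ρ_wall] with a warning;
a lumen sum exceeding the box area is instead a data error. Crack areas
default to 0 and may be supplied per sector; crack *detection* is out of
scope.

**Fibre correction.** Methods that cannot detect fibres overestimate ρ. The
corrected variant assumes every cell occupies its lumen plus a 4 μm wall band
around the equivalent-circle perimeter (footprint `π (r + t)²`). The box area
left after subtracting detected-cell footprints and cracks is attributed to
undetected fibres of mean footprint, and their lumina (estimated count ×
mean fibre lumen) are added to the lumen accounting. The mean fibre geometry
comes from the ≥10 detected fibres of the same ring when available, else from
the configured `fibre_lumen_area`. This estimator is a deliberately simple,
fully specified area-budget argument: it is exact when the box is tiled by
identical fibres and degrades gracefully with size dispersion; it does not
model cell-type-specific wall thickness or non-circular fibre outlines.

## Synthetic anatomy generator

The generator produces the study conditions for all validation. Ring widths
are Gaussian (floored to keep several sectors per ring); rings are laid end
to end from position 0. Vessel counts are Poisson with mean
`density × ring area`.

- **Diffuse-porous** (three presets: small-vessel ~900 μm² median at
  180 mm⁻², medium ~1600 μm² at 120 mm⁻², semi-diffuse ~1300 μm² at
  140 mm⁻²): log-normal lumen areas with a multiplicative decline of
  expected area toward the latewood (the expected area at the ring end is
  0.35–0.5 × that at the start), giving the right-skewed distribution and
  falling radial profile characteristic of these woods.
- **Ring-porous** (oak-like): a two-component log-normal mixture — large
  earlywood vessels (median 30 000 μm², ≈ 195 μm diameter; mixture weight
  0.12) confined to the first 25 % of the ring, small latewood vessels
  (median 1500 μm²) in the remainder — at 18 mm⁻² total density. The weight
  and density are jointly constrained: the weight must be high enough that
  cells above the latewood 99th percentile are ≥90 % earlywood (bimodality
  that survives observation), while the earlywood lumen fraction must stay
  packable by rejection sampling (≈ 0.27 of the earlywood band here).

Vessel centroids are placed by dart throwing, largest first, with bounded
retries so lumen discs never overlap within a ring; exhausting retries raises
a generation error advising lower density. Vessels carry mildly elliptical
axes (aspect ratio 0.75–1.0) consistent with their area. Fibres are laid on a
jittered square grid — mimicking the quasi-regular packing of fibre tissue —
with spacing chosen so fibre lumina occupy a target fraction (default 0.25)
of the area, thinned where they would overlap vessel lumina; their areas are
log-normal truncated at the vessel threshold. The per-sector fibre lumen sum
is therefore known ground truth for density-correction tests.

**Observation model.** Each simulated acquisition method applies, in order:
a size-dependent miss draw (probability `miss_max · exp(−A/decay)`, largest
for small cells), multiplicative mean-one log-normal measurement noise and an
optional systematic gain, pixel quantisation (floor to a multiple of the
pixel area), and a hard detection limit — physical acquisition first,
software thresholding last. The random stream depends only on the run seed
and the method label, never on the thresholds, so sweeping the detection
limit produces nested subsets of one fixed noisy measurement: detection-limit
monotonicity (VD/VN/RCA never rise, D_h/MLA never fall) then holds exactly,
not just in expectation. The bundled method presets (thin section at
0.44 μm pixels with a 20 μm² floor; micro-CT at 3 μm voxels with a 250 μm²
floor; surface pictures at 4.2 μm pixels with a 450 μm² floor) are
qualitative stand-ins spanning the resolution range of real instruments —
their miss curves are free parameters of the simulation, not calibrated
instrument properties.

**What the synthetic validation does not show.** The generator has no vessel
grouping or tangential banding, no rays, no within-ring density fluctuation
beyond the vessel trend, no tissue deformation, cracks, or segmentation
artefacts other than the parametric miss/noise/quantisation chain, and
cross-ring disc overlap is not prevented at ring boundaries. Passing tests
demonstrate that the *computations* are correct and respond to detection
limits as theory predicts — not that any real instrument pair will show a
particular R² or offset.

## Method comparison

Annual series of each parameter are compared by OLS of the compared method on
the reference (thin section with cut-off), requiring ≥3 shared years. The
offset from the 1:1 line is the mean of per-year relative differences
`100 × mean((cmp − ref)/ref)`, excluding (and counting) zero-reference years;
the mean relative residual from the fitted line is also reported, since
"offset" is used in both senses in the field — the 1:1 version is the
headline field. Significance uses the slope t-test at 0.05 with no
multiple-testing correction. A year-blocked bootstrap (resampling whole
years) provides a CI for the offset.

Radial K_s/ρ profiles are compared on a common 0–100 % relative-position
axis. The smoother is a fully specified substitute for a penalized mixed
additive model: (1) per-year means are subtracted (absorbing the year-level
random intercept) and the method grand mean restored; (2) a cubic B-spline
regression on relative position is fitted per method, with the interior-knot
count (0–8, quantile-placed) chosen by GCV `n·RSS/(n − p)²`; (3) pointwise
95 % bands come from a year-blocked bootstrap (default 500 resamples,
seeded), refitting with the selected knots. With a single year the bands fall
back to the OLS prediction standard error and the fit is flagged
low-confidence. Bands are widened, when necessary, to bracket the point
estimate. Grid positions where a method's band excludes the reference mean
are flagged as significant differences.

## Numerical and degenerate-input choices

- Empty cell sets: ring `D_h` and `MLA` are NaN (undefined, never zero);
  VD = VN = RCA = 0 (genuinely nothing detected).
- `VN` is reported un-rounded (`VD × ring area`): rounding would corrupt the
  regressions.
- Degenerate (zero) ellipse axes fall back to the circle formula.
- The observation-model invariant `min_detectable_area ≥ pixel_area` keeps
  quantisation from silently creating zero-area cells.
- CSV round-trips are exact: floats are written with shortest-round-trip
  representation, and wholly absent optional columns are omitted and re-read
  as absent.
- All stochastic stages (generation, observation, bootstraps) derive from a
  single configured seed; observation streams are salted with a CRC of the
  method label so methods are independent but reproducible.

## Problem sizes

Default presets use 12 rings at realistic densities (≈ 1.5–2.5 × 10⁵ cells
per sample including fibres); the generator is vectorised and builds such a
sample in ~1–2 s. The test suite uses smaller models (4–5 rings, reduced
fibre fill) where full scale adds nothing to the property under test, and
the acceptance script runs both full presets end to end.
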