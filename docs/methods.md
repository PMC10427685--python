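# Methods

`mitomorph` quantifies mitochondrial morphology in transmission electron
micrographs (TEM) and relative gene expression from qPCR plates.  This note
documents the models, the conventions the package fixes where the underlying
protocol leaves them open, the synthetic data the validation rests on, and
the known limitations.

## The segmentation chain

Mitochondria appear in TEM as electron-dense (dark) profiles on a brighter
cytoplasmic background.  The chain runs in a fixed order; every stage is
deterministic and its intermediate output is retrievable:

1. **Inversion.** `out = (2^depth − 1) − in`, so that downstream stages see
   bright particles on a dark background.
2. **Rolling-ball background subtraction** (default radius 60 px).  The
   background is the grayscale opening of the image by a ball-shaped
   structuring element — the surface traced by a ball of that radius rolled
   under the intensity landscape.  It removes slow illumination gradients
   while preserving features narrower than the ball.  *Numerical choice:*
   for radii ≥ 24 px the background is estimated on a bilinearly downscaled
   copy (factor `ceil(radius/15)`) and resized back, then clamped to lie at
   or below the image so the residual is nonnegative.  At the default radius
   this is ~30× faster than the exact full-resolution opening; the
   difference is confined to curvature on the scale of single pixels, far
   below the particle scale.  Small radii run the exact opening.
3. **FFT bandpass** (default pass band: structure sizes 8–60 px).  The
   protocol this follows names only the two size bounds, so the transfer
   function is fixed here and exposed in closed form (`bandpass_gain`) for
   verification: with `s` the characteristic size of a structure (the full
   period of a sinusoid) the amplitude gain is Gaussian in log-size,

       G(s) = 2^−((ln s − ln s0)/w)²,   s0 = √(small·large),
                                        w = ln(large/small)/2,

   which equals exactly 1/2 at both cuts, is maximal at the geometric
   mid-size, and attenuates monotonically outside.  The DC component is
   removed.  The image is reflect-padded by the large cut before the
   transform; without padding, the filter halo of a feature near one border
   wraps around to the opposite border (the image is not periodic), which
   measurably contaminated region-of-interest histograms in validation.
4. **Scan-line stripe suppression** (optional; default vertical, 5%
   tolerance).  Stripes varying along x (vertical lines) concentrate on the
   horizontal frequency axis.  Components whose wave vector lies within
   `tolerance/100 × 90°` of that axis are attenuated by the angular notch
   `1 − 2^−(θ/θ_tol)²`.  The notch applies only at frequencies at or above
   the band's low cut (`s ≤ large`): scan-line stripes are in-band by
   nature, the band term already attenuates the excluded low-frequency
   core, and notching the axis at very low frequency forces every column
   mean to a common value, which erodes the flanks of any large particle
   (measured: best-achievable Jaccard on a clean 30 px-radius disk dropped
   from 0.94 to 0.82 with a full-axis notch).  A pure period-12 px stripe
   pattern is still reduced by ~98.5% in amplitude.
5. **Rescale.** The filtered image is affinely mapped onto the input
   dynamic range (min → 0, max → 2^depth − 1) and quantized; this is the
   representation the threshold stage consumes.
6. **Maximum-entropy (Kapur) threshold.**  The gray level `t` maximizing
   `H_b(t) + H_f(t)`, the Shannon entropies of the normalized histogram
   below and above `t`.  Zero-probability bins contribute zero; class
   validity is decided on integer pixel counts (a floating-point cumulative
   sum can admit a degenerate empty class); ties break toward the lowest
   `t`.  8-bit images use all 256 levels; 16-bit images are binned to 256
   levels and the threshold mapped back to the upper edge of the selected
   bin.  *Scope:* by default the histogram is the whole image; the
   orchestrated analysis restricts it to the analysis-ROI pixels, because
   the ROIs exist precisely to exclude plasma membrane and other
   high-contrast regions whose in-band response otherwise dominates the
   histogram and misplaces the entropy split.  Binarization (`img > t`)
   always covers the full frame.

## Morphometry

ROI polygons (drawn on the unprocessed micrograph) clip the binary mask
using pixel-center, boundary-inclusive point-in-polygon tests.  Connected
components are labeled under 8-connectivity and particles of 600 px or less
are discarded — an exclusive bound: a 600 px particle is dropped, 601 px is
kept.  The floor applies to post-clipping pixel counts.

Per particle, with area `A` in px², perimeter `P` in px:

| parameter    | definition                                   |
|--------------|----------------------------------------------|
| area         | pixel count (optionally nm² via pixel size)  |
| area²        | A²                                           |
| perimeter    | weighted boundary length (below)             |
| major, minor | axes of the ellipse with equal second moments|
| Feret        | maximum caliper diameter                     |
| circularity  | 4πA/P², capped at 1                          |
| roundness    | 4A/(π·major²)                                |
| aspect ratio | major/minor                                  |
| form factor  | P²/(4πA), uncapped                           |

Conventions fixed here (the protocol delegates them to a built-in whose
behavior must be pinned down):

- **Perimeter** is the corner-weighted boundary estimate (straight steps 1,
  diagonal √2, corner transitions (1+√2)/2), computed on the hole-filled
  particle so it measures the outer boundary.  On a digital disk of radius
  30 it reads ~5% above the analytic circumference, which keeps measured
  circularity of a disk at ≈ 0.91.
- **Feret's diameter** is the maximum pairwise distance over convex-hull
  vertices of *pixel centers*; a single-pixel particle has Feret 0.  (Tools
  that use pixel corners report values larger by ~1 px.)
- **Circularity** is capped at 1; the form factor is reported uncapped so
  the identity `FF × (4πA/P²) = 1` holds exactly.
- **Holes** are not filled for the area unless requested
  (`fill_holes=True`); a degenerate (collinear) pixel set has its minor
  axis floored at 1 px and is flagged.

## Group statistics

The statistical unit is the cell: particles are averaged per cell, and
conditions are compared on per-cell means.  Per parameter the battery is:

- **Shapiro–Wilk screen** (scipy's Royston implementation), advisory only —
  a deviation is logged but never switches the test, since the protocol
  names no non-parametric fallback.
- **One-way ANOVA** from the classical between/within decomposition;
  p-values from the F distribution.
- **Dunnett's many-to-one test**, two-sided, comparing each treatment to
  the shared control with `t_i = (ȳ_i − ȳ_0)/√(MSW(1/n_i + 1/n_0))`.
  Adjusted p-values are `P(max_j |T_j| ≥ |t_i|)` under the joint null,
  evaluated by seeded Monte Carlo (default 10⁵ draws; the seed is an API
  parameter and is recorded in output).  The shared control induces
  correlation `ρ_ij = √(n_i n_j/((n_i+n_0)(n_j+n_0)))` (0.5 balanced),
  realized by the factor construction `Z_i = √(1−d_i²)U_i + d_i U_0`,
  `d_i = √(n_i/(n_i+n_0))`.  Null samples are cached per
  (k, df, correlation, draws, seed), so simulation studies pay the sampling
  cost once.  With one treatment the procedure reduces to the pooled
  two-sample t-test (verified to |Δp| < 0.005); the measured family-wise
  error over 1000 null datasets (k = 3, n = 24) is 0.048.
- **Fisher's LSD** (unadjusted pairwise t on the pooled error term) as the
  per-comparison alternative.

Biological replicates are pooled into the per-cell analysis rather than
nested (no mixed-effects layer) — matching the per-cell presentation the
morphometry is designed for.

## qPCR relative expression

Technical triplicates are screened before averaging: if the triplicate's
sample SD exceeds 0.5 cycles, the single replicate whose removal minimizes
the remaining pair's SD is dropped; if the best pair still exceeds the
limit, the whole triplicate is excluded.  This is the most conservative
reading of an "outliers removed" rule that always keeps at least two
replicates.  Reference-gene triplicates pass the same rule.  Every decision
is logged with the computed SDs.

Fold changes assume doubling per cycle: per biological sample,
`ΔCt = mean Ct(target) − mean Ct(reference)`; per condition,
`ΔΔCt = ΔCt − mean ΔCt(control)`; `fold = 2^−ΔΔCt`.  ΔΔCt is computed per
biological replicate and then summarized, so a dispersion (SEM of
per-sample folds) is reported alongside the point estimate.  Amplification
efficiency estimation from standard curves is out of scope.

## Synthetic data and what validation shows

The generator plants non-overlapping ellipses (rejection sampling, 1000
tries) with anti-aliased coverage rasterization, so pixel-counted area
converges to the analytic `πab`.  Ground truth per particle is analytic:
area `πab`, perimeter by Ramanujan's second approximation (relative error
< 10⁻⁶ vs arc-length quadrature for aspect ratios ≤ 10), Feret `2a`,
circularity `4π·area/perimeter²`, roundness `b/a`.

Scene defaults (chosen once, as plausible TEM-like conditions in pixel
units — the source protocol does not state a pixel size, so all geometry is
in px with an optional nm/px scalar): 256×256 8-bit frames; background at
0.78 of dynamic range with a corner-to-corner gradient of 0.08; particle
gray level 0.30; Gaussian noise SD 0.03; vertical stripes of amplitude 0.04
and period 12 px; a dark membrane band (22 px, level 0.08) on ~20% of
frames, excluded by the auto-generated ROI with a 40 px gap so the ROI also
clears the band's filter-scale overshoot halo (~30 px), as a manually drawn
ROI excluding "regions of high contrast" would.  Experiments draw 5
particles per cell with semi-major axes uniform on 22–30 px and shape
ratio b/a on 0.65–0.95; the treated condition scales semi-axes by
√(1 − size_shift) so its expected particle area is (1 − size_shift) of the
control's and even a 30% reduction keeps every particle above the 600 px
floor.  Per-image streams derive from the master seed via spawned seed
sequences; identical seeds give byte-identical rasters.

What passing the synthetic validation shows: the chain recovers planted
geometry (per-particle Jaccard ≥ 0.93, area within ~1.5% on average across
a 25-cell experiment; per-cell mean-area correlation > 0.99) and detects a
planted 30% mean-area reduction at 25 cells/condition in every tested seed
while flagging ~5% under the null.  What it does not show: performance on
real TEM texture (cristae, ribosomes, heterogeneous staining), on touching
or overlapping mitochondria (the generator forbids overlap, matching the
single-particle measurement model), or on membrane geometries other than a
straight band.  The 600 px floor also means heavily shrunken real
mitochondria could be censored in ways the synthetic sizes avoid by
construction.

## Degenerate inputs and tie-breaks

Constant images: no threshold exists (error); rolling-ball output is all
zeros.  Threshold ties break toward the lowest gray level.  Empty ROI sets
are an error ("no ROI" is distinct from "whole image").  Cells with zero
particles are omitted from aggregation.  A triplicate that loses QC is a
flagged state, not an error.  Monte Carlo p-values carry a +1 continuity
guard so they are never exactly zero.
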