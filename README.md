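# mitomorph

Quantitative mitochondrial morphometry for transmission electron microscopy
(TEM), with the statistics and qPCR relative-expression analysis that
typically accompany it.

Mitochondrial stress — for example propionic-acid exposure in neuronal cell
models — remodels mitochondria: they become smaller and rounder as fission,
biogenesis and degradation rebalance.  Detecting that objectively from TEM
requires an automated pipeline rather than visual impression.  `mitomorph`
implements such a pipeline end to end for researchers doing cell-biology
image analysis:

- **Segmentation** of electron-dense mitochondria: intensity inversion,
  rolling-ball background subtraction (radius 60 px), FFT bandpass (8–60 px
  structures) with vertical scan-line stripe suppression (5% directional
  tolerance), maximum-entropy (Kapur) thresholding.
- **Morphometry** inside user-supplied region-of-interest polygons (drawn to
  exclude plasma membrane and other high-contrast regions): particles above
  an exclusive 600 px floor are measured for eight parameters — area, area²,
  perimeter, Feret's diameter, circularity `4πA/P²`, roundness
  `4A/(π·major²)`, aspect ratio, and form factor `FF = P²/(4πA)`.
- **Statistics** on per-cell means (the cell is the statistical unit):
  Shapiro–Wilk screening, one-way ANOVA, Dunnett's many-to-one comparisons
  against the control (seeded Monte Carlo adjustment), optional Fisher's
  LSD.
- **Expression**: 2^−ΔΔCt relative quantification with the triplicate
  SD > 0.5 outlier rule and a full QC audit log.
- **Synthetic validation**: a generator of TEM-like micrographs whose
  planted particles have analytically known morphology, so the whole chain
  is testable against ground truth without any external data.

See `docs/methods.md` for the models, conventions and numerical choices.

## Worked example

Generate a two-condition synthetic experiment (25 cells per condition, a
planted 30% mean-area reduction in the treated group), run the full
segmentation → morphometry → statistics chain, and score it against the
generator's ground truth:

```python
import json
import mitomorph as mm

report = mm.validate_pipeline(seed=42, n_cells=25, size_shift=0.3)
print(json.dumps(report, indent=2))
```

prints

```json
{
  "seed": 42,
  "n_cells": 25,
  "size_shift": 0.3,
  "n_particles_measured": 250,
  "n_particles_matched": 250,
  "mean_abs_area_error": 0.014572464582699552,
  "per_cell_area_correlation": 0.9985495964959206,
  "area_p_adjusted": 9.99990000099999e-06,
  "area_significant": true,
  "pass_area_error": true,
  "pass_correlation": true,
  "detected": true
}
```

Reading: all 250 planted mitochondria were segmented and matched back to
their ground-truth ellipses; measured areas deviate from the analytic areas
by 1.5% on average; per-cell mean areas correlate with truth at r = 0.999;
and Dunnett's test flags the planted area reduction at an adjusted
p ≈ 10⁻⁵ — the treated group is correctly detected as having smaller
mitochondria.

The same stages are scriptable from the shell:

```sh
mitomorph simulate --n-cells 25 --size-shift 0.3 --seed 42 --out exp/
mitomorph segment exp/control_cell000.tif mask.tif
mitomorph measure --roi exp/control_cell000.roi.json --out particles.csv mask.tif
mitomorph stats --control control --out results.csv cells.csv
mitomorph qpcr --reference B2M --control control --out folds.csv cts.csv
mitomorph run-all config.yaml
mitomorph validate --seed 42 --n-cells 25 --size-shift 0.3
```

For qPCR, a triplicate of (20.0, 20.1, 22.0) cycles has SD 1.15 > 0.5, so
the 22.0 replicate is dropped (remaining pair SD 0.07); a target at
ΔΔCt = 2 cycles relative to control reports a fold change of exactly
2⁻² = 0.25.

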