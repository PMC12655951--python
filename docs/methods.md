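# Methods

This note documents the models, algorithms and numerical choices behind
pomoforce: what each pipeline stage assumes, which tunables matter, what the
synthetic-data generator does and does not emulate, and where the design was
genuinely open.

## Units and conventions

Force in N, deformation in mm, pressure in MPa (N/mm² equals MPa exactly,
so no conversion constant appears anywhere). The deformation axis is always
the *contact axis*: samples before the first force ≥ 0.1 N are discarded
and the first retained sample defines δ = 0. All reported features —
including the elastic-fit intercept — refer to this axis. Forces are
clipped at zero from below during preprocessing and never smoothed at I/O
time; smoothing is purely a detection-stage concern, so files remain a
faithful record of the instrument output.

## Curve segmentation

**Rupture (Fb).** The global force maximum; ties break to the first index.
This is deterministic and needs no tunables. A maximum at the very last
sample is flagged (`rupture_at_end`) because the plateau window behind it
is then empty.

**Yield (Fa).** The yield point is defined conceptually (first permanent
subcutaneous failure) but must be operationalized on sampled data. The
detector is two-stage, all thresholds in `FeatureConfig`:

1. *Drop event.* The force is smoothed with a centered 5-sample moving
   average (the only smoothing in the package — short enough not to touch
   the elastic fit). The detector fires at the first index i, before the
   rupture index, where the smoothed force falls by at least
   max(`drop_frac`·F, `drop_min_n`) = max(2 % F, 0.1 N) within the next
   `drop_window_mm` = 0.2 mm (never looking past the rupture index, so the
   rupture drop itself cannot fire it). The yield index is then the raw-force
   argmax between i and the sample achieving the drop: this recovers the
   unsmoothed local peak exactly on clean data and is robust to the early
   firing that smoothing causes.
2. *Residual fallback.* Curves where failure appears only as a slope break
   have no drop. Here the elastic line is fitted first (see below, seeded
   at the max-slope window since the elastic rise is the steepest sustained
   segment before rupture), and the yield is the first index where the raw
   force stays below the fitted line by more than `resid_frac` = 5 % of the
   fitted value over at least `resid_persist_mm` = 0.05 mm. The persistence
   requirement rejects single-sample noise excursions. The incremental scan
   is verified against an exhaustive oracle in the test suite.

If neither stage fires the sample is flagged `yield_not_found` and excluded
from Fa/Pa/Kf statistics only — never dropped wholesale, which preserves
power for the parameters that were measured.

**Elastic fit (Ka, intercept).** Ordinary least squares on a window ending
at the yield index. The window start is found by backward expansion: seed
with the `min_span_mm` = 0.2 mm window ending at the yield, then grow
toward index 0 while two gates hold:

* the window R² stays ≥ `r2_min` = 0.995, and
* the candidate point's prediction residual stays within
  `pred_resid_k` = 3.5 times the current fit RMSE, floored at
  `pred_resid_floor_n` = 1 µN.

The second gate exists because the contact segment is, physically and in
the simulator, *tangent* to the elastic line: its residuals grow only
quadratically away from the junction, so an R² criterion alone absorbs a
large part of the contact arc and biases both coefficients (measurably: on
the noiseless reference curve a pure-R² expansion walks all the way to
index 0 and shifts the slope by ~1.5 N/mm). The predictive gate stops
within one sample of the junction on clean data (coefficients exact to
machine precision) and within ~3.5σ of it under noise. The RMSE floor makes
the gate well-defined on exactly linear data.

**Plateau (Fc).** Arithmetic mean of raw forces at deformations ≥ rupture
deformation + `plateau_offset_mm` = 1.0 mm. Raw samples are used, not
resampled ones; an empty window flags the sample (`plateau_empty`).

**Aggregate curve.** Each curve is linearly interpolated onto the inclusive
grid 0, 0.2, …, 5.0 mm; grid points beyond a curve's own end are excluded
for that curve; mean and sample SD (ddof = 1) are reported per grid point
with the contributing count.

## Morphology

Density is the exact per-fruit ratio m/V; a density column in input files
is advisory only (cross-checked, warned at |Δ| > 0.01 g/cm³) because the
computed ratio is authoritative. Genotype summaries report mean and sample
SD (ddof = 1, the breeding-trial convention); density is summarized as the
mean of per-fruit ratios, consistent with its per-fruit definition — note
mean-of-ratios and ratio-of-means legitimately differ by up to ~0.02 g/cm³
at these dispersions.

## Statistics

Kruskal–Wallis (tie-corrected, χ² approximation, k−1 df) is used instead of
ANOVA because mechanical phenotypes routinely violate normality. Dunn's
post hoc z uses pooled mean ranks with tie correction; raw p-values are
two-sided normal. The adjustment defaults to Holm — safe under any
dependence — with `bonferroni` and `none` available (`none` mirrors
workflows that report unadjusted pairwise p-values). For k = 2 the KW H
equals the squared Dunn z, tie-corrected, an identity the tests exploit.

Correlations are pairwise-complete Pearson (flagged samples contribute
every pair for which both values are finite), masked at p < 0.05;
zero-variance variables yield NaN r and an unset mask rather than an error.

PCA operates on complete cases only, z-scored per variable — i.e. a
correlation-matrix PCA, chosen because the variables span MPa, N/mm, g/cm³
and cm³ and a covariance PCA would be dominated by volume's numeric range.
Components are ordered by explained variance and sign-fixed so each loading
column's largest-magnitude entry is positive (signs are otherwise
arbitrary). In the biplot, loadings are scaled ×5 for readability; scores
never are.

## Synthetic data generator

The generator emulates the phenomenology of apple puncture curves: a short
nonlinear contact arc (flat probe face conforming to curved skin), a linear
elastic rise, a small drop at yield, a recovery rise to the rupture
maximum, a drop to a slowly declining plateau, out to 5 mm. Construction is
piecewise on a uniform grid (step 0.005 mm ≈ one sample per 0.1 s at
0.05 mm/s; configurable) with every breakpoint snapped to a grid node, and
`GroundTruth` records the feature values the emitted samples actually
encode, so noiseless curves round-trip through extraction exactly — the
basis of the round-trip test battery.

Two shape choices are deliberate:

* The curve starts exactly at the contact threshold (0.1 N), mirroring an
  instrument that begins its record at declared contact. This keeps contact
  preprocessing an exact no-op on clean data, so the elastic intercept is a
  well-defined round-trip quantity (a curve starting below threshold would
  re-zero between grid nodes and shift the intercept by up to Ka·step).
* The contact arc is the power law F = th + (F_L − th)(δ/δ0)^n with the
  exponent n = Ka·δ0/(F_L − th) *derived* from slope continuity with the
  elastic line at δ0 — not a free parameter. The tangency makes elastic
  window selection genuinely hard, which is the property worth testing.

Noise is i.i.d. Gaussian on all segments (σ = 0.05 N in the cultivar
presets), negative forces clipped; curves are deterministic given the spec
seed. Autocorrelated crack noise (the jagged plateau of very crisp flesh)
is out of scope for v1.

**Cultivar presets.** The mechanical scale is anchored by two published
cultivar means: Pa = 1.1 MPa (HL648, both years) and 0.7 MPa (B217). The
remaining cultivar means (0.90/1.00/0.85 MPa for B32/B231/B273) and all
dispersion choices are this package's own: Fa ~ Normal with 8 % CV,
Kf ~ Uniform(0.70, 0.95) with Fb = Fa/Kf, Fc = 0.45·Fb ± 10 %, yield
deformation ~ Normal(1.0, 0.08) mm, intercept ~ Normal(−3.0, 0.6) N
(bounded), Ka derived as (Fa − intercept)/δ_yield. Morphology draws volume,
density, height and diameters from published per-cultivar mean/SD normals
(truncated positive) and sets mass = density × volume, so mean mass and
mean density both track their published values; the induced mass SD is
≈ ρ̄·SD(V) rather than the published mass SD — a deliberate trade-off, since
drawing mass independently would inflate the density SD far beyond the
published 0.01–0.02 g/cm³ of the tight cultivars. Mechanics and morphology
are drawn independently within a fruit; the density–Pc correlation seen in
real fruit is therefore *not* emulated, and passing tests say nothing about
it. What the simulation round-trips do establish is that the segmentation,
fit and statistics recover known inputs under realistic noise, curve shape
and group structure.

**Default study design** (18/10/10/9/9 fruits for B32/HL648/B217/B231/B273
in year one, 24 for HL648 in year two; the two HL648 years are kept as
separate groups) matches the sampling the statistical battery is meant for;
with it, KW on Pa rejects in ≥ 95 % of replicate batches at α = 0.05.

## Degenerate inputs and tie-breaks

Rupture ties → first index. All-identical statistical groups → explicit
degenerate-data error (scipy's NaN is converted). Fewer complete rows than
PCA variables → truncation to the data rank with a warning. Zero-count
genotypes → omitted from the study. Curves shorter than 10 samples,
non-monotone grids, or never reaching the contact threshold → hard errors
at I/O time, by contract.

## Known limitations

* The yield detector's thresholds are defaults chosen for 8–60 N apple
  curves; very soft fruit (Fb < 5 N) approaches the absolute drop floor
  (0.1 N) and may need `drop_min_n` lowered.
* Stage 2 reports the first *sustained 5 % shortfall*, which by
  construction lies slightly beyond the true slope break; on drop-free
  curves Fa is therefore a small overestimate with a known sign.
* No viscoelastic or Hertzian material parameters, no FEM, no bruise-volume
  prediction; the parameters are empirical and probe-geometry-specific
  (pressures scale as 1/d², nothing corrects for indenter shape).
* Year effects are handled only by treating the second-year group as a
  separate genotype level, not modelled.
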