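# Methods

## The measurement model

`caripix` analyses sequential before/after-demineralization line scans of
exposed root dentin.  The physical picture is:

- a proton microbeam (spot < 10 µm) steps along a line crossing the dentin
  surface and a 4 µm Cu fiducial foil placed 800 µm inside the outer edge;
- per scan point, the Ca Kα X-ray (PIXE) and F gamma (PIGE) channels record
  counts proportional, to first order, to the local elemental concentration
  times the accumulated beam charge, plus a channel background;
- the Cu Kα channel records the foil: a 4 µm top-hat convolved with the
  Gaussian beam spot;
- the same specimen is re-scanned after acid demineralization; only a rigid
  longitudinal offset separates the two scans' coordinate frames.

The analysis chain is: charge-normalise and calibrate each channel
(linear yield→concentration map fitted on reference materials), locate the
Cu foil in both scans, shift the after profiles by the fiducial difference
onto the before grid, average in 10 µm bins anchored at the Cu reference,
find the 5%/95% lesion boundaries against the intact-dentin Ca mean, and
integrate the four lesion metrics (Ca loss, F uptake before/after, F
penetration before/after, µCT mineral loss).  Cohorts of FCM-treated vs
control specimens are then compared with exact Mann–Whitney U tests and
Spearman rank correlations.

Assumptions: yields are linear in concentration over the dentin range
(no matrix/stopping-power corrections); the inter-scan misalignment is a
pure 1D translation (a single point fiducial cannot constrain more); the
before/after scans sample the same physical line.

## The synthetic cohort

No raw data from sequential PIXE/PIGE caries experiments are deposited, so
the generator produces ground-truth specimens with the statistical
structure the analysis assumes.  Parametric forms were chosen for
closed-form integrals and boundary crossings, not as a mechanistic model of
dentin chemistry:

- **Ca before**: flat at `ca_sound`.
  **Ca after**: 0 for z < `erosion` (receded surface), then
  `ca_surface_after + (ca_sound − ca_surface_after)·σ((z − erosion −
  lesion_mid)/lesion_width)` — a sigmoid recovery to sound dentin.
- **F**: `f_amplitude·exp(−z/λ)` with λ = `f_decay` before and
  `f_decay·f_depth_gain` (default gain 1.8) after demineralization — F
  reaches deeper through the porous demineralized matrix.  Controls have
  `f_amplitude = 0`.
- **Counting model**: Poisson counts with mean
  `(yield·concentration + background)·charge` per point; a documented
  `noise_free` mode returns the means exactly and underpins the round-trip
  tests.
- **µCT**: grey = `gain·density + intercept + N(0, noise_sd)` at 8.1 µm
  steps, where density shares the Ca ground truth (intact dentin ↦
  1100 mg/cm³), so PIXE Ca loss and µCT mineral loss are correlated by
  construction.
- **Cohort**: `n_pairs` teeth (default 9), each contributing one FCM and
  one control specimen.  Both members share a per-tooth lesion-severity
  latent `s ~ N(1, 0.25)` multiplying `lesion_mid`; all other truth
  parameters are drawn independently per specimen.  The FCM member's
  `lesion_mid` is attenuated by `1 − κ·min(f_amplitude/f_ref, 1)`
  (default κ = 0.6) — the simplest mechanism producing the negative
  F-uptake/Ca-loss association that fluoride intervention studies report.
  Every scan carries an independent rigid stage offset ~ N(0, 20 µm) that
  registration must undo.  A single master seed spawns independent
  per-specimen streams.

Default truth distributions (mean, sd): sound-dentin Ca 27 ± 1 wt%
(domain-typical, configurable), surface Ca after 8 ± 2 wt%, lesion midpoint
150 ± 40 µm, sigmoid width 20 ± 5 µm, erosion 20 ± 8 µm, F amplitude
200 ± 60 ppm (FCM), F decay length 50 ± 15 µm.  Beam defaults: 10 µm step
and spot FWHM, yields 400 counts/(wt%·charge) for Ca, 0.5 counts/(ppm·charge)
for F, 5000 counts/charge on the Cu foil, backgrounds of a few counts per
point.  These are generator stand-ins chosen once for realistic count rates
(≈10⁴ Ca counts per point, ≈1–2% relative noise), not estimates of any
instrument.

What the generator does **not** emulate — and therefore what passing tests
cannot show about real data: beam-spot smearing of the Ca/F channels (only
the Cu channel is convolved with the spot), energy-resolved detector
response, matrix effects and secondary fluorescence, specimen curvature or
lateral misalignment between scan lines, and remineralization kinetics.
Tests demonstrate that the analysis recovers the truth *of this model*;
instrument-specific biases need real calibration data.

## Numerical and design choices

- **Calibration** is a least-squares line with intercept; PIGE/PIXE yield is
  first-order proportional to concentration and the five-level apatite
  series supports a line.  A quadratic option exists behind the `degree`
  flag (off by default).  Reference abscissae default to ppm for F and wt%
  for Ca and are unit-configurable.  Apatite F content is computed
  stoichiometrically from Ca₁₀(PO₄)₆(OH)₂₋₂ₓF₂ₓ with IUPAC standard atomic
  weights (x = 1 → 3.767 wt% F).  Calibrated concentrations below zero are
  floored at 0 — counts below background cannot mean negative
  concentration.  The floor biases near-zero F upward, which is why control
  F-uptake integrals sit a few thousand ppm·µm above zero rather than at 0.
- **Fiducial localization**: counts-weighted centroid of the contiguous
  supra-threshold cluster around the global Cu maximum, threshold at
  background + 3√background (Poisson reasoning), background estimated by
  the channel median.  The centroid gives sub-step precision; ties between
  disjoint clusters resolve to the cluster holding the global maximum, with
  a warning.  Because the threshold is a 3σ rule, isolated background
  points occasionally exceed it; the resulting warnings are expected and
  harmless.
- **Registration** is translation-only; after profiles are linearly
  interpolated onto the before grid and unshared grid ends are flagged
  missing, never extrapolated.
- **Binning**: 10 µm bins anchored at the Cu reference, value = mean of
  covered points, empty bins flagged missing.  Integration is the rectangle
  rule on bins (matching the "average per 10 µm, then integrate" protocol);
  trapezoid is available behind a flag.  The default scan grid starts at a
  half-step (−55 µm) so points sample bin centers, making the rectangle
  rule a midpoint rule on noise-free profiles.
- **Boundaries**: first linear-interpolated upcrossing of 5% (outer) and
  95% (inner) of the intact-dentin Ca mean, scanning inward.  Intact dentin
  is averaged over a 200 µm window adjacent to the Cu reference on the
  sound side.  A profile never below the 95% level is a no-lesion result; a
  profile with no 5% crossing (already above it at the start of coverage)
  takes the start of coverage as its outer surface — this is what makes the
  flat before-profile integrate from the specimen surface, so eroded
  material counts as loss.
- **Integration region** for the losses runs from the *before* profile's
  outermost surface to the Cu reference; F uptake uses the same common
  region by default (`f_region="before_surface"`), while F penetration is
  measured from each profile's own surface.  Negative bin differences are
  kept by default (unbiased under noise); `clamp_nonnegative` is available.
- **F detection limit**: the calibrated equivalent of background +
  3√background counts, with the background estimated from the intact-dentin
  window of the before scan; a fixed `f_lod` can override it.
- **µCT registration**: the simulator has no inter-scan offset argument —
  profiles live in the scanner's reconstruction frame — so the pipeline
  treats before/after µCT profiles as co-registered and anchors the
  integration region 800 µm inside the before profile's 5%-rule surface.  A
  plateau-matching shift search was considered and rejected: the sound
  region is flat, so the objective is degenerate exactly where it would
  have to be evaluated.
- **Two analysis lines** per specimen are averaged into one metric record
  before cohort statistics (the cohort n counts specimens, not lines).
- **Statistics**: two-sided tests throughout (conservative; the directional
  claims do not change the convention).  The Mann–Whitney p is computed by
  full enumeration of all C(n₁+n₂, n₁) labelings whenever both groups have
  ≤ 10 observations — chosen to cover the nine-per-group design exactly —
  with midranks for ties; larger samples use the tie- and
  continuity-corrected normal approximation (scipy).  Spearman's rho is the
  Pearson correlation of midranks with a t-approximate p and an exact
  permutation option for n ≤ 9.  The paired specimen design is analysed
  with an *unpaired* test, mirroring field practice; this is conservative
  when the pairing latent is active.  Consequently the type-I-error
  calibration check runs the generator in its null configuration
  (κ = 0, severity_sd = 0: independent specimens, no group difference),
  where the unpaired test's nominal level is the right target.

## Problem sizes

The test suite and acceptance script use: the default nine-pair cohort for
the worked example and group medians; a 25-pair (50-specimen) cohort for
correlation structure and the estimated-vs-true Ca-loss regression slope;
200 replicate truth-level cohorts for the direction check; 100 scan pairs
for registration recovery; 2000 truth-level null cohorts for the type-I
error rate; and ≥ 200 random instances per brute-force oracle comparison.
Truth-level replicates use the closed-form Ca-loss integral rather than
re-simulating scans, which is exact under the generator and keeps the
replicate loops light.

## Known limitations

- The calibration and LOD logic assume the channel background is stationary
  along the scan; a depth-dependent background would bias F uptake.
- The boundary rule degrades when `ca_surface_after` approaches
  `0.05·ca_sound` from below, where the 5% crossing can jump between the
  erosion edge and the sigmoid ramp.
- Registration precision is set by the Cu peak statistics; at Cu SNR near
  the acceptance threshold (5) the half-step recovery guarantee no longer
  holds.
- The unpaired Mann–Whitney is conservative for the paired design it is
  applied to; a sign-flip or Wilcoxon signed-rank alternative would be more
  powerful but is deliberately out of scope.
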