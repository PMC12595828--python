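# Methods

## The measurement problem

The ependymal glycocalyx (Gcx) is a glycan-rich layer, a few hundred
nanometres to about a micrometre thick, coating the apical surface of the
ependymal cells that line the brain ventricles.  In dual-channel
immunofluorescence it appears as a thin lectin-positive band sitting just
luminal of the cell body, which is delineated by a cytoplasmic marker
(S100β).  Neither channel has a sharp geometric edge at optical resolution:
each boundary appears as a smooth sigmoidal intensity transition.  gcxquant
quantifies the layer by:

1. **Thickness** — along a measurement line drawn perpendicular to the
   surface (lumen → parenchyma), each channel's intensity profile is fitted
   with a smooth model and the boundary is localized at the *inflection
   point of the rising phase*.  The lectin inflection marks the outer Gcx
   boundary; the marker inflection marks the apical membrane.  Their
   distance `T = x_marker − x_lectin` is the Gcx thickness at that site.
2. **Coverage** — the percent of the *analyzable* surface arc length that is
   glycan-positive, where marker-negative gaps at least `min_gap_um` long
   (denudation: the cell layer itself is lost) are excluded from both the
   numerator and the denominator.  Coverage therefore describes Gcx loss on
   morphologically intact ependyma only.
3. **Region metrics** — mean intensity over masks (e.g. a 17-µm
   periventricular band for microglial Iba-1), per-cell positivity rates,
   and connected-component areas (macrophage-like Kolmer cells), used as
   inflammation readouts around the primary measurements.

## Inflection localization

Two interchangeable localizers operate on the same rising-phase window:

* **polynomial8** (routine method): least-squares polynomial of degree 8.
  The fit runs on a scaled abscissa internally (degree-8 Vandermonde systems
  on raw micrometre coordinates are severely ill-conditioned); coefficients
  are reported in original units but evaluation and differentiation use the
  scaled representation.  Inflection candidates are the real roots of the
  second derivative (companion-matrix roots; imaginary parts below 1e−9 are
  treated as real) inside the search window.  Roots with negative third
  derivative — slope maxima, the transition the eye picks on a rising edge —
  are preferred; ties are broken by proximity to the half-maximum upcrossing
  of the fitted curve.  When no slope-maximum root exists (e.g. a cubic-like
  segment whose only inflection is a slope minimum) the localizer falls back
  to any real second-derivative root in the window and records the fallback
  in the diagnostics; only a window with no real root at all is an error.
* **logistic4** (validation method): four-parameter logistic
  `y = A + (B−A)·σ((x−x0)/s)` fitted by nonlinear least squares
  (initialization A = min, B = max, x0 = first half-range upcrossing,
  s = window/10; bounds keep s > 0 and x0 in the window; a few deterministic
  restarts on non-convergence).  The logistic is parameterized in position,
  not log-concentration: the profiles are spatial and the inflection is the
  midpoint x0 itself.

**Rising-phase window.**  The profile is Savitzky–Golay smoothed (cubic,
~1 µm window); the window is the maximal contiguous interval around the
first half-maximum upcrossing where the smoothed derivative exceeds 5% of
its maximum.  On a gentle monotone sigmoid this spans essentially the whole
profile; on a band-shaped lectin profile (rise, plateau, fall) it ends
before the peak, so the decaying flank never contaminates the fit.  The
model is fitted over the window padded by 0.4 µm per side (expanded
minimally when the sample count would fall below the model's requirement).

Both localizers are invariant to affine intensity transforms (`y → αy + β`,
α > 0) and equivariant to position shifts — which is why inflection distance
works as a thickness metric independent of staining brightness and of where
the line starts.  On noise-free synthetic edges both methods recover the
true edge to well under 0.01 µm; their paired differences on noisy
ensembles are centred within ~0.001 µm of zero.

**Method-agreement verdict.**  `validate_method_agreement` summarizes the
paired per-curve inflection differences by paired t and Bland–Altman and
declares the methods *equivalent* iff the 95% CI of the bias lies inside a
declared margin (default 0.1 µm, one pixel).  A plain
"non-significant paired t" rule was rejected deliberately: on noise-free
ensembles the difference SD collapses and a ~0.0004 µm systematic offset
becomes "significant", which is the classic pathology of using a
significance test as an equivalence test.  The CI-within-margin rule is the
standard equivalence criterion and behaves correctly at both extremes.

## Synthetic data model

The generator is the package's ground-truth oracle.  With σ the standard
logistic and distances in µm:

    lectin(x) = baseline + A_L · [σ((x − x_L)/s) − σ((x − x_L − band)/s)]
    marker(x) = baseline + A_M · σ((x − x_L − T)/s)

then Gaussian blur (point-spread σ_psf) and additive Gaussian noise, sampled
every `pixel_size`.  Because the logistic derivative is symmetric about its
midpoint, Gaussian blur leaves each rising-phase inflection exactly at the
recorded edge — the recorded truth stays valid after blurring.  The lectin
channel is a *band* (rise then decay, default width 1.5 µm) rather than a
step because the Gcx is a thin layer; only its rising edge carries the
boundary.

Defaults (chosen once; the acquisition pixel size and sampling interval are
not constrained by the source workflow, so these are package choices):

| parameter | default | rationale |
|---|---|---|
| pixel_size | 0.1 µm | sub-resolves reported thicknesses (~0.37–0.82 µm) at desk scale |
| window_length | 5 µm | both edges plus ≥ 3·s margin |
| edge_width s | 0.1 µm | sharp but optically plausible transition |
| psf_sigma | 0.15 µm | confocal-like lateral blur |
| noise_sd | 0 (5 = "5% of amplitude" in noisy studies) | amplitudes are arbitrary units (default 100) |
| lectin_band_width | 1.5 µm | thin-layer band, wider than any tested T |

Surface scenes render a sinusoidal (or user-supplied) polyline with the
lumen above; every pixel gets a signed distance to the surface
(parenchyma positive) and an arc coordinate via a densely resampled
KD-tree, and the two channels follow the profile model in the normal
direction with the local thickness.  Coverage and denudation are realized
as exact arc-length intervals (the glycan-positive patchwork is drawn in
~20 µm chunks and the last chunk is trimmed so annotated coverage equals the
requested fraction *exactly*); within denudation intervals the marker stays
at baseline.  Default scene: 160×1024 px at 0.25 µm/px (≈ 260 µm of
surface, amplitude 2 µm, period 60 µm) — coverage needs arc length, not
sub-pixel thickness accuracy, so coarser pixels keep scenes fast.

Cohorts are hierarchical: animal means are normal around the group mean with
between-animal SD, site values normal around the animal mean with
within-animal SD.  Group presets carry the published summaries (thickness
young vs aged for LEL/PNA/RCA-I; coverage 77.25 vs 33.06%; the
post-hemorrhage coverage time course sham/day-3/day-7; cytoplasmic PNA
positivity).  The between-animal SD defaults to S.E.M·√n_animals (the
printed dispersion is an animal-level standard error); the within-animal SD
is not derivable from printed summaries and defaults to twice the
between-animal SD, reflecting site-to-site scatter dominating in
16-sites-per-animal designs.  Percent-valued cohorts are clipped to
[0, 100] (a stated generator contract).  The day-1 post-hemorrhage coverage
value is not in the available text, so that preset carries sham/day-3/day-7
only.

What the generator does *not* emulate: cilia and microvilli texture,
Poisson shot noise (additive Gaussian only, configurable), autofluorescence
gradients, sectioning artifacts, or hemorrhage imagery.  Passing tests
therefore demonstrate correctness of the measurement machinery under the
stated optical model, not robustness to every real-tissue artifact.

## Image-level operations

Line profiles are sampled at pixel-size steps with bilinear interpolation,
each sample averaged over `averaging_width` (default 3) parallel samples one
pixel apart — the averaging width of the original workflow is not stated, so
this is a package default.  Background subtraction defaults to a
5th-percentile constant (the estimator used upstream is likewise unstated).
Positivity ties at a threshold count as negative (fixed rule).  Component
labeling uses 8-connectivity with a 4-pixel minimum area.

Coverage thresholds default to a background-referenced rule:
`bg + 0.3·(P95(band) − bg)` with bg the channel's 5th percentile (plus a
tiny epsilon so a signal-free band reads fully negative even without
noise).  Otsu over the band samples is available (`threshold_method="otsu"`)
but is *not* the default because it fails on unimodal band distributions —
on a fully covered surface it splits the positive population in half.
`min_gap_um` defaults to 5 µm (≈ one cell width): shorter marker-negative
runs are treated as intact-but-unstained, not denuded.

Thickness surveys draw `n_sites` (default 16, the published per-animal site
count) seeded-uniform arc positions on intact surface, cast a 5-µm normal
line (2.5 µm each side), and apply the per-site measurement.  Negative T is
flagged (`negative_thickness`), never clamped or dropped — clamping would
bias group means.  Failed fits mark the site failed; QC bookkeeping
guarantees requested = measured + failed.

## Statistics

Summaries are mean ± S.E.M.  Two-group comparisons use the pooled-variance
Student t (Welch via flag); multi-group time courses use one-way ANOVA with
Dunnett's two-sided many-to-one comparisons, delegated to SciPy's
multivariate-t implementation with a recorded seed; adjusted p values are
clipped to be at least the unadjusted p of the same statistic (the
inequality holds exactly; the clip guards against Monte-Carlo integration
error of order 1e−4).  Bland–Altman limits of agreement use the fixed 1.96
multiplier (matching conventional published limits), not the t-quantile
variant.  Pearson p values come from `t = r√((n−2)/(1−r²))`.

Degenerate inputs are handled explicitly: identical constant groups give
t = 0, p = 1; constant groups with unequal means are an error; an all-zero
difference vector gives a degenerate CI.  No multiplicity correction is
applied across lectins when the 21-lectin panel is screened — each lectin is
reported as its own test, matching the upstream analysis.

Note on pseudo-replication: thickness tests pool 16 sites × 3–5 animals as
independent points.  This reproduces the upstream design; a mixed-effects
treatment of the animal/site hierarchy is a possible extension, not
implemented.

## Problem sizes and numerical choices

The test suite and the acceptance script size their simulations for a
single desk CPU: 10 repetitions × 200 edges for method agreement, 10,000
vectorized replicates for the t-test calibration, 1,000 replicates for the
Dunnett familywise-error check, 60 profiles for the thickness correlation,
and 160×1024 px coverage scenes.  All randomness flows from explicit seeds;
identical (spec, seed) inputs reproduce outputs bit-for-bit.

Known limitations: the band-shaped lectin profile induces a small stable
bias in the polynomial localizer (well under a pixel on noise-free data);
strongly curved surfaces compress the normal-coordinate mapping by ~d/R and
bias image-based thickness slightly upward; the inflection-distance metric
itself reads ~20% below direct physical measurements in the source
validation — that offset is a property of the metric, deliberately left
uncalibrated because its dependence on band geometry is unknown.
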