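# Methods

This note documents the models, conventions, and numerical choices behind
isletquant, and what its synthetic-data tests do and do not establish
about real data.

## Morphometry

### Pipeline

A nuclear-stained z-stack is collapsed by maximum-intensity projection,
thresholded into a binary mask, cleaned by a series of erosions and
dilations, and measured per 8-connected particle. The defaults are:

| parameter | default | rationale |
|---|---|---|
| threshold | Otsu | no auto method is canonical for this assay; Otsu is the standard bimodal criterion. A constant image raises and asks for a manual threshold, mirroring the flag-and-review workflow |
| erosions / dilations | 2 / 2, disk radius 1 px | removes specks up to a few pixels without measurably changing a ≥100 µm object (<1 % area change on a 200-px disk) |
| connectivity | 8 | matches common particle-analysis behaviour |
| perimeter | Crofton (4 directions) | asymptotically unbiased for smooth convex shapes, so a digitized circle measures circularity ≈ 1.00. It overestimates circularity for axis-aligned polygons (a square measures ≈ 0.88 instead of π/4 ≈ 0.785); islets are smooth, so the bias does not affect the QC gate in practice |
| QC | 0.5 ≤ C ≤ 1 (inclusive), area fraction < 18 % (strict) | gates are applied per particle; a flagged particle flags its image in the review manifest. Flagged particles are always reported, never dropped |

Circularity is clipped at 1: digitization can push 4πA/P² slightly above
1 for near-circles. When an image contains several accepted particles the
largest is treated as the islet; the rest are reported but excluded from
group summaries.

### Size formulas

Two conventions deserve explanation because the obvious alternatives are
inconsistent with published pseudoislet numbers:

* **Equivalent diameter** is d = 2·√(A/π) — the diameter of the circle
  with the measured area. The alternative 0.5·√(A/π) that sometimes
  appears in methods text gives ≈ 52 µm for a 0.034 mm² pseudoislet,
  inconsistent with the ~200 µm diameters those areas imply; 2·√(A/π)
  gives 208 µm, inside the published 199–211 µm range.
* **Ellipsoid volume** is V = (4/3)·π·a·b² with a and b the **full**
  fitted-ellipse axes. With full axes, a 0.208 mm pseudoislet gives
  V ≈ 0.038 mm³, matching the published ≈ 0.034 mm³ volume means; the
  geometric prolate-spheroid volume with semi-axes is exactly ⅛ of this
  and is exposed via `ellipsoid_volume(..., semi_axes=True)`.

Group summaries report mean, sample SD (n−1), and CV % = 100·SD/mean per
metric; CV is undefined (raises) for n < 2 or non-positive mean.

## Perifusion

Fractions are collected every minute between 49 and 58 min and every
2 min otherwise; timestamps denote collection-end times. The default
schedule is 52 min at 2.8 mmol/L glucose followed by a 16-min
secretagogue ramp. Basal is the mean over all pre-stimulus fractions
(t ≤ 52 min); the post-stimulus return to 2.8 mmol/L is not part of
basal.

* SI₁ = mean secretion over fractions collected in [53, 56] min / basal
  (exactly 4 fractions on the canonical grid); SI₂ = mean over [57, 70]
  min / basal. Window endpoints are inclusive. The second-phase window
  deliberately extends 2 min past the canonical stimulus end (68 min),
  as the protocol defines it.
* The first/second ratio SI₁/SI₂ is computed per donor and then averaged
  within groups; `compare_groups_ratio` expresses group means as a
  percent of a reference group.
* AUC is the trapezoidal integral of the fold-over-basal trace across
  the stimulus window, with **no baseline subtraction** — basal is
  reported alongside so a baseline-subtracted variant is one subtraction
  away. The trace is treated as piecewise linear, making the AUC
  additive over adjacent windows and invariant to interior grid points
  on linear segments. Whether published AUCs are baseline-subtracted is
  not stated anywhere we can check; the unsubtracted convention is the
  reproducible default.
* Normalization: fold-over-basal (divide by basal mean; idempotent) or
  percent-of-total (requires the total insulin content; fractions then
  sum to 100 when the total equals the summed fractions).

## Synthetic data

### Image phantoms

Objects are ellipses with a constant footprint through z and a parabolic
intensity falloff (1.0 at mid-depth, 0.1 at the outermost plane), so the
max projection equals the mid-plane and recovers the footprint exactly.
Debris are 3–5-px specks placed clear of any object at a random z;
Gaussian noise is added last and clipped at 0. Objects may not overlap or
touch the border — either would make per-object ground truth ambiguous —
and ground truth is the analytic ellipse area π·(a/2)·(b/2) and the axes
themselves.

What the phantoms do **not** emulate: optical PSF blur, photobleaching,
intensity inhomogeneity within the islet, touching islets, and
out-of-focus debris. Passing recovery tests therefore shows the
measurement chain is unbiased on well-separated smooth objects, not that
segmentation is robust to real microscopy artifacts.

### Secretion traces

Inside the stimulus window starting at t₀ the noiseless model is

    S(t) = basal · [1 + a1·(1 − e^{−x/τ_r})·e^{−x/τ_d} + a2·σ(x)],  x = t − t₀

with σ ramping linearly 0 → 1 across the window, and S = basal outside.
The transient term is the first phase, the saturating ramp the second;
this is the simplest form able to produce first/second ratios both above
1 (fresh-islet-like) and below 1 (culture-blunted). Fraction values are
the model evaluated at the collection time (not integrated over the
fraction), matching how the analysis treats fractions. Noise is
multiplicative log-normal with unit mean and coefficient of variation
`noise_cv`; no published distributional description of fraction noise
exists, so this is a stand-in, not an estimate of donor variability, and
the default study-level `noise_cv` of 0.1 is a plausible assay-level
figure rather than a fitted one.

Three presets emulate the study arms' glucose responses. Their
first-phase amplitudes were solved (once, analytically, against the
noiseless model on the canonical grid) so the grid first/second ratios
equal the arms' reported means — fresh 2.88, cultured-intact 0.97,
pseudoislet 1.73 — with peak heights of ≈ 6.8×, 2.5×, and 3.6× basal:

| preset | a1 | τ_r (min) | τ_d (min) | a2 |
|---|---|---|---|---|
| fresh | 14.867 | 1.0 | 2.0 | 0.8 |
| cultured | 1.834 | 1.5 | 4.0 | 1.5 |
| pseudoislet | 6.398 | 1.2 | 2.5 | 1.0 |

Ground truth for each simulated trace is the noiseless model averaged
over the **same fractions** the analysis windows select, so zero-noise
closure is exact by construction and is verified to 10⁻⁹. The
independent check integrates the model's differential form (two linear
ODEs whose difference is the transient) with RK4 at 0.01-min steps and
reproduces the ground truth to < 0.5 %. A continuous time-average over
the windows is *not* the reference: the grid is non-uniform (1-min
fractions early in the second-phase window), so fraction means
legitimately differ from continuous means by several percent.

Under 5 % multiplicative fraction noise the ratio estimate
SI₁/SI₂ = mean(4 fractions)/mean(13 fractions) carries a relative SD of
≈ 3 %, so individual traces can deviate beyond 5 %; the recovery
property is therefore stated on the mean absolute relative error over
200 traces (observed ≈ 2.6 %).

### qPCR fixtures

Target Ct = reference Ct + 5 − log₂(fold) + N(0, σ_Ct), with σ_Ct = 0.25
cycles by default and fold the injected group effect. At σ_Ct = 0 the
ΔCt analysis recovers injected folds exactly; with noise, linear-scale
averaging of 2^−ΔCt is slightly upward-biased (log-normal mean), which
is the convention's own property, not an artifact.

## qPCR analysis

Amplification efficiency is assumed exactly 2 (no standard curves are
modelled). Expression is 2^(Ct_ref − Ct_target); group folds divide each
sample's linear expression by the reference group's mean linear
expression, so the reference mean fold is identically 1. Whether
published group means average linear expressions or Ct values is
ambiguous; linear-scale averaging is implemented because "taking the
average of the reference group as 1" operates on expression values.
Multi-reference-gene geometric means are out of scope.

## Statistics

The two-group rule: paired t-test when all values are paired; otherwise
a two-sided F test on the sample variances (larger variance in the
numerator, p doubled and capped at 1 — sidedness is a package choice, as
none is canonical) gates between the pooled Student t-test and Welch's
correction, at α = 0.05 throughout. The gated procedure's empirical
type-I error under equal-variance normals is 0.05 ± 0.01 (10,000
replicates, n = 10 per group, seed-pinned). With equal sample variances
and equal n, Welch's statistic coincides with Student's to rounding
error. Identical paired samples are short-circuited to t = 0, p = 1
rather than the 0/0 the raw formula produces. No multiple-testing
correction is applied anywhere, deliberately — comparisons across many
genes should be interpreted accordingly.

## Problem sizes and determinism

The test suite and the acceptance script use 50 phantoms per noise
condition (512² × 9 stacks, 100–400 µm objects), 200 simulated traces
per noise condition, and 10,000 replicates for the type-I calibration —
sizes at which every Monte-Carlo margin above is stable to reruns. All
randomness flows through `numpy.random.default_rng` seeded from a single
integer; identical seeds reproduce every output byte-for-byte, and the
pipeline records the seed, the thresholds actually used, and the package
version in its JSON summary.

## Known limitations

- No 3-D segmentation or nuclei counting; morphometry is strictly
  projection-based, so the "volume" is an ellipsoid extrapolation from a
  2-D fit.
- The 18 % area gate is applied per particle; the rule's original intent
  (per particle vs per image) is ambiguous, and the flag propagates to
  the image either way.
- Secretion-kinetics deconvolution, ELISA plate parsing, and
  amplification-curve fitting are out of scope.
- The trace noise model and preset amplitudes emulate reported group
  means, not any donor's raw trace; per-donor heterogeneity in kinetics
  (τ values) is not modelled.
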