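# isletquant

Quantitative analysis of human islet and pseudoislet experiments:
spheroid **morphometry** from nuclear-stained fluorescence z-stacks,
**dynamic insulin-secretion metrics** from perifusion fraction series,
**ΔCt relative gene expression**, and the matching **two-group
statistics** — plus a synthetic generator of islet phantoms and biphasic
secretion traces with analytic ground truth, so every stage is testable
without any raw microscope or perifusion data.

Pseudoislets (spheroids re-aggregated from dissociated islet cells) are a
platform for genetic manipulation of primary human islets; assessing them
requires quantifying how uniform their size is and how well they retain
biphasic glucose-stimulated insulin secretion (GSIS). This package
implements those measurements end to end.

## What it computes

**Morphometry** (per nuclear-stained z-stack): maximum-intensity
projection → binary threshold (Otsu, with a manual override) → erosions
and dilations to remove debris → per-particle measurement with a
moment-based ellipse fit → QC gates. For each particle:

- cross-sectional area *A* (mm²) and fitted-ellipse full axes *a*, *b* (mm)
- circularity *C* = 4π·A/P² (accepted range 0.5–1)
- area fraction (particle must be < 18 % of the image; failures are
  flagged for manual review, never dropped)
- ellipsoidal volume *V* = (4/3)·π·a·b² (full-axis convention; see
  `docs/methods.md` for why, and `semi_axes=True` for the geometric
  ⅛-scale variant)
- equivalent-circle diameter *d* = 2·√(A/π) (µm)
- per-group mean, sample SD, and CV % = 100·SD/mean

**Perifusion** (per fraction series on the canonical grid — fractions
every minute during 49–58 min, every 2 min otherwise; 52 min at
2.8 mmol/L glucose then a 16-min secretagogue ramp):

- normalization: fold over mean basal secretion, or percent of total
  insulin content
- stimulation indices SI₁ (mean over 53–56 min / basal) and SI₂
  (mean over 57–70 min / basal)
- first/second-phase ratio SI₁/SI₂ — an index of first-phase prominence
- trapezoidal AUC across the stimulus window (no baseline subtraction)

**qPCR**: relative expression 2^−ΔCt against a reference gene (PPIB),
fold-changes versus a reference group whose mean is taken as 1.

**Statistics**: Student's *t*-test gated by a two-sided *F* test on the
variances (Welch correction when *p*F < 0.05), paired *t* when all values
are paired, and the coefficient of variation.

## Worked example

```python
from isletquant.synthetic import (PhantomObject, PhantomSpec,
                                  generate_phantom_stack, GLUCOSE_PRESETS,
                                  simulate_perifusion_trace)
from isletquant.morphometry import measure_stack, equivalent_diameter, ellipsoid_volume
from isletquant.perifusion import build_sampling_grid, secretion_metrics

# a 300 x 150 um elliptical islet phantom with debris and noise
spec = PhantomSpec(
    objects=(PhantomObject(center_xy=(256.0, 256.0), major_axis_um=300.0,
                           minor_axis_um=150.0, orientation_rad=0.5),),
    n_debris=4, noise_sd=50.0, seed=1,
)
stack, truth = generate_phantom_stack(spec)
particles, mask = measure_stack(stack)
islet = max(particles, key=lambda p: p.area_mm2)
print(f"area      {islet.area_mm2:.4f} mm^2   (truth {truth.areas_mm2[0]:.4f})")
print(f"axes      {islet.major_axis_mm:.3f} x {islet.minor_axis_mm:.3f} mm")
print(f"diameter  {equivalent_diameter(islet.area_mm2):.1f} um")
print(f"volume    {ellipsoid_volume(islet.major_axis_mm, islet.minor_axis_mm):.4f} mm^3")

# a fresh-islet-like biphasic GSIS trace on the canonical fraction grid
grid = build_sampling_grid(70.0)
trace, gt = simulate_perifusion_trace(GLUCOSE_PRESETS["fresh"], grid)
m = secretion_metrics(trace)
print(f"SI1 {m.si_first:.2f}  SI2 {m.si_second:.2f}  "
      f"ratio {m.first_second_ratio:.2f}  AUC {m.auc_ramp:.1f}")
```

Output:

```
area      0.0353 mm^2   (truth 0.0353)
axes      0.300 x 0.150 mm
diameter  212.1 um
volume    0.0283 mm^3
SI1 5.01  SI2 1.74  ratio 2.88  AUC 41.1
```

The segmented area matches the phantom's analytic ellipse area
(π·0.15·0.075 mm²) despite debris and noise — the erosion/dilation
cleanup removes the specks before measurement. The fresh-islet preset
shows the classic biphasic profile: a sharp first phase five-fold over
basal and a lower sustained second phase, giving a first/second ratio of
2.88.

The command line mirrors the library:

```bash
isletquant synth --out fixtures --seed 3          # phantoms + traces + Ct table
isletquant measure-spheroids --input fixtures --out morph
isletquant perifusion-metrics --trace fixtures/trace_fresh_01.csv --out peri
isletquant qpcr-folds --input fixtures/qpcr_ct.csv --out folds.csv
isletquant all --out run --seed 1                 # full pipeline + summary.json
```

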