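# stonewin

Half-value window sizing of dense objects in non-contrast CT: a
reproducible, semi-automated measurement algorithm, a synthetic
stone-phantom simulator, a simulated multi-observer reading study, and
the agreement (LOAM) and outcome-prediction (logistic) statistics used
to compare display window settings.

## Why

Ureteral stone size drives the choice between conservative management
and intervention, but the measured size depends on how the CT image is
displayed. A display window (center WC, width WW) renders attenuation
above WC + WW/2 white and below WC − WW/2 black. The scanner's point
spread blurs a stone's edge into a ramp, so a low white threshold (a
soft-tissue window, WC 50/WW 400) makes the stone *bloom* larger, while
reading near its peak (inside a bone window, WC 300/WW 1120, gray
levels −260 to 860 HU) makes it smaller — and where in that wide ramp a
reader perceives the border varies between readers.

A **half-value window** sets WW = 0 and WC to half the stone-to-
background attenuation difference (background ≈ 0 HU by convention).
For a symmetric point spread, the blurred edge crosses half-amplitude
at the true edge — the FWHM principle — so this binary display removes
the blooming artifact and, because the threshold is computed rather
than perceived, removes most interreader variability. Two variants
differ in the statistic taken from a circular ROI: the **MEAN** of a
circle inside the stone, or the **MAX** of a circle enclosing it; MAX
needs no judgement about the stone border at all and is the candidate
for semi-automated measurement.

This package implements the window algebra and the measurement protocol
(three orthogonal 3 mm reformations, largest Feret diameter retained),
simulates stone phantoms and observer panels around it, and estimates
the limits of agreement with the mean (LOAM) under an additive two-way
random-effects model

    y_ij = mu + a_i + b_j + e_ij,
    LOAM = z * sqrt((1 - 1/m)(sigma_B^2 + sigma_E^2)),

with modified-large-sample confidence intervals, plus logistic
prediction curves P(passage) = expit(b0 + b1 * size) per observer and
window.

## Worked example

```python
import stonewin as sw

# a 6.0 mm, 800 HU stone blurred by a 1.0 mm FWHM point spread
spec = sw.PhantomSpec(semi_axes=(3.0, 3.0, 3.0), center=(7.0, 7.0, 7.0),
                      stone_hu=800.0, psf_fwhm=1.0,
                      voxel_spacing=(0.2, 0.2, 0.2), volume_shape=(71, 71, 71))
vol, truth = sw.render_phantom(spec)          # truth == (6.0, 6.0, 6.0)

m = sw.measure_stone(vol, (35, 35, 35), "half_value_max", slab_thickness=0.2)
print(round(m.largest_diameter, 2))           # 5.82  (half-value: ~true size)

soft = sw.measure_stone(vol, (35, 35, 35), "soft_tissue", slab_thickness=0.2)
print(round(soft.largest_diameter, 2))        # 7.16  (blooming overestimate)
```

The half-value MAX measurement recovers the 6.0 mm sphere to within a
pixel-and-curvature margin (5.82 mm), while the soft-tissue display at
its default perceived edge blooms the same stone to 7.16 mm.

A full simulated reader study (40 stones, five observers with different
perceived-edge habits, four windows):

```python
demo = sw.run_demo(sw.StudyConfig(seed=1, n_stones=40))
for w, r in demo["loam"].items():
    print(f"{w:16s} LOAM ±{r.loam:.2f} mm (95% CI {r.ci_low:.2f}–{r.ci_high:.2f})")
```

```
bone             LOAM ±1.49 mm (95% CI 1.05–3.85)
soft_tissue      LOAM ±0.68 mm (95% CI 0.45–1.82)
half_value_mean  LOAM ±0.27 mm (95% CI 0.24–0.31)
half_value_max   LOAM ±0.16 mm (95% CI 0.14–0.18)
```

The interreader variability shrinks by an order of magnitude from the
bone window to the half-value MAX window: the wide bone ramp amplifies
between-reader differences in perceived edge, while the half-value MAX
threshold is algorithmic. The same tables feed multi-observer
Bland–Altman plot data and per-observer logistic passage curves, whose
90%-probability size read-off shifts left as windows measure smaller.

The same pipeline is available from the shell:

```
stonewin run-demo --seed 1 --out demo/
stonewin agree --table demo/study.csv --out loam.json
stonewin curves --table demo/study.csv --out curves.csv
```

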