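# lenszones

Quantifying ageing of the human crystalline lens from anterior-segment
swept-source OCT volumes.

With age the lens thickens, its anterior surface steepens, and its internal
layers — the optical signal discontinuity (OSD) zones C1α, C1β, C2, C3, C4
and the nucleus of the Oxford nomenclature — change in both thickness and
back-scatter. `lenszones` implements the full computational chain needed to
measure these changes from raster-scanned OCT volumes, together with a
synthetic eye-phantom/cohort generator so the whole chain can be exercised
and validated without patient data:

* **phantom** — parametric six-conicoid eye geometry (cornea, lens capsule,
  nucleo-cortical interfaces) with an equivalent-index double-shell lens
  (indices 1 / 1.3665 / 1.3266 / 1.3749 / 1.3947 / 1.3749 / 1.3270) and
  zone-resolved reflectivities; 49-eye ageing cohorts in which every
  parameter follows a linear age model (e.g. lens thickness +0.023 mm/yr,
  cortex +0.017, C3 +0.0146; anterior lens radius
  `R(age) = −0.053·age + 12.25` mm) with realistic cross-sectional scatter.
* **render** — telecentric forward model: rays refracted at each surface by
  vectorial Snell's law, samples deposited at cumulative *optical* path
  length (Σ nₖ·geometric path), specular interface peaks, unit-mean
  exponential speckle. Default raster 300 × 300 A-scans over 8 × 8 mm²,
  1500 axial samples of 8.9 µm.
* **segmentation** — specular-peak detection of the six interfaces with
  shear-aligned speckle averaging and 2nd-order polynomial surface fits;
  axial motion alignment of B-scans by corneal-peak cross-correlation.
* **refraction** — layer-by-layer ray-tracing correction from optical-path
  to geometric coordinates through the double-shell index chain.
* **biometry** — radii of curvature `R = 1/(2|a|)` within the central
  3.5 mm and central thicknesses along the lens apex axis.
* **densitometry** — axial densitogram in a 66.5 µm-radius cylindrical ROI,
  five-sample smoothing, OSD-zone boundaries at inflection points
  (gradient maxima), per-zone thickness and optical density (×10³ a.u.).
* **stats** — Spearman rank correlations with Benjamini–Hochberg FDR
  control and OLS ageing rates, Mann–Whitney U group comparisons,
  multivariable linear regression with VIF screening and a Breusch–Pagan
  check, two-way-random ICC, the minimum detectable Spearman coefficient at
  a given power, and the objective scatter index (OSI) of a double-pass PSF
  (peripheral 12–20 arcmin over central 1 arcmin intensity).

## Worked example

```python
import lenszones as lz

# a phantom eye at the cohort mean age, imaged end to end
phantom = lz.make_eye_for_age(39.24)
scan = lz.ScanGeometry(n_ascans_x=100, n_ascans_y=100)
volume = lz.render_volume(phantom, scan, speckle=True, seed=7)
result = lz.measure_volume(volume, media=phantom.media)

b = result["biometry"]
print(f"lens  {b.thickness_lens:.3f} mm (truth {phantom.lens_thickness:.3f})")
print(f"R_ant {b.radius_lens_ant:.2f} mm (truth {phantom.surfaces['lens_ant'].radius:.2f})")

# a synthetic ageing cohort and its age-correlation report
table = lz.sample_cohort(seed=1)
report = lz.spearman_with_bh(table)
print(report.table.loc[report.table.variable == "thickness_lens",
                       ["r_s", "p_bh", "rate_per_year"]])
```

prints

```
lens  4.536 mm (truth 4.540)
R_ant 10.81 mm (truth 10.17)
        r_s          p_bh  rate_per_year
0  0.887335  2.362020e-16       0.024613
```

i.e. the imaging chain recovers the 4.54 mm central lens thickness to a few
µm under speckle (single-B-scan radii carry a few percent of speckle
noise), and a single 49-eye cohort shows the strong positive
lens-thickness/age correlation with a fitted rate near the generating
0.023 mm/yr (individual cohorts scatter around it; the median over many
seeds converges to the model value).

There is also a thin CLI (`lenszones simulate|render|measure|stats|all`).

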