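# Methods

This note documents the models, algorithms and numerical choices behind
`lenszones`: what the synthetic data emulate, how each processing stage
works, which parameters matter, and where the design was genuinely open.

## The eye model and the synthetic cohort

The phantom is a six-surface anterior segment: corneal anterior/posterior,
lens anterior/posterior capsule and the anterior/posterior nucleo-cortical
interfaces, each a rotationally symmetric conicoid. Light propagation uses
an equivalent-index double-shell lens: one index for the cortex and one for
the nucleus, in the chain air 1, cornea 1.3665, aqueous 1.3266, cortex
1.3749, nucleus 1.3947, cortex 1.3749, vitreous 1.3270. No gradient index
is modelled — the equivalent-index simplification is part of the method
being implemented, and it is also why the reconstructed posterior lens
curvature is the quantity most sensitive to model error.

**Surfaces default to paraboloids (conic constant −1), not spheres.** The
measurement convention of the field reports the apical radius as
`R = 1/(2a)` of a 2nd-order polynomial fitted over the central 3.5 mm. For
a *sphere* of R ≈ 3.7 mm that estimator carries a deterministic truncation
bias of ≈ (3/14)(h/R)² ≈ 5% (h = 1.75 mm half-chord) — the quartic term of
the circle projects onto the quadratic basis. A paraboloid is exactly the
shape class a 2nd-order polynomial represents, so with parabolic surfaces
the generator and the measurement convention agree and round-trip radius
recovery is meaningful at the percent level. Spherical surfaces remain
available (`conic_constant=0`); the unit tests quantify their bias
explicitly.

**Age models.** Every cohort parameter follows `value = intercept +
slope·age`. Slopes are the published ageing rates (lens 0.023, cortex
0.017, nucleus 0.006, C1α 0.001, C1β 0.0011, C2 −0.0002, C3 0.0146,
C4 0.0006 mm/yr; anterior lens radius −0.053, anterior nucleus −0.013,
posterior nucleus −0.006, posterior lens +0.0032 mm/yr; zone densities in
a.u./yr; OSI +0.014/yr, AULCSF −0.0047/yr, VA +0.0005 logMAR/yr).
Intercepts anchor each line to the reference cross-sectional mean at the
mean age 39.24 y, except the two capsule radii whose published regression
intercepts (12.25 and 5.787 mm) are used directly. Whether the
cross-sectional means correspond to the fitted lines at the mean age is a
modelling convention, not an asserted fact.

Three places required a choice because the printed reference numbers are
not mutually consistent:

* the thickness means are not additive (4.54 ≠ 1.99 + 2.39 mm); lens and
  cortex keep their anchors and the nucleus is anchored at
  lens − cortex = 2.55 mm (its slope 0.006 = 0.023 − 0.017 is consistent);
* the C3 optical density is taken as 43 ± 11 ×10³ a.u. — the alternative
  reading (4.3) contradicts both its own ageing rate (+434 a.u./yr over a
  70-year range) and C3 being a hyper-reflective zone;
* the cortex-density ageing rate (552 a.u./yr) implies more age-driven
  variance than the quoted SD contains; the residual SD is floored at 20%
  of the SD instead of an imaginary value.

**Scatter.** Residual SDs solve `SD² = (slope·18.8)² + σ²` so a default
cohort reproduces the reference SDs. Cortex and nucleus residuals are
drawn jointly (correlation −0.686) and the lens is their sum, which keeps
additivity exact *and* all three SDs on target. Zone thicknesses are drawn
from their own lines and rescaled by cortex/Σzones (≈ 0.995) so they sum
to the cortex exactly; this perturbs the recovered C3 rate by < 1%.
Ages are uniform on [9, 78] and mean-shifted to 39.24 (the true age
distribution is unknown). Vision metrics (OSI, AULCSF, VA) and lens
density share a small residual correlation matrix chosen so their total
pairwise correlations approximate the reported weak associations once the
common age trend is included. Extreme noise draws that would make a zone
thickness negative are clamped to 5 µm (a vanishing zone), not rejected.

What the generator does **not** emulate: accommodation, gradient-index
optics, age-dependent refractive indices, corneal/anterior-chamber ageing
(fixed schematic-eye values: radii 7.8/6.5 mm, thickness 0.55 mm, aqueous
depth 3.0 mm), non-linear density–age trends, eccentric fixation, tear
film, and pathology. Passing recovery tests therefore demonstrates the
*pipeline's* correctness under the stated physics, not clinical validity
on real eyes.

## Forward rendering

Telecentric raster: one ray per A-scan, parallel to the axis, entering at
a 0.5 mm air standoff above the corneal apex (the zero-delay reference of
a real scan; without it the corneal peak would sit at sample 0 and be
undetectable). Conicoid intersections are solved by vectorised Newton
iteration; refraction is vectorial Snell's law; sample depth is cumulative
optical path length. Media deposit their mean backscatter (cortical levels
subdivided by the OSD zone layers, whose boundary surfaces interpolate the
bounding interfaces), interfaces deposit Gaussian specular peaks (σ = 1
sample), and speckle multiplies every voxel by an i.i.d. unit-mean
exponential variate. Near the lens equator (|lateral| ≳ 3 mm) the nucleus
shells cross; ray segments are clamped to zero thickness there, which is
outside the 3.5 mm analysis zone. Volumes are float32 on a 16-bit a.u.
scale: clipping exponentially-speckled ~40·10³ a.u. zones at 65535 would
bias means by ~15–20% and break the mean-preservation property of the
speckle model.

## Motion alignment

Axial jitter between B-scans is estimated by cross-correlating each
B-scan's corneal-peak profile (central 25 columns, lightly smoothed) with
its neighbour, with sub-sample lag refinement. The cumulative lag curve
mixes true motion with the smooth sag of the surfaces across the slow
axis, so it is detrended with a quadratic (the sag of a conicoid) and only
the high-frequency residual is applied as an integer shift. Jitter-free
volumes receive zero (noiseless) or ≤ 1-sample (speckled) shifts; injected
±5-sample jitter is recovered to ≤ 1 sample.

## Interface segmentation

Detection must survive fully developed speckle (unit contrast). The stages:

1. **Seed**: a mean axial profile over a narrow central block, augmented
   with adjacent B-scans (independent speckle). Candidate peaks are ranked
   by *local contrast* — height above the darkest sample within the peak
   footprint — because every true interface abuts an optically empty
   medium (aqueous, vitreous, nucleus) while speckle bumps ride on bright
   plateaus; the six best-separated winners are the interfaces.
2. **Tracking**: each interface grows outward column by column. At every
   column the neighbouring ±3 A-scans are shear-aligned along the locally
   estimated slope and averaged (speckle suppression without smearing
   sloped surfaces), the maximum is searched within ±6 samples of a model
   prediction, and candidates are again scored by local contrast with a
   preference for the candidate furthest toward the interface's dark side
   (spurious bumps exist only on the bright side, which otherwise causes
   one-sided drift). The track model is a polynomial refit after every
   accepted column, with its degree gated on the lateral span covered so
   an under-constrained quadratic cannot run away. The strong interfaces
   (cornea, capsule) are tracked absolutely; the weaker nucleo-cortical
   interfaces are tracked as smooth offsets from their capsule reference.
3. **Re-search**: a robust global quadratic (iterated MAD rejection) of
   the pass-1 positions re-centres a tight ±4-sample search per column,
   repairing any local capture by bright zone structure.
4. **Refinement**: sub-sample positions by parabolic interpolation of the
   3 samples around the maximum *after removing a model baseline* — the
   reflectivity step under a specular peak becomes a ramp of the smoothing
   width and pulls a naive vertex up to ~1 sample toward the bright side.

Surface fits are least-squares quadratics over the central 3.5 mm with one
MAD-based outlier-rejection pass. Detection runs over a region ~45% wider
than the analysis zone because refraction pulls deep-surface points toward
the axis.

## Refraction correction and biometry

Correction proceeds layer by layer: the air-side entry surface is
geometric already; each deeper interface is mapped by propagating every
column's ray a geometric distance `ΔOPL/n` along its refracted direction,
the mapped points are refitted (normals for the next Snell step), and so
on. The *measured* per-column OPLs drive the propagation (the quadratic
fit only fills invalid columns, and such columns are excluded from the
corrected refit — extrapolated depths refracting into the fit support were
the largest single bias source, +2.5% on posterior radii). Image
resampling is bilinear (scattered linear interpolation) or per-column
nearest-neighbour; the pipeline uses nearest-neighbour so densitometry
statistics are not interpolation-smoothed. Radii are `1/(2|a|)` of the
quadratic restricted to the 3.5 mm zone (planar flag below
10⁻⁶ mm⁻¹); thicknesses are distances along the apex axis (the line
through the anterior and posterior lens apices), measured from shared
intersection points so lens = cortex + nucleus holds exactly.

Verified accuracy (mean-age phantom): noiseless radii within 0.3%, central
thicknesses within 5 µm; with default speckle, lens thickness within
±10 µm on 20/20 seeds at the reduced 100×100 raster, radii within ~4% at
the native 300-A-scan raster. Nucleus radii from a *single* speckled
B-scan at the reduced raster are the least robust output (~1 seed in 20
fails visibly) — consistent with the deeper interfaces being the least
reproducible structures to grade.

## Densitometry and zone segmentation

The densitogram averages, per axial sample, all voxel columns whose
lateral centre lies within 66.5 µm of the apex axis (a cylinder; 21
columns at the native 26.7 µm pitch), cropped apex-to-apex. Boundary
finding uses the five-sample moving-average curve; densities always use
the raw curve. Internal boundaries sit at prominent maxima of the
|central-difference gradient| between the reflectivity plateaus, with the
narrow specular nucleo-cortical lines treated as boundaries in their own
right (their flanks masked from the gradient, their centres refined by a
baseline-ramp-subtracted centroid). In the pipeline the two nucleus
anchors come from the B-scan segmentation, which sees far more lateral
structure than the narrow ROI.

Under default speckle the zone-step gradient SNR in a 66.5 µm ROI is below
one, so weak boundaries cannot be read from the curve alone — the same
reason the reference procedure kept a human grader as its only manual
step. The automated counterpart: strong inflections are kept wherever the
data places them (within ±4 samples of their nominal slot), and slots
without a significant inflection fall back to the Oxford-layout template
scaled to the measured cortex/nucleus spans. Noiseless segmentation never
invokes the template (all eight inflections are strong); speckled
boundaries are accurate to ≤ 4 samples but lean on the layout prior, so
speckled zone thicknesses should be read as template-regularised
measurements. A per-boundary override path exists for manual correction.
Prominence threshold (5% of dynamic range), smoothing window (5) and ROI
radius (66.5 µm) are configurable.

Zone metrics: per-zone thickness (anterior + posterior parts summed for
cortical zones), density as the mean unsmoothed intensity between
boundaries (reported ÷10³), and region densities for lens, cortex and
nucleus over the corresponding unions.

## Statistics

* Spearman correlations with average ranks; exact two-sided P for tie-free
  samples up to n = 12 via a subset-DP over the null distribution of
  Σ i·π(i) (full enumeration is infeasible at 12!), t-approximation
  otherwise (n = 49 always uses the approximation; the reference's method
  is unstated).
* Benjamini–Hochberg step-up across the 23-variable age-correlation family
  (family membership configurable), plus OLS rates of change per year.
* Mann–Whitney U: exact null when n_a·n_b ≤ 400 without ties, otherwise
  normal approximation with tie and continuity corrections.
* MVLR: OLS with iterative VIF screening (largest VIF > 10 removed first)
  and a Breusch–Pagan homoscedasticity test on the final residuals.
* ICC(2,1) (two-way random, absolute agreement, single measures) and
  ICC(3,1) from the ANOVA decomposition, cross-checked against pingouin.
* Power: two-sided Fisher-z with Spearman variance 1.06/(n−3); the minimum
  detectable coefficient solves power(ρ) = 0.80 by bracketed root finding
  and is cross-checked by rank-based simulation (bivariate normal with
  Pearson r = 2·sin(πρ/6)). At n = 49, α = 0.05: ρ ≈ 0.40.
* OSI: mean intensity in the 12–20 arcmin annulus of a double-pass PSF
  divided by the central-peak intensity (≤ 1 arcmin), times a configurable
  device-like calibration constant (default 100 — the commercial scaling
  is proprietary; only the ratio is physically defined).

## Problem sizes and determinism

The validation experiments use a 49-eye cohort (50 seeds for the recovery
medians), a reduced 100 × 100 × 1500 raster for end-to-end imaging
(≈ 15 s per eye) and central-row renderings of the native 300 × 300 raster
for round-trip geometry checks. Every random operation takes an explicit
seed; regenerating with the same seed is bit-identical.

## Known limitations

* The renderer's specular peaks are idealised Gaussians with fixed
  amplitudes; real interface reflectance varies with angle and pathology.
* Sensitivity roll-off and depth-dependent focus are omitted (the
  instrument class being modelled is engineered to minimise them).
* Refraction correction is 2-D in the B-scan plane; strongly decentred
  eyes would need two-axis correction.
* Speckled zone segmentation is template-regularised (above); imaging-mode
  zone ageing trends partially reflect that prior, which is why the
  cohort-statistics validation runs on the cohort-table path.
* The double-shell index chain is age-independent; apparent posterior-lens
  curvature inherits any real index ageing, as the equivalent-index
  approach implies.
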