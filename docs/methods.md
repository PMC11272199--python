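# Methods

## What the package models

The package reproduces, on synthetic data, the measurement chain used
to quantify age-related corkscrew degeneration of cerebral medullary
arteries on USPIO-enhanced dual-echo gradient-echo MRI: phantom
synthesis → contrast-map synthesis → vesselness segmentation →
artery/vein classification → centerline extraction → tortuosity
metrics → cohort statistics.  Every stage is usable on its own; the
pipeline module composes them deterministically under one seed.

## Phantom rendering

Vessels are parametric space curves (straight, sinusoid, helix,
smoothed random walk) with a lumen radius; the corkscrew geometry is a
circular helix with radius 0.1–0.2 mm, pitch 0.3–0.6 mm per turn and
5–8 turns, whose axis runs in-plane on the anisotropic grid — medullary
arteries course within axial slices, and only the in-plane half of the
winding is resolvable at 0.25×0.25×1 mm.  The default lumen radius is
0.1 mm (a 200 µm vessel, the typical calibre of a medullary artery at
its origin).

The dual-echo renderer is a contrast-ordering model, not Bloch physics:

- background tissue = 1.0 (arbitrary units);
- veins attenuate to `a_vein = 0.35` at TE1 in *all* volumes (intrinsic
  deoxyhemoglobin susceptibility) and get an extra `te2_factor = 0.8`
  at the long echo;
- arteries are invisible pre-contrast and attenuate to
  `a_artery = 0.6` post-contrast (the agent also multiplies into veins:
  vein post = `a_vein · a_artery`), so veins are always darker;
- attenuation is weighted by the per-voxel lumen volume fraction,
  estimated by supersampling each voxel box (2×2×5 probes, finest along
  the slice axis).  Thin in-plane vessels therefore leave a partial
  signal in every slice they touch instead of vanishing between slice
  centers;
- blooming is an isotropic-in-mm increase of the apparent radius
  (`bloom_mm = 0.15`) applied post-contrast to all vessels and
  pre-contrast to veins.  An earlier voxel-based dilation was rejected:
  one voxel along the slice axis is 1 mm, which smears the vessel
  through-plane and erases the in-plane winding signal entirely;
- optional perivascular-space sheaths render as hyperintense annuli
  (1.3× background) in the pre-contrast volumes;
- i.i.d. Gaussian noise (default σ = 0.02) is added per volume from
  seeded, independent streams, and intensities clipped at 0.  Gaussian
  rather than Rician because the synthetic magnitudes sit far above the
  noise floor; the noise level itself is a convention, since no
  intensity scale is prescribed for the real acquisition.

Voxelization labels a voxel when its center lies within the lumen
radius of the curve, with distances computed in physical mm
(anisotropy-aware); curves are densified to 1/8 of the smallest spacing
first.  Voxel centers sit at `(index + 0.5) · spacing`, 0-based.

## Contrast maps

The arteriogram `MRA_nl` is `clamp(TE1 − TE2, 0)^γ` on the pre-contrast
pair, min–max rescaled to [0, 1]; γ defaults to 2.  The exact nonlinear
subtraction used in practice is not standardized, so a monotone
power-law contrast expansion stands in and is exposed in config.  The
venogram `MRV` is the post/pre TE1 ratio with an ε-floored denominator
(1e-6), background ≈ 1, vessels < 1.  Projections are sliding-slab
maxima/minima (`n − thickness + 1` output slabs), matching how a 4-slab
mIP is read on 1 mm slices.

## Segmentation and classification

The vesselness filter is the classic three-ratio Hessian measure
(plate ratio α = 0.5, blob ratio β = 0.5, structureness c = auto: half
the maximum Frobenius norm per scale) over physical scales
{0.25, 0.5, 1.0} mm.  Anisotropy is handled by per-axis Gaussian sigmas
(`scale / spacing` voxels) and derivatives in physical units; dark
vessels are detected by sign-flipping the input.

Because the auto structureness constant scales with the strongest
structure in the field of view, a faint corkscrew next to a dark fat
vein would be suppressed in a single global pass.  Scene segmentation
is therefore two-pass: a permissive global pass (threshold 0.05) finds
candidate components; each candidate is then re-evaluated in a padded
crop (local auto-c) and cut at 43 % of its own local peak — the
relative response profile along a vessel is far more stable across
geometries than the absolute response.  The crop's pad ring is
suppressed where it is interior to the volume (a truncated neighbour
rings strongly in the Hessian), and local fragments belonging to one
coarse component are unioned (the coarse pass certifies their
connectivity).  Components below 20 voxels are dropped.

Artery/vein labels follow the visibility rule: a component visible
(dark) pre *and* post contrast is a vein; visible post only, an artery;
neither, unknown.  Visibility is the 5th percentile of component
intensity over the background median, cut at 0.9.  A low percentile
rather than the median is used because blooming inflates components
with near-background voxels; the cut is 0.9 rather than a stricter
value because partial volume caps an in-plane artery's darkest voxel
near 0.84 of background on a 4:1 anisotropic grid, while noise-only
components stay above ~0.96 at the default noise level.

## Centerlines

The nominal path is 3D topological thinning followed by the weighted
graph diameter between skeleton endpoints (26-neighbour graph, physical
edge lengths, lexicographic tie-breaks; closed skeletons are opened at
the smallest voxel and flagged).  Three robustness measures proved
necessary on the anisotropic grids this pipeline targets:

1. thinning runs on a z-replicated near-isotropic grid — anisotropic
   thinning of fat tubes produced point and ring skeletons;
2. when the extracted endpoints fail to span the component (endpoint
   distance < 0.6 of the principal-axis extent, or fewer than 3
   points), the path falls back to principal-axis slab centroids,
   which is well-defined for the unbranched, axis-monotone tubes this
   package assumes (branch-aware tree centerlines are out of scope);
3. the path is refined by cross-section mask centroids: each resampled
   point moves, perpendicular to its local tangent, onto the centroid
   of component voxels within ±0.125 mm of its cross-sectional plane
   (2 iterations).  The offset field is low-passed on the base
   parameterization (window 3) before being applied, because aliased
   centroids at the sampling limit otherwise inject high-frequency
   zigzag that inflates arc length.  A voxel skeleton cannot carry
   sub-voxel geometry, and the corkscrew winding amplitude
   (0.1–0.2 mm) is below one in-plane voxel — without this step the
   recovered course of any corkscrew is essentially straight.  The
   refinement uses only binary mask geometry, never image intensities.

Centerlines are then uniformly resampled at 0.1 mm with a centered
moving average (window 5; first/last half-window points untouched, so
endpoints are preserved), and 0.2 mm is trimmed from each end — the
filter's boundary response bends tube caps, which otherwise pushes a
straight tube's TI above the 1.005 calibration target.  With these
defaults a noise-free straight tube measures TI ≈ 1.0003 and the
reference 5-turn corkscrew TI ≈ 1.18.

## Tortuosity metrics

All metrics operate on resampled centerlines in mm.  TI = AL/DL with an
explicit error on coincident endpoints.  BL is the maximum distance to
the infinite endpoint line (not the segment).  Curvature is the
three-point Menger circumradius reciprocal over a ±2-sample window
(collinear triples → 0); on digitized vessels the curvature maximum is
the most jitter-sensitive statistic and should be read as an upper
envelope.  Turning points count direction-of-bending reversals: an
event fires when the unit discrete normal has rotated by at least 60°
(‖ΔN‖² ≥ 1) since the last event, with a 0.2 mm minimum arc separation
and normals defined only where discrete curvature exceeds 0.2 /mm.
Slow continuous rotation (a helix) accumulates events, so a 5-turn
corkscrew registers ≥ 5 turns; a second counter reporting full windings
of the normal (revolutions / 2π) is provided because a visual
"corkscrew turn" is ambiguous between the two readings.  cw-ICM uses κ
in 1/mm and is therefore not claimed to be numerically comparable to
published cohort tables whose curvature units are unstated.
Per-subject summaries average per-vessel metrics unweighted (a
length-weighted flag exists).  The per-slice count averages, over all
axial slices, the number of distinct tortuous vessels intersecting each
slice.  PVS co-localization counts 26-connected sheath components,
fills their lumina (slice-wise along each axis, since an open-ended
tube has no closed cavity) and calls a sheath "containing" a tortuous
artery when ≥ 50 % of that artery's voxels lie inside.

## Cohort generator

Ages are uniform on [21, 70].  The tortuous-vessel count is the
quadratic law `0.037·age² − 1.458·age + 35.34` plus N(0, 15) noise,
floored at 0 and left continuous (counts are per-slice averages, not
integers).  TI/BL/cw-ICM means rise linearly in age, anchored to
young/old group summaries (TI 1.10→1.14, BL 0.31→0.60 mm,
cw-ICM 7.89→12.31 between mean ages 32 and 62) with Gaussian noise
(sd 0.03, 0.11, 2.75) — group summaries are all the source material
provides, so a linear link is the minimal generative assumption.
Covariates (sex, BMI, blood pressure, four risk flags) are drawn from
the cohort's marginal summaries, independent of age; passing tests
therefore show correct recovery machinery, not realistic confounding
structure.  The generator is the study condition, not a tuning knob.

## Statistics

Two-group comparisons screen normality per group (Shapiro–Wilk) and use
the independent t-test or a rank test accordingly, with the
significance threshold Bonferroni-divided across the continuous
variables (α/4 = 0.0125 for the standard four-measure battery);
categorical variables use Fisher's exact test.  One-way ANOVA pairs
with Tukey HSD (statsmodels); for two groups Tukey reduces exactly to
the t-test, which is tested.  The quadratic fit is plain OLS on
[age², age, 1] and is exact on noise-free polynomials.  Partial
correlation residualizes both variables on the covariates and
correlates residuals (t-test on n − k − 2 df); variables fully
explained by covariates return r = 0 rather than noise, and collinear
covariate sets are flagged.  Multiple regression reports standardized
(z-scored) coefficients — single predictor ⇒ Pearson r — alongside raw
ones, adjusted R², and a Kolmogorov–Smirnov residual-normality screen.
Inter-rater reliability is ICC(2,1) (two-way random effects, absolute
agreement, single measure) from ANOVA mean squares with McGraw–Wong
F-based 95 % bounds; identical raters give 1, zero between-subject
variance gives 0.  Partial correlation and the ICC are implemented from
first principles and cross-checked against pingouin in the tests.

## Problem sizes and determinism

Default test and acceptance runs use single-vessel volumes of roughly
16–40 × 32–36 × 5 voxels, a 5-vessel demo scene of 72 × 32 × 6 voxels,
50-vessel populations, and 2000-subject cohorts; these sizes make every
check run in seconds while leaving all algorithmic behaviour intact.
One global seed fans out into per-stage child seeds via seed sequences,
so adding draws to one stage never shifts another; identical config and
seed reproduce byte-identical outputs (uncompressed NIfTI, checksummed
in the run manifest).

## Known limitations

- The renderer is a contrast-ordering model; no susceptibility field
  simulation, B1 effects, motion, or anatomical background.
- Corkscrews whose winding amplitude is small relative to the bloomed
  apparent radius render as featureless thick tubes and measure
  TI ≈ 1 — a genuine resolution limit, visible in the population tail.
- κ_max (and hence cw-ICM) on digitized vessels is inflated by residual
  sampling jitter relative to the analytic curvature.
- Vessel trees, branch points and origin tracking are out of scope;
  every component is treated as one unbranched tube.
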