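# Methods

## Scope

`lvmass` quantifies left-ventricular mass (LVM) from traced 2D
echocardiographic borders and 1D calipers, compares methods against a
reference mass with a full agreement protocol, and generates synthetic LV
phantoms with analytic ground truth so that every operation is testable
without image data.  Inputs are already-traced contours (ordered point
lists in cm, view-local 2D frames); image formation, segmentation and
frame selection are upstream and out of scope.

## Volume primitives

**Biplane method of disks.** The ventricular long axis of an apical
contour runs from the midpoint of the mitral base segment to the vertex
farthest from it.  The axis is cut into `N` slabs of equal height
(default `N = 20`, the guideline-standard count); at each slab midpoint
the chord width perpendicular to the axis is the total length of the
slicing line inside the polygon (even-odd rule over edge crossings, exact
for simple polygons and robust to mild non-convexity).  With chords
`a_i`, `b_i` from the two orthogonal apical views,

    V = (pi/4) * sum_i a_i b_i * h,     h = L / N  [ml, lengths in cm].

When the two views' axis lengths differ, the common length is the longer
one and each view's chords are sampled at the common slab *fractions* of
its own axis.  Slab-midpoint sampling makes the disk sum a midpoint
quadrature: on smooth solids of revolution the error is second order
(measured order 2.00 on a half prolate spheroid; 0.031% at `N = 20`).

**Mean wall thickness.** From the parasternal short-axis (PSAX) pair,
`t = sqrt(A1/pi) - sqrt(A2/pi)` — the difference of equivalent-circle
radii of the epicardial (`A1`) and endocardial (`A2`) areas.  The
equivalent-radius construction was chosen over averaged point-wise
thickness because it uses exactly the two traced areas and is exact for
concentric circles.

**Teichholz volume.** `V = 7 d^3 / (2.4 + d)` from the internal diameter.

## The five mass methods

All methods convert myocardial volume to mass with density 1.05 g/ml
(configurable; infarct edema can raise effective density).

1. **Devereux (1D)** — ASE-corrected cube formula
   `0.8 * 1.04 * [(IVSd + LVIDd + PWTd)^3 - LVIDd^3] + 0.6` g.  The
   corrected variant (not the original Penn convention) is used because
   current guidelines recommend it.
2. **Area-Length (2D)** — `rho * (5/6) * [A1 (L + t) - A2 L]` with `L`
   the AP4CH long-axis length.
3. **Truncated Ellipsoid (2D)** — prolate spheroid cut by the mitral
   plane at distance `d` below the widest cross-section, with
   `b = sqrt(A2/pi)`:

        mass = rho pi { (b+t)^2 [(2/3)(a+t) + d - d^3/(3(a+t)^2)]
                        - b^2  [(2/3) a   + d - d^3/(3 a^2)] }.

   `a` and `d` are obtained by splitting the AP4CH long axis at its
   widest-chord plane (dense chord scan, argmax).  Whether the original
   analysis software used the AP4CH length or the longer apical view is
   not determinable; AP4CH is used, matching the method's view pairing.
4. **Biplane endo-/epicardial tracing (2D)** — disk volumes of the
   endocardial and epicardial biplane tracings;
   `mass = rho (V_epi - V_endo)`.  Epicardial contours may lack base
   landmarks, in which case the endocardial base midpoint anchors their
   axis (same mitral plane).
5. **Disk expansion ("novel", 2D)** — only the endocardial biplane
   tracing plus the PSAX pair are needed: `t` is added to every disk
   (each diameter grows by `2t`, wall on both margins) and the axis
   extends apically by `t` (the base is the mitral plane, where no
   myocardium is added), reconstructing `EDV_EPI` without tracing the
   apical epicardium; `mass = rho (EDV_EPI - EDV_ENDO)`.

### The disk-expansion rule

How the lengthened axis is re-discretised is not uniquely determined by
"add t to each disk", so it sits behind `MethodConfig.apex_extension`:

* `extend` (default): the epicardial axis `L + t` is cut into the same
  `N` slabs; each slab samples the endocardial chord at its own absolute
  depth (zero beyond the endocardial apex, where the disk contains wall
  only) and widens it by `2t`.
* `none`: diameters widened by `2t` on the unchanged axis (no apical cap).
* `stretch`: the endocardial diameter list reused on slabs of height
  `(L + t)/N`, i.e. the profile stretched axially.

Measured against the analytic shell mass over a 5x5x5 grid of anatomically
calibrated shapes (`a` 6.0-8.5 cm, `b` 2.2-2.7 cm, `t` 0.8-1.2 cm,
`d = 1` cm), the systematic error bands are:

| rule    | min    | mean   | max   |
|---------|--------|--------|-------|
| extend  | -6.0%  | -0.85% | +3.7% |
| none    | -8.9%  | -3.1%  | +1.9% |
| stretch | +17.1% | +18.8% | +20.6%|

`extend` was chosen as the default for its accuracy against the ground
truth on noiseless geometry; `stretch` grossly over-adds wall laterally
(it inflates the entire epicardial volume by `t/L`) and is retained for
comparison only.  On deliberately non-anatomical shapes the band is much
wider (a hemispherical cavity with `t/L = 1/3` reconstructs ~26% low);
the rule is a thin-wall, elongated-ventricle approximation.  The polygon
pipeline reproduces an independent analytic-chord oracle of the same rule
to better than 0.001% at 720 contour points.

## Agreement statistics

The reference (necropsy-style truth, or a baseline reading) is treated as
the true value, not as a second method: differences are
`predicted - reference` (positive = overestimation), the CV denominator
is the cohort mean of the *reference* (baseline mean for reader
variability), and the SEE comes from regressing the predicted on the
reference.  Limits of agreement use exactly 1.96 x SD of the differences
(the 95% convention).  Proportional bias is the OLS slope of difference
on reference with its two-sided t-test; significance threshold 0.05,
two-sided, no multiplicity adjustment.  Per-subject accuracy ranking uses
the absolute percentage difference; ties split credit equally so counts
sum to n.  All statistics are verified against explicit-loop summation
oracles to 1e-12 on random fixtures.

## The phantom generator

A phantom is a truncated prolate spheroid shell with uniform wall
(`ShellSpec`): endocardial semi-axes `(a, b)` (optionally `b_x != b_y`
for a non-revolution stress test), mitral plane at height `d` above the
widest cross-section, epicardium concentric with every semi-axis enlarged
by `t`.  The shell volume is closed-form, so each phantom carries exact
ground truth, and — by construction — the truncated-ellipsoid method is
an *exact* oracle on noiseless renderings.  Cohorts draw target mass,
LVIDd and wall thickness from truncated normals (+/- 3 SD) calibrated to
the validation cohort: mass 132 +/- 11 g, LVIDd 4.8 +/- 0.3 cm, wall
0.97 +/- 0.08 cm, `d` 1.0 +/- 0.1 cm, n = 34; the apical semi-axis is
then solved per subject (Brent root-finding on the closed-form volume) so
that each subject's true mass equals its drawn target exactly.

### Tracing-noise model

Defaults, chosen once and then frozen:

| parameter           | default | unit            | role |
|---------------------|---------|-----------------|------|
| `point_jitter_sd`   | 0.024   | fraction radius | smoothed multiplicative radial jitter |
| `smooth_frac`       | 0.25    | fraction        | correlation length of the jitter field |
| `endo_epi_corr`     | 0.75    | –               | shared field between endo/epi of one image |
| `thickness_bias`    | +0.05   | cm              | parasternal wall-thickness over-read |
| `apical_epi_bias`   | -0.05   | cm              | apical epicardial border drop-out |
| `landmark_jitter_sd`| 0.08    | cm              | mitral-annulus landmark jitter (tapered) |
| `caliper_sd`        | 0.045   | cm              | 1D linear-measure noise |

The jitter field is coherent along the border (a reader's hand wanders
smoothly, it does not shake per vertex), endo- and epicardial tracings of
the same still frame share most of their error (which is what makes
difference-based methods reproducible), linear calipers are less noisy
than whole-contour tracings, the parasternal wall tends to be over-read
(trabeculae and septal bands included in the wall) while the apical
epicardium tends to be under-traced (drop-out near the lung interface),
and annulus landmark jitter is tapered into the neighbouring border so it
cannot fold the polygon.  `point_jitter_sd` and `caliper_sd` were
calibrated so that simulated inter-reader CVs land in the ~9-10% range
reported for repeated expert readings (realised 8-12% across the five
methods over check seeds); the systematic-bias magnitudes are plausible
reading conventions, not fitted quantities.

### What the phantom does *not* emulate

No speckle or image-level artifacts, no regional wall thinning or infarct
density heterogeneity, no foreshortening, no systolic phase, and — most
importantly for method comparison — no departure of the true shape from
the truncated-spheroid family.  The last point has a direct consequence:
because the truncated-ellipsoid method is the exact generative model of
every phantom, its only error here is tracing noise, and on these
phantoms it (and the explicit endo/epi tracing) rank at or near the top
on cohort bias and CV, with the disk-expansion method carrying its small
reconstruction band (replicate means over 100 cohorts: TE +9 g / 7.4%,
biplane endo-epi -6 g / 6.9%, disk-expansion +10 g / 8.7%, Area-Length
+36 g / 9.3%, Devereux +44 g / 21.5%).  In vivo the ordering differs —
real ventricles are not perfect truncated spheroids, and the geometric
model error that then dominates the 1D/2D model-based methods is exactly
what these phantoms exclude.  Passing tests on this generator therefore
validate the implementations and the noise-propagation behaviour, not
the clinical superiority ranking of the methods.

## Numerical choices

* Chord extraction: vectorised even-odd crossing scan in the axis frame;
  a vertex exactly on the slicing line is counted on exactly one of its
  edges (half-open rule), so crossings always pair.
* Long-axis apex: farthest vertex from the base midpoint; exact ties
  (semicircular cavities) break towards the vertex farthest from the base
  line.
* Widest-chord split for TE/A-L: 200-slab scan, argmax.
* Degenerate inputs raise typed errors (`ContourError`, `GeometryError`,
  `TracingError`, `AnalysisError`) rather than returning NaNs; zero-wall
  inputs are errors for the thickness operation and exact zeros for the
  area-length mass.
* All stochastic operations take explicit seeds / generators; cohorts
  spawn one child stream per subject, so per-subject results do not
  depend on cohort size.
* Paired t on zero-variance, zero-mean differences returns p = 1 by
  convention.

## Limitations

Single-plane PSAX level (widest cross-section) rather than mid-papillary;
no 3D echocardiography; no LVM indexing or hypertrophy classification; no
end-systolic mass.  The disk-expansion axis convention is one of several
defensible readings of "add t to each disk" and is therefore exposed as a
configuration switch rather than hard-coded.
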