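# Methods

## The analysis

`fetrelapse` implements a relapse-pattern and target-volume-simulation
analysis for radiotherapy of glioblastoma guided by amino-acid PET
(O-(2-¹⁸F-fluoroethyl)-L-tyrosine, FET). The setting: after surgical
resection, a patient is imaged with FET-PET and contrast-enhanced MRI both
at radiotherapy planning (baseline) and again at tumor recurrence. The
questions the pipeline answers per case and per cohort are

1. how well the metabolically active tumor volume (FET, tumor-to-brain
   ratio TBR ≥ 1.6) and the MRI contrast-enhancement volume agree at each
   time point (intersection volume, and as a percentage of the FET volume);
2. how much of the recurrent FET-positive volume (FET-2) lay inside the
   delivered boost PTV-1 (the FET-based CTV with no added margin, 72 Gy)
   and inside the standard MRI-based PTV-2 (60 Gy);
3. how the resection cavity changed between the time points (shrinkage in
   ml; shift in mm of a representative centre point, operationalised as the
   mask centroid);
4. how well *simulated* target volumes — the baseline FET or MRI volume
   expanded isotropically by 0, 5, 7 or 10 mm — would have covered the
   recurrence, and how large the corresponding PTVs (expansion + 5 mm setup
   margin) would have been; and
5. whether paired differences across the cohort (FET- vs MRI-based
   coverage, simulated vs delivered PTV size) are significant under the
   exact two-sided Wilcoxon signed-rank test at α = 5 %.

## Data model and geometry

All structures live on a shared axis-aligned voxel grid (spacing in mm,
voxel-centre convention, 0-based indices); inputs are assumed co-registered
and no resampling is performed. Masks are binary on voxel centres — a
structure's volume in ml is voxel count × voxel volume / 1000, with no
partial-volume weighting. I/O is NIfTI-1 via nibabel (masks as uint8
{0,1}, scalar volumes as float64 so values round-trip losslessly);
orientation metadata beyond spacing and origin is carried but not
interpreted.

Margin expansion computes the Euclidean distance transform of the mask
complement (`scipy.ndimage.distance_transform_edt`, `sampling=spacing`) and
keeps voxels with distance ≤ margin. This is exactly "every voxel centre
within the margin of some member voxel centre", respects anisotropic
spacing, and is verified in the tests against an independent brute-force
route: binary dilation with an explicitly constructed anisotropic ball
footprint. A relative-plus-absolute tolerance of `margin·1e-12 + 1e-9` mm
absorbs floating-point rounding for voxels landing exactly on the margin
distance (e.g. a 5 mm margin on a 1 mm grid), so ties are inclusive.
Composition of expansions is *not* assumed exact:
`expand(m, a+b) ⊇ expand(expand(m, a), b)` holds, with volume agreement
within one voxel-shell on convex digital sets.

TBR is voxel uptake divided by the *mean* uptake over an explicit
user-supplied normal-brain reference mask (the source cohort does not
document its reference-region placement, so it is an input; the phantom
generator emits a contralateral one). The contour threshold comparison is
inclusive (TBR ≥ 1.6) and configurable; no connected-component or
minimum-size filtering is applied. Because TBR is a ratio, the contour is
invariant to global rescaling of the PET image.

Recurrence-pattern classification has no published operational rule, so
the package defines one: 26-connected components of the relapse mask are
each labelled *local* when more than 5 % (configurable) of the component's
volume lies inside PTV-2, else *distant*; the case label is the
aggregation (local / local+distant / distant).

The standard MRI-based CTV-2 uses a 15 mm clinical margin around the
enhancement volume plus a 5 mm setup margin for PTV-2; edema-based and
organ-at-risk-adapted editing of CTV-2 is out of scope beyond an optional
brain-mask clip. The delivered boost PTV-1 carries no setup margin,
whereas the *simulated* FET-based PTVs add 5 mm on top of each CTV margin;
both behaviours are reachable through the `setup_margin_mm` parameter.

## Synthetic phantoms

The generator emulates the *statistical and geometric structure* of the
cohort, not anatomy: all shapes are spheres on (by default) an 80³ grid at
2 mm spacing, inside a 60 mm-radius "brain" of uniform reference uptake.
Default parameters are the cohort-level conditions of the analysis:

| parameter | default | meaning |
|---|---|---|
| cavity radius (baseline) | 20 mm (33.5 ml) | post-surgical resection cavity |
| cavity shrink | 12 ml | baseline − relapse cavity volume |
| cavity shift | 6 mm | centroid displacement, jittered direction |
| FET-1 radius / TBR level | 14 mm / 2.0 | baseline lesion straddling the cavity rim (5 mm outward offset) |
| MRI-1 overlap | 12 % of FET-1 | baseline enhancement blob |
| FET-2 fraction in FET-1 | 39 % | relapse lesion partly inside baseline lesion |
| MRI-2 overlap | 13 % of FET-2 | relapse enhancement blob |
| noise | 0 (off) | additive Gaussian on PET before TBR |

Blob offsets are solved analytically from the sphere–sphere lens-volume
formula (bisection on the monotone branch) rather than by iterative search
on the voxel masks; because the cavity subtracts part of each lesion ball,
the solver targets the *effective* lesion volume (ball minus the analytic
cavity lens; for the relapse lesion this couples to its own placement and
is resolved by a three-step fixed-point iteration). Achieved fractions are
then recomputed from the emitted voxel masks themselves and reported as
ground truth, landing within a few percentage points of the configured
targets (exactness of the *achieved* values is what the recovery tests
use). Cohorts jitter per-case parameters uniformly (shift ±4 mm, shrink
±6 ml, radii ±15 %, overlap fractions ±0.08) so cohort means converge to
the configured targets; a fixed seed reproduces a cohort bitwise.

With zero noise the TBR autocontour recovers the ground-truth masks
voxel-for-voxel, which is what makes the end-to-end parameter-recovery
test exact. What passing phantom tests do **not** show: behaviour on real
PET noise (Poisson projection statistics), heterogeneous uptake,
non-spherical or infiltrative lesion geometry, registration error, or
manual-contouring variability.

## Statistics

Summary rows report n, mean, median (midpoint convention), sample SD
(n−1; 0 for a single value), min and max; rounding to one decimal happens
only at presentation. The paired test is the Wilcoxon signed-rank test:
zero differences dropped (Wilcoxon's original procedure), midranks for
tied |d|, statistic W = min(W⁺, W⁻), and the *exact* two-sided
p = min(1, 2·P(W⁺ ≤ W)) computed over all 2ⁿ sign assignments via a
polynomial-convolution recursion on doubled (integer) midranks — feasible
up to n = 25, far beyond this cohort's n = 13. Exact mode is the default
deliberately: on the PTV-size comparison (12 non-zero, one-signed
differences) the exact test gives p = 2/4096 ≈ 4.9·10⁻⁴, whereas the
uncorrected normal approximation gives ≈2·10⁻³ and would not support a
p < 0.001 statement. The normal fallback (tie-corrected variance) exists
for larger n.

## Packaged cohort tables

The 13-patient per-patient tables are packaged as CSV fixtures (T1
volumes/overlaps, T2 boost coverage, T3 simulated-CTV coverage, T4 PTV
volumes). On load, every column's recomputed median is checked against the
printed median row — with n = 13 the median is itself a printed value, so
this transcription checksum is exact. Known internal inconsistencies of
the source tables are preserved verbatim rather than "fixed": T1 patient 4
prints an intersection (1.3 ml) larger than its FET-1 volume (1.1 ml); in
T2 several ml and % columns are mutually inconsistent (the % column is
treated as authoritative); printed mean rows were evidently rounded from
unrounded per-patient values and are reproduced within a small documented
tolerance (±0.2 ml for T1, ±1 ml for T4's integer columns, else half an
ulp of the printed precision); printed SDs match neither the sample nor
the population convention exactly and are cross-checked at ±0.7 for T1
only. Fixture mode supports only what the printed numbers support: the
source's per-patient *images* are not distributed, so imaging-mode results
on real data are not reproducible from this package — the phantom tests
and the fixture tables cover the two halves separately.

## Problem sizes and numerical choices

Default grids are desk-scale by design: 1 mm isotropic for analytic
geometry checks, 2 mm/80³ for phantom cohorts (a 13-case cohort runs the
full pipeline in well under a minute). Degenerate inputs fail loudly and
specifically: empty masks cannot be expanded or used as fraction
denominators, empty or non-positive background regions are reference
errors, all-zero paired differences are a degenerate test, and structures
on incompatible grids refuse to combine (tolerance 10⁻⁶ mm) instead of
being resampled. Cases with empty segmented structures surface null
fields or errors rather than being dropped silently.

## Known limitations

- Spherical phantom geometry only; no deformable anatomy or realistic
  noise models.
- The "representative centre point" of the cavity is the centroid; the
  source study used a manually chosen point, and sensitivity to this
  choice is out of scope.
- Margin expansion is geometric (Euclidean); planning-system-specific
  raster expansions may differ at the voxel level.
- No DICOM-RT support, no dose computation, no registration — inputs must
  already share a grid.
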