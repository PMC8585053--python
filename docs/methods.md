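# Methods

## The measurement problem

After secondary alveolar bone grafting (ABG) in cleft lip/palate patients,
clinicians follow the consolidation of the graft on cone-beam CT (CBCT).
Raw CBCT attenuation (Hounsfield units, HU) is not a calibrated densitometric
quantity — it drifts with scanner, field of view and patient age — so graft
density is expressed relative to an intra-patient reference: the bone marrow
of the pogonion (chin). `graftdens` implements that protocol: geometric
placement of circular regions of interest (ROIs) on the graft and the
pogonion, the calibrated density ratio, its longitudinal change, graft
volumetrics, and the agreement statistics used to validate the measurement.

## Measurement model

All images are 3-D scalar grids with voxel-center addressing: axis 0 is the
sagittal index (left–right), axis 1 the coronal index (anterior–posterior),
axis 2 the axial index (inferior–superior); the physical position of voxel
`(i,j,k)` is `origin + index·spacing` in mm. Anatomy arrives as a
co-registered integer label map naming graft, the two adjacent teeth,
cortical bone, pogonion marrow, other bone, and air.

**Plane selection.** The superior and inferior measurement planes are the
highest and lowest axial slices containing graft voxels; the middle plane is
the floor of their index midpoint (even spans have no exact middle slice).
A plane is eligible only if the inter-tooth gap at the midpoint exceeds
2.5 mm; an extreme plane that fails steps one slice inward until one
passes, and every substitution is recorded in the output for audit. The
gap is measured as the sum of the midpoint's Euclidean clearances to the
two teeth.

**Circle placement.** All graft circles are centred at the midpoint of the
segment joining the two in-plane tooth centroids:

* Method A: radius = (nearest-tooth clearance) − 1 mm — the largest circle
  whose boundary keeps 1 mm from the nearer tooth. It is *not* bounded by
  cortical bone; in wide-gap/thin-defect anatomy it can therefore include
  cortical or air density, which is the method's known drawback.
* Method B: radius = min(tooth clearance, cortical clearance) — the largest
  circle that just transects the teeth (tooth-limited regime) or is tangent
  to the cortical plates (cortical-limited regime). The binding constraint
  is reported with the ROI.
* Method C: fixed radius 1 mm (2 mm diameter); refused when the midpoint is
  closer than 1 mm to a tooth.
* Pogonion reference: on the sagittal slice through the marrow centroid,
  the largest circle inscribed in the marrow mask — centre at the maximum
  of the interior Euclidean distance transform, radius that maximum, ties
  broken toward the lowest index pair.

**Distance convention.** All clearances are exact Euclidean distances to
voxel *centers* of the labelled regions, not to sub-voxel surfaces.
Midpoint clearances are computed by direct vectorised minimisation (exact
for off-grid query points); the pogonion circle uses the sampled exact
distance transform. The independent brute-force oracle used in testing
measures against the *continuous footprint* of the mask (union of voxel
squares, grid boundary counted as background); the two conventions agree
to within half the in-plane voxel diagonal, `0.5·√(sx²+sy²)`, which is the
tolerance all cross-convention geometry assertions use.

**Density sampling.** The HU mean of an ROI is the arithmetic mean over
voxel centers strictly inside the disc (distance < radius, with a 1 nm
guard so exact-boundary voxels are excluded regardless of floating-point
rounding). The graft HU of a scan is the mean of the three plane means.

**Adjusted BMD and change.** With `HU_sel` the graft HU and `HU_pog` the
pogonion reference of the same scan,

    BMD_a (%) = 100 · HU_sel / HU_pog

and for two follow-ups T1 and T2,

    enhancement rate (%) = 100 · (BMD_a,T2 − BMD_a,T1) / BMD_a,T1
    volume change (%)    = 100 · (V_T2 − V_T1) / V_T1      (negative = loss)

The pogonion is re-measured at each timepoint. When two measurement
sessions exist per scan, the final graft HU is the mean of the six plane
means and the final pogonion HU the mean of the two session values, with
BMD_a recomputed from those finals. Cohort summaries must average
per-subject rates, never compute a rate from cohort-mean BMDs — the two
differ whenever baselines vary.

**Volumetrics.** Graft volume is exact voxel counting times voxel volume;
no partial-volume correction or smoothing, matching what a label-map
export from interactive segmentation yields.

## Agreement statistics

Bland–Altman analysis and the intraclass correlation coefficient are
implemented from their definitions. Differences are `x − y`; bias is their
mean, limits of agreement `bias ± 1.96·sd` with the sample (n−1) standard
deviation. Intra-rater reliability uses ICC(3,1) — two-way mixed effects,
consistency, single measurement — from the subjects × sessions ANOVA mean
squares; the form identifier is recorded in every result. A fixed single
rater re-measuring on separate dates is the textbook ICC(3,1) setting,
which is why only that form is offered. Group tests (paired t, Wilcoxon
signed-rank, repeated-measures ANOVA, Friedman, Spearman) delegate to
standard routines; the repeated-measures F is the treatment-over-residual
mean-square ratio from the same two-way decomposition.

## The synthetic phantom

No clinical CBCTs ship with the package; the phantom generator supplies
volumes with known ground truth. It emulates only the geometry the
protocol needs:

* two parallel tooth cylinders (circular axial cross-section, radius
  3 mm) whose surfaces are `gap` apart (default 6 mm; specs at or below
  2.5 mm are refused, mirroring the plane-eligibility bound),
* graft tissue packing the defect channel between the cortical plates and
  up to the tooth surfaces over a configurable axial slice range,
* two cortical slabs (thickness 1.2 mm) bounding the defect
  anteriorly/posteriorly — with the default defect thickness (8 mm) the
  teeth bind Method B (tooth-limited regime); narrowing the defect below
  the gap makes the cortical plates bind,
* a pogonion marrow ellipsoid (semi-axes 4.8 × 6.0 × 3.2 mm) embedded in a
  mandibular bone block, disjoint and non-adjacent to the graft,
* air elsewhere.

Each region takes a constant HU mean plus i.i.d. zero-mean Gaussian noise
(default sd 50 HU). Defaults: 80 × 80 × 88 voxels at 0.4 mm isotropic —
the resolution typical of craniofacial CBCT — graft 293.88 HU and pogonion
312.86 HU (magnitudes representative of a 6-month post-graft scan),
cortical 1200 HU, teeth 1500 HU, other bone 600 HU, air −1000 HU. The
noise sd is a plausible stand-in for CBCT voxel noise, not an estimate
from data: voxel-level dispersion inside real grafts is not well
characterised. All randomness flows from a single integer seed.

Longitudinal pairs set the T2 graft HU so that the *noise-free*
enhancement rate equals the programmed value exactly (also under an
optional pogonion drift), and rescale the T2 graft axial extent to realise
a programmed volume change; the T2 noise stream is seeded from the T1 seed
plus a fixed offset (10007), keeping derived seeds below 2³¹.

**What the phantom does not emulate** — and hence what passing tests do
not show about clinical data: real anatomy (curved roots, trabecular
texture, partial-volume blur), beam hardening and scatter, PACS
compression, patient motion, and observer variability in the underlying
segmentation. Recovery results on phantoms validate the geometry and
arithmetic of the implementation, not the clinical accuracy of CBCT
densitometry.

## Numerical choices and degenerate inputs

* In-plane spacings must be equal on measurement planes (circles are
  Euclidean circles in mm); anisotropic axial spacing is accepted by I/O.
* Method B refuses radii at or below half an in-plane voxel; the pogonion
  circle likewise.
* A zero (or |·| < 1e-6 HU) pogonion reference, a non-positive baseline
  BMD or volume, constant inputs to Spearman, all-zero-difference
  Wilcoxon, and zero-total-variance ICC matrices are all refused with
  explicit errors rather than propagating NaNs. Identical paired series
  are the one deliberate exception: the paired t returns (0, 1), and a
  fully tied Friedman table returns statistic 0 — "no difference at all"
  is a meaningful null result, while a zero-variance nonzero shift is not.
* Grid validation requires equal shapes and spacings/origins within
  1e-6 mm between a volume and its label map.

## Problem sizes used in validation

The simulation-based checks use 20 phantoms (or 20 T1/T2 pairs) per
condition at the default 80 × 80 × 88 grid, and 20 replicate studies of 20
phantoms for the method-concordance check — sizes at which the standard
error of a mean recovery bias is well under the asserted bounds (±2%
absolute for adjusted BMD at 50 HU noise, ±3% for enhancement-rate
recovery) while the whole suite runs in well under a minute per check.

## Known limitations

* Distances to voxel centers overestimate surface clearances by up to one
  voxel; all geometric guarantees carry half-voxel-diagonal tolerances.
* The ordering `radius_A ≤ radius_B` holds only in the tooth-limited (B2)
  regime; in cortical-limited anatomy Method A — which ignores cortical
  bone by design — can exceed Method B and sample cortical density.
* The tool is deterministic: "sessions" model repeated human measurement
  only through perturbed inputs or configs supplied by the caller.
* Only ICC(3,1) is provided; absolute-agreement or average-measure forms
  would need a different variance decomposition.
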