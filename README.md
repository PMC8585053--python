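# graftdens

CBCT-based density and volume assessment of alveolar bone grafts.

After secondary alveolar bone grafting (ABG) in cleft lip/palate patients,
the consolidation of the graft is followed on cone-beam CT. Because raw
CBCT attenuation (HU) is not calibrated across scanners or patient age,
graft density is expressed relative to the patient's own pogonion bone
marrow. `graftdens` implements this protocol for researchers and clinical
image analysts:

* three geometric placements of the measurement circle on each of three
  axial planes through the graft — **Method A** (largest circle keeping
  1 mm from the adjacent teeth), **Method B** (largest circle transecting
  the teeth or tangent to the cortical plates), **Method C** (fixed 2 mm
  diameter) — plus the largest circle inscribed in the pogonion marrow as
  the calibration reference;
* the adjusted bone mineral density and its longitudinal change,

  ```
  BMD_a (%)             = 100 · HU_selected / HU_pogonion
  enhancement rate (%)  = 100 · (BMD_a,T2 − BMD_a,T1) / BMD_a,T1
  volume change (%)     = 100 · (V_T2 − V_T1) / V_T1
  ```

* graft volumetrics from a segmentation label map (exact voxel counting);
* the agreement statistics used to validate such protocols — Bland–Altman
  limits of agreement and ICC(3,1), implemented from their definitions —
  plus the usual paired and repeated-measures comparison tests;
* a seeded synthetic CBCT phantom generator of an alveolar-cleft graft
  site with known ground truth, so every geometric and densitometric step
  is testable against programmed values.

Inputs are NIfTI volumes in HU with a co-registered integer label map
naming graft, the two adjacent teeth, cortical bone, pogonion marrow and
air. See `docs/methods.md` for the full measurement model and conventions.

## Worked example

Generate a longitudinal phantom pair with a programmed 20 % density
enhancement and −4 % volume change, then measure it:

```python
import graftdens as gd
from graftdens import run_measurement, enhancement_rate, mask_volume

spec = gd.PhantomSpec(seed=42)
(v1, l1, t1), (v2, l2, t2) = gd.generate_longitudinal_pair(
    spec, enhancement_rate_pct=20.0, volume_change_pct=-4.0)

for tag, (v, l) in {"T1": (v1, l1), "T2": (v2, l2)}.items():
    for rec in run_measurement(v, l, timepoint=tag):
        print(f"{tag} method {rec.method}: graft {rec.graft_hu:7.2f} HU, "
              f"pogonion {rec.pogonion_hu:7.2f} HU, BMD_a {rec.bmd_a_pct:6.2f} %")

b1 = run_measurement(v1, l1, ["B"])[0].bmd_a_pct
b2 = run_measurement(v2, l2, ["B"], "T2")[0].bmd_a_pct
print(f"enhancement rate (Method B): {enhancement_rate(b1, b2):.2f} %")
```

prints

```
T1 method A: graft  290.94 HU, pogonion  308.22 HU, BMD_a  94.39 %
T1 method B: graft  293.93 HU, pogonion  308.22 HU, BMD_a  95.36 %
T1 method C: graft  295.05 HU, pogonion  308.22 HU, BMD_a  95.73 %
T2 method A: graft  352.21 HU, pogonion  312.78 HU, BMD_a 112.61 %
T2 method B: graft  352.24 HU, pogonion  312.78 HU, BMD_a 112.61 %
T2 method C: graft  346.01 HU, pogonion  312.78 HU, BMD_a 110.62 %
enhancement rate (Method B): 18.09 %
```

The three methods agree closely because the phantom graft is homogeneous;
the per-scan BMD_a values sit near the phantom's true ratio (93.9 % at T1,
112.7 % at T2 for this seed's programmed change), and the measured
enhancement rate scatters around the programmed 20 % with the phantom's
50 HU voxel noise. The same pipeline is available from the shell:

```
graftdens phantom --spec spec.yaml --out phantom/
graftdens measure --config run.yaml
graftdens report --t1 t1.json --t2 t2.json --out report.json
```

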