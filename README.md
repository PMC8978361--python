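# cinedense

Cine DENSE (Displacement ENcoding with Stimulated Echoes) myocardial strain
analysis and test–retest reproducibility emulation.

DENSE is a cardiovascular MR technique that stores the displacement of
myocardial tissue since an end-diastolic encoding instant directly in image
phase: for encoding frequency `ke` (cycles/mm), the phase in direction *d*
is `phi_d = 2*pi*ke*u_d`, observed wrapped into `(-pi, pi]`.  Recovering
strain from a cine DENSE series therefore means: unwrap the phase on the
myocardium, convert it to Eulerian displacement, invert the displacement
map into Lagrangian material-point trajectories, fit a local deformation
gradient `F`, form the Green–Lagrange tensor `E = (FᵀF − I)/2`, and project
it to the circumferential / radial directions about the LV center of mass
(short axis: `Ecc`, `Err`) or the wall-centerline tangent (long axis:
`Ell`).  Left-ventricular twist is the mean in-plane rotation of a slice's
myocardium about the LV center; torsion is the least-squares slope of
end-systolic twist versus slice position along the long axis (°/cm).

The package is aimed at researchers who need a fully tested, reusable
implementation of this analysis chain together with the statistical
machinery used in reproducibility studies — Bland–Altman bias and limits of
agreement, the duplicate-measurement coefficient of variation
(`CV_p = (|x₁−x₂|/√2) / |(x₁+x₂)/2| × 100` per myocardial point, averaged
within each AHA segment), the one-way random single-measure intraclass
correlation coefficient, and the conventional excellent/good/fair/poor
bands (CV ≤ 10 / ≤ 20 / ≤ 40 / > 40 %; ICC > 0.74 / > 0.6 / ≥ 0.4 / < 0.4).

Because no public cine DENSE data accompany the studies this design
emulates, the package ships an analytic deforming-LV phantom with
closed-form ground truth: an annulus deforming by `r(R,t) = a(t)R + b(t)`
plus a rigid per-slice twist, giving exact stretches `lambda_r = a`,
`lambda_c = (aR+b)/R` and hence exact `Ecc`/`Err` everywhere, rendered
through the DENSE encoding equation with wrapping and complex Gaussian
noise.  Every stage of the pipeline is validated against this oracle, and a
configurable study emulator reproduces the intra-user / inter-user /
inter-scan comparison design on synthetic duplicate scans.

## Worked example

Calibrate a phantom to a healthy left ventricle (global `Ecc` −0.18,
`Err` 0.35, `Ell` −0.15, torsion 2.79 °/cm), render it noise-free at 1.7 mm
pixel spacing, and run the full analysis chain:

```python
import numpy as np
from cinedense import phantom, pipeline, strain

spec = phantom.calibrate_deformation(
    -0.18, 0.35, -0.15, phantom.twists_for_torsion((0.0, 25.0, 50.0), 2.79)
)

summaries = []
for view in ("SAX-base", "SAX-mid", "SAX-apex"):
    series, roi = phantom.render_dense_series(spec, view, pixel_spacing=1.7, seed=0)
    summary = pipeline.analyze_series(series, roi)
    summaries.append(summary)
    print(f"{view}: ES Ecc = {summary.es_ecc:+.3f}  ES Err = {summary.es_err:+.3f}  "
          f"twist = {summary.es_twist:+.2f} deg")

torsion = strain.compute_torsion(
    [s.es_twist for s in summaries], [s.slice_location for s in summaries]
)
print(f"global Ecc = {np.mean([s.es_ecc for s in summaries]):+.3f}")
print(f"torsion    = {torsion:+.2f} deg/cm")
```

prints

```
SAX-base: ES Ecc = -0.175  ES Err = +0.334  twist = -1.95 deg
SAX-mid: ES Ecc = -0.172  ES Err = +0.333  twist = +4.84 deg
SAX-apex: ES Ecc = -0.172  ES Err = +0.331  twist = +11.62 deg
global Ecc = -0.173
torsion    = +2.71 deg/cm
```

The recovered global circumferential strain (−0.173) and torsion
(2.71 °/cm) sit within measurement error of the prescribed ground truth
(−0.18, 2.79): the residual comes from finite pixel sampling and the
temporal polynomial smoothing of the trajectories, exactly the error
sources a real acquisition faces.  The per-slice twists follow the
prescribed linear base→apex profile.

A full emulated reproducibility study (synthetic cohort, duplicate scans,
five comparison types, agreement tables and bullseye CSVs) runs from the
command line:

```sh
cinedense run-all --out study-output --seed 1
cinedense compare study-output
```

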