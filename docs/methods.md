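# Methods

## The measurement chain

Cine DENSE encodes tissue displacement in image phase.  At every frame and
in-plane encoding direction *d*, a myocardial pixel at current position `x`
carries `phi_d = wrap(2*pi*ke*u_d(x))`, where `u(x)` is the displacement of
the material point now at `x` since the end-diastolic encoding instant and
`ke` is the encoding frequency (0.1 cycles/mm throughout, matching the
standard 3 T protocol; pixel spacing 3.4 mm is the protocol default, with
finer grids used for validation).  The analysis chain is:

1. **Phase unwrapping** (`phase.unwrap_phase`).  Quality-guided region
   growing within the per-frame myocardial mask.  The quality map is the
   inverse local variance of the wrapped phase gradients in a 3×3 window
   (phase-derivative variance); growth starts at the maximum-quality pixel
   and proceeds through a max-heap, each pixel unwrapped against its
   best already-unwrapped 4-neighbour.  Temporal continuity: the seed of
   frame *t* is offset by the multiple of 2π that brings it within π of
   frame *t−1*'s value at the same location (nearest valid pixel if the
   mask moved).  The first frame is assumed wrap-free (|u| < 1/(2·ke) at
   the first acquired frame), so its wrapped phase is taken as unwrapped.
   Disconnected mask components are unwrapped independently and flagged.
   Ties in quality resolve to the lowest (row, col) index — determinism
   over elegance.

2. **Displacement** (`phase.to_displacement`): `u_d = phi_d / (2*pi*ke)`,
   in mm, sampled at the current pixel (Eulerian), pointing from the
   reference position to the current one.

3. **Tissue tracking** (`phase.track_trajectories`).  Material points are
   seeded on the reference-frame mask pixels.  For each frame the masked
   pixels x with computed reference positions `X = x − u(x)` form a
   scattered sample of the inverse motion map; `u` is interpolated over
   those reference positions (Delaunay linear interpolation) and evaluated
   at the seeds, giving `x_seed(t) = X_seed + u`.  Two boundary details
   matter on an annulus: (a) the Delaunay triangulation of an annular
   cloud spans the cavity, so queries landing in oversized simplices (any
   edge > 3 pixels) are *not* linearly interpolated; (b) those queries,
   and seeds marginally outside the hull at the wall rim, are extrapolated
   by a distance-weighted local quadratic fit over data points within
   3 pixels (≥ 8 points; linear with ≥ 4; otherwise the seed is invalid
   from that frame on).  A purely nearest-neighbour fallback leaves rim
   position errors of order 0.1 mm because the displacement field curves
   on the scale of the endocardial radius; the quadratic fit reduces them
   to below 0.01 mm.  Trajectories are optionally smoothed per coordinate
   by a least-squares polynomial in time (degree 6 by default, applied
   when ≥ 10 frames; configurable, including off).  The raw trajectories
   are kept alongside the fitted ones.

4. **Strain** (`strain.deformation_gradient`, `green_strain`).  For each
   point, the local motion `dx ≈ F dX` is fit by least squares over
   reference-configuration neighbours within 2.5 pixels.  Where ≥ 8
   neighbours exist the fit includes quadratic terms and `F` is the
   Jacobian of that local model: at the wall boundary the neighbourhood is
   one-sided and a purely linear fit is biased by field curvature, which
   at 1 mm spacing is the difference between per-point strain errors of
   ~0.02 and ~0.003.  For locally affine motion both fits coincide.
   Collinear or under-populated neighbourhoods flag the point invalid
   rather than raising.  `E = (FᵀF − I)/2`.

5. **Projection and endpoints** (`strain.polar_project`,
   `longitudinal_project`, `strain_summary`).  Short axis: `e_r` points
   from the LV center of mass (derived from the reference epicardial
   contour) to the point's reference position, `e_c` is `e_r` rotated +90°;
   `Ecc = e_cᵀEe_c`, `Err = e_rᵀEe_r`.  Long axis: `e_l` is the local
   tangent of the wall centerline (midline of each wall's points binned
   along the mitral-midpoint→apex axis, tangents by central differences).
   End systole is operationalized as the frame minimizing the whole-slice
   `Ecc` curve (the whole-slice `Ell` curve on the long axis); `Err` is
   read at that same frame for internal consistency.  Whole-slice means
   are unweighted means over valid points (not means of segment means);
   the three-slice "global" value is the unweighted mean of the three
   whole-slice values.  Global `Ell` is the mean of the end-systolic
   values of AHA segments 9 and 12, the two mid-ventricular segments a
   4-chamber view cuts.

6. **Segmentation bookkeeping** (`strain.assign_segments`).  AHA
   16-segment model: the angular origin is the ray from the LV center
   through the anterior RV-insertion landmark, angles grow
   counter-clockwise in image orientation; basal and mid levels use six
   60° sectors (ids 1–6, 7–12), the apical level four 90° sectors
   (13–16); sectors are half-open `[start, end)`.  The 4-chamber view maps
   each wall's basal/mid/apical thirds to segments 3/9/14 (septal side)
   and 6/12/16 (lateral side).  The angular convention is documented
   rather than claimed universal — published analyses differ in origin and
   rotation, which is precisely why segmental endpoints are sensitive to
   landmark placement.

7. **Twist and torsion** (`strain.compute_twist`, `compute_torsion`).
   Twist is the mean signed angle between `X − C` and `x(t) − C` over all
   valid points (counter-clockwise positive, apex-to-base viewing
   convention); all valid pixels contribute, not only midwall points.
   Torsion is the least-squares slope of end-systolic twist versus slice
   position in cm; with z increasing base→apex, counter-directional
   base/apex rotation yields positive torsion.  No radius normalization is
   applied — the unit is °/cm of long-axis distance.

## The synthetic phantom

The phantom exists to give every pipeline stage a closed-form oracle, so
controllability beats realism wherever the two conflict.

* **Short axis.**  A reference annulus (endo 25 mm, epi 35 mm at the base,
  radii tapering 10 % per 25 mm level; slices at z = 0, 25, 50 mm) deforms
  by the affine radial map `r(R,t) = a(t)R + b(t)` plus a rigid per-slice
  twist `psi(z,t)`.  Stretches are exact: `lambda_r = a`,
  `lambda_c = (aR+b)/R`; the rigid twist adds no in-plane strain.  The
  affine map decouples the transmural-mean `Ecc` and `Err`, which the
  calibration targets prescribe independently — an incompressible map
  could not hit both.
* **Calibration.**  `Err` is spatially constant, fixing
  `a = sqrt(2·Err+1)`.  The area-weighted transmural mean of `lambda_c²`
  has a closed form in `b`, so the `Ecc` target reduces to a quadratic;
  the root preserving a positive endocardial radius (and smaller |b|) is
  taken, and infeasible targets (strain ≤ −0.5, negative discriminant,
  collapsing endocardium) raise.  `b` is re-solved per slice position, so
  the subject has a uniform transmural-mean `Ecc` along the axis and a
  repositioned scan samples a consistent deformation field.
* **Septal dysfunction.**  An optional multiplier scales the deformation
  coefficients down over a raised-cosine angular window (half-width 90°)
  centred on the septum.  The map then acquires angular derivatives; the
  analytic strain includes those exact terms
  (`F = [[r_R, r_Θ/R], [0, r/R]]` in the reference polar basis), so the
  oracle property survives.  The septal pattern is a qualitative emulation
  with a configurable multiplier (patients default to 0.5), not a claimed
  reproduction of any measured segmental distribution.
* **Long axis.**  Two straight wall strips (cavity half-width 25 mm, wall
  10 mm, length 80 mm) under a uniform longitudinal stretch pinned at the
  apex: `Ell = (lambda_l²−1)/2` exactly, with
  `lambda_l = sqrt(2·Ell_target+1)`.
* **Time course.**  40 frames at 15 ms; activation
  `s(t) = sin²(pi·t/(2·t_es))` rising to 1 at `t_es = 345 ms`, then linear
  relaxation to 0.3 of peak by the last frame.  All deformation
  coefficients scale with `s(t)`.
* **Rendering.**  Default field of view 120 mm (the protocol's region of
  signal generation; also guarantees the four 8×8 corner patches used for
  noise estimation stay clear of the epicardium at 3.4 mm).  Per frame the
  deformed-annulus membership and Eulerian displacement are computed by
  exact inversion of the map; each direction's complex image
  `M0·exp(i·phi_true)` receives additive complex Gaussian noise (SD
  `noise_sd`, default 4.0 against `M0 = 100`, i.e. magnitude SNR 25,
  comfortably above the quality-control cut of 12) before magnitude/phase
  extraction.  Identical seeds give bit-identical series.
* **Cohorts.**  Subject-level strain targets are drawn from the
  healthy/patient group distributions (means ± SDs of the reference strain
  table); each subject is rendered twice, Scan B with all slice positions
  shifted by 2 mm and independent noise, emulating removal and
  repositioning between scans.

What the phantom does *not* emulate: spiral k-space acquisition and
off-resonance artifacts, through-plane motion, stimulated-echo T1 signal
decay, papillary muscles and trabeculation, irregular wall geometry, and
contouring error beyond the parametric mask perturbations.  Passing tests
therefore demonstrate the correctness of the analysis chain and the
behaviour of the statistics under controlled perturbations — not clinical
performance on real acquisitions.

## The emulated reproducibility study

Each "user" is a deterministic perturbation of the analysis inputs: mask
erosion/dilation in pixels, RV-insertion landmark rotation within a jitter
range (seeded draw), and an offset to the temporal smoothing degree.  A
zero-perturbation user reproduces the reference analysis bit-for-bit.  The
default design pairs: intra-user (reference vs. +1 smoothing degree, 1°
jitter), inter-user-same-site (1-px dilation, 3° jitter, −1 degree),
inter-user-different-site (1-px dilation, 5° jitter, −2 degrees),
inter-user-human-DL (a distinct mask-generation profile standing in for a
fully automatic analysis: 1-px dilation, 2° jitter, +2 degrees), and
inter-scan (reference analysis of Scan B).  The perturbation magnitudes
are chosen so the induced analysis differences are ordered intra-user <
inter-user < inter-scan, mirroring the design intuition that re-analysis
by the same user differs least and a separate acquisition differs most.

Masked pixels whose magnitude falls below 25 % of the median myocardial
magnitude are excluded before unwrapping: background swept in by a
generous contour carries no stimulated-echo signal, and feeding its random
phase into unwrapping corrupts the boundary.  This gate also makes mask
dilation a graded perturbation instead of a catastrophic one.  Erosion is
not a default at 3.4 mm because the apical annulus is only ~2 pixels wide
there and a 1-px erosion empties it.

Pairing for the statistics: unit-level endpoints (whole-slice `Ecc`/`Err`
per slice, global `Ell`, torsion per subject) pair directly.  Segmental
`Ecc` pairs pointwise by reference-pixel identity (intersection of the two
observations' seed sets, segments taken from the first observation); the
segment CV is the mean point CV over the segment, the pooled value is the
mean ± SD across subjects of their segment-mean CVs, and the segmental ICC
uses per-(subject, segment) mean strains as units so between-unit spread
exists.  Points whose pair-mean |strain| is below 0.02 are excluded from
CV averages (and counted): near-zero means make the ratio diverge, which
is also why septal segments — where dysfunction drives strain toward
zero — show inflated CVs when the floor is lifted.

## Statistics

* Bland–Altman: bias = mean(o₁−o₂); limits = bias ± 1.96·SD (sample SD,
  n−1).
* Duplicate CV per point: `(|x₁−x₂|/√2) / |(x₁+x₂)/2| × 100` %.
* ICC: one-way random, single measure — `(MSB − MSW)/(MSB + MSW)` for
  k = 2 — the most conservative common variant, chosen because
  reproducibility studies in this area rarely state the model; the 95 % CI
  is the standard F-distribution interval.  Zero between-unit variance is
  reported as computed with a degeneracy flag, never clamped.
* Bands: CV ≤ 10 excellent, ≤ 20 good, ≤ 40 fair, > 40 poor; ICC > 0.74
  excellent, > 0.6 good, ≥ 0.4 fair, < 0.4 poor.  The conventional band
  edges leave (0.59, 0.6] and exactly 0.4 textually unassigned; both are
  resolved to "fair" so the bands partition the line.

## Numerical choices and degenerate inputs

* Phase wraps into the half-open interval `(-pi, pi]`:
  `wrap(phi) = phi − 2π·ceil((phi−π)/2π)`, so +π is a fixed point and
  1.2π maps to −0.8π.
* Phase SNR = mean myocardial magnitude ÷ background complex-noise SD,
  the background SD estimated from the Rayleigh mean of four 8×8 corner
  patches (`sigma = mean/sqrt(pi/2)`); a zero-noise background reports
  +inf.  Series below 12 are discarded; a series exactly at 12 is kept
  (the discard rule is strict "less than").
* Seed selection, region-growing order and neighbour choice in unwrapping
  break ties by lowest (row, col).
* Moment matrices in the F fit are scaled by the neighbourhood radius and
  ridge-stabilized at 1e−12; collinearity is detected by the eigenvalue
  ratio of the linear sub-block.
* All study randomness derives from one master seed via `SeedSequence`
  plus a CRC of the (subject, user, scan) label, so adding a subject or
  comparison does not reshuffle the others.

## Validation problem sizes

The oracle-equivalence check runs the noise-free basal slice at 1 mm
spacing (~1 900 material points); strain-table recovery runs all three
short-axis slices and the long axis noise-free at 1.7 mm; the
radial-resolution property uses five noise seeds at the 3.4 mm protocol
spacing; the reproducibility-ordering check emulates ten healthy subjects,
three short-axis slices, duplicate scans and three comparison types over
five study seeds.  These sizes keep the full validation on a laptop-scale
budget while leaving every slice with enough pixels for the boundary
effects the tests are about.

## Known limitations

2D in-plane analysis only (no through-plane encoding or multi-slice
coupling during unwrapping); segmental `Err` and segmental `Ell` are not
endpoints (their reproducibility is known to be poor-to-fair and long-axis
segmental conventions are weakly standardized); the human-subject
reproducibility magnitudes of any real multicenter study cannot be
reproduced from synthetic data — the study emulator reproduces the design
and the orderings, not the published coefficients; DICOM ingestion is out
of scope (the HDF5 + JSON interchange container is the only on-disk
format).
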