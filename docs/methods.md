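# Methods

`ionrobust` studies how scanned proton and carbon-ion treatment plans for
skull-base targets degrade under small rigid setup errors, and whether
choosing beam directions that avoid density interfaces improves stability.
Because clinical planning CTs cannot be redistributed, the study runs on
synthetic phantoms that reproduce the geometric drivers of the effect.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic setting can and cannot show.

## Phantoms

A phantom is a relative water-equivalent density grid (water = 1, air =
1e-3) plus binary structure masks on the same grid, in the patient frame
(LR, AP, SI).  The skull-base archetype contains:

* a soft-tissue head ellipsoid bounded by an *external* contour; densities
  outside it are overridden with air, as is standard before particle-dose
  computation;
* an ellipsoidal CTV near the head center.  Default semi-axes of
  (20, 19, 17) mm with ±15 % per-axis seeded jitter give CTV volumes of
  roughly 17–41 cm³, inside the clinically representative 15.6–90.7 cm³
  band.  The population studies use (19, 18, 16) mm with ±10 % jitter
  (≈17–31 cm³), the lower-to-mid part of that band, to keep spot counts at
  desk scale;
* a bone slab (density 1.6) in the lateral entrance channel whose
  anteroposterior edge sits at the target midplane: lateral rays to the
  dorsal target half cross bone, ventral rays do not.  This is the
  "strong tissue interface transverse to the beam" failure mode.  The slab
  is limited in SI extent so cranially tilted beams can avoid it;
* a sinus-like air cavity anterior–inferior to the target;
* an abutting dorsal OAR ("brainstem", a SI cylinder clipped against the
  PTV so the two share faces but no voxels), paired lateral "optic nerves"
  and a midline "chiasm".

Interface densities and geometry are configurable, not canonical: there is
no accepted scalar definition of "severe heterogeneity", so the phantom
family declares one concrete operationalization.  Generation is a pure
function of (spec, seed).

**CTV→PTV margin.** Anisotropic expansion by 2 mm LR/AP and 2.5–3 mm SI
(3 mm for 3 mm slice spacing, else 2.5 mm).  A voxel joins the PTV iff its
center lies inside the ellipsoidal metric (semi-axes = margins) of some CTV
voxel center; this is implemented as binary dilation with a precomputed
structuring element and is exactly equal to the exhaustive per-voxel
distance test (tested on ≤32³ grids).

## Dose engine

Parallel (divergence-free) pencil beams — the standard simplification, and
what makes a shift along the beam axis exactly dose-neutral.  For a field
with direction d and transverse frame (u, v):

dose(x) = Σᵢ wᵢ · B(Rᵢ, WEPL(x) + bolus) · G(u(x) − uᵢ, v(x) − vᵢ; FWHMᵢ)

* **WEPL** is the midpoint-rule line integral of trilinearly interpolated
  density along −d, step 0.5 mm, from the grid bounding box to the voxel
  (accuracy about half a voxel at the boundary; exact slab phantoms agree
  with closed forms to < 1 mm).  Machine range limits default to
  20–300 mm WEPL.
* **B** is an analytic Bragg curve, not measured base data (none are
  published with typical machine libraries): an entrance plateau at
  0.30 (carbon) / 0.35 (proton) of the peak with a gentle quadratic rise, a
  Gaussian peak of height exactly 1 at depth = range (σ = 1.7 mm carbon /
  1.2 mm proton, emulating ripple-filter broadening so stacked layers at
  the 3 mm / 2 mm depth steps form a smooth SOBP), an erfc distal cutoff of
  the plateau, and an optional exponential fragment tail (off by default —
  with it on, the "< 1 % of peak at range + 5 falloff widths" contract
  would not hold).
* **G** is a 2-D Gaussian of the in-air spot FWHM, interpolated linearly in
  range between the machine endpoints (carbon 7.5→5.0 mm, proton
  11.0→5.5 mm); no depth broadening by default, since only in-air spot
  sizes are specified clinically.  The profile is cut off at 5 σ
  (3.7 × 10⁻⁶ of the axial value).
* **Raster placement**: energy layers every 3 mm (carbon) / 2 mm (proton)
  in WEPL covering the target's depth span; per layer, a transverse lattice
  at 2 mm / 3 mm pitch covering the bracketing voxels' projection dilated
  by tolerance × FWHM (default tolerance 0.7, the middle of the clinical
  0.4–1.0 band).  A target shallower than the minimum range without bolus
  is an error; a 20 mm water-equivalent bolus shifts all nominal ranges.
* **Superposition** is evaluated layer by layer (spots in a layer share
  range and FWHM): a depth-dose lookup table (0.05 mm sampling) applied to
  the WEPL volume, times a transverse fluence map.  For axis-aligned beams
  the fluence is evaluated exactly on the voxel lattice; oblique beams
  deposit on a 1 mm lateral lattice and interpolate bilinearly (≈1–2 %
  local smoothing).  The factorization is algebraically identical to the
  per-spot sum and is verified against a naive per-voxel triple-sum oracle.

**RBE.** Protons: fixed 1.1 applied after field summation, so the
weighted/absorbed ratio is exactly 1.1 everywhere.  Carbon: a monotone
piecewise-linear surrogate factor in residual range (3.4 at the end of
range falling to 1.3 at 300 mm), applied per spot-voxel inside the
superposition.  This is explicitly *not* a microdosimetric model; it
reproduces the qualitative behavior that matters here — RBE-weighted
optimization forces physical-dose modulation across the target and raises
the effective dose near the end of range.

## Inverse planning

Quadratic objective on RBE-weighted dose normalized by prescription: a
two-sided PTV term ((d − p)/p)², one-sided OAR overdose terms, and a small
one-sided "normal-tissue shoulder" term (weight 0.05) on a 4-voxel shell
around the PTV that keeps the 95 % isodose conformal.  Near-max OAR
constraints exclude the allowed hottest volume fraction (brainstem: 1 % may
exceed 54 Gy(RBE) carbon / 60 proton, but never the surface limit 60 / 63).
Penalty weights (PTV 1, OAR 40, normal 0.05) are configuration values; the
clinical trade-off they encode is that OAR limits are near-hard.

Modes: `uc` joint optimization without OAR terms; `mc` (IMPT) joint with
OAR terms; `sc` (SFUD) optimizes each field separately to a uniform
prescription/n_fields target with OAR limits scaled by the same fraction,
then sums.  Solver: L-BFGS-B with exact non-negativity bounds (projection,
not post-hoc clipping), uniform initialization at the weight giving mean
PTV dose = prescription, at most 500 iterations and a relative-change stop
of 1e-9 (a looser 1e-6 stop left OAR excesses above the reporting
tolerance).  Everything is deterministic.  Infeasible constraint sets are
not errors: the optimizer returns the best compromise, as clinical systems
do.

Prescriptions default to 60 Gy(RBE) in 20 fractions (carbon) and
66 Gy(RBE) in 33 fractions (proton), representative midpoints of the
clinical ranges for these indications.

## Robustness battery

Setup errors are simulated as rigid translations of the irradiation fields
with respect to the density grid: spot lateral positions move by the
shift's transverse component per field, WEPL and structures stay fixed,
weights are frozen.  Indices are always evaluated against the unshifted
masks (the field-shift formulation implies this reading).  Consequences,
all tested: zero shift reproduces the planned dose bit-exactly; a shift
along a field's axis is exactly dose-neutral; in homogeneous media a
transverse shift translates the dose pattern rigidly.

The shift set enumerates all vectors with components in {0, ±c}, equal in
absolute value where nonzero, with 3-D magnitude in {1, 2} mm — 52 vectors,
26 per magnitude (6 + 12 + 8).  Δ indices are signed (shifted − initial), so
a coverage loss appears negative.  Population summaries report
median/quartiles/extrema and the fraction of shifts with |ΔV95|, |ΔHI| <
1 pp and |ΔD| < 2 Gy(RBE).  Paired comparisons use the two-sided exact
binomial sign test with ties dropped (the classical convention).

## Beam-direction selection

The clinical practice of visually picking entrance channels free of density
interfaces is operationalized as a WEPL-spread score: for each target
voxel, trace the WEPL along the candidate direction at the voxel and at its
images under the 1 mm shift-set members projected transverse to the beam,
and take the spread (max − min); the score is the mean over target voxels
(max aggregation available).  Spreads are computed on *water-excess* WEPL
(WEPL minus the unit-density geometric path in the grid) so a uniform water
block scores exactly zero at every incidence angle and the score measures
density structure, not entry-face obliquity.  Candidates span couch yaw
0–60° cranial × inclination ±45° about the SI axis on both lateral sides
(5° grid by default; the population studies use 15° with 2 mm ray sampling,
which does not change the ranking on these phantoms).  The two-beam setup
minimizes the total score subject to ≥30° pairwise separation, exhaustively,
with enumeration-order tie-breaks.  OAR geometry is deliberately ignored at
this stage; OARs are handled downstream by the optimizer.

## Problem sizes and determinism

Default study sizes: water benchmark 56³ voxels at 2 mm with a 24 mm cubic
CTV; population phantoms 52×52×44 at 2.5 mm, 10 seeds, mc plans, the eight
2 mm shifts transverse to the LR axis.  These sizes were chosen so a full
population comparison runs on a laptop-class single core in minutes while
keeping ≥10³ voxels per structure for stable DVH statistics.  All
randomness (phantom jitter) flows from explicit seeds; planning and dose
computation are seed-free and deterministic, so identical configurations
reproduce byte-identical reports.

## What the synthetic setting shows — and what it does not

The phantoms reproduce the *mechanism*: range perturbation from interfaces
transverse to the beam, coverage loss bounded by margin geometry, and the
advantage of heterogeneity-avoiding directions.  The published per-patient
index values from clinical CTs are not reproducible here and are not
targeted; only directional/structural findings are asserted (e.g. ROB
setups lose less coverage than LR under transverse shifts on phantoms with
lateral interfaces).  Real anatomies add features the phantoms lack:
continuous Hounsfield-to-stopping-power spectra, curved multi-scale
interfaces, immobilization devices (deliberately excluded), rotational
setup errors (out of scope), and fractionation averaging.  Passing tests
therefore validate the pipeline's mechanics and the qualitative physics,
not clinical index magnitudes.

## Known limitations

* Analytic Bragg curves and a surrogate carbon RBE table — adequate for
  Δ-index comparisons, not for absolute Gy(RBE) accuracy.
* No nuclear fragmentation build-up, scatter kernels, or Monte Carlo
  transport; no depth widening of the lateral spot profile by default.
* Parallel-beam geometry (no divergence); isocentric effects of couch
  rotations are reduced to the direction vector.
* The SFUD recipe (uniform prescription/n per field, proportionally scaled
  OAR limits) is one of several defensible readings of per-field
  modulation.
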