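# Methods

`ventriband` simulates the mechanics of a dilated right ventricle (RV)
before and after pulmonary valve replacement (PVR) augmented with
*contracting bands*: cable-like elements spanning the RV cavity whose
zero-stress length shortens actively during systole. The single outcome
measure is the RV ejection fraction, EF = (EDV − ESV)/EDV × 100, and its
change ΔEF = EF(band model) − EF(baseline). This note records the model,
its assumptions, the synthetic-data design, numerical choices, and known
limitations.

## Geometry: an idealized bi-ventricle in place of patient CMR

Real studies of this kind segment short-axis CMR stacks per patient. No
imaging data ships with this package; instead `geometry.generate_contour_stack`
produces a *synthetic segmented stack*: a truncated ellipsoid of
revolution for the LV endocardium (equatorial radius 25 mm, long semi-axis
60 mm at reference size, truncated at 0.5·c above and 0.9·c below the
equator), a 10 mm LV wall, and a crescent RV wrapped around the LV
epicardium over a 150° span with a 5 mm free wall. The free-wall bulge
amplitude is solved (Brent's method on the Simpson volume) so the RV
cavity matches a prescribed volume; dilated TOF-like ventricles
(200–670 ml) are produced simply by large targets. Per-patient geometries
scale isotropically with (EDV/204 ml)^{1/3} while wall thicknesses stay
absolute (dilation thins the wall relative to the cavity).

Conventions: long axis = +z, slices apex→base, lengths in mm, volumes in
ml, pressures converted mmHg→kPa (1 mmHg = 0.133322 kPa) at the geometry
module's boundary. Contours are sampled at 100 points per slice by
default, matching the endocardial stress-sampling density.

Cavity volumes from stacks use Simpson's rule over slice areas
(`scipy.integrate.simpson`); on meshes they use the divergence theorem
over the deformed endocardial surface closed by flat basal/apical caps.

## Meshing

`meshing.build_mesh` resamples each slice onto a common angular grid about
the LV centroid and builds trilinear hexahedra with exactly two
through-wall layers (inner/outer), the construction that carries the
two-layer fiber model. Sampled radii are inflated by
√((2π/N)/sin(2π/N)) so inscribed polygons carry the continuum
cross-sectional areas. The crescent free wall collapses onto the LV
epicardium at its angular junctions and apical extent
(wedge-degenerate hexahedra with positive Gauss-point Jacobians), which
closes the RV cavity without special casing. Element labels:

* `layer` ∈ {inner, outer};
* `region` ∈ {LV, RV, septum, scar, patch}: LV-wall elements facing the
  RV cavity are the septum; scar and patch are parameterized windows on
  the RV free wall (defaults: two 25%-span × 30%-height windows in the
  basal half, the synthetic analogue of surgeon-identified patch/scar).

Fibers are helix angles from the local circumferential direction toward
the long axis: LV/septum −60° (outer) / +80° (inner); RV free wall
−45° / +40°, values from the diffusion/histology literature commonly used
when patient fiber imaging is unavailable.

## Material model

Tissue is hyperelastic, anisotropic, nearly incompressible:

W = c₁(I₁−3) + c₂(I₂−3) + D₁[exp(D₂(I₁−3)) − 1] + (K₁/K₂)[exp(K₂(I₄−1)²) − 1]

with I₄ = n_f·C n_f the squared fiber stretch. Two deliberate choices:

* **K₂ inside the exponential.** The fiber term is implemented as
  (K₁/K₂)[exp(K₂(I₄−1)²) − 1]; the variant with a bare exponent is
  available via `k2_in_exponent=False`. With K₂ ≈ 3 dimensionless, the
  K₂-inside form is the standard exponential fiber law and the only one
  in which K₂ is not redundant.
* **Isochoric split.** The deviatoric energy is evaluated on isochoric
  invariants (J^{−2/3}-scaled) with a volumetric penalty κ/2 (J−1)²,
  κ = 1000·c₁ per element. On incompressible states (det C = 1) this
  coincides with the plain form above, and it makes the reference
  configuration exactly stress free, which the plain invariants with a
  pure penalty would not.

Fibers bear no compressive load (the anisotropic term is active only for
I₄ > 1). c₂ = 0 in every shipped parameter set but is kept for
generality. The packaged table (`data/materials.csv`) carries the
reference parameter values per region and cycle phase: stiff
"end-ejection" rows (myocardium inner layer c₁ = 7.64 kPa, K₁ = 36.55 kPa)
and compliant "end-filling" rows (c₁ = 2.78 kPa, K₁ = 13.29 kPa);
isotropic patch (26.52/26.52/9.0), scar (half the patch), and band
(c₁ = 900 kPa systolic / 70 kPa diastolic).

**Active contraction by parameter switching.** Myocardial contraction
enters through the phase-dependent parameter sets, blended linearly in a
half-cosine systolic weight w(t) (0 at begin ejection, 1 at begin
filling), not through an added active-stress term; the reported states
are the two anchors, for which only the endpoint parameter sets matter.

## Loading and boundary conditions

Cavity pressures are prescribed on the RV and LV endocardium as follower
loads on the deformed surface; the epicardium is traction free. The
two-phase waveform (half-cosine fall over the systolic fraction 0.4 of
the cycle, half-cosine rise over filling, 30 samples per cycle) is a
parametric stand-in for a recorded pressure trace; its extrema are the
patient's peak RV pressure and a 4 mmHg diastolic minimum (RV diastolic
pressures are low and unreported; the exact minimum only shifts the
calibrated systolic stiffness scale). LV peak pressure defaults to
120 mmHg (also unreported; the LV is not calibrated — the RV is the
studied chamber). Cycle phase 0 is *begin ejection* (maximum pressure,
EDV); the minimum-pressure sample is *begin filling* (ESV). Isovolumic
phases are not modeled.

The base ring is fixed longitudinally (u_z = 0) with in-plane freedom,
plus two in-plane pins that remove the remaining rigid-body modes; net
in-plane pressure loads vanish by construction (the only open surface is
the flat base), so the pins carry no structural load.

Inertia is dropped: loading is a prescribed-pressure sequence, tissue
density is not part of the parameter set, and only configuration states
are reported, so each time point is a quasi-static equilibrium. A
consequence worth stating: the solution at each time point is unique
given the load, so consecutive cycles are identical to solver tolerance
and the periodic-convergence metric falls below 0.1% at the second cycle
(a dynamic code needs a few cycles; this one needs two by construction).

## Discretization and solver

Total-Lagrangian trilinear hexahedra, 2×2×2 Gauss quadrature. The
volumetric penalty uses **mean dilatation** — κ(J̄−1) with J̄ the
element-averaged Jacobian — because the pointwise penalty volumetrically
locks trilinear elements (verified on the thick-sphere benchmark: 15%
under-inflation pointwise vs 0.1–0.2% with mean dilatation). The
consistent tangent adds the rank-one κV₀ (∂J̄/∂u)(∂J̄/∂u)ᵀ coupling; the
material tangent dS/dC is obtained by forward finite differences of the
analytic stress (consistent to ~1e−7, preserving Newton convergence to
the 1e−6 relative-residual tolerance), and the follower-pressure load
stiffness is assembled analytically. Newton iteration uses a
backtracking line search on the residual norm and adaptive load stepping
between the previous and target load states; failed increments are
halved down to 1e−3 of the step.

Default mesh resolution is an 8 mm circumferential edge length scaled
with heart size (≈ 600–700 elements, two element layers through the
wall, slice-spacing axial resolution); a full 21-model single-patient
battery at this resolution runs in a few minutes on one CPU. Verification:
the pressurized thick-walled incompressible sphere (octant mesh, symmetry
BCs) reproduces the classical closed-form inflation relation to well
under 1%.

## Preshrink and calibration

In-vivo contours are acquired under load. The zero-load geometry is
recovered by shrinking endocardial contours 3% toward their centroids
(the stated 2–3% range; the fallback 3% is used because the subsequent
stiffness calibration already enforces the end-systolic volume match that
would otherwise select the rate), compressing the slice stack 3% along
the long axis, and solving a single epicardial scale factor (Brent) so
the total wall volume is conserved — enforced globally, since the
conservation statement concerns the *total* ventricular wall. For the
crescent rings the septal radius follows the scaled epicardium and the
free-wall bulge scales with the endocardial rate, which keeps the stack
meshable and makes the operation exactly invertible.

Calibration then adjusts one joint multiplicative scale on (c₁, D₁, K₁)
of the ventricular tissue per anchor phase — preserving the table's
internal ratios rather than moving three parameters independently — by a
secant iteration on the log-scale until the pressurized RV volume matches
the target to 0.2% relative error: the systolic set against ESV under the
minimum pressure, the diastolic set against EDV under the peak pressure.
Volume is strictly decreasing in the scale, so the secant converges in a
handful of iterations; full-cycle recalibration is unnecessary because
the anchors are the only reported states.

## Bands

A band is a tension-only cable between two RV free-wall endocardial
attachment nodes (default cross-section 10 mm², a plausible surgical
band; the value is a free design parameter and scales the effect size).
Its reference length L is the path length in the baseline model's
begin-filling (end-systolic) state — the configuration in which models
are built from end-systole imaging — and its zero-stress length follows
the periodic schedule L·(1 − r·w(t)): 100%L at the diastolic anchor,
(1−r)·L at peak systole for contraction ratio r ∈ {0, 10, 15, 20}%.
The axial force is the incompressible neo-Hookean cable law
N = 2c₁A₀(λ − λ⁻²), λ > 1 only.

The passive/active asymmetry that drives the study's central finding is
material, not kinematic: an *active* band follows the phase-blended band
material (900 kPa systolic, 70 kPa diastolic — "active relaxation"),
while a *passive* band (r = 0) keeps the stiff systolic material
throughout and therefore resists diastolic expansion. This reproduces the
reported volume signature: passive bands reduce the begin-ejection (EDV)
volume with little effect at begin filling, active bands reduce the
begin-filling (ESV) volume while leaving EDV within 1% of baseline.

Five plans: A (anterior mid-level band), B (posterior mid-level), C =
A+B, D (band at the papillary-muscle base level), E = A+B+D. The
idealized geometry has no papillary muscles; the anchors are
parameterized span/height fractions documented in `plans.PLAN_BANDS`
(A: 0.10–0.55 of the span at 0.55 height; B: 0.45–0.90 at 0.55;
D: 0.10–0.90 at 0.30). Per patient: 1 baseline + 5 plans × {passive,
10%, 15%, 20%} = 21 models.

## Outcome extraction and statistics

EF uses the cavity volumes at the two anchors (begin ejection = EDV,
begin filling = ESV). Stress/strain model values are means of the maximum
principal Cauchy stress and Green–Lagrange strain over 100 evenly spaced
(arc-length) points per slice of the RV endocardial surface, interpolated
from node-averaged element tensors. Cohort rows report mean ± sample SD
(n−1 denominator, validated against the reference table's clinical
column). Plans are compared with the exact two-sided paired Wilcoxon
signed-rank test: the full 2ⁿ sign-assignment null distribution (built by
polynomial convolution over doubled ranks; zeros handled by Pratt's
method, ties by average ranks), appropriate at n = 7 where the asymptotic
test is meaningless; seven uniformly positive differences give
p = 2/2⁷ = 0.015625.

## What the synthetic data does and does not show

The generator reproduces the study *conditions*: per-patient EDV/ESV/peak
pressure magnitudes, two-layer walls with literature fiber angles,
scar/patch inserts, and the loading protocol. It does not reproduce
patient *shapes* — no outflow tract, trabeculation, or per-patient
asymmetry — so per-patient EF values and band lengths are not
reproduced numerically; what carries over is the qualitative pattern
(passive ΔEF < 0 ≤ active ΔEF, monotone in r, more bands stronger), which
the tests assert on a 3-patient cohort, and the order of magnitude of
wall stress (~60 kPa at begin ejection, ~4 kPa at begin filling).
Band effect sizes are larger than on patient geometries (a chord across
an idealized crescent is mechanically efficient), so ΔEF magnitudes
should be read as scaled-up analogues, not predictions.

Known limitations:

* The crescent geometry with the exponential material saturates passive
  inflation near a volume doubling; patients with EDV/ESV ≳ 1.8
  (EF ≳ 45%) have no calibrated solution on this geometry and are
  excluded from synthetic cohorts (`reference_cohort` filters them).
  Patient-specific CMR shapes, which the original workflow uses,
  accommodate larger volume excursions at lower strain.
* Structure only: no fluid–structure interaction, valve dynamics, or
  flow energetics; EF from a pressure-driven structural model is the
  stated scope.
* Quasi-static: no inertia or viscoelasticity; rate effects in the band
  transition are not modeled.
* Coarse default meshes (two elements through-wall) are resolution
  choices for desk-scale batteries; stress extrema are resolution
  sensitive even though cavity volumes (hence EF) converge quickly.
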