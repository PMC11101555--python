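# Methods

## Physical model and assumptions

Paravalvular leakage is modelled as stationary, incompressible,
pressure-driven viscous flow in the thin gap between the deployed stent
frame and the aortic root.  Four assumptions reduce the problem to a
surface PDE:

1. **Diastolic, quasi-steady flow.**  Leakage matters while the valve
   is closed; the transvalvular pressure difference is taken constant
   at the mean aortic pressure (MAP) over diastole.
2. **Newtonian blood**, viscosity μ = 0.0035 Pa·s, density
   ρ = 1060 kg/m³.
3. **No inertia/turbulence** in the gap: a Poiseuille profile across
   the gap thickness.
4. **Thin film**: the gap width h is small compared with the lateral
   extent of the leakage paths, so the Reynolds lubrication equation
   holds on the mid-gap surface Ω:

       ∇·[ (h³/12μ) ∇p ] = 0  in Ω,     q = −(h³/12μ) ∇p,

   with q the in-plane volumetric flux per unit width (m²/s).

These assumptions exclude transient effects, wall compliance,
non-Newtonian rheology and jet inertia below the valve; the model is a
screening tool, not a replacement for CFD where those effects matter.

## Geometry: slice stacks and the mid-gap shell

The gap is described by a *slice stack*: at each axial height z_k the
inner (stent) and outer (wall) boundaries are sampled as radii
R_i(θ_j), R_o(θ_j) on a common set of angular stations.  Stacks come
from the parametric generators, from slice-stack files (JSON/CSV), or
from ray-sampling a pair of STL surfaces (farthest stent hit, nearest
wall hit beyond it; lumina that are not star-shaped with respect to the
chosen axis are outside the method's scope and raise errors rather than
silently mis-sampling).

Contact is encoded as R_i ≥ R_o; the gap h = max(R_o − R_i, 0) is
clamped at zero.  The stack is lofted into a triangulated shell at the
radial midpoint r_m = (R_i + R_o)/2 with one node per station, periodic
closure in θ, nodal gap field taken from the stack without smoothing,
and the top/bottom slices as the inlet (aortic, high pressure) and
outlet (ventricular) Dirichlet sets.

Slice areas use the periodic trapezoid rule on ½·max(R_o²−R_i², 0);
the leakage volume V = Σ A_k Δl_k uses half-spacing weights at the end
slices so the weights sum exactly to the axial length.  Default
sampling is 64 slices × 256 stations; both converge at least second
order in resolution (exponentially for smooth profiles), so coarser
sampling is usually adequate.

## Finite-element discretisation

Linear (P1) triangular shell elements.  Each triangle is mapped to an
orthonormal 2-D frame in its own plane (first edge + normal; the
assembled matrix is invariant to the in-plane basis choice, which is
enforced by a rotation test).  The gap is interpolated linearly from
the nodes and the element conductance c = h³/12μ is evaluated at
quadrature points: a one-point (centroid) rule by default, with an
optional three-point mid-edge rule (`quadrature="midedge"`); on smooth
gap fields the two differ well below the geometric discretisation
error.  The stiffness matrix is symmetric positive-semidefinite with
the constants as its nullspace; Dirichlet rows are eliminated and the
reduced SPD system solved by sparse LU by default, with a
Jacobi-preconditioned conjugate-gradient fallback (`solver="cg"`,
relative tolerance 1e-12) for very large meshes.

**Contact regularisation.**  Nodal gaps are clamped below at
ε = 1e-9 m before assembly.  Zero-gap (contact) regions therefore act
as extremely high — but finite — resistances: dead-end and fully
blocked paths stay in the system instead of making it singular, and a
fully occluded channel reports a tiny ε-limited flow together with a
runtime warning instead of silently returning zero.  ε is far below
any physically meaningful gap (nm scale), so open-channel results are
unaffected.

**Flow-rate extraction.**  The flow rate is the consistent-flux
(boundary-residual) functional of the Galerkin solution.  It is
evaluated in two algebraically identical forms: per-boundary residual
sums Q_in, Q_out (whose agreement, typically ~1e-13 relative, is the
conservation diagnostic) and the dissipation form
Q = Σ_e A_e |q_e|²/c_e / Δp, a sum of non-negative element terms that
remains accurate when a blocked channel drops the flow many orders of
magnitude below the open-gap scale and cancellation swamps the
residual sums.  The reported Q is the dissipation form.  A direct line
integration of q·n across a mid cross-section is computed as an
independent check; a >1 % disagreement triggers an under-resolution
warning.

## Orifice-consistent pressure scaling

Driving the shell with the raw MAP treats the leak as a full annular
die; physically it is closer to an orifice.  The boundary pressure is
rescaled in five deterministic steps (all recorded in the
`ScalingReport` trace):

1. select the slice with the smallest maximum gap among slices with
   positive area (ties → smallest z); this is the throttling slice;
2. orifice flow Q_B = C_d √(2Δp/ρ)·A₂(1−(A₂/A₁)²)^(−1/2) with Δp the
   unscaled MAP, A₂ the selected slice's area, A₁ the aortic
   cross-section;
3. invert the annular-die relation Q_c(Δp) — evaluated by the periodic
   trapezoid rule over the slice's stations, linear in Δp, so the
   inversion is exact division — for the pressure that would drive Q_B
   through a die shaped like that slice over the full axial length L;
4. volume correction f_V = A₂L / V;
5. Δp_app = f_V · Δp_inverted, applied at the inlet above the
   reference pressure p₀.

The annular-Poiseuille bracket is used in the orientation
Φ(B) = 1 − B⁴ − (1−B²)²/ln(1/B), which is positive on 0 < B < 1 (the
same expression is sometimes printed with the opposite sign); Φ → 1 as
B → 0 recovers pipe Poiseuille flow and Φ → 0 at contact.  All steps
are linear in Q_B, so scaling the MAP by s scales Δp_app by √s; for
axially uniform stacks f_V = 1 exactly.

Defaults, configurable throughout: C_d = 0.61 (sharp-edged orifice),
A₁ from a 25 mm aorta diameter (both should be patient-specific in
real use), p₀ = 0, MAP = 100 mmHg, heart rate 70 bpm, diastolic
fraction 0.65.  Unit conversions are exact (1 mmHg = 133.322 Pa); the
classic die-verification case is conventionally quoted at the rounded
13.32 kPa, and that value is used when reproducing it.

## Severity grading

RV = Q · (60/HR)·f_dia, graded on the Kappetein scale.  The published
class bounds leave [59, 60) ml unassigned ("30–59" vs "> 60"); this
package takes moderate = [30, 60) ml so the scale is gapless, and
reserves "none" for exactly RV = 0.

## Synthetic geometries

The generators stand in for segmented post-deployment geometries in
every test, with closed-form behaviour:

- **Annular die** — uniform gap; closed-form flow for verification.
- **Eccentric annulus** — R_i(θ) = e·cosθ + √(R_i²−e²sin²θ); smooth
  θ-varying gap, tangency at e = R_o − R_i.
- **Nodule annulus** — separable cosine bumps (C¹) on the stent
  boundary, parameterised by radial protrusion d_r, circumferential
  arc d_c and axial extent; overlaps combine by max; the ISO 5840
  bench nodule (d_r = 2 mm, d_c = 4 mm) is predefined.  The bump shape
  beyond (d_r, d_c) is a modelling choice; any smooth compact bump
  would do.
- **Pocket channel** — flat strip with a rectangular deeper pocket and
  a *linear* ramp, so the controlled quantity max|∇h| equals
  (h_pocket−h_base)/transition_length exactly; used to exercise
  gap-gradient sensitivity.

What these do **not** emulate: real calcification morphology, stent
strut imprints, segmentation noise, or wall compliance.  Passing tests
on them validates the numerics (discretisation, conservation,
scalings, the scaling pipeline), not the fidelity of any particular
patient geometry.

## Verification summary

- Closed-form die flow (10/11/30 mm, 13.32 kPa, μ = 0.0035):
  697.5 ml/s; the FE shell solve gives 697.4 ml/s (0.02 % apart,
  within the ~(h/r_m)² ≈ 1 % thin-film error budget), with < 0.1 %
  change from a 128×32 to a 256×64 mesh.
- The FE solver agrees with an independent finite-volume
  resistor-network solver to < 0.05 % on θ-varying gaps.
- Exact invariants checked to near machine precision: Q ∝ Δp, Q ∝ h³
  for uniform scalings, inlet/outlet conservation, die-inversion round
  trip, f_V = 1 on uniform stacks.

Problem sizes in the shipped tests and the acceptance script (up to
256×64 stations, ~16k nodes) were chosen as the point where the die
verification is converged to 0.1 %; the solver itself handles much
finer meshes.

## Known limitations

- Thin-film validity degrades as h/r_m grows; the die case at 0.1 is
  near the practical upper end.
- Single-ray slicing assumes a star-shaped lumen about the device
  axis.
- The severity grade inherits the strong h³ (and R⁴ in the scaling
  step) sensitivity to gap segmentation accuracy; small segmentation
  errors move RV substantially.
- The scaled boundary condition depends on which slice is selected;
  geometries whose narrowest slice is atypical of the channel can
  over- or under-scale the pressure.
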