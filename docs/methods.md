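# Methods

`vesica` post-processes MRI urodynamics of bladder voiding: two segmented
bladder surfaces (pre- and post-void, STL, millimetres) plus an optional
real-time bladder-area curve are turned into a wall-displacement field,
regional/asymmetry statistics, voiding kinematics, and a simplified
two-dimensional simulation of the intravesical flow the wall motion drives.

## The radial separable wall-motion model

A spherical frame is anchored at the volume centroid of the post-void
bladder (computed by exact tetrahedral decomposition of the closed surface,
not a vertex mean, so it is independent of how densely the segmentation
sampled each region). In that frame the bladder-wall displacement is modelled
as purely radial with separable space and time dependence:

    d_r(θ, φ, t) = d0(θ, φ) · α(t),        d_θ = d_φ = 0,

where d0 is the total displacement between the pre- and post-void surfaces
along the ray (θ, φ) and α runs from 0 at the start of voiding to 1 at the
end. This is the same family of simplifications used for cardiac-chamber
wall-motion estimation; it is valid only for surfaces that are star-shaped
about the chosen origin, which the implementation enforces by failing when
more than 5 % of the radial rays do not cross a surface exactly once (the
nearest crossing is used and flagged when a ray crosses several times).

d0 is measured by ray casting with the Möller–Trumbore ray–triangle
intersection algorithm (authored here, vectorised over faces; it is
cross-checked in the tests against an independent 3×3 linear-system
intersector on 10⁴ random ray/triangle pairs). Sampling directions default
to the pre-void vertices — which makes the field directly usable for
geometry interpolation, vertex i ↔ sample i — with a Fibonacci-sphere
`uniform_sphere(n)` mode for mesh-resolution-independent statistics.
`d0 = r_pre − r_post` is positive for inward motion; negative values are
retained in the statistics.

### Regions and asymmetry

Each sample carries three independent binary labels from the sign of its
direction in the anatomical frame: anterior/posterior (y), dome/base (z),
left/right (x); exact boundary samples (|component| < 1e-12) go to the
positive side for determinism. Regional five-number summaries use linearly
interpolated quartiles. The left–right asymmetry ratio is

    100 · |median_L − median_R| / ((median_L + median_R) / 2).

The normalisation by the mean of the two medians was chosen because reported
asymmetries in this setting reach well beyond 100 %, which a max- or
single-side denominator cannot produce symmetrically; with this form a
gain of g between sides gives 200(g−1)/(g+1) %, saturating at 200 %.
Displacement probability densities are Gaussian KDEs (SciPy, Silverman
bandwidth); a zero-variance sample degenerates to a flagged point mass.

## Voiding time dependence α(t)

From a real-time area curve A(t) (mid-sagittal cross-section, mm²):

    α(t) = sqrt( (A(t) − A(t0)) / (A(tend) − A(t0)) ),

clipped to [0, 1] (the square root amplifies noise near t0, where the
numerator can go slightly negative). Smoothing before the ratio is a
5-sample moving average, applied **adaptively**: a median-based diagnostic
compares third to second differences (i.i.d. noise gives a ratio near
√(20/6) ≈ 1.8, a smooth trend a ratio of order the sample spacing) and the
moving average is skipped for already-smooth curves. This keeps the
noiseless algebraic identity exact — applying the area-ratio formula to the
curve induced by the canonical α reproduces it to 1e-12 — while still
stabilising noisy measurements.

The canonical parametric form, used when no real-time curve exists for a
subject (only one of the healthy subjects in the motivating protocol had
real-time imaging; the same α was reused for the others, supported here via
`alpha="canonical"`), is the square root of a raised cosine:

    α(t) = sqrt( (1 − cos(π·τ)) / 2 ) = sin(π·τ/2),   τ = (t − t0)/(tend − t0).

Its induced area curve A0 + (Aend − A0)·α² is exactly the sigmoidal raised
cosine observed in real-time imaging, with the area changing slowest at the
start and end of voiding. Note the corollary for the *volume* rate: since
α̇(t0) = π/(2T) ≠ 0, the flow rate Q = −dV/dt does **not** vanish at t0
under this model; Q is maximal near the start and decays to 0 at tend. Only
the area rate is slow at both ends.

`fit_sqrt_cosine` recovers (t0, tend) of this form from a measured α curve
by Levenberg–Marquardt least squares (duration parametrised as log T to keep
tend > t0).

### Voiding-window detection

The coarse rule marks t0 as the last sample before the smoothed area first
drops 1 % of the total change below its start value, and tend as the first
sample within 1 % of the end value. On a sigmoidal curve these crossings lag
the true endpoints by (2/π)·asin(√0.01) ≈ 6.4 % of the voiding duration by
construction — the curve is flattest exactly at the endpoints — so the
default detector refines the coarse window by least-squares fitting the
raised-cosine area model seeded from it, which reaches sample precision on
clean curves and stays within two sample intervals at 1 % noise.
`refine=False` returns the bare threshold crossings.

### Kinematics

Geometry at time t moves every pre-void vertex radially toward the origin by
d0·α(t) (topology unchanged; α = 0 returns the pre mesh bitwise). V(t) is
the exact mesh volume of each interpolated geometry; Q(t) = −dV/dt by
central differences (no spline fitting, so the integral of Q telescopes back
to the volume change: conservation holds to < 0.5 % on all fixtures).

## Synthetic fixtures

No imaging data accompany the package, so fixtures are generated:
icospheres (star-shaped by construction) at full-bladder scale — default
pre-void radius 42 mm ≈ 310 mL, in the plausible range for a fluid-challenge
protocol — with three displacement patterns:

- **uniform**: d0 = shrink_fraction·r_pre everywhere;
- **dome_weighted** (healthy-control-like): the uniform displacement scaled
  by 1 + (dome_gain − 1)·max(0, cos θ_dome), dome-dominant as in healthy
  voiding; defaults shrink 0.5, dome gain 1.5;
- **asymmetric** (BPH-like): the left hemisphere scaled by asym_gain with a
  smooth 10°-wide blend band at the midplane (a hard seam would be
  unphysical and ill-posed for ray-casting recovery); defaults shrink 0.15
  — walls moving ~30 % as far as the control fixture, matching the reported
  25–50 % range for obstructed voiding — and gain 1.8, giving a 57 %
  asymmetry against the controls' few percent.

Ground truth (the analytic d0 function, hemisphere medians from a dense
Fibonacci sampling, and the implied asymmetry) accompanies every pair. Area
curves are the induced raised cosine with optional i.i.d. additive Gaussian
noise (no noise model is established for real-time area measurements; i.i.d.
Gaussian is the neutral choice), seeded for reproducibility, with optional
flat plateaus for window-detection tests.

What the fixtures deliberately do not emulate: segmentation error, partial
volume effects, non-star-shaped anatomies (median-lobe intrusion), true
detrusor mechanics, or tangential wall motion. Passing the recovery tests
therefore shows the estimator is exact for data generated by its own model
class, plus faceting error — not that real bladders satisfy the radial
model.

## The 2D voiding-flow simulation

The motivating 3D patient-specific simulations used a commercial cut-cell
adaptive-mesh solver; this package deliberately replaces that with a
desk-scale two-dimensional mid-plane solver, and all flow comparisons are
internal and ordinal — never numeric against 3D results.

**Domain.** Each interpolated voiding geometry is sliced by a chosen frame
plane (sagittal `normal="x"` by default; coronal `normal="y"` puts the
left–right asymmetry in-plane). Because the radial motion maps planes
through the origin onto themselves, the contour sequence is consistent with
the 3D kinematics. Contours are stored as star-shaped radius functions
r(θ, t_k) on a uniform 360-point θ grid. A rigid straight channel of
diameter D (prostatic urethra; user input, default 6 mm) and length L
(default 20 mm) is grafted at the inferior pole, reaching up just inside the
final bladder contour so the domains stay connected; the outlet at its far
end is at zero gauge pressure (atmospheric). Fluid defaults: water at body
temperature (ρ = 1000 kg/m³, μ = 0.7 mPa·s).

**Solver.** Incompressible Navier–Stokes on a uniform staggered MAC grid,
fractional-step with *incremental* pressure correction: explicit first-order
upwind advection, implicit (backward Euler) diffusion, exact discrete
projection via a sparse direct factorisation (operators are cached and
rebuilt only when a cell changes phase or dt is re-adapted). The moving
bladder wall is a direct-forcing staircase immersed boundary: faces between
fluid and wall cells carry the local radial wall velocity (zero on the rigid
channel); wall-tangential values enter the diffusion stencil through
half-cell ghost mirroring, which keeps plane walls second-order accurate.
Open (outlet/inlet) faces carry a full momentum equation with a zero-gradient
diffusion closure and the half-cell pressure gradient against the imposed
face pressure. The incremental form matters: a non-incremental split leaves
an O(ν·dt/h²) steady-state error at tangential walls (the ghost condition is
applied to the predictor field, which is offset by dt·∇p), which showed up
as a dt-dependent Poiseuille deficit before the scheme was switched.

Time steps adapt to CFL ≤ 0.5 (default 0.4) with hysteresis so the cached
implicit operators are reused across many steps; the channel must be
resolved by at least 8 cells across D. Validation: the pressure-driven
channel reaches the analytic Poiseuille maximum to solver tolerance at 8–32
cells across (the discrete wall stencil's +1/n² overshoot cancels exactly
against sampling the parabola half a cell off-centre, so the profile
maximum is nodally exact; the full-profile L∞ error converges as O(h²) and
is the quantity used for the grid-convergence test); post-projection
divergence is at machine precision (≤ 1e-6 required); and the integrated
outlet flux matches the analytic shrink of the fluid-domain area to < 2 %.
The conserved reference is the area of the bladder contour **unioned** with
the channel rectangle (computed with Shapely per contour snapshot): the
bladder-only contour overlaps the channel by a time-varying amount of order
D/(2πR) ≈ 3–4 %, so only the union obeys an exact mass balance.

**Metrics.** Vorticity ω = ∂v/∂x − ∂u/∂y by central differences at cell
centres (exact for linear fields). The bladder-averaged vorticity uses
|ω| over bladder cells only (channel excluded, one-cell erosion so the
stencil stays in-fluid): a *signed* average of a recirculating flow can
cancel to zero, which would make between-group comparison meaningless.
Dimensionless vorticity is mean|ω|·D/Ū with Ū = Q/D in the 2D flux
convention (an optional pseudo-3D mode uses Ū = Q/(πD²/4)); it removes the
flow-rate difference between subjects. The recirculation fraction of a step
is the share of bladder cells whose velocity points more than 90° away from
the local direction to the outlet, counting only cells faster than 1 % of
the instantaneous maximum (streamline pictures motivate a quantitative
stand-in; this is ours). For comparing the *size* of recirculation regions
across runs the package reports the recirculated **area** (fraction ×
instantaneous bladder area): runs that empty to very different residual
volumes make the fraction misleading — a nearly empty bladder can post a
large fraction from a small recirculating region — whereas the area ranks
the regions themselves. Both are reported.

Determinism: the solver contains no randomness; identical inputs give
bit-identical metrics.

## Problem sizes and defaults used in the shipped analyses

The test-suite and acceptance analyses run the generator at icosphere
subdivision 3–4 (1 280–5 120 faces), flow grids of h = 0.75–1.0 mm with
D = 6–8 mm channels (8–10 cells across), and voiding durations of 6–12 s at
bladder radii 20–30 mm; these sizes were chosen as the smallest at which the
mesh-convergence and mass-balance margins are comfortably met. The group
comparison runs the control fixture on the sagittal plane and the BPH-like
fixture on the coronal plane, where its left–right asymmetry is in-plane.

## Known limitations

- The displacement model ignores tangential motion and any torsion of the
  detrusor; d0 is as reported only where the anatomy is star-shaped about
  the post-void centroid.
- Anatomical axes cannot be recovered from STL files; for real exports they
  must be supplied (`--axes`), and region labels are only as good as that
  input.
- The flow model is 2D, laminar, Newtonian, one-way coupled (prescribed
  wall motion, no fluid–structure interaction), with a straight rigid
  urethra; its outputs are for within-package ordinal comparison.
- First-order upwind advection is diffusive; fine vortical structure is
  under-resolved at the default grids, which is acceptable for the
  area-integrated metrics reported but not for pointwise fields.
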