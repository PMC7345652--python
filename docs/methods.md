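# Methods

`diadflow` characterizes the wall shear stress (WSS) that endothelial
monolayers experience in plain and annular ("dish-in-a-dish", DiaD) culture
dishes on an orbital shaker. This note documents the models, the numerical
choices, and what the synthetic test conditions do and do not establish about
real dishes.

## The physical setting

A dish of outer diameter D (inner diameter d for annular designs) holds a
few millimetres of culture medium (density ρ = 1000 kg/m³, dynamic viscosity
μ = 0.7 mPa·s at 37 °C, surface tension γ = 0.072 N/m — the `EGM2_37C`
preset) and translates on a circular orbit of diameter d_ob at angular speed
ω without rotating. The sloshing wave this drives exerts a tangential stress
τ = μ ∂u/∂z|₀ on the substrate. Endothelial biology cares about two summary
statistics of τ(t): its maximum over a period per radial position (τ_max)
and the oscillatory shear index

    OSI = 1 − |∫₀ᵀ τ dt| / ∫₀ᵀ |τ| dt ,

which is 0 for perfectly unidirectional shear and 1 for symmetric reversal.
Sustained shear below 0.2 Pa (or strongly oscillatory shear) is atheroprone;
laminar shear above 1 Pa with low OSI is atheroprotective. Note the OSI
definition used here has no ½ prefactor, so its full range is [0, 1]; the
classification default `osi_cut = 0.1` refers to this scale.

## Analytic layer

Closed-form diagnostics (module `analytic`):

* orbital Reynolds number Re = ρωd_ob²/μ, reported rounded to the nearest
  500 (the only rounding consistent with the conventional quoted figures
  3000 / 11000 / 18500 for 10/19/25-mm orbits at 200 rpm);
* far-field comparator from the extended solution of Stokes' second
  problem, τ = a√(ρμω³) with a = d_ob/2, valid only for depth ≫ Stokes
  layer and distant side walls — 0.401 Pa at 200 rpm on a 10-mm orbit. This
  is a comparator, not a prediction: it ignores dish geometry entirely;
* Stokes layer thickness δ = √(2ν/ω) (≈ 0.26 mm at 200 rpm), the diagnostic
  that selects the wall-shear closure;
* Young–Laplace pressure jump and volume-of-fluid property mixing, shipped
  as standalone utilities. The surrogate solver itself is single-phase and
  neglects surface tension (the Bond number ρgL²/γ is ≫ 1 at dish scale).

## Shallow-water surrogate

The reference treatment of this flow is two-phase 3D CFD (k-epsilon
turbulence, VOF interface capture). This package deliberately replaces it
with single-layer shallow-water dynamics — the only reduction that runs a
full design sweep on a desk — and therefore treats all absolute stress
magnitudes as order-of-magnitude statements, while trends, limits and
post-processing are quantitative. In the translating (non-rotating) dish
frame the orbital drive is exactly the uniform rotating body force
F(t) = aω²(cos ωt, sin ωt); there is no Coriolis term. The depth h and
depth-averaged velocity u obey

    ∂h/∂t + ∇·(hu) = 0
    ∂u/∂t + (u·∇)u = −g∇h + F(t) − τ_b/(ρh) + ν_e∇²u

with zero normal flow at the walls.

Numerics (module `solver`): cell-centered finite volumes on a polar grid
(default 32×64). Mass uses a conservative Rusanov flux — the dissipative
½c(h_R − h_L) term is what stabilizes gravity waves on a colocated grid —
so volume is conserved to machine precision away from the wet/dry floor.
Momentum uses first-order upwind advection, central pressure gradients, a
flux-form polar Laplacian for the eddy viscosity (default ν_e = 10⁻⁵ m²/s,
a numerical regularization standing in for unresolved horizontal mixing),
and semi-implicit bottom friction for stiffness at small depth. Time
stepping is a two-stage Heun scheme; `dt="auto"` targets CFL 0.4 on
√(4gh₀) + 3aω and rounds the steps per period to a multiple of the stored
samples per period (20, so stored samples fall on exactly uniform phases).
The still-water state with zero forcing is preserved to machine precision.

Plain dishes (d = 0) use a 1-mm numerical core with the same wall treatment
as a physical inner dish; the excluded area is < 0.1% of a 35-mm dish.
Wet/dry handling floors the depth at h_min = 10 µm with zero velocity on
floored cells; if more than 10% of cells sit at the floor the run aborts
with a dry-out diagnostic — that regime (very low fill on a large orbit) is
outside the surrogate's validity, and sweep rows record it as a failure
flag rather than a number.

The run integrates period by period from rest and stops when the relative
L2 change of the velocity field between successive periods falls below
10⁻⁴, or at the total-time cap. The default cap is
max(4.0 s, (discard_periods + 2)·T) with discard_periods = 10: a fixed
4.0 s covers 12 periods at 200 rpm but not at 100 rpm, so the cap adapts to
keep the analysed period beyond the transient discard at every speed. The
analysis window is always the last full period. The fixed-step transient
protocol (dt = 0.01 s, 4.0 s) remains expressible, but on default grids it
violates the CFL bound of this explicit scheme and is rejected with a
diagnostic rather than integrated unstably.

### Wall-shear closures

The substrate stress is reconstructed from the depth-averaged velocity in
post-processing:

* `lubrication`: τ = 3μu/h, the quasi-steady parabolic profile — correct
  when h ≲ δ, retained for shallow fills and for its transparency in tests;
* `stokes_layer` (default, since fills of 2–4 mm are ≫ δ): each cell's
  velocity over the stored period is decomposed into Fourier harmonics of
  the forcing frequency, and the oscillating-plate transfer function
  τ̂ₙ = (1 + i)√(ρμnω/2)·ûₙ is applied per harmonic n ≥ 1. For a pure
  harmonic at ω this is exactly the classical oscillatory boundary-layer
  result, and on a prescribed uniform oscillation of amplitude aω it
  reproduces the far-field analytic value a√(ρμω³) to rounding — the
  consistency link between the solver and the analytic layer.

  The steady (n = 0) component needs care. The Eulerian time mean of the
  depth-averaged velocity contains a spurious radial drift that merely
  compensates the wave correlation flux ⟨h′u′⟩; the physically transported
  current is the depth-weighted mean ū = ⟨hu⟩/⟨h⟩, whose radial part
  vanishes in a periodic state. Its wall stress is taken as
  τ₀ = μū/δ = √(ρμω/2)·ū — the conductance of a steady current embedded in
  an oscillatory boundary layer (the standard wave–current enhancement),
  not the depth-scale 3μū/h, which would underestimate it by roughly h/δ.
  This steady component is what gives the surrogate its unidirectional
  shear at the dish rim; without it the reconstructed OSI is identically 1.

In-solver bottom friction uses the in-phase (dissipative) part of the same
closures: 3μ/(ρh²) for lubrication, √(ρμω/2)/(ρh) for the Stokes layer.

## Radial post-processing

Module `shear` rotates each cell's WSS vector into its local (tangential,
radial) frame, groups cells into equal-width radial bins (default one bin
per radial grid row), and reports per bin: τ_max (max over member cells and
samples), the area/time-weighted mean |τ|, the OSI with area-weighted sums
over member cells and the period inside one formula (the grid-independent
aggregation choice), the main shear direction (angle of the numerator
vector; 0° tangential, positive tilting outward), and the regime label.
Bins with identically zero shear report OSI as missing with a warning.
Radial positions are normalized between the dish walls d and D; for plain
dishes this is r/(D/2). Whether the vector sum behind the main direction
runs over time only or over cells and time is ambiguous in common usage;
this module sums over both and documents it.

## Design sweep

Module `sweep` runs the surrogate over the Cartesian grid of the five
printed dish designs (35 and 134 mm plain; 89/56, 134/89, 134/56 annular),
orbit diameters {10, 19, 25} mm, speeds {100, 125, 150, 200} rpm and fill
heights {2, 3, 4} mm — 180 combinations, of which the 72-row design sweep
over the annular-relevant subset completes in desk time at the default
32×64 grid. Ranking uses min–max-normalized criteria (τ_max ↑, max OSI ↓,
τ_max coefficient of variation ↓, culture area ↑) under user weights
summing to 1, because "best" genuinely depends on whether an experiment
needs maximal shear, homogeneity, or cell yield; the composite is invariant
to positive rescaling of any criterion. The viscosity-scaling helper
reports the √factor (oscillatory-layer) and linear (lubrication) bounds as
a bracket for medium-thickening interventions rather than a single number.

## Bioassay analytics

Module `bioassay` covers the downstream validation readouts:

* orientation histograms by the local-gradient structure tensor (Gaussian
  gradient σ = 1 px, tensor averaging σ = 4 px, 90 bins × 2°,
  energy×coherence weighting). This is a well-defined equivalent of the
  interactive directionality tools commonly used on micrographs, not a
  re-implementation of any specific one; dominant angle is the circular
  mean (period 180°) of the top mode;
* ΔΔCt relative quantification: ΔCt = Ct_target − Ct_reference per sample
  (technical replicates averaged on Ct), ΔΔCt against the control-group
  mean, fold change 2^(−ΔΔCt) assuming perfect efficiency. The reference
  gene is a user input; reference-gene stability screening (e.g. GeNorm) is
  out of scope;
* two-sided single-outlier Grubbs test with the t-based critical value,
  applied at most once per group;
* pooled-variance Student's t-test with conventional */**/*** levels.
  Zero-variance input with equal means returns (t, p) = (0, 1); with
  unequal means it is rejected as undefined.

## Synthetic fixtures and what passing means

All tests run on synthesized inputs: stripe images with known orientation,
Ct tables with prescribed cycle shifts, WSS series with an analytically
known OSI (a tangential field reversing for a fraction f of the period has
OSI = 1 − |1 − 2f| exactly), and the surrogate's own deterministic runs.
These establish internal correctness — oracle equivalence of the stepper
and the profile statistics to 10⁻¹⁰–10⁻¹², exact recovery of closed-form
cases, conservation, and the monotone trends of τ_max with speed, orbit and
fill height. They do not establish agreement with 3D CFD magnitudes: the
surrogate's τ_max values run roughly 1.5–2.5× above the reference CFD
levels for the same conditions (it resolves no vertical structure and
overestimates near-resonant wave amplitudes), and its OSI values are
compressed toward the high end away from the rim. Radial orderings,
parameter trends, and every quantity in the analytic and planning layers
are reproduced quantitatively.

## Problem sizes

Default runs use the 32×64 polar grid with 20 stored samples per period and
a ≤ 12–14 period integration; a plain 35-mm dish needs ~4000 steps per
period (the 1-mm core sets the azimuthal CFL limit) and runs in under a
minute, annular dishes in seconds. Unit and property tests use 4×8 to
16×32 grids; the brute-force stepper oracle runs 3 steps on 6×12. These
sizes are the package's defaults and were chosen so the full
characterization grid remains an interactive computation.

## Known limitations

* Depth-averaged dynamics: no vertical velocity structure, no k-epsilon
  turbulence, no interface reconstruction, no contact-line physics, and no
  overtopping of the inner dish (walls are effectively infinitely tall).
* The wall-shear closure is linear per harmonic; wave–turbulence
  interaction in the boundary layer is not modelled.
* Quantitative CFD agreement is explicitly out of scope; the recommended
  operating points from ranking should be read through the composite
  weights used to produce them.
* The orientation analysis assumes roughly uniform illumination; no
  background correction or segmentation is performed.
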