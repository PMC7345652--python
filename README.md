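# diadflow

Wall-shear-stress characterization of plain and annular ("dish-in-a-dish",
DiaD) culture dishes on orbital shakers.

Endothelial cells respond to the shear stress of flowing medium: sustained
laminar shear above ~1 Pa with a stable direction is atheroprotective, while
low (< 0.2 Pa) or strongly oscillatory shear is atheroprone. Orbital shakers
are the cheapest way to expose millions of cells to flow, but the sloshing
wave produces a radially inhomogeneous mix of both regimes. Mounting a small
dish inside a larger one turns the vessel into an annular channel that
promotes unidirectional flow — if the geometry, orbit, speed and fill height
are chosen well. `diadflow` is a toolkit for making that choice: it combines
the closed-form hydrodynamic estimates, a desk-scale depth-averaged
shallow-water simulation of the dish, the radial τ_max/OSI post-processing,
a design-sweep ranking, and the analytics used to validate such platforms
experimentally (cell-orientation histograms, ΔΔCt qPCR quantification,
Grubbs outlier screening, Student's t-tests).

The two summary statistics are the per-radius maximum wall shear stress
τ_max and the oscillatory shear index

    OSI = 1 − |∫₀ᵀ τ dt| / ∫₀ᵀ |τ| dt

over one orbital period T (0 = unidirectional, 1 = fully reversing). The
simulator solves depth-averaged shallow-water equations in the translating
dish frame, forced by the rotating body force a·ω²(cos ωt, sin ωt), and
reconstructs the substrate stress with an oscillatory boundary-layer
(Stokes-layer) closure applied per Fourier harmonic. Absolute magnitudes
are surrogate-level (full 3D two-phase CFD is the reference there); radial
structure, parameter trends and all planning arithmetic are quantitative.
See `docs/methods.md` for the model, closures and limitations.

## Worked example

Closed-form estimates for a 10-mm orbit at 200 rpm:

```
$ diadflow analytic --orbit-mm 10 --rpm 200
omega_rad_s: 20.944
reynolds_raw: 2992.0
reynolds_reported: 3000
stokes_tau_max_Pa: 0.401
stokes_layer_mm: 0.2585
```

The Reynolds number (~3000) sits at the laminar–turbulent transition; the
far-field Stokes comparator says an unbounded fluid sheared by this orbit
would exert 0.401 Pa on the bottom, and the 0.26-mm oscillatory boundary
layer is much thinner than a 2–4 mm fill, which justifies the Stokes-layer
wall closure.

Planning arithmetic for annular dishes built from a 60-mm inner dish
(actual diameters: the product names 35/60/100/150 mm correspond to 35, 56,
89 and 134 mm culture surfaces):

```
$ diadflow plan --inner 60 --height-mm 3
| label   |   D_mm |   d_mm |   area_cm2 |   volume_ml |   height_mm |   cells_at_density |
|:--------|-------:|-------:|-----------:|------------:|------------:|-------------------:|
| 89/56   |     89 |     56 |      37.58 |        11.3 |           3 |             939533 |
| 134/56  |    134 |     56 |     116.4  |        34.9 |           3 |            2909900 |
```

So a 134/56 DiaD filled to 3 mm takes 35 mL of medium and carries ~2.9
million cells at the standard 25,000 cells/cm² seeding density (the 134/89
design has 79 cm² and ~2 million cells).

Simulating the 134/56 DiaD on a 10-mm orbit at 200 rpm with 3 mm of medium
and profiling the result:

```python
from diadflow import *
from diadflow.shear import compute_profile

series = simulate(
    DishGeometry.from_mm(134, 56),
    ShakerConfig.from_rpm(orbit_mm=10, rpm=200),
    EGM2_37C,
    FillSpec(height_mm=3),
    SimulationSettings(),          # 32x64 polar grid, Stokes-layer closure
)
profile = compute_profile(series)
print(profile.to_dataframe().iloc[::8].round(3).to_string(index=False))
```

```
 r_norm  tau_max_Pa  tau_mean_Pa   osi  main_direction_deg       regime  oscillatory
  0.016       0.749        0.323 0.756               8.195 intermediate         True
  0.266       1.430        0.516 0.980             -82.148 intermediate         True
  0.516       1.700        0.574 0.879              -2.560 intermediate         True
  0.766       1.677        0.561 0.701               3.091 intermediate         True
```

τ_max peaks mid-channel at ~1.7 Pa and the main shear direction at the
outer half of the channel stays within a few degrees of tangential (0°),
i.e. the flow travels around the annulus; the OSI of this design on a
10-mm orbit remains substantial (it is dominated by the oscillatory part
of the wave), which is exactly why a sweep over designs and operating
points is worth running
(`diadflow sweep`, or `run_sweep`/`rank_designs` from Python) before
committing an experiment to one configuration.

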