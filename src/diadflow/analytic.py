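"""Closed-form hydrodynamic estimates for dishes on an orbital shaker.

These are the desk-side numbers one computes before (or instead of) running a
simulation: the orbital Reynolds number that decides whether the flow is
laminar or turbulent, the far-field wall-shear comparator from the extended
solution of Stokes' second problem, the Stokes boundary-layer thickness that
justifies the wall-shear closure, and two interface utilities (Laplace
pressure jump, volume-of-fluid property mixing) that belong to full two-phase
CFD but are handy as standalone calculators.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

__all__ = [
    "FluidProperties",
    "ShakerConfig",
    "EGM2_37C",
    "AIR_37C",
    "rpm_to_omega",
    "omega_to_rpm",
    "reynolds_number",
    "report_reynolds",
    "stokes_wss_max",
    "stokes_layer_thickness",
    "laplace_pressure",
    "vof_mix",
]


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian fluid: density ρ (kg/m³), dynamic viscosity μ (Pa·s),
    surface tension γ (N/m)."""

    density: float
    dynamic_viscosity: float
    surface_tension: float = 0.0

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if not self.dynamic_viscosity > 0:
            raise ValueError(f"viscosity must be positive, got {self.dynamic_viscosity}")
        if self.surface_tension < 0:
            raise ValueError(f"surface tension must be non-negative, got {self.surface_tension}")

    @property
    def kinematic_viscosity(self) -> float:
        """ν = μ/ρ in m²/s."""
        return self.dynamic_viscosity / self.density


#: Endothelial growth medium at 37 °C: ρ = 1000 kg/m³, μ = 0.7 mPa·s, γ = 0.072 N/m.
EGM2_37C = FluidProperties(density=1000.0, dynamic_viscosity=0.7e-3, surface_tension=0.072)

#: Air at 37 °C (for VOF property mixing).
AIR_37C = FluidProperties(density=1.2, dynamic_viscosity=1.9e-5, surface_tension=0.0)


@dataclass(frozen=True)
class ShakerConfig:
    """Orbital shaker drive: orbit diameter d_ob (m) and angular speed ω (rad/s).

    The deck translates on a circle of diameter ``orbit_diameter`` without
    rotating, so every point of the dish describes the same circular orbit of
    radius a = d_ob/2.
    """

    orbit_diameter: float
    omega: float

    def __post_init__(self) -> None:
        if self.orbit_diameter < 0:
            raise ValueError(f"orbit diameter must be non-negative, got {self.orbit_diameter}")
        if not self.omega > 0:
            raise ValueError(f"angular speed must be positive, got {self.omega}")

    @classmethod
    def from_rpm(cls, orbit_mm: float, rpm: float) -> "ShakerConfig":
        """Construct from orbit diameter in mm and speed in rev/min."""
        return cls(orbit_diameter=orbit_mm * 1e-3, omega=rpm_to_omega(rpm))

    @property
    def orbit_radius(self) -> float:
        """a = d_ob/2 in metres."""
        return self.orbit_diameter / 2

    @property
    def period(self) -> float:
        """Orbital period T = 2π/ω in seconds."""
        return 2 * math.pi / self.omega

    @property
    def rpm(self) -> float:
        return omega_to_rpm(self.omega)


def rpm_to_omega(rpm: float) -> float:
    """Convert rev/min to rad/s: ω = 2π·rpm/60 (200 rpm → 20.94 rad/s)."""
    if rpm < 0:
        raise ValueError(f"rpm must be non-negative, got {rpm}")
    return 2 * math.pi * rpm / 60


def omega_to_rpm(omega: float) -> float:
    return omega * 60 / (2 * math.pi)


def reynolds_number(fluid: FluidProperties, shaker: ShakerConfig) -> float:
    """Orbital Reynolds number Re = ρ·ω·d_ob²/μ.

    A first diagnostic of the flow regime: ≲3000 sits in the laminar/turbulent
    transition zone, well above is turbulent. Returns the raw value; use
    :func:`report_reynolds` for the conventional rounded figure.
    """
    return (
        fluid.density
        * shaker.omega
        * shaker.orbit_diameter**2
        / fluid.dynamic_viscosity
    )


def report_reynolds(re: float) -> int:
    """Round a Reynolds estimate to the nearest 500 for reporting.

    With medium properties this maps the three common orbit sizes
    (10/19/25 mm at 200 rpm) to 3000, 11000 and 18500.
    """
    return int(round(re / 500) * 500)


def stokes_wss_max(fluid: FluidProperties, shaker: ShakerConfig) -> float:
    """Far-field maximum wall shear stress τ = a·√(ρμω³), in Pa.

    Extended-Stokes'-second-problem comparator for an orbitally shaken dish:
    the substrate oscillates under effectively unbounded fluid at rest, so the
    wall stress is that of an oscillating plate with velocity amplitude a·ω.
    Valid only when the fluid depth is much larger than the Stokes layer
    thickness and side walls are far away; it ignores dish geometry and fill
    height entirely, which is why it is a comparator and not a predictor.
    """
    return shaker.orbit_radius * math.sqrt(
        fluid.density * fluid.dynamic_viscosity * shaker.omega**3
    )


def stokes_layer_thickness(fluid: FluidProperties, shaker: ShakerConfig) -> float:
    """Oscillatory boundary-layer penetration depth δ = √(2ν/ω), in metres.

    Diagnostic for the wall-shear closure choice: the Stokes-layer closure is
    appropriate when the fluid depth h ≫ δ (δ ≈ 0.26 mm at 200 rpm for
    culture medium, against 2–4 mm fills).
    """
    return math.sqrt(2 * fluid.kinematic_viscosity / shaker.omega)


def laplace_pressure(gamma: float, r_medium: float, r_air: float) -> float:
    """Young–Laplace pressure jump p_M − p_A = γ·(1/r_M + 1/r_A), in Pa.

    ``r_medium`` and ``r_air`` are the interface curvature radii measured from
    the liquid and gas sides. Standalone utility: the depth-averaged surrogate
    solver itself neglects surface tension (Bond number ≫ 1 at dish scale).
    """
    if r_medium == 0 or r_air == 0:
        raise ZeroDivisionError("interface curvature radius must be non-zero")
    return gamma * (1 / r_medium + 1 / r_air)


def vof_mix(p_medium: float, p_air: float, alpha_medium: float) -> float:
    """Volume-of-fluid property mixing P = α_M·P_M + (1 − α_M)·P_A.

    The medium and air volume fractions satisfy α_M + α_A = 1 by construction.
    Utility for two-phase property bookkeeping; the surrogate solver is
    single-phase.
    """
    if not 0 <= alpha_medium <= 1:
        raise ValueError(f"volume fraction must be in [0, 1], got {alpha_medium}")
    return alpha_medium * p_medium + (1 - alpha_medium) * p_air
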