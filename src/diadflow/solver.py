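"""Depth-averaged shallow-water surrogate for orbital-shaker dish flow.

The full problem — two-phase 3D Navier–Stokes with a free surface in a dish
translating on a circular orbit — is reduced to single-layer shallow-water
dynamics of the medium depth h(r, θ, t) and depth-averaged horizontal
velocity u(r, θ, t) on a polar grid, posed in the dish frame. Because the
dish translates without rotating, the orbital motion enters purely as a
spatially uniform rotating body force a·ω²·(cos ωt, sin ωt); there is no
Coriolis term. The governing equations are

    ∂h/∂t + ∇·(h u) = 0
    ∂u/∂t + (u·∇)u = −g ∇h + F(t) − τ_b/(ρ h) + ν_e ∇²u

with zero normal flow at the dish walls and a bottom-friction stress τ_b
supplied by the wall-shear closure. The wall shear stress on the substrate,
τ = μ ∂u/∂z at z = 0, is reconstructed in post-processing from the
depth-averaged velocity by one of two closures:

``lubrication``
    Quasi-steady parabolic vertical profile: τ = 3 μ u / h. Appropriate when
    the depth is comparable to or smaller than the Stokes layer.
``stokes_layer`` (default)
    Oscillatory boundary layer at the forcing frequency: the complex velocity
    amplitude û at ω is extracted over the last period and
    τ̂ = (1 + i)·√(ρμω/2)·û. Appropriate when h ≫ δ = √(2ν/ω), which holds
    for 2–4 mm fills at 100–200 rpm (δ ≈ 0.26–0.37 mm).

Velocity is stored in Cartesian components of the dish frame; spatial
operators are evaluated on the polar grid (conservative flux form for mass,
upwind advection and central pressure gradients for momentum). The solver is
deterministic: identical inputs give bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .analytic import FluidProperties, ShakerConfig
from .geometry import DishGeometry, FillSpec

__all__ = [
    "SimulationSettings",
    "PolarGrid",
    "FlowFieldSeries",
    "SolverError",
    "ConfigurationError",
    "DryOutError",
    "CFLError",
    "SamplingError",
    "build_grid",
    "orbital_forcing",
    "simulate",
    "wall_shear",
]


class SolverError(RuntimeError):
    """Base class for surrogate-solver failures."""


class ConfigurationError(SolverError):
    """Invalid grid or time-stepping configuration."""


class DryOutError(SolverError):
    """Depth collapsed to the floor over more than 10% of cells."""


class CFLError(SolverError):
    """Time step violates the CFL stability bound (or the run diverged)."""


class SamplingError(SolverError):
    """Stored time sampling too coarse for the requested closure."""


@dataclass
class SimulationSettings:
    """Numerical settings for :func:`simulate`.

    Parameters
    ----------
    n_r, n_theta : int
        Radial and azimuthal cell counts (≥ 4 and ≥ 8).
    dt : float or "auto"
        Time step in seconds. ``"auto"`` picks a CFL-limited step and rounds
        the steps-per-period up to a multiple of ``samples_per_period`` so
        stored samples fall on exactly uniform phases.
    total_time : float or "auto"
        Simulated-time cap. ``"auto"`` is max(4.0 s, (discard_periods + 2)·T)
        so the analysis period always lies beyond the transient discard.
    discard_periods : int
        Minimum number of start-up periods excluded from analysis.
    closure : {"stokes_layer", "lubrication"}
        Bottom-friction / wall-shear closure.
    eddy_viscosity : float
        Horizontal eddy viscosity ν_e (m²/s); numerical regularization
        standing in for unresolved horizontal mixing.
    gravity : float
        g in m/s².
    min_depth : float
        Wet/dry floor h_min (m); velocity is zeroed on floored cells.
    periodic_tol : float
        Relative L2 change of the velocity field between successive periods
        below which the flow is declared periodic and the run stops.
    samples_per_period : int
        Stored samples per orbital period (≥ 20).
    core_radius : float
        Inner core radius ε used for plain dishes (d = 0), treated as a
        zero-normal-flow axis proxy.
    cfl : float
        CFL number used when ``dt == "auto"``.
    """

    n_r: int = 32
    n_theta: int = 64
    dt: float | str = "auto"
    total_time: float | str = "auto"
    discard_periods: int = 10
    closure: str = "stokes_layer"
    eddy_viscosity: float = 1e-5
    gravity: float = 9.81
    min_depth: float = 10e-6
    periodic_tol: float = 1e-4
    samples_per_period: int = 20
    core_radius: float = 1e-3
    cfl: float = 0.4

    def __post_init__(self) -> None:
        if self.n_r < 4:
            raise ConfigurationError(f"n_r must be >= 4, got {self.n_r}")
        if self.n_theta < 8:
            raise ConfigurationError(f"n_theta must be >= 8, got {self.n_theta}")
        if isinstance(self.dt, str):
            if self.dt != "auto":
                raise ConfigurationError(f"dt must be a positive number or 'auto', got {self.dt!r}")
        elif not self.dt > 0:
            raise ConfigurationError(f"dt must be positive, got {self.dt}")
        if isinstance(self.total_time, str) and self.total_time != "auto":
            raise ConfigurationError(
                f"total_time must be a positive number or 'auto', got {self.total_time!r}"
            )
        if self.closure not in ("stokes_layer", "lubrication"):
            raise ConfigurationError(f"unknown closure {self.closure!r}")
        if self.samples_per_period < 20:
            raise ConfigurationError(
                f"samples_per_period must be >= 20, got {self.samples_per_period}"
            )


@dataclass(frozen=True)
class PolarGrid:
    """Cell-centered annular polar grid.

    Radial cell centers ``r`` lie strictly inside (r_in, r_out); azimuthal
    centers ``theta`` are uniform on [0, 2π). ``cell_area`` is the exact
    annular-sector area ½(r_e[i+1]² − r_e[i]²)·Δθ, so the summed grid area
    differs from the closed-form annulus area only through the inner-core
    treatment of plain dishes.
    """

    geom: DishGeometry
    r_edges: np.ndarray  # (n_r + 1,)
    r: np.ndarray  # (n_r,)
    theta: np.ndarray  # (n_theta,)
    dr: float
    dtheta: float

    @property
    def n_r(self) -> int:
        return self.r.size

    @property
    def n_theta(self) -> int:
        return self.theta.size

    @property
    def r_in(self) -> float:
        return float(self.r_edges[0])

    @property
    def r_out(self) -> float:
        return float(self.r_edges[-1])

    @property
    def cell_area(self) -> np.ndarray:
        """(n_r, n_theta) array of cell areas in m²."""
        ring = 0.5 * (self.r_edges[1:] ** 2 - self.r_edges[:-1] ** 2) * self.dtheta
        return np.repeat(ring[:, None], self.n_theta, axis=1)

    @property
    def min_cell_size(self) -> float:
        """Smallest cell extent (limits the explicit time step)."""
        return min(self.dr, float(self.r[0]) * self.dtheta)


def build_grid(geom: DishGeometry, settings: SimulationSettings) -> PolarGrid:
    """Construct the annular polar grid for a dish.

    For plain dishes (d = 0) the inner boundary is a small core of radius
    ``settings.core_radius`` with the same zero-normal-flow treatment as a
    physical inner wall; the excluded core area is negligible (< 0.1% of a
    35-mm dish).
    """
    r_in = geom.inner_radius if geom.is_annular else settings.core_radius
    r_out = geom.outer_radius
    if r_out - r_in <= 0:
        raise ConfigurationError("outer radius must exceed inner (or core) radius")
    r_edges = np.linspace(r_in, r_out, settings.n_r + 1)
    r = 0.5 * (r_edges[:-1] + r_edges[1:])
    dtheta = 2 * np.pi / settings.n_theta
    theta = (np.arange(settings.n_theta) + 0.5) * dtheta
    return PolarGrid(
        geom=geom,
        r_edges=r_edges,
        r=r,
        theta=theta,
        dr=float(r_edges[1] - r_edges[0]),
        dtheta=dtheta,
    )


def orbital_forcing(shaker: ShakerConfig, t: float) -> np.ndarray:
    """Dish-frame body force per unit mass at time t: a·ω²·(cos ωt, sin ωt).

    This is the (sign-reversed) frame acceleration of the translating dish;
    its magnitude a·ω² is constant and its direction rotates at ω.
    """
    a = shaker.orbit_radius
    w = shaker.omega
    return a * w**2 * np.array([np.cos(w * t), np.sin(w * t)])


@dataclass
class FlowFieldSeries:
    """One analysed orbital period of depth-averaged fields on a polar grid.

    Arrays are sampled at uniform instants ``times`` spanning exactly one
    period (end-exclusive). ``tau`` is filled by :func:`wall_shear`.
    """

    grid: PolarGrid
    times: np.ndarray  # (n_t,)
    h: np.ndarray  # (n_t, n_r, n_theta)
    u: np.ndarray  # (n_t, n_r, n_theta, 2)  dish-frame Cartesian
    omega: float
    h0: float
    closure: str
    tau: Optional[np.ndarray] = None  # (n_t, n_r, n_theta, 2), Pa
    diagnostics: dict = field(default_factory=dict)

    @property
    def period(self) -> float:
        return 2 * np.pi / self.omega

    @property
    def n_samples(self) -> int:
        return self.times.size

    def volume(self, k: int | None = None) -> float | np.ndarray:
        """Fluid volume (m³) at sample k, or at all samples if k is None."""
        area = self.grid.cell_area
        if k is not None:
            return float(np.sum(self.h[k] * area))
        return np.einsum("tij,ij->t", self.h, area)

    @classmethod
    def from_arrays(
        cls,
        grid: PolarGrid,
        times: np.ndarray,
        u: np.ndarray,
        h: np.ndarray | float,
        omega: float,
        closure: str = "stokes_layer",
        tau: np.ndarray | None = None,
    ) -> "FlowFieldSeries":
        """Build a series from prescribed fields (fixtures, analytic checks)."""
        times = np.asarray(times, dtype=float)
        u = np.asarray(u, dtype=float)
        if np.isscalar(h):
            h_arr = np.full(u.shape[:-1], float(h))
        else:
            h_arr = np.asarray(h, dtype=float)
        return cls(
            grid=grid,
            times=times,
            h=h_arr,
            u=u,
            omega=omega,
            h0=float(np.mean(h_arr[0])),
            closure=closure,
            tau=tau,
        )

    def save_npz(self, path) -> None:
        """Write fields and grid to a NumPy .npz archive."""
        np.savez_compressed(
            path,
            times=self.times,
            h=self.h,
            u=self.u,
            tau=self.tau if self.tau is not None else np.empty(0),
            omega=self.omega,
            h0=self.h0,
            closure=self.closure,
            r_edges=self.grid.r_edges,
            theta=self.grid.theta,
            outer_diameter=self.grid.geom.outer_diameter,
            inner_diameter=self.grid.geom.inner_diameter,
            label=self.grid.geom.label,
        )

    @classmethod
    def load_npz(cls, path) -> "FlowFieldSeries":
        with np.load(path, allow_pickle=False) as z:
            geom = DishGeometry(
                float(z["outer_diameter"]), float(z["inner_diameter"]), str(z["label"])
            )
            r_edges = z["r_edges"]
            theta = z["theta"]
            grid = PolarGrid(
                geom=geom,
                r_edges=r_edges,
                r=0.5 * (r_edges[:-1] + r_edges[1:]),
                theta=theta,
                dr=float(r_edges[1] - r_edges[0]),
                dtheta=float(2 * np.pi / theta.size),
            )
            tau = z["tau"]
            return cls(
                grid=grid,
                times=z["times"],
                h=z["h"],
                u=z["u"],
                omega=float(z["omega"]),
                h0=float(z["h0"]),
                closure=str(z["closure"]),
                tau=None if tau.size == 0 else tau,
            )


# --------------------------------------------------------------------------
# spatial operators
# --------------------------------------------------------------------------


class _Stepper:
    """Explicit two-stage (Heun) shallow-water stepper with semi-implicit
    bottom friction.

    The update for one step of size dt from state (h, u) at time t is

        stage 1:  dh1 = −∇·(h u);  R1 = rhs_u(h, u, t)
                  h* = h + dt·dh1
                  u* = (u + dt·R1) / (1 + dt·λ(h*))
                  floor h*, zero u* on floored cells
        stage 2:  dh2 = −∇·(h* u*);  R2 = rhs_u(h*, u*, t + dt)
                  h⁺ = h + dt/2·(dh1 + dh2)
                  u⁺ = (u + dt/2·(R1 + R2)) / (1 + dt·λ(h⁺))
                  floor h⁺, zero u⁺ on floored cells

    where rhs_u = −(u·∇)u − g∇h + F(t) + ν_e∇²u and λ(h) is the linear
    friction rate of the closure: 3μ/(ρh²) for ``lubrication`` and
    √(ρμω/2)/(ρh) for ``stokes_layer`` (the in-phase part of the oscillatory
    boundary-layer stress). Mass is updated in conservative flux form with
    first-order upwind face depths, so volume is conserved to machine
    precision except where the depth floor engages.
    """

    def __init__(
        self,
        grid: PolarGrid,
        fluid: FluidProperties,
        shaker: ShakerConfig,
        settings: SimulationSettings,
    ) -> None:
        self.grid = grid
        self.fluid = fluid
        self.shaker = shaker
        self.s = settings
        th = grid.theta
        self.cos_t = np.cos(th)
        self.sin_t = np.sin(th)
        th_f = th + grid.dtheta / 2  # azimuthal face angles (face j between j and j+1)
        self.cos_tf = np.cos(th_f)
        self.sin_tf = np.sin(th_f)
        self.area = grid.cell_area
        self.r = grid.r[:, None]  # broadcast over theta
        self.r_edges = grid.r_edges
        # friction rate prefactors
        mu = fluid.dynamic_viscosity
        rho = fluid.density
        if settings.closure == "lubrication":
            self._lam = lambda h: 3 * mu / (rho * h**2)
        else:
            c = np.sqrt(rho * mu * shaker.omega / 2)
            self._lam = lambda h: c / (rho * h)

    # -- operators ---------------------------------------------------------

    def div_hu(self, h: np.ndarray, u: np.ndarray) -> np.ndarray:
        """−∂h/∂t from conservative Rusanov face fluxes of h·u.

        The face flux is ½(h_L u_L·n + h_R u_R·n) − ½·c·(h_R − h_L) with
        c = max(|u·n| + √(g h)) over the two sides; the dissipative term
        couples odd–even modes and stabilizes gravity waves on the
        colocated grid while remaining exactly conservative.
        """
        g = self.grid
        grav = self.s.gravity
        ux, uy = u[..., 0], u[..., 1]
        # radial faces: interior edges k = 1..n_r-1 between cells k-1 and k
        u_r = ux * self.cos_t + uy * self.sin_t
        unL, unR = u_r[:-1, :], u_r[1:, :]
        hL, hR = h[:-1, :], h[1:, :]
        c = np.maximum(np.abs(unL) + np.sqrt(grav * hL), np.abs(unR) + np.sqrt(grav * hR))
        flux_r = (0.5 * (hL * unL + hR * unR) - 0.5 * c * (hR - hL)) * (
            g.r_edges[1:-1, None] * g.dtheta
        )  # m³/s per face
        # azimuthal faces: face j between cells j and j+1 (periodic)
        unL = -ux * self.sin_tf + uy * self.cos_tf  # each side projected on ê_θ(face)
        unR = -np.roll(ux, -1, axis=1) * self.sin_tf + np.roll(uy, -1, axis=1) * self.cos_tf
        hR_t = np.roll(h, -1, axis=1)
        c_t = np.maximum(
            np.abs(unL) + np.sqrt(grav * h), np.abs(unR) + np.sqrt(grav * hR_t)
        )
        flux_t = (0.5 * (h * unL + hR_t * unR) - 0.5 * c_t * (hR_t - h)) * g.dr
        # net outward volume flux per cell: +outer/−inner radial face, +j/−(j−1) face
        net = np.zeros_like(h)
        net[:-1, :] += flux_r  # outflow through the outer face of cell k-1
        net[1:, :] -= flux_r  # inflow through the inner face of cell k
        net += flux_t  # outflow through face j
        net -= np.roll(flux_t, 1, axis=1)  # inflow through face j-1
        return net / self.area

    def _ddr_upwind(self, f: np.ndarray, u_r: np.ndarray) -> np.ndarray:
        g = self.grid
        bd = np.zeros_like(f)
        bd[1:, :] = (f[1:, :] - f[:-1, :]) / g.dr
        fd = np.zeros_like(f)
        fd[:-1, :] = (f[1:, :] - f[:-1, :]) / g.dr
        return np.where(u_r > 0, bd, fd)

    def _ddtheta_upwind(self, f: np.ndarray, u_t: np.ndarray) -> np.ndarray:
        g = self.grid
        bd = (f - np.roll(f, 1, axis=1)) / g.dtheta
        fd = (np.roll(f, -1, axis=1) - f) / g.dtheta
        return np.where(u_t > 0, bd, fd)

    def _ddr_central(self, f: np.ndarray) -> np.ndarray:
        g = self.grid
        d = np.empty_like(f)
        d[1:-1, :] = (f[2:, :] - f[:-2, :]) / (2 * g.dr)
        d[0, :] = (f[1, :] - f[0, :]) / g.dr
        d[-1, :] = (f[-1, :] - f[-2, :]) / g.dr
        return d

    def _ddtheta_central(self, f: np.ndarray) -> np.ndarray:
        return (np.roll(f, -1, axis=1) - np.roll(f, 1, axis=1)) / (2 * self.grid.dtheta)

    def _laplacian(self, f: np.ndarray) -> np.ndarray:
        """Polar Laplacian with zero-flux (Neumann) walls."""
        g = self.grid
        # radial part: (1/r) d/dr (r df/dr), flux form on edges
        dfr = np.zeros((g.n_r + 1, g.n_theta))
        dfr[1:-1, :] = (f[1:, :] - f[:-1, :]) / g.dr  # zero at walls
        rad = (
            g.r_edges[1:, None] * dfr[1:, :] - g.r_edges[:-1, None] * dfr[:-1, :]
        ) / (self.r * g.dr)
        ang = (np.roll(f, -1, axis=1) - 2 * f + np.roll(f, 1, axis=1)) / (
            self.r**2 * g.dtheta**2
        )
        return rad + ang

    def rhs_u(self, h: np.ndarray, u: np.ndarray, t: float) -> np.ndarray:
        """Momentum right-hand side excluding bottom friction."""
        s = self.s
        ux, uy = u[..., 0], u[..., 1]
        u_r = ux * self.cos_t + uy * self.sin_t
        u_t = -ux * self.sin_t + uy * self.cos_t
        out = np.empty_like(u)
        # advection (u·∇)f = u_r ∂f/∂r + (u_t/r) ∂f/∂θ, upwind
        for k, f in ((0, ux), (1, uy)):
            adv = u_r * self._ddr_upwind(f, u_r) + (u_t / self.r[:, 0][:, None]) * (
                self._ddtheta_upwind(f, u_t)
            )
            out[..., k] = -adv + s.eddy_viscosity * self._laplacian(f)
        # pressure gradient −g∇h (central)
        h_r = self._ddr_central(h)
        h_t = self._ddtheta_central(h) / self.r
        out[..., 0] -= s.gravity * (h_r * self.cos_t - h_t * self.sin_t)
        out[..., 1] -= s.gravity * (h_r * self.sin_t + h_t * self.cos_t)
        # orbital body force, uniform in space
        fx, fy = orbital_forcing(self.shaker, t)
        out[..., 0] += fx
        out[..., 1] += fy
        return out

    def apply_floor(self, h: np.ndarray, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h_min = self.s.min_depth
        dry = h <= h_min
        if dry.any():
            h = np.where(dry, h_min, h)
            u = np.where(dry[..., None], 0.0, u)
        return h, u

    def step(
        self, h: np.ndarray, u: np.ndarray, t: float, dt: float
    ) -> tuple[np.ndarray, np.ndarray]:
        dh1 = -self.div_hu(h, u)
        r1 = self.rhs_u(h, u, t)
        h_star = h + dt * dh1
        h_star, _ = self.apply_floor(h_star, u)
        u_star = (u + dt * r1) / (1 + dt * self._lam(h_star))[..., None]
        h_star, u_star = self.apply_floor(h_star, u_star)
        dh2 = -self.div_hu(h_star, u_star)
        r2 = self.rhs_u(h_star, u_star, t + dt)
        h_new = h + dt / 2 * (dh1 + dh2)
        h_new, _ = self.apply_floor(h_new, u)
        u_new = (u + dt / 2 * (r1 + r2)) / (1 + dt * self._lam(h_new))[..., None]
        return self.apply_floor(h_new, u_new)


# --------------------------------------------------------------------------
# main driver
# --------------------------------------------------------------------------


def _resolve_timestep(
    grid: PolarGrid,
    settings: SimulationSettings,
    shaker: ShakerConfig,
    h0: float,
) -> tuple[float, int, int]:
    """Return (dt, steps_per_period, sample_stride)."""
    T = shaker.period
    spp = settings.samples_per_period
    if settings.dt == "auto":
        speed = np.sqrt(settings.gravity * 4 * h0) + 3 * shaker.orbit_radius * shaker.omega
        dt0 = settings.cfl * grid.min_cell_size / speed
        steps = int(np.ceil(T / dt0))
        steps = int(np.ceil(steps / spp)) * spp  # multiple of samples_per_period
        dt = T / steps
        stride = steps // spp
    else:
        dt = float(settings.dt)
        steps = max(1, int(round(T / dt)))
        stride = max(1, steps // spp)
        if steps % stride:
            stride = 1
    return dt, steps, stride


def simulate(
    geom: DishGeometry,
    shaker: ShakerConfig,
    fluid: FluidProperties,
    fill: FillSpec,
    settings: SimulationSettings | None = None,
) -> FlowFieldSeries:
    """Run the shallow-water surrogate and return the last analysed period.

    Integrates period by period from rest. After each period the velocity
    fields sampled over that period are compared with the previous period;
    when the relative L2 change drops below ``settings.periodic_tol`` the flow
    is declared periodic and the run stops, otherwise it continues to the
    total-time cap. The returned series holds the last full period sampled at
    ``samples_per_period`` uniform instants (more when a fixed dt does not
    divide evenly).

    Raises
    ------
    DryOutError
        If more than 10% of cells sit at the depth floor at a period end.
    CFLError
        If a fixed dt violates the CFL bound, or the run diverges.
    """
    if settings is None:
        settings = SimulationSettings()
    grid = build_grid(geom, settings)
    h0 = fill.resolve_height_m(geom)
    if h0 < 4 * settings.min_depth:
        raise ConfigurationError(
            f"fluid depth {h0:.2e} m must be at least 4x the depth floor "
            f"{settings.min_depth:.2e} m"
        )
    T = shaker.period
    dt, steps_per_period, stride = _resolve_timestep(grid, settings, shaker, h0)
    if isinstance(settings.total_time, str):
        total_time = max(4.0, (settings.discard_periods + 2) * T)
    else:
        total_time = float(settings.total_time)
        if total_time < T:
            raise ConfigurationError("total_time must cover at least one orbital period")
    n_periods_max = max(2, int(np.ceil(total_time / T)))

    stepper = _Stepper(grid, fluid, shaker, settings)
    h = np.full((grid.n_r, grid.n_theta), h0)
    u = np.zeros((grid.n_r, grid.n_theta, 2))
    area = grid.cell_area
    v0 = float(np.sum(h * area))
    dmin = grid.min_cell_size

    n_samples = steps_per_period // stride
    prev_u = None
    samples_t = np.empty(n_samples)
    samples_h = np.empty((n_samples, grid.n_r, grid.n_theta))
    samples_u = np.empty((n_samples, grid.n_r, grid.n_theta, 2))
    residuals: list[float] = []
    max_drift = 0.0
    converged = False
    t = 0.0
    periods_run = 0

    for p in range(n_periods_max):
        k = 0
        # divergence is detected explicitly below; silence transient overflow
        with np.errstate(over="ignore", invalid="ignore"):
            for step_i in range(steps_per_period):
                if step_i % stride == 0:
                    samples_t[k] = t
                    samples_h[k] = h
                    samples_u[k] = u
                    k += 1
                h, u = stepper.step(h, u, t, dt)
                t += dt
        periods_run = p + 1
        if not np.isfinite(h).all() or not np.isfinite(u).all():
            raise CFLError(
                f"simulation diverged in period {periods_run} "
                f"(dt={dt:.3e} s, grid {grid.n_r}x{grid.n_theta})"
            )
        # runtime CFL check (binding for user-fixed dt)
        speed = float(np.max(np.abs(u))) + float(np.sqrt(settings.gravity * np.max(h)))
        if speed * dt > dmin:
            raise CFLError(
                f"CFL violation: dt={dt:.3e} s exceeds {dmin / speed:.3e} s "
                f"allowed by wave/advection speed {speed:.3f} m/s"
            )
        dry_frac = float(np.mean(h <= settings.min_depth * (1 + 1e-9)))
        if dry_frac > 0.10:
            raise DryOutError(
                f"dry-out: {dry_frac:.0%} of cells at the depth floor after "
                f"period {periods_run} (regime outside surrogate validity)"
            )
        drift = abs(float(np.sum(h * area)) - v0) / v0
        max_drift = max(max_drift, drift)
        if prev_u is not None:
            num = float(np.linalg.norm(samples_u - prev_u))
            den = float(np.linalg.norm(samples_u)) + 1e-300
            res = num / den
            residuals.append(res)
            if res < settings.periodic_tol:
                converged = True
                break
        prev_u = samples_u.copy()

    series = FlowFieldSeries(
        grid=grid,
        times=samples_t.copy(),
        h=samples_h.copy(),
        u=samples_u.copy(),
        omega=shaker.omega,
        h0=h0,
        closure=settings.closure,
        diagnostics={
            "periods_run": periods_run,
            "converged": converged,
            "period_residuals": residuals,
            "volume_drift": max_drift,
            "dt": dt,
            "steps_per_period": steps_per_period,
        },
    )
    wall_shear(series, fluid, shaker, settings.closure)
    return series


def wall_shear(
    series: FlowFieldSeries,
    fluid: FluidProperties,
    shaker: ShakerConfig | None = None,
    closure: str | None = None,
) -> np.ndarray:
    """Reconstruct the substrate wall-shear-stress vector field τ = μ ∂u/∂z|₀.

    ``lubrication`` evaluates τ = 3 μ u / h sample by sample (quasi-steady
    parabolic vertical profile).

    ``stokes_layer`` decomposes each cell's velocity time series over the
    stored period into Fourier harmonics of the forcing frequency and applies
    the oscillating-plate transfer function per harmonic n ≥ 1,

        τ̂_n = (1 + i)·√(ρ μ n ω / 2)·û_n,

    while the steady (n = 0) component — the residual swirling current — is
    taken as the depth-weighted transport mean ū = ⟨h u⟩/⟨h⟩ (whose radial
    part vanishes in a periodic state, unlike the Eulerian mean, which merely
    compensates the wave flux ⟨h′u′⟩) with the wall conductance of a current
    embedded in the oscillatory boundary layer, τ_0 = μ ū / δ = √(ρμω/2)·ū.
    For a pure harmonic oscillation at ω this reduces exactly to
    τ̂ = (1 + i)·√(ρμω/2)·û. The samples must span exactly one period
    uniformly (end-exclusive), which makes the discrete transform exact for
    resolved harmonics.

    The result is stored on ``series.tau`` and returned; shape
    (n_t, n_r, n_theta, 2) in Pa.
    """
    closure = closure or series.closure
    mu = fluid.dynamic_viscosity
    rho = fluid.density
    if closure == "lubrication":
        tau = 3 * mu * series.u / series.h[..., None]
    elif closure == "stokes_layer":
        n = series.n_samples
        if n < 20:
            raise SamplingError(
                f"stokes_layer closure needs >= 20 samples per period, got {n}"
            )
        omega = shaker.omega if shaker is not None else series.omega
        spec = np.fft.rfft(series.u, axis=0)  # (n_f, n_r, n_theta, 2)
        harmonics = np.arange(spec.shape[0])
        mult = (1 + 1j) * np.sqrt(rho * mu * harmonics * omega / 2)
        tau_spec = spec * mult[:, None, None, None]
        # steady component: transport-mean current through the wave boundary layer
        u_transport = (series.h[..., None] * series.u).mean(axis=0) / series.h.mean(
            axis=0
        )[..., None]
        tau_spec[0] = n * np.sqrt(rho * mu * omega / 2) * u_transport
        tau = np.fft.irfft(tau_spec, n=n, axis=0)
    else:
        raise ConfigurationError(f"unknown closure {closure!r}")
    series.tau = tau
    return tau
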