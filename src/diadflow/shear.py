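"""Radial post-processing of wall-shear-stress fields: τ_max, OSI, regimes.

Each cell's WSS vector time series is first rotated into its local frame
(tangential, radial) using the cell azimuth, so that "flow going around the
dish" has the same representation at every azimuth. Cells are then grouped
into equal-width radial bins between d/2 and D/2 and, per bin:

``tau_max``
    maximum |τ| over member cells and time samples;
``tau_mean``
    area- and time-weighted mean of |τ|;
``osi``
    oscillatory shear index,
    OSI = 1 − |Σ_cells Σ_t w·τ_rot·Δt| / (Σ_cells Σ_t w·|τ_rot|·Δt),
    with w the cell area and the numerator the magnitude of the vector sum.
    0 means perfectly unidirectional shear, 1 a fully reversing one;
``main_direction``
    direction of the numerator vector sum, in degrees, with 0° along the
    local tangential direction and positive angles tilting outward radially.

Regime labels follow the endothelial-biology thresholds: sustained shear
below 0.2 Pa is atheroprone, above 1 Pa with low OSI atheroprotective.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .solver import FlowFieldSeries

__all__ = [
    "RadialProfile",
    "BinnedShear",
    "ResolutionError",
    "rotate_to_local",
    "radial_bin",
    "tau_max_profile",
    "tau_mean_profile",
    "osi_profile",
    "classify",
    "compute_profile",
]

#: Atheroprone upper τ_max threshold (Pa): low laminar shear below this.
TAU_LOW_PA = 0.2
#: Atheroprotective lower τ_max threshold (Pa): high laminar shear above this.
TAU_HIGH_PA = 1.0
#: Default OSI cut separating unidirectional from oscillatory regimes.
OSI_CUT = 0.1


class ResolutionError(ValueError):
    """More radial bins requested than the grid can populate."""


def rotate_to_local(vector: np.ndarray, theta: float | np.ndarray) -> np.ndarray:
    """Project dish-frame 2-vectors onto the local (tangential, radial) frame.

    The tangential unit vector at azimuth θ is (−sin θ, cos θ) (direction of
    increasing θ) and the radial one is (cos θ, sin θ). Works element-wise on
    arrays whose last axis holds (x, y); ``theta`` broadcasts against the
    leading axes.
    """
    vector = np.asarray(vector, dtype=float)
    theta = np.asarray(theta, dtype=float)
    vx, vy = vector[..., 0], vector[..., 1]
    tangential = -vx * np.sin(theta) + vy * np.cos(theta)
    radial = vx * np.cos(theta) + vy * np.sin(theta)
    return np.stack([tangential, radial], axis=-1)


@dataclass
class BinnedShear:
    """Rotated WSS time series grouped into radial bins.

    ``tau_rot`` has shape (n_t, n_r, n_theta, 2) with components
    (tangential, radial); ``bin_index`` maps each radial grid row to its bin;
    ``weights`` are cell areas (m²); ``dt`` is the uniform sample spacing.
    """

    bin_edges: np.ndarray  # (n_bins + 1,) radii in m
    r_norm: np.ndarray  # (n_bins,) bin-center radial position in [0, 1]
    bin_index: np.ndarray  # (n_r,) bin of each radial row
    tau_rot: np.ndarray  # (n_t, n_r, n_theta, 2)
    weights: np.ndarray  # (n_r, n_theta)
    dt: float
    n_bins: int

    def members(self, b: int) -> np.ndarray:
        """Radial row indices belonging to bin ``b``."""
        return np.nonzero(self.bin_index == b)[0]


def radial_bin(series: FlowFieldSeries, n_bins: int | None = None) -> BinnedShear:
    """Group the rotated WSS series into equal-width radial bins.

    Bins span the wetted radii of the grid with equal widths; every cell
    belongs to exactly one bin via its center radius. ``r_norm`` is the bin
    center normalized between d and D, i.e. 0 at the inner wall and 1 at the
    outer wall (for plain dishes simply r/(D/2), so the small numerical core
    makes the first center start slightly above 0).

    Raises
    ------
    ResolutionError
        If some bin would contain no grid cells (n_bins > n_r).
    ValueError
        If the series has no wall-shear field yet.
    """
    if series.tau is None:
        raise ValueError("series has no WSS field; run wall_shear first")
    grid = series.grid
    if n_bins is None:
        n_bins = grid.n_r
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    edges = np.linspace(grid.r_in, grid.r_out, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, grid.r, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    if (counts == 0).any():
        raise ResolutionError(
            f"{int((counts == 0).sum())} of {n_bins} radial bins are empty; "
            f"reduce n_bins (grid has n_r={grid.n_r})"
        )
    tau_rot = rotate_to_local(series.tau, grid.theta)
    centers = 0.5 * (edges[:-1] + edges[1:])
    # normalization between the dish walls d/2 and D/2 (not the numerical core)
    r_lo = grid.geom.inner_radius
    width = grid.geom.outer_radius - r_lo
    times = series.times
    dt = float(times[1] - times[0]) if times.size > 1 else 1.0
    return BinnedShear(
        bin_edges=edges,
        r_norm=(centers - r_lo) / width,
        bin_index=idx,
        tau_rot=tau_rot,
        weights=grid.cell_area,
        dt=dt,
        n_bins=n_bins,
    )


def tau_max_profile(binned: BinnedShear) -> np.ndarray:
    """Per-bin maximum |τ| over member cells and time samples (Pa)."""
    mag = np.linalg.norm(binned.tau_rot, axis=-1)  # (n_t, n_r, n_theta)
    row_max = mag.max(axis=(0, 2))  # (n_r,)
    out = np.zeros(binned.n_bins)
    np.maximum.at(out, binned.bin_index, row_max)
    return out


def tau_mean_profile(binned: BinnedShear) -> np.ndarray:
    """Per-bin area- and time-weighted mean of |τ| (Pa)."""
    mag = np.linalg.norm(binned.tau_rot, axis=-1)
    w_mag = (mag * binned.weights).sum(axis=(0, 2))  # (n_r,)
    w_tot = binned.weights.sum(axis=1) * binned.tau_rot.shape[0]  # (n_r,)
    num = np.bincount(binned.bin_index, weights=w_mag, minlength=binned.n_bins)
    den = np.bincount(binned.bin_index, weights=w_tot, minlength=binned.n_bins)
    return num / den


def osi_profile(binned: BinnedShear) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin oscillatory shear index and main shear direction.

    Returns ``(osi, main_direction_deg)``. OSI is
    1 − |Σ w τ_rot Δt| / (Σ w |τ_rot| Δt), summing over member cells and the
    stored period; the main direction is the angle of the numerator vector,
    0° tangential, positive toward outward radial. Bins with identically zero
    shear have undefined OSI and are reported as NaN with a warning.
    """
    w = binned.weights[None, ..., None]  # broadcast over time and components
    vec = (binned.tau_rot * w).sum(axis=(0, 2)) * binned.dt  # (n_r, 2)
    mag = (np.linalg.norm(binned.tau_rot, axis=-1) * binned.weights).sum(axis=(0, 2)) * binned.dt
    vec_b = np.zeros((binned.n_bins, 2))
    np.add.at(vec_b, binned.bin_index, vec)
    mag_b = np.bincount(binned.bin_index, weights=mag, minlength=binned.n_bins)
    osi = np.full(binned.n_bins, np.nan)
    direction = np.full(binned.n_bins, np.nan)
    nz = mag_b > 0
    num = np.linalg.norm(vec_b, axis=-1)
    osi[nz] = 1.0 - num[nz] / mag_b[nz]
    osi[nz] = np.clip(osi[nz], 0.0, 1.0)  # guard rounding at the boundaries
    direction[nz] = np.degrees(np.arctan2(vec_b[nz, 1], vec_b[nz, 0]))
    if (~nz).any():
        warnings.warn(
            f"OSI undefined in {int((~nz).sum())} bin(s) with zero shear; reported as NaN",
            RuntimeWarning,
            stacklevel=2,
        )
    return osi, direction


def classify(
    tau_max: np.ndarray,
    osi: np.ndarray,
    tau_low: float = TAU_LOW_PA,
    tau_high: float = TAU_HIGH_PA,
    osi_cut: float = OSI_CUT,
) -> tuple[list[str], np.ndarray]:
    """Label each bin's shear regime.

    Returns ``(labels, oscillatory_flags)`` where labels are
    ``"atheroprone_low"`` (τ_max < tau_low), ``"atheroprotective"``
    (τ_max > tau_high and OSI ≤ osi_cut) or ``"intermediate"``; bins whose
    OSI exceeds ``osi_cut`` are additionally flagged oscillatory.
    """
    tau_max = np.asarray(tau_max, dtype=float)
    osi = np.asarray(osi, dtype=float)
    labels = []
    for tm, o in zip(tau_max, osi):
        if tm < tau_low:
            labels.append("atheroprone_low")
        elif tm > tau_high and (np.isnan(o) or o <= osi_cut):
            labels.append("atheroprotective")
        else:
            labels.append("intermediate")
    oscillatory = np.nan_to_num(osi, nan=0.0) > osi_cut
    return labels, oscillatory


@dataclass
class RadialProfile:
    """Per-radial-bin shear summary of one analysed period."""

    r_norm: np.ndarray
    tau_max: np.ndarray  # Pa
    tau_mean: np.ndarray  # Pa
    osi: np.ndarray
    main_direction: np.ndarray  # degrees, 0 = tangential
    regime: list[str]
    oscillatory: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_norm": self.r_norm,
                "tau_max_Pa": self.tau_max,
                "tau_mean_Pa": self.tau_mean,
                "osi": self.osi,
                "main_direction_deg": self.main_direction,
                "regime": self.regime,
                "oscillatory": self.oscillatory,
            }
        )


def compute_profile(
    series: FlowFieldSeries,
    n_bins: int | None = None,
    tau_low: float = TAU_LOW_PA,
    tau_high: float = TAU_HIGH_PA,
    osi_cut: float = OSI_CUT,
) -> RadialProfile:
    """Full radial profile of a simulated (or prescribed) period."""
    binned = radial_bin(series, n_bins)
    tau_max = tau_max_profile(binned)
    tau_mean = tau_mean_profile(binned)
    osi, direction = osi_profile(binned)
    labels, oscillatory = classify(tau_max, osi, tau_low, tau_high, osi_cut)
    return RadialProfile(
        r_norm=binned.r_norm,
        tau_max=tau_max,
        tau_mean=tau_mean,
        osi=osi,
        main_direction=direction,
        regime=labels,
        oscillatory=oscillatory,
    )
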