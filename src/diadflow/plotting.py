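"""Visualization helpers: WSS heatmaps over the dish footprint and radial
profile plots."""

from __future__ import annotations

import numpy as np

from .shear import RadialProfile
from .solver import FlowFieldSeries

__all__ = ["wss_heatmap", "plot_profile"]


def wss_heatmap(series: FlowFieldSeries, sample: int | None = None, vmax: float | None = 0.6, ax=None):
    """Polar heatmap of |τ| on the dish substrate.

    ``sample`` picks one stored instant; None plots the per-cell maximum over
    the period. ``vmax`` fixes the color scale (0–0.6 Pa by default, handy
    when comparing designs side by side); pass None to autoscale.
    """
    import matplotlib.pyplot as plt

    if series.tau is None:
        raise ValueError("series has no WSS field; run wall_shear first")
    mag = np.linalg.norm(series.tau, axis=-1)
    field = mag.max(axis=0) if sample is None else mag[sample]
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    grid = series.grid
    theta_edges = np.linspace(0, 2 * np.pi, grid.n_theta + 1)
    mesh = ax.pcolormesh(
        theta_edges, grid.r_edges * 1e3, field, vmin=0.0, vmax=vmax, cmap="viridis"
    )
    ax.set_ylim(0, grid.r_out * 1e3)
    ax.set_yticklabels([])
    ax.set_xticklabels([])
    ax.figure.colorbar(mesh, ax=ax, label="|τ| (Pa)")
    ax.set_title(f"{grid.geom.label} dish")
    return ax


def plot_profile(profile: RadialProfile, ax=None):
    """τ_max and OSI against normalized radial position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(profile.r_norm, profile.tau_max, "o-", color="tab:blue", label=r"$\tau_{max}$ (Pa)")
    ax.set_xlabel("normalized radial position")
    ax.set_ylabel(r"$\tau_{max}$ (Pa)", color="tab:blue")
    ax2 = ax.twinx()
    ax2.plot(profile.r_norm, profile.osi, "s--", color="tab:red", label="OSI")
    ax2.set_ylabel("OSI", color="tab:red")
    ax2.set_ylim(0, 1)
    return ax
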