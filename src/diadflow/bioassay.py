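"""Experimental-validation analytics: cell orientation, ΔΔCt, outliers, t-tests.

The flow-assay readouts that accompany the hydrodynamic characterization:

* orientation histograms of endothelial monolayer micrographs via the local
  gradient structure tensor (cells align with the main shear direction under
  atheroprotective flow and orient randomly under oscillatory shear);
* relative gene-expression quantification from qPCR cycle thresholds by the
  ΔΔCt method against a reference gene and a static control group;
* single-outlier Grubbs screening of replicate groups;
* pooled-variance two-sample Student's t-tests with the conventional
  */**/*** significance levels.

A fixture generator produces deterministic synthetic inputs (stripe images
with known orientation, Ct tables with known effects, WSS vector series with
analytically known OSI) so every routine is testable without microscope or
qPCR data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .solver import FlowFieldSeries, PolarGrid, SimulationSettings, build_grid
from .geometry import DishGeometry

__all__ = [
    "OrientationHistogram",
    "DegenerateImageError",
    "orientation_histogram",
    "delta_delta_ct",
    "grubbs_test",
    "grubbs_critical_value",
    "two_sample_ttest",
    "significance_stars",
    "make_fixtures",
]


class DegenerateImageError(ValueError):
    """Image has no gradient content (constant intensity)."""


@dataclass
class OrientationHistogram:
    """Energy-weighted distribution of local structure orientations.

    Angles are in degrees in [−90, 90), measured from the image x axis
    (columns), with the row index treated as +y. ``weights`` sum to 1.
    """

    bin_centers: np.ndarray
    weights: np.ndarray
    dominant_angle: float
    dispersion: float  # circular standard deviation, degrees

    def __post_init__(self) -> None:
        if (self.weights < 0).any():
            raise ValueError("histogram weights must be non-negative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("histogram weights must sum to 1")


def _wrap_half(angle_deg: np.ndarray | float) -> np.ndarray | float:
    """Wrap orientation angles (period 180°) into [−90, 90)."""
    return (np.asarray(angle_deg) + 90.0) % 180.0 - 90.0


def orientation_histogram(
    image: np.ndarray,
    n_bins: int = 90,
    gradient_sigma: float = 1.0,
    tensor_sigma: float = 4.0,
) -> OrientationHistogram:
    """Histogram of local structure orientations of a grayscale image.

    The image is smoothed with a Gaussian of ``gradient_sigma`` pixels, the
    per-pixel gradient structure tensor is averaged over ``tensor_sigma``
    pixels, and the orientation perpendicular to the dominant gradient (i.e.
    along the image structures) is accumulated into ``n_bins`` bins over
    [−90, 90), weighted by tensor energy × coherence so isotropic regions
    contribute little. The dominant angle is the circular mean (period 180°)
    of the top mode (peak bin ± 5 bins); dispersion is the circular standard
    deviation of the whole distribution.

    Raises
    ------
    DegenerateImageError
        For a constant image (zero gradient everywhere).
    ValueError
        For images smaller than 64×64 pixels.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 64:
        raise ValueError(f"need a 2-D grayscale image of at least 64x64 px, got {image.shape}")
    smoothed = gaussian_filter(image, gradient_sigma)
    gy, gx = np.gradient(smoothed)  # rows = y, columns = x
    jxx = gaussian_filter(gx * gx, tensor_sigma)
    jyy = gaussian_filter(gy * gy, tensor_sigma)
    jxy = gaussian_filter(gx * gy, tensor_sigma)
    energy = jxx + jyy
    if not energy.max() > 0:
        raise DegenerateImageError("constant image: orientation is undefined")
    # dominant gradient orientation, rotated 90° to the structure orientation
    grad_angle = 0.5 * np.arctan2(2 * jxy, jxx - jyy)
    struct_angle = _wrap_half(np.degrees(grad_angle) + 90.0)
    lam_diff = np.sqrt((jxx - jyy) ** 2 + 4 * jxy**2)
    coherence = np.where(energy > 0, lam_diff / (energy + 1e-300), 0.0)
    w = (energy * coherence).ravel()
    edges = np.linspace(-90.0, 90.0, n_bins + 1)
    hist, _ = np.histogram(struct_angle.ravel(), bins=edges, weights=w)
    total = hist.sum()
    if not total > 0:
        raise DegenerateImageError("image has no oriented structure")
    weights = hist / total
    centers = 0.5 * (edges[:-1] + edges[1:])
    # top mode: circular mean over peak bin ± 5 bins (doubled angles, period 180°)
    peak = int(np.argmax(weights))
    idx = (peak + np.arange(-5, 6)) % n_bins
    ang2 = np.radians(2 * centers[idx])
    z = np.sum(weights[idx] * np.exp(1j * ang2))
    dominant = float(_wrap_half(np.degrees(np.angle(z)) / 2))
    # circular dispersion of the full histogram
    z_all = np.sum(weights * np.exp(1j * np.radians(2 * centers)))
    r = min(abs(z_all), 1.0)
    dispersion = float(np.degrees(np.sqrt(-2 * np.log(max(r, 1e-300)))) / 2)
    return OrientationHistogram(
        bin_centers=centers, weights=weights, dominant_angle=dominant, dispersion=dispersion
    )


def delta_delta_ct(
    table: pd.DataFrame,
    target_gene: str,
    reference_gene: str = "GAPDH",
    control_group: str = "static",
) -> pd.DataFrame:
    """Relative expression by the ΔΔCt method.

    ``table`` is long-format with columns ``sample, group, gene, ct``
    (technical replicates — duplicate sample/gene rows — are averaged on Ct
    first). Per sample, ΔCt = Ct_target − Ct_reference; ΔΔCt subtracts the
    control-group mean ΔCt; fold change = 2^(−ΔΔCt), assuming perfect
    amplification efficiency.

    Returns a per-sample DataFrame with columns
    ``sample, group, dct, ddct, fold_change``.
    """
    required = {"sample", "group", "gene", "ct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"Ct table is missing columns {sorted(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    ct = (
        table.groupby(["sample", "group", "gene"], as_index=False)["ct"]
        .mean()
        .pivot_table(index=["sample", "group"], columns="gene", values="ct")
    )
    for gene in (target_gene, reference_gene):
        if gene not in ct.columns or ct[gene].isna().any():
            raise ValueError(f"gene {gene!r} missing for some samples")
    out = ct.reset_index()[["sample", "group"]].copy()
    out["dct"] = (ct[target_gene] - ct[reference_gene]).to_numpy()
    control = out.loc[out["group"] == control_group, "dct"]
    if control.empty:
        raise ValueError(f"control group {control_group!r} not present in table")
    out["ddct"] = out["dct"] - control.mean()
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out


def grubbs_critical_value(n: int, alpha: float = 0.05) -> float:
    """Two-sided critical value of the single-outlier Grubbs statistic."""
    t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_test(values, alpha: float = 0.05) -> int | None:
    """Two-sided single-outlier Grubbs test.

    Returns the index of the flagged value, or None if the maximum
    studentized deviation G = max|x − x̄|/s stays below the critical value at
    level ``alpha``. Applied at most once per group (one candidate outlier).

    Raises
    ------
    ValueError
        For fewer than 3 values or zero sample standard deviation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"Grubbs test needs at least 3 values, got {n}")
    s = x.std(ddof=1)
    if not s > 0:
        raise ValueError("Grubbs test undefined for zero-variance data")
    dev = np.abs(x - x.mean())
    g = dev.max() / s
    if g > grubbs_critical_value(n, alpha):
        return int(np.argmax(dev))
    return None


def two_sample_ttest(a, b) -> tuple[float, float]:
    """Pooled-variance two-sided Student's t-test.

    Returns ``(t, p)``. Degenerate input (zero pooled variance) yields
    ``(0.0, 1.0)`` when the means agree and raises otherwise, since a
    difference with no variance has no meaningful t statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero pooled variance with unequal means: t is undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Conventional significance marks: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# fixture generation
# --------------------------------------------------------------------------


def make_fixtures(kind: str, parameters: dict | None = None, seed: int = 0):
    """Deterministic synthetic inputs for the analytics above.

    Kinds
    -----
    ``"stripes"``
        Sinusoidal stripe image with known orientation. Parameters:
        ``angle_deg`` (default 30), ``shape`` (128, 128), ``frequency``
        (cycles/px, 0.08), ``noise`` (sd, 0).
    ``"ct_table"``
        Long-format Ct table with a static control group and one flow group.
        Parameters: ``genes`` mapping gene → Ct shift in cycles for the flow
        group (negative = upregulated), ``n_per_group`` (3), ``reference_ct``
        (18), ``target_ct`` (24), ``noise`` (cycles sd, 0), ``reference_gene``
        ("GAPDH").
    ``"wss_series"``
        One period of a WSS vector field on a small annular grid whose
        tangential component holds +magnitude for a fraction (1 − f) of the
        period and −magnitude for the fraction f = ``reversal_fraction``,
        giving an exactly known OSI of 1 − |1 − 2f| (so 0.5 at f = 0.25).
        Parameters: ``reversal_fraction`` (0.25), ``magnitude`` (Pa, 1.0),
        ``n_samples`` (20), ``omega`` (rad/s, 20.944).

    Identical (kind, parameters, seed) return bit-identical fixtures.
    """
    p = dict(parameters or {})
    rng = np.random.default_rng(seed)
    if kind == "stripes":
        angle = np.radians(p.get("angle_deg", 30.0))
        shape = p.get("shape", (128, 128))
        freq = p.get("frequency", 0.08)
        noise = p.get("noise", 0.0)
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
        # intensity constant along (cos a, sin a): stripes oriented at `angle`
        phase = 2 * np.pi * freq * (-xx * np.sin(angle) + yy * np.cos(angle))
        img = 0.5 + 0.5 * np.sin(phase)
        if noise:
            img = img + rng.normal(0.0, noise, size=img.shape)
        return img
    if kind == "ct_table":
        genes = p.get("genes", {"KLF2": -1.0})
        n = p.get("n_per_group", 3)
        ref_ct = p.get("reference_ct", 18.0)
        tgt_ct = p.get("target_ct", 24.0)
        noise = p.get("noise", 0.0)
        ref_gene = p.get("reference_gene", "GAPDH")
        rows = []
        for group, shifted in (("static", False), ("flow", True)):
            for i in range(n):
                sample = f"{group}_{i + 1}"
                rows.append((sample, group, ref_gene, ref_ct + (rng.normal(0, noise) if noise else 0.0)))
                for gene, shift in genes.items():
                    ct = tgt_ct + (shift if shifted else 0.0)
                    if noise:
                        ct += rng.normal(0, noise)
                    rows.append((sample, group, gene, ct))
        return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])
    if kind == "wss_series":
        f = p.get("reversal_fraction", 0.25)
        mag = p.get("magnitude", 1.0)
        n_t = p.get("n_samples", 20)
        omega = p.get("omega", 20.944)
        if not 0 <= f <= 1:
            raise ValueError(f"reversal_fraction must be in [0, 1], got {f}")
        geom = p.get("geom", DishGeometry.from_mm(134, 56))
        settings = SimulationSettings(n_r=p.get("n_r", 4), n_theta=p.get("n_theta", 8))
        grid = build_grid(geom, settings)
        T = 2 * np.pi / omega
        times = np.arange(n_t) / n_t * T
        sign = np.where(times < (1 - f) * T, 1.0, -1.0)
        # tangential unit vector at each azimuth, dish-frame components
        tang = np.stack([-np.sin(grid.theta), np.cos(grid.theta)], axis=-1)  # (n_theta, 2)
        tau = (
            sign[:, None, None, None]
            * mag
            * np.broadcast_to(tang, (grid.n_r, grid.n_theta, 2))[None, ...]
        )
        u = np.zeros_like(tau)
        return FlowFieldSeries.from_arrays(
            grid, times, u, h=3e-3, omega=omega, tau=tau.copy()
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
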