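"""Tangential curvature and refractive power maps.

The tangential (instantaneous) curvature along each meridian is

    Kt = |d2Z/drho2| / (1 + (dZ/drho)^2)^(3/2),

with the radial derivatives of the height Z taken along the meridian.  The
tangential refractive power uses the keratometric index convention

    Pt = (n_h - n_air) / Rt        (Rt in metres),

with n_h = 1.3375, i.e. Pt [D] = 337.5 / Rt [mm].  The hypothetical index
compensates for the posterior corneal surface, which Placido-style
topographers do not measure; when both surfaces *are* known the Gaussian
thick-lens formula (:func:`gaussian_net_power`) applies instead.

Derivatives are computed with least-squares local-polynomial (Savitzky–Golay)
filters so that differentiation and smoothing are mutually consistent on
noisy height data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d
from scipy.signal import savgol_filter

from .grids import CartesianGrid, PolarGrid
from .surface import CornealSurface

__all__ = [
    "RefractiveIndices",
    "GaussianOpticsParams",
    "CurvatureMap",
    "PowerMap",
    "DifferenceMap",
    "radial_distance",
    "tangential_curvature",
    "tangential_power",
    "gaussian_net_power",
    "power_difference_map",
    "smooth_map",
]

#: physiologic plausibility bounds; values outside are masked, not clipped
_KT_BOUNDS = (0.05, 0.5)  # mm^-1
_POWER_BOUNDS = (20.0, 80.0)  # D


@dataclass(frozen=True)
class RefractiveIndices:
    """Refractive indices of the ocular media (Gullstrand relaxed-eye values)."""

    n_air: float = 1.0
    n_cornea: float = 1.376
    n_aqueous: float = 1.336
    n_keratometric: float = 1.3375

    def __post_init__(self) -> None:
        for name in ("n_air", "n_cornea", "n_aqueous", "n_keratometric"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class GaussianOpticsParams:
    """Inputs to the thick-lens (Gaussian optics) corneal power formula."""

    r_anterior: float  # mm
    r_posterior: float  # mm
    cct: float  # central corneal thickness, mm
    indices: RefractiveIndices = field(default_factory=RefractiveIndices)

    def __post_init__(self) -> None:
        if self.r_anterior == 0 or self.r_posterior == 0:
            raise ValueError("surface radii must be nonzero")
        if not (0.0 <= self.cct < 0.8):
            raise ValueError("CCT must be in [0, 0.8) mm")


@dataclass
class CurvatureMap:
    """Tangential curvature Kt (mm^-1) and radius Rt (mm) per node."""

    grid: PolarGrid | CartesianGrid
    tangential_curvature: np.ndarray  # mm^-1
    mask: np.ndarray

    @property
    def tangential_radius(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.tangential_curvature > 0, 1.0 / self.tangential_curvature, np.nan)


@dataclass
class PowerMap:
    """Tangential refractive power Pt (D) per node."""

    grid: PolarGrid | CartesianGrid
    power: np.ndarray  # D
    mask: np.ndarray


@dataclass
class DifferenceMap:
    """Post-minus-pre tangential power change (D) per node."""

    grid: PolarGrid | CartesianGrid
    delta_power: np.ndarray  # D
    mask: np.ndarray


def radial_distance(grid: CartesianGrid | PolarGrid) -> np.ndarray:
    """Node-wise radial distance from the apex, rho_g = sqrt(Xg^2 + Yg^2) (mm)."""
    return grid.node_rho()


def tangential_curvature(
    surface: CornealSurface,
    window: int = 5,
    polyorder: int = 2,
    physiologic_bounds: tuple[float, float] | None = _KT_BOUNDS,
) -> CurvatureMap:
    """Meridional tangential curvature of a polar-grid surface.

    First and second radial derivatives are estimated per meridian with a
    Savitzky–Golay filter (default 5-point local quadratic).  Curvature is
    reported as a magnitude (convex-positive).  The apex node (where the
    meridional parametrisation is singular) and the outermost ``window//2``
    fringe nodes are masked, as are nodes with incomplete stencils due to
    missing data and — unless ``physiologic_bounds`` is None — nodes with
    curvature outside the plausible corneal range (0.05–0.5 mm^-1).
    """
    if not surface.is_polar:
        raise ValueError(
            "tangential_curvature operates per meridian: resample to a polar grid first"
        )
    grid: PolarGrid = surface.grid  # type: ignore[assignment]
    if grid.n_radii < max(5, window):
        raise ValueError(f"need at least {max(5, window)} radial samples per meridian")
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and exceed polyorder")
    dr = grid.radial_spacing

    h = surface.heights.copy()
    mask = surface.mask.copy()
    # fill masked nodes so the filter runs; anything within a half-window of a
    # masked node is masked afterwards (incomplete stencil)
    if mask.any():
        for i in range(grid.n_angles):
            row_bad = mask[i]
            if row_bad.all():
                continue
            if row_bad.any():
                r = grid.radii
                h[i, row_bad] = np.interp(r[row_bad], r[~row_bad], h[i, ~row_bad])
        half = window // 2
        widened = mask.copy()
        for s in range(1, half + 1):
            widened[:, s:] |= mask[:, :-s]
            widened[:, :-s] |= mask[:, s:]
        mask = widened
        h[surface.mask & mask] = 0.0  # fully-masked rows: value irrelevant
        h = np.nan_to_num(h)

    dz = savgol_filter(h, window, polyorder, deriv=1, delta=dr, axis=1, mode="interp")
    d2z = savgol_filter(h, window, polyorder, deriv=2, delta=dr, axis=1, mode="interp")
    with np.errstate(invalid="ignore"):
        kt = np.abs(d2z) / np.power(1.0 + dz**2, 1.5)

    out_mask = mask.copy()
    out_mask[:, 0] = True  # apex: rho = 0 singular on polar sampling
    half = window // 2
    out_mask[:, -half:] = True  # outer fringe: one-sided stencil
    out_mask |= ~np.isfinite(kt)
    if physiologic_bounds is not None:
        out_mask |= (kt < physiologic_bounds[0]) | (kt > physiologic_bounds[1])
    kt = np.where(out_mask, np.nan, kt)
    return CurvatureMap(grid, kt, out_mask)


def tangential_power(
    curv: CurvatureMap, indices: RefractiveIndices | None = None
) -> PowerMap:
    """Convert tangential curvature to keratometric refractive power.

    Pt [D] = (n_h - n_air) / Rt [m]  =  (n_h - n_air) * 1000 * Kt [mm^-1].
    """
    if indices is None:
        indices = RefractiveIndices()
    dn = indices.n_keratometric - indices.n_air
    if dn <= 0:
        raise ValueError("keratometric index must exceed the ambient index")
    p = dn * 1000.0 * curv.tangential_curvature
    mask = curv.mask | ~np.isfinite(p) | (p < _POWER_BOUNDS[0]) | (p > _POWER_BOUNDS[1])
    return PowerMap(curv.grid, np.where(mask, np.nan, p), mask)


def gaussian_net_power(params: GaussianOpticsParams) -> float:
    """Thick-lens net corneal power (D) from both surface radii and thickness.

    P_net = P_ant + P_post - (CCT / n_cornea) * P_ant * P_post, with
    P_ant = (n_cornea - n_air)/R_ant and P_post = (n_aqueous - n_cornea)/R_post,
    radii in metres, CCT in metres.
    """
    n = params.indices
    r_ant_m = params.r_anterior * 1e-3
    r_post_m = params.r_posterior * 1e-3
    cct_m = params.cct * 1e-3
    p_ant = (n.n_cornea - n.n_air) / r_ant_m
    p_post = (n.n_aqueous - n.n_cornea) / r_post_m
    return p_ant + p_post - (cct_m / n.n_cornea) * p_ant * p_post


def power_difference_map(pre: PowerMap, post: PowerMap) -> DifferenceMap:
    """Node-wise post-minus-pre power change; masks are unioned."""
    if pre.grid != post.grid:
        raise ValueError("power maps are on different grids; re-mesh upstream first")
    mask = pre.mask | post.mask
    delta = np.where(mask, np.nan, post.power - pre.power)
    return DifferenceMap(pre.grid, delta, mask)


def _masked_gaussian_cartesian(values: np.ndarray, mask: np.ndarray, sigma_nodes) -> np.ndarray:
    w = (~mask).astype(float)
    v = np.where(mask, 0.0, values)
    num = gaussian_filter(v * w, sigma_nodes, mode="constant")
    den = gaussian_filter(w, sigma_nodes, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[mask] = np.nan
    return out


def smooth_map(dmap: DifferenceMap, sigma: float = 0.15) -> DifferenceMap:
    """Mask-aware Gaussian smoothing with a physical kernel width (mm).

    On Cartesian grids this is isotropic plane smoothing.  On polar grids the
    kernel is applied separably: along the radius with a fixed width
    ``sigma``, and along each ring with an angular width ``sigma / r``
    (capped at 60 deg), which approximates isotropic plane smoothing away
    from the apex.  ``sigma = 0`` is the identity.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return DifferenceMap(dmap.grid, dmap.delta_power.copy(), dmap.mask.copy())
    if isinstance(dmap.grid, CartesianGrid):
        dx = float(np.diff(dmap.grid.x_coords)[0])
        dy = float(np.diff(dmap.grid.y_coords)[0])
        out = _masked_gaussian_cartesian(dmap.delta_power, dmap.mask, (sigma / dy, sigma / dx))
        return DifferenceMap(dmap.grid, out, dmap.mask.copy())

    grid: PolarGrid = dmap.grid  # type: ignore[assignment]
    dr = grid.radial_spacing
    dphi = 360.0 / grid.n_angles  # assumes uniform angular sampling
    w = (~dmap.mask).astype(float)
    v = np.where(dmap.mask, 0.0, dmap.delta_power)
    # radial pass (axis 1), truncated at the map edges
    num = gaussian_filter1d(v * w, sigma / dr, axis=1, mode="constant")
    den = gaussian_filter1d(w, sigma / dr, axis=1, mode="constant")
    # angular pass per ring (axis 0), periodic; width shrinks with radius
    for j, r in enumerate(grid.radii):
        if r <= 0:
            continue
        sig_deg = np.rad2deg(sigma / r)
        sig_nodes = min(sig_deg, 60.0) / dphi
        if sig_nodes <= 0:
            continue
        num[:, j] = gaussian_filter1d(num[:, j], sig_nodes, mode="wrap")
        den[:, j] = gaussian_filter1d(den[:, j], sig_nodes, mode="wrap")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[dmap.mask] = np.nan
    return DifferenceMap(grid, out, dmap.mask.copy())
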