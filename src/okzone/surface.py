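"""Corneal surfaces: height fields on a grid, with laterality and missing-data mask.

Heights follow the ``Z = -sag`` convention: the apex is the reference (Z = 0)
and the surface drops away from the apex-tangent plane, so Z is increasingly
negative toward the periphery.  With this sign the piston and defocus
coefficients of a Zernike height fit come out negative, matching clinical
reporting of elevation fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import (
    CloughTocher2DInterpolator,
    LinearNDInterpolator,
    RegularGridInterpolator,
)

from .grids import CartesianGrid, PolarGrid

__all__ = [
    "CornealSurface",
    "polar_to_cartesian",
    "remesh_to_common_grid",
    "mirror_for_laterality",
]

_LATERALITIES = ("OD", "OS")
_MAX_ABS_HEIGHT_MM = 6.0


@dataclass
class CornealSurface:
    """One eye's anterior corneal height field.

    Parameters
    ----------
    grid : PolarGrid or CartesianGrid
        Sampling lattice.
    heights : ndarray, mm
        Elevation Z at each node (0 at the apex, negative peripherally).
        Shape must match ``grid.shape``.
    laterality : {"OD", "OS"}
        Right or left eye.
    mask : ndarray of bool, optional
        True where data are absent.  Masked nodes carry NaN-safe zeros in
        ``heights`` and are skipped by every downstream operation.
    """

    grid: PolarGrid | CartesianGrid
    heights: np.ndarray
    laterality: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.laterality not in _LATERALITIES:
            raise ValueError(f"laterality must be one of {_LATERALITIES}, got {self.laterality!r}")
        h = np.asarray(self.heights, dtype=float)
        if h.shape != self.grid.shape:
            raise ValueError(f"heights shape {h.shape} does not match grid shape {self.grid.shape}")
        if self.mask is None:
            mask = ~np.isfinite(h)
        else:
            mask = np.asarray(self.mask, dtype=bool)
            if mask.shape != h.shape:
                raise ValueError("mask shape does not match heights shape")
            mask = mask | ~np.isfinite(h)
        valid = h[~mask]
        if valid.size and np.any(np.abs(valid) >= _MAX_ABS_HEIGHT_MM):
            raise ValueError("implausible corneal heights (|Z| >= 6 mm); check units (mm expected)")
        h = h.copy()
        h[mask] = np.nan
        self.heights = h
        self.mask = mask

    # -- basic geometry -------------------------------------------------
    @property
    def is_polar(self) -> bool:
        return isinstance(self.grid, PolarGrid)

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.node_xy()

    def node_rho(self) -> np.ndarray:
        return self.grid.node_rho()

    def n_valid(self) -> int:
        return int((~self.mask).sum())

    def copy(self) -> "CornealSurface":
        return CornealSurface(self.grid, self.heights.copy(), self.laterality, self.mask.copy())

    # -- interpolation helper -------------------------------------------
    def interpolate_at(self, x: np.ndarray, y: np.ndarray, method: str = "auto") -> np.ndarray:
        """Heights at arbitrary display-frame points (NaN outside support).

        For a fully valid polar surface a separable cubic interpolant in
        (angle, radius) space is used (fast, periodic in angle); otherwise
        triangulation-based cubic interpolation over the valid scattered
        nodes, with a linear fallback at the convex-hull fringe.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if method == "auto":
            method = "structured" if (self.is_polar and not self.mask.any()) else "scattered"
        if method == "structured":
            if not self.is_polar:
                raise ValueError("structured interpolation requires a polar grid")
            return self._interp_polar_structured(x, y)
        return self._interp_scattered(x, y)

    def _interp_polar_structured(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        grid: PolarGrid = self.grid  # type: ignore[assignment]
        ang = grid.meridian_angles
        # wrap-pad the angular axis so interpolation is periodic
        npad = min(3, ang.size)
        ang_ext = np.concatenate([ang[-npad:] - 360.0, ang, ang[:npad] + 360.0])
        h_ext = np.concatenate(
            [self.heights[-npad:], self.heights, self.heights[:npad]], axis=0
        )
        kind = "cubic" if ang.size >= 4 and grid.radii.size >= 4 else "linear"
        itp = RegularGridInterpolator(
            (ang_ext, grid.radii), h_ext, method=kind, bounds_error=False, fill_value=np.nan
        )
        rho = np.hypot(x, y)
        phi = np.rad2deg(np.arctan2(y, x)) % 360.0
        out = itp(np.stack([phi.ravel(), rho.ravel()], axis=-1)).reshape(x.shape)
        out = np.where(rho > grid.radii[-1], np.nan, out)
        return out

    def _interp_scattered(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        gx, gy = self.node_xy()
        ok = ~self.mask
        pts = np.column_stack([gx[ok], gy[ok]])
        vals = self.heights[ok]
        if pts.shape[0] < 4:
            raise ValueError("too few valid nodes for scattered interpolation")
        # de-duplicate coincident nodes (the polar apex appears once per meridian)
        pts_r = np.round(pts, 12)
        _, idx = np.unique(pts_r, axis=0, return_index=True)
        pts, vals = pts[idx], vals[idx]
        q = np.column_stack([x.ravel(), y.ravel()])
        ct = CloughTocher2DInterpolator(pts, vals)
        out = ct(q)
        bad = ~np.isfinite(out)
        if bad.any():
            lin = LinearNDInterpolator(pts, vals)
            out[bad] = lin(q[bad])
        return out.reshape(x.shape)


def polar_to_cartesian(surface: CornealSurface, target: CartesianGrid) -> CornealSurface:
    """Resample a polar surface onto a Cartesian grid.

    Nodes with rho_g beyond the outermost measured radius (or inside holes the
    interpolation cannot bridge) are masked.
    """
    if not surface.is_polar:
        raise ValueError("polar_to_cartesian expects a polar-grid surface")
    grid: PolarGrid = surface.grid  # type: ignore[assignment]
    if grid.n_angles < 3:
        raise ValueError("need at least 3 meridians to resample")
    if target.x_coords.size == 0 or target.y_coords.size == 0:
        raise ValueError("target grid is empty")
    x, y = target.node_xy()
    h = surface.interpolate_at(x, y)
    rho = np.hypot(x, y)
    h = np.where(rho > grid.radii[-1], np.nan, h)
    return CornealSurface(target, h, surface.laterality)


def remesh_to_common_grid(
    pre: CornealSurface, post: CornealSurface
) -> tuple[CornealSurface, CornealSurface]:
    """Resample ``post`` onto ``pre``'s grid so the two maps are node-wise comparable.

    Uses triangulation-based (Clough–Tocher) cubic interpolation of the post
    surface at the pre surface's nodes; the pre surface is returned unchanged.
    The union of the masks is propagated.  If the post surface is already on
    the pre grid it is returned as-is (identity re-mesh).
    """
    if pre.laterality != post.laterality:
        raise ValueError(f"laterality mismatch: pre is {pre.laterality}, post is {post.laterality}")
    if post.grid == pre.grid:
        h = post.heights.copy()
        m = pre.mask | post.mask
        h[m] = np.nan
        return pre, CornealSurface(pre.grid, h, post.laterality, m)
    # measured-region overlap check: both must cover a central 3 mm radius
    for name, s in (("pre", pre), ("post", post)):
        rho = s.node_rho()
        if not np.any((rho <= 3.0) & ~s.mask):
            raise ValueError(f"{name} surface has no valid data within the central 3 mm radius")
    x, y = pre.node_xy()
    h = post.interpolate_at(x, y, method="scattered")
    m = pre.mask | ~np.isfinite(h)
    return pre, CornealSurface(pre.grid, h, post.laterality, m)


def mirror_for_laterality(surface: CornealSurface) -> CornealSurface:
    """Mirror a surface into its fellow-eye orientation.

    The display-frame X axis is negated and the laterality toggled.  Because
    the nasal side sits on opposite display sides for OD and OS, anatomical
    directions are preserved: a nasal-superior feature of an OD surface is
    still nasal-superior on the mirrored OS surface.  The operation is an
    involution and preserves heights and mask node-wise.
    """
    other = "OS" if surface.laterality == "OD" else "OD"
    if surface.is_polar:
        grid: PolarGrid = surface.grid  # type: ignore[assignment]
        # x -> -x maps meridian angle phi -> (180 - phi) mod 360
        new_ang = (180.0 - grid.meridian_angles) % 360.0
        order = np.argsort(new_ang)
        new_grid = PolarGrid(new_ang[order], grid.radii)
        h = surface.heights[order]
        m = surface.mask[order]
        return CornealSurface(new_grid, h, other, m)
    cg: CartesianGrid = surface.grid  # type: ignore[assignment]
    # x_coords are symmetric about 0, so the grid is unchanged; flip columns
    return CornealSurface(
        cg, surface.heights[:, ::-1].copy(), other, surface.mask[:, ::-1].copy()
    )
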