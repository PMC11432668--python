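"""Sampling grids for anterior corneal surfaces.

Two grid families are supported:

* :class:`PolarGrid` — the acquisition lattice of Placido videokeratoscopes:
  a fixed set of meridian angles crossed with a fixed set of radial distances
  from the corneal apex.  The default density (300 meridians x 333 radii over
  0–6 mm) mirrors the export grid of the Medmont E300.
* :class:`CartesianGrid` — a uniform x/y lattice covering the map area,
  used for display-space operations and re-meshing.

Coordinate frame
----------------
Surfaces are stored in the *display* frame: ``+Y`` is superior and ``+X`` is
the right-hand side of the map as conventionally displayed, which is the
nasal side for a right eye (OD) and the temporal side for a left eye (OS).
Meridian angles are measured counterclockwise from ``+X``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PolarGrid", "CartesianGrid", "default_polar_grid", "default_cartesian_grid"]

#: Acquisition grid density: number of meridians and radial positions.
DEFAULT_N_ANGLES = 300
DEFAULT_N_RADII = 333
#: Radial extent of the measured map in mm.
DEFAULT_MAX_RADIUS_MM = 6.0
#: Cartesian map half-span in mm (maps cover -6..6 mm in x and y).
DEFAULT_HALF_SPAN_MM = 6.0


@dataclass(frozen=True)
class PolarGrid:
    """Polar sampling lattice: ``meridian_angles`` (deg, CCW from +X) x ``radii`` (mm)."""

    meridian_angles: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        ang = np.asarray(self.meridian_angles, dtype=float)
        rad = np.asarray(self.radii, dtype=float)
        if ang.ndim != 1 or rad.ndim != 1:
            raise ValueError("meridian_angles and radii must be 1-D")
        if ang.size < 1 or rad.size < 1:
            raise ValueError("grid must contain at least one angle and one radius")
        if np.any(ang < 0.0) or np.any(ang >= 360.0):
            raise ValueError("meridian angles must lie in [0, 360)")
        if np.any(np.diff(ang) <= 0):
            raise ValueError("meridian angles must be strictly increasing (and unique)")
        if np.any(rad < 0.0):
            raise ValueError("radii must be non-negative")
        if rad.size > 1 and np.any(np.diff(rad) <= 0):
            raise ValueError("radii must be strictly increasing")
        object.__setattr__(self, "meridian_angles", ang)
        object.__setattr__(self, "radii", rad)

    @property
    def n_angles(self) -> int:
        return self.meridian_angles.size

    @property
    def n_radii(self) -> int:
        return self.radii.size

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape of node-wise fields: (n_angles, n_radii)."""
        return (self.n_angles, self.n_radii)

    @property
    def radial_spacing(self) -> float:
        """Uniform radial step in mm; raises if the radii are not uniform."""
        dr = np.diff(self.radii)
        if dr.size == 0:
            raise ValueError("grid has a single radius; no spacing defined")
        if not np.allclose(dr, dr[0], rtol=1e-6, atol=1e-12):
            raise ValueError("radii are not uniformly spaced")
        return float(dr[0])

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Display-frame x, y (mm) of every node, shape (n_angles, n_radii)."""
        phi = np.deg2rad(self.meridian_angles)[:, None]
        r = self.radii[None, :]
        return r * np.cos(phi), r * np.sin(phi)

    def node_rho(self) -> np.ndarray:
        """Radial distance from the apex of every node, shape (n_angles, n_radii)."""
        return np.broadcast_to(self.radii[None, :], self.shape).copy()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PolarGrid):
            return NotImplemented
        return (
            self.meridian_angles.shape == other.meridian_angles.shape
            and self.radii.shape == other.radii.shape
            and np.array_equal(self.meridian_angles, other.meridian_angles)
            and np.array_equal(self.radii, other.radii)
        )


@dataclass(frozen=True)
class CartesianGrid:
    """Uniform Cartesian lattice: ``x_coords`` (nasal–temporal) x ``y_coords`` (sup–inf), mm."""

    x_coords: np.ndarray
    y_coords: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x_coords, dtype=float)
        y = np.asarray(self.y_coords, dtype=float)
        for name, c in (("x_coords", x), ("y_coords", y)):
            if c.ndim != 1 or c.size < 2:
                raise ValueError(f"{name} must be 1-D with at least 2 points")
            d = np.diff(c)
            if np.any(d <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-12):
                raise ValueError(f"{name} must be uniformly spaced")
            if abs(c[0] + c[-1]) > 1e-9:
                raise ValueError(f"{name} must be symmetric about 0")
        object.__setattr__(self, "x_coords", x)
        object.__setattr__(self, "y_coords", y)

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape of node-wise fields: (n_y, n_x) — row-major image layout."""
        return (self.y_coords.size, self.x_coords.size)

    def node_xy(self) -> tuple[np.ndarray, np.ndarray]:
        x, y = np.meshgrid(self.x_coords, self.y_coords)
        return x, y

    def node_rho(self) -> np.ndarray:
        """Radial distance rho_g = sqrt(Xg^2 + Yg^2) of every node."""
        x, y = self.node_xy()
        return np.hypot(x, y)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CartesianGrid):
            return NotImplemented
        return (
            self.x_coords.shape == other.x_coords.shape
            and self.y_coords.shape == other.y_coords.shape
            and np.array_equal(self.x_coords, other.x_coords)
            and np.array_equal(self.y_coords, other.y_coords)
        )


def default_polar_grid(
    n_angles: int = DEFAULT_N_ANGLES,
    n_radii: int = DEFAULT_N_RADII,
    max_radius: float = DEFAULT_MAX_RADIUS_MM,
) -> PolarGrid:
    """The acquisition-style polar grid: uniform angles in [0, 360), uniform radii 0..max.

    Whether the native instrument grid is uniform in radius is not documented;
    uniform radial spacing is assumed (and is what downstream differentiation
    expects), with the density configurable.
    """
    angles = np.arange(n_angles) * (360.0 / n_angles)
    radii = np.linspace(0.0, max_radius, n_radii)
    return PolarGrid(angles, radii)


def default_cartesian_grid(n: int = 241, half_span: float = DEFAULT_HALF_SPAN_MM) -> CartesianGrid:
    """Uniform Cartesian grid covering -half_span..half_span mm (default 0.05 mm step)."""
    c = np.linspace(-half_span, half_span, n)
    return CartesianGrid(c, c.copy())
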