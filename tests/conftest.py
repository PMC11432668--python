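"""Shared fixtures: small polar grids and analytic surfaces.

Unit tests run on reduced grid densities (the operators are resolution
independent); the acceptance suite exercises the full 300x333 acquisition
grid.
"""

from __future__ import annotations

import numpy as np
import pytest

from okzone import BaselineParams, CornealSurface, PolarGrid, generate_baseline_surface
from okzone.grids import default_polar_grid


@pytest.fixture(scope="session")
def small_grid() -> PolarGrid:
    """120 meridians x 161 radii over 0-6 mm: fast but derivative-accurate."""
    return default_polar_grid(n_angles=120, n_radii=161)


@pytest.fixture(scope="session")
def tiny_grid() -> PolarGrid:
    """Very coarse grid for sampling-theory tests where map accuracy is irrelevant."""
    return default_polar_grid(n_angles=24, n_radii=41)


def sphere_surface(radius: float, grid: PolarGrid, laterality: str = "OD") -> CornealSurface:
    params = BaselineParams(flat_radius=radius, steep_radius=radius, q=0.0, noise_sd=0.0)
    return generate_baseline_surface(params, grid, seed=0, laterality=laterality)


def analytic_sphere_sag(radius: float, rho: np.ndarray) -> np.ndarray:
    """Height (Z = -sag) of a sphere of the given radius: z = -(R - sqrt(R^2 - rho^2))."""
    return -(radius - np.sqrt(radius**2 - rho**2))


@pytest.fixture(scope="session")
def sphere75(small_grid) -> CornealSurface:
    return sphere_surface(7.5, small_grid)
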