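"""Corneal astigmatism from the central tangential power map.

The flat and steep meridians are searched with a 1 deg angular step over the
central 3 mm diameter of the tangential power map (the map centre is taken
to lie on the corneal visual axis); the steep-minus-flat power difference is
the corneal astigmatism magnitude.  Lenticular astigmatism is assumed
unchanged between visits, so the post-minus-pre change in this quantity is
the ortho-k–induced corneal astigmatism change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import PolarGrid
from .power import PowerMap

__all__ = [
    "AstigmatismResult",
    "meridional_power_profile",
    "quantify_astigmatism",
    "astigmatism_change",
]

#: central zone radius (3 mm diameter) and axis search resolution
CENTRAL_ZONE_RADIUS_MM = 1.5
AXIS_STEP_DEG = 1.0
_FLAT_PROFILE_EPS_D = 1e-6


@dataclass
class AstigmatismResult:
    """Flat/steep meridian powers and their difference (corneal astigmatism)."""

    flat_power: float  # D
    steep_power: float  # D
    flat_axis: float | None  # deg in [0, 180); None if indeterminate
    steep_axis: float | None  # deg in [0, 180)
    magnitude: float  # D, steep - flat >= 0


def meridional_power_profile(
    power: PowerMap,
    zone_radius: float = CENTRAL_ZONE_RADIUS_MM,
    step_deg: float = AXIS_STEP_DEG,
    semi_meridian: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean tangential power versus meridian axis over the central zone.

    For each axis theta in 0..180 (exclusive) at ``step_deg`` resolution, the
    unmasked power within ``zone_radius`` of the apex is averaged over the
    two opposite semi-meridians theta and theta+180 (or over theta only when
    ``semi_meridian`` — then the axis range is 0..360).  The apex node,
    where tangential curvature is undefined on polar sampling, is excluded.

    Returns ``(axes_deg, mean_power_D)``.
    """
    if not isinstance(power.grid, PolarGrid):
        raise ValueError("meridional profile requires a polar-grid power map")
    grid = power.grid
    in_zone = (grid.radii > 0) & (grid.radii <= zone_radius)
    if not in_zone.any():
        raise ValueError("power map has no nodes inside the central zone")
    sub = power.power[:, in_zone]
    sub_ok = ~power.mask[:, in_zone]
    frac_masked = 1.0 - sub_ok.sum() / sub_ok.size
    if frac_masked > 0.20:
        raise ValueError(
            f"{frac_masked:.0%} of central-zone nodes are masked (limit 20%)"
        )
    # per-measured-meridian mean, then periodic interpolation to the 1 deg comb
    with np.errstate(invalid="ignore"):
        counts = sub_ok.sum(axis=1)
        sums = np.where(sub_ok, sub, 0.0).sum(axis=1)
    have = counts > 0
    mer_mean = np.full(grid.n_angles, np.nan)
    mer_mean[have] = sums[have] / counts[have]

    src_ang = grid.meridian_angles[have]
    src_val = mer_mean[have]
    # periodic linear interpolation in angle
    ext_ang = np.concatenate([src_ang - 360.0, src_ang, src_ang + 360.0])
    ext_val = np.concatenate([src_val, src_val, src_val])

    span = 360.0 if semi_meridian else 180.0
    axes = np.arange(0.0, span, step_deg)
    if semi_meridian:
        prof = np.interp(axes, ext_ang, ext_val)
    else:
        prof = 0.5 * (np.interp(axes, ext_ang, ext_val) + np.interp(axes + 180.0, ext_ang, ext_val))
    return axes, prof


def quantify_astigmatism(power: PowerMap, **profile_kwargs) -> AstigmatismResult:
    """Flat/steep meridian powers and astigmatism magnitude of a power map.

    Flat = profile minimum, steep = profile maximum.  A profile flat to below
    1e-6 D yields magnitude 0 with indeterminate axes.
    """
    axes, prof = meridional_power_profile(power, **profile_kwargs)
    if np.ptp(prof) < _FLAT_PROFILE_EPS_D:
        p = float(np.mean(prof))
        return AstigmatismResult(p, p, None, None, 0.0)
    i_flat = int(np.argmin(prof))
    i_steep = int(np.argmax(prof))
    return AstigmatismResult(
        flat_power=float(prof[i_flat]),
        steep_power=float(prof[i_steep]),
        flat_axis=float(axes[i_flat]),
        steep_axis=float(axes[i_steep]),
        magnitude=float(prof[i_steep] - prof[i_flat]),
    )


def astigmatism_change(pre: AstigmatismResult, post: AstigmatismResult) -> float:
    """Signed induced-astigmatism change (D): post magnitude minus pre magnitude."""
    return post.magnitude - pre.magnitude
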