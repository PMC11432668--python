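"""Treatment-zone boundary detection, circle fitting and decentration.

The ortho-k treatment zone shows up on the post-minus-pre tangential power
difference map as a central region of negative power change (flattening)
surrounded by a positive annulus (the reverse-curve steepening).  Its
boundary is located per meridian as the first outward negative-to-positive
zero crossing of the power change, the scattered crossings are fitted with a
least-RMS circle, and the circle centre relative to the corneal apex gives
the decentration vector.

Quadrant conventions follow the clinical quarter tables: quadrants 1–4 are
the standard display-frame quadrants (x>0,y>0 is quadrant 1, then
counterclockwise), so quadrant 3 is temporal-inferior for right eyes and
nasal-inferior for left eyes.  Decentration angles are reported from the
nasal axis — counterclockwise for OD, clockwise for OS — which makes the
reported angle of anatomically mirrored cases identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .grids import PolarGrid
from .power import DifferenceMap

__all__ = [
    "TZBoundary",
    "FittedCircle",
    "DecentrationResult",
    "NoTreatmentZoneError",
    "detect_tz_boundary",
    "fit_circle",
    "compute_decentration",
    "categorize_decentration",
    "quadrant_name",
]

#: detection gates: central flattening depth (D) within this radius (mm),
#: and the minimum number of meridians that must yield a boundary crossing
CENTRAL_FLATTENING_GATE_D = -0.25
CENTRAL_GATE_RADIUS_MM = 2.0
MIN_CROSSING_MERIDIANS = 8

_QUADRANT_NAMES = {
    "OD": {1: "nasal-superior", 2: "temporal-superior", 3: "temporal-inferior", 4: "nasal-inferior"},
    "OS": {1: "temporal-superior", 2: "nasal-superior", 3: "nasal-inferior", 4: "temporal-inferior"},
}


class NoTreatmentZoneError(ValueError):
    """Raised when the difference map shows no detectable treatment zone."""


@dataclass
class TZBoundary:
    """Per-meridian boundary crossings of the treatment zone (display frame, mm)."""

    points: np.ndarray  # (k, 2) x, y
    meridians_without_crossing: int

    @property
    def n_points(self) -> int:
        return int(self.points.shape[0])


@dataclass
class FittedCircle:
    """Least-RMS circle through the boundary points."""

    centre_x: float  # mm
    centre_y: float  # mm
    radius: float  # mm
    fit_rms: float  # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("fitted radius must be positive")


@dataclass
class DecentrationResult:
    """Treatment-zone decentration relative to the corneal apex."""

    radius: float  # mm
    angle: float  # deg from the nasal axis (CCW for OD, CW for OS)
    quadrant: int  # 1-4, clinical quarter table for the laterality
    category: str  # small | moderate | large
    laterality: str
    on_boundary: bool = False  # centre exactly on an axis (tie-broken)

    @property
    def direction_name(self) -> str:
        return quadrant_name(self.quadrant, self.laterality)


def quadrant_name(quadrant: int, laterality: str) -> str:
    """Anatomical name of a quarter index for the given eye."""
    return _QUADRANT_NAMES[laterality][quadrant]


def detect_tz_boundary(delta: DifferenceMap) -> TZBoundary:
    """Locate the treatment-zone boundary on a polar difference map.

    For each meridian, walking outward from the innermost unmasked node, the
    first negative-to-positive sign change of the power difference is
    recorded, with the crossing radius located by linear interpolation
    between the bracketing nodes.  A crossing only qualifies once the
    meridian has actually dipped below the flattening gate (-0.25 D), so
    meridians that merely graze zero on noise are counted as having no
    crossing rather than contributing fabricated boundary points.

    Raises
    ------
    NoTreatmentZoneError
        If no node within 2 mm of the apex shows at least 0.25 D of
        flattening, or fewer than 8 meridians yield a crossing.
    """
    if not isinstance(delta.grid, PolarGrid):
        raise ValueError("detect_tz_boundary expects a polar-grid difference map; resample first")
    grid = delta.grid
    v = delta.delta_power
    m = delta.mask

    central = (grid.radii[None, :] <= CENTRAL_GATE_RADIUS_MM) & ~m
    if not np.any(central & (v < CENTRAL_FLATTENING_GATE_D)):
        raise NoTreatmentZoneError(
            f"no central flattening below {CENTRAL_FLATTENING_GATE_D} D "
            f"within {CENTRAL_GATE_RADIUS_MM} mm of the apex"
        )

    pts: list[tuple[float, float]] = []
    n_missing = 0
    phi = np.deg2rad(grid.meridian_angles)
    r = grid.radii
    for i in range(grid.n_angles):
        row = v[i]
        ok = ~m[i]
        idx = np.flatnonzero(ok)
        crossing = None
        dipped = False
        # consecutive unmasked pairs only: no bridging across data holes
        for a, b in zip(idx[:-1], idx[1:]):
            if b != a + 1:
                continue
            dipped = dipped or row[a] <= CENTRAL_FLATTENING_GATE_D
            if dipped and row[a] < 0.0 and row[b] > 0.0:
                t = -row[a] / (row[b] - row[a])
                crossing = r[a] + t * (r[b] - r[a])
                break
        if crossing is None:
            n_missing += 1
        else:
            pts.append((crossing * np.cos(phi[i]), crossing * np.sin(phi[i])))
    if len(pts) < MIN_CROSSING_MERIDIANS:
        raise NoTreatmentZoneError(
            f"only {len(pts)} meridians yield a boundary crossing "
            f"(minimum {MIN_CROSSING_MERIDIANS})"
        )
    return TZBoundary(np.array(pts), n_missing)


def fit_circle(boundary: TZBoundary) -> FittedCircle:
    """Least-RMS circle fit: algebraic Kåsa initialiser, geometric Gauss–Newton refinement."""
    pts = np.asarray(boundary.points, dtype=float)
    if pts.shape[0] < MIN_CROSSING_MERIDIANS:
        raise ValueError(f"need at least {MIN_CROSSING_MERIDIANS} boundary points")
    x, y = pts[:, 0], pts[:, 1]
    # Kåsa: minimise ||x^2 + y^2 - 2ax - 2by - c||
    a_mat = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    rhs = x**2 + y**2
    sol, _, rank, _ = np.linalg.lstsq(a_mat, rhs, rcond=None)
    if rank < 3:
        raise ValueError("degenerate boundary: points are collinear or coincident")
    cx, cy = sol[0], sol[1]
    r0 = np.sqrt(max(sol[2] + cx**2 + cy**2, 0.0))
    if r0 <= 0 or not np.isfinite(r0):
        raise ValueError("degenerate boundary: Kåsa initialiser failed")

    def residual(p: np.ndarray) -> np.ndarray:
        return np.hypot(x - p[0], y - p[1]) - p[2]

    fit = least_squares(residual, x0=[cx, cy, r0], method="lm")
    cx, cy, radius = fit.x
    if radius <= 0 or not np.isfinite(radius):
        raise ValueError("degenerate boundary: circle refinement failed")
    rms = float(np.sqrt(np.mean(residual(fit.x) ** 2)))
    return FittedCircle(float(cx), float(cy), float(radius), rms)


def categorize_decentration(radius: float) -> str:
    """Clinical decentration category: small (<=0.5), moderate (0.5..1.0], large (>1.0) mm."""
    if radius < 0:
        raise ValueError("decentration radius must be non-negative")
    if radius <= 0.5:
        return "small"
    if radius <= 1.0:
        return "moderate"
    return "large"


def compute_decentration(circle: FittedCircle, laterality: str) -> DecentrationResult:
    """Decentration vector of a fitted treatment-zone circle.

    Radius is the apex-to-centre distance.  The reported angle is measured
    from the nasal axis in the eye's conventional sense (CCW for OD, CW for
    OS); numerically this is the CCW angle of the centre in the
    nasal-positive frame.  The quadrant is the display-frame quarter index
    per the clinical quarter tables; centres exactly on an axis are assigned
    to the lower-numbered adjacent quarter and flagged ``on_boundary``.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    cx, cy = circle.centre_x, circle.centre_y
    radius = float(np.hypot(cx, cy))
    # nasal-positive (anatomical) x: nasal is +X for OD, -X for OS on the display
    x_nasal = cx if laterality == "OD" else -cx
    angle = float(np.rad2deg(np.arctan2(cy, x_nasal)) % 360.0)

    on_boundary = radius == 0.0 or cx == 0.0 or cy == 0.0
    if radius == 0.0:
        quadrant = 1
    else:
        if cx > 0 and cy >= 0:
            quadrant = 1
        elif cx <= 0 and cy > 0:
            quadrant = 2
        elif cx < 0 and cy <= 0:
            quadrant = 3
        else:  # cx >= 0 and cy < 0
            quadrant = 4
        # tie-break axis cases to the lower-numbered adjacent quarter
        if cx == 0.0 and cy > 0:
            quadrant = 1
        if cy == 0.0 and cx < 0:
            quadrant = 2
        if cx == 0.0 and cy < 0:
            quadrant = 3
    return DecentrationResult(
        radius=radius,
        angle=angle,
        quadrant=quadrant,
        category=categorize_decentration(radius),
        laterality=laterality,
        on_boundary=on_boundary,
    )
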