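"""Synthetic pre/post ortho-k cornea generator with known ground truth.

Baseline corneas are biconic surfaces (flat/steep apical radii, a common
asphericity Q, an arbitrary flat-meridian axis) with optional Zernike
perturbations and measurement noise.  Ortho-k reshaping is imposed in
*power space*: a radially symmetric tangential-power-change profile — a
difference of Gaussians with a central flattening trough and a
reverse-curve annulus — is centred at the prescribed decentration point and
converted exactly to height changes per meridian, so the treatment-zone
boundary (the first negative-to-positive crossing of the power difference)
sits at ``tz_radius`` around the imposed centre by construction.

Measurement noise is a spatially correlated Gaussian field (default 2 um
amplitude, 0.75 mm correlation length).  Placido topographers reconstruct
height by integrating ring slopes and interpolate a dense export grid from
a few dozen rings, so raw-height error is smooth at the grid scale; white
noise at 0.018 mm spacing would be unphysical and would swamp the second
derivative that tangential curvature needs.  Set ``noise_correlation_mm=0``
for i.i.d. noise.

Cohort generation can couple the imposed decentration to a baseline shape
asymmetry (tilt + vertical coma along the decentration direction), emulating
the clinical observation that corneal asymmetry drives where a rotationally
symmetric ortho-k lens settles.  Without such coupling decentration would be
unpredictable from baseline topography by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.ndimage import gaussian_filter1d
from scipy.signal import savgol_filter

from .grids import PolarGrid, default_polar_grid
from .surface import CornealSurface
from .tzone import DecentrationResult, categorize_decentration
from .zernike import zernike_term

__all__ = [
    "BaselineParams",
    "TreatmentGroundTruth",
    "CohortSpec",
    "CohortEye",
    "generate_baseline_surface",
    "apply_orthok_treatment",
    "generate_cohort",
    "truth_decentration",
]

#: keratometric scaling between curvature (mm^-1) and power (D)
_POWER_PER_CURVATURE = 337.5
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class BaselineParams:
    """Baseline (pre-ortho-k) cornea description.

    Defaults follow a typical myopic ortho-k population: Sim-K around
    42.6 D flat / 44.0 D steep (apical radii 7.92 / 7.68 mm), mild prolate
    asphericity, 2 um correlated measurement noise.
    """

    flat_radius: float = 7.92  # mm, apical radius of the flat meridian
    steep_radius: float = 7.68  # mm, <= flat_radius
    flat_axis: float = 0.0  # deg, display frame
    q: float = -0.25  # asphericity (prolate < 0)
    zernike_perturbations: tuple[tuple[int, int, float], ...] = ()  # (n, m, coeff mm)
    noise_sd: float = 0.002  # mm
    noise_correlation_mm: float = 0.75  # 0 => i.i.d. noise

    def __post_init__(self) -> None:
        if not (6.0 <= self.steep_radius <= self.flat_radius <= 10.0):
            raise ValueError("need 6 <= steep_radius <= flat_radius <= 10 mm")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.noise_correlation_mm < 0:
            raise ValueError("noise_correlation_mm must be non-negative")


@dataclass(frozen=True)
class TreatmentGroundTruth:
    """Imposed ortho-k reshaping parameters (decentration in anatomical mm).

    ``decentration_x`` is positive toward the nasal side and
    ``decentration_y`` positive toward the superior side, independent of
    laterality.
    """

    decentration_x: float  # mm, nasal positive
    decentration_y: float  # mm, superior positive
    tz_radius: float = 1.8  # mm, treatment-zone boundary radius
    central_flattening: float = 5.0  # D, power reduction at the TZ centre
    annulus_gain: float = 3.0  # D, peak steepening of the reverse-curve annulus
    annulus_width: float = 1.0  # mm, FWHM of the annulus bump
    astig_reduction: float = 0.0  # D, extra trough depth along the steep axis
    steep_axis: float = 90.0  # deg, display frame, axis of the deeper flattening

    def __post_init__(self) -> None:
        if np.hypot(self.decentration_x, self.decentration_y) > 2.5:
            raise ValueError("decentration magnitude must be <= 2.5 mm")
        if not (1.0 <= self.tz_radius <= 3.5):
            raise ValueError("tz_radius must be in [1, 3.5] mm")
        if self.central_flattening < 0:
            raise ValueError("central_flattening must be non-negative")
        if self.central_flattening > 0 and self.annulus_gain >= 2.0 * self.central_flattening:
            raise ValueError("annulus_gain must be below twice the central flattening")
        if self.annulus_gain <= 0 and self.central_flattening > 0:
            raise ValueError("annulus_gain must be positive")
        if self.annulus_width <= 0:
            raise ValueError("annulus_width must be positive")
        if self.astig_reduction < 0:
            raise ValueError("astig_reduction must be non-negative")
        if self.central_flattening > 0 and self.astig_reduction > 0.6 * self.central_flattening:
            raise ValueError("astig_reduction must not exceed 60% of the central flattening")

    @property
    def radius(self) -> float:
        return float(np.hypot(self.decentration_x, self.decentration_y))


def truth_decentration(truth: TreatmentGroundTruth, laterality: str) -> DecentrationResult:
    """Ground-truth decentration expressed like a measured result.

    Converts the anatomical-frame truth vector into the reported angle
    (from the nasal axis, in the eye's sense) and clinical quarter index.
    """
    if laterality not in ("OD", "OS"):
        raise ValueError("laterality must be OD or OS")
    # display frame: nasal is +X for OD, -X for OS
    cx = truth.decentration_x if laterality == "OD" else -truth.decentration_x
    cy = truth.decentration_y
    radius = float(np.hypot(cx, cy))
    x_nasal = truth.decentration_x
    angle = float(np.rad2deg(np.arctan2(cy, x_nasal)) % 360.0)
    if radius == 0.0:
        quadrant = 1
    elif cx > 0 and cy >= 0:
        quadrant = 1
    elif cx <= 0 and cy > 0:
        quadrant = 2
    elif cx < 0 and cy <= 0:
        quadrant = 3
    else:
        quadrant = 4
    on_axis = radius == 0.0 or cx == 0.0 or cy == 0.0
    if radius > 0:
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
        on_boundary=on_axis,
    )


# ---------------------------------------------------------------------------
# baseline surfaces
# ---------------------------------------------------------------------------

def _biconic_sag(x: np.ndarray, y: np.ndarray, params: BaselineParams) -> np.ndarray:
    """Sag (positive, mm) of the rotated biconic at display-frame points."""
    alpha = np.deg2rad(params.flat_axis)
    u = x * np.cos(alpha) + y * np.sin(alpha)  # along the flat meridian
    v = -x * np.sin(alpha) + y * np.cos(alpha)
    cf = 1.0 / params.flat_radius
    cs = 1.0 / params.steep_radius
    num = cf * u**2 + cs * v**2
    arg = 1.0 - (1.0 + params.q) * (cf**2 * u**2 + cs**2 * v**2)
    arg = np.maximum(arg, 0.0)
    return num / (1.0 + np.sqrt(arg))


def _correlated_noise(
    grid: PolarGrid, sd: float, corr_mm: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian height-noise field with approximate isotropic correlation length."""
    white = rng.standard_normal(grid.shape)
    if sd == 0.0:
        return np.zeros(grid.shape)
    if corr_mm == 0.0:
        return sd * white
    dr = grid.radial_spacing
    dphi = 360.0 / grid.n_angles
    out = gaussian_filter1d(white, corr_mm / dr, axis=1, mode="reflect")
    for j, r in enumerate(grid.radii):
        if r <= 0:
            continue
        sig_deg = min(np.rad2deg(corr_mm / r), 60.0)
        out[:, j] = gaussian_filter1d(out[:, j], sig_deg / dphi, mode="wrap")
    s = out.std()
    if s > 0:
        out *= sd / s
    return out


def generate_baseline_surface(
    params: BaselineParams,
    grid: PolarGrid | None = None,
    seed: int = 0,
    laterality: str = "OD",
) -> CornealSurface:
    """Biconic baseline surface plus Zernike perturbations plus noise.

    Zernike perturbation radii are normalised by the grid's outermost radius.
    Deterministic for a given seed.  Heights use the Z = -sag convention.
    """
    if grid is None:
        grid = default_polar_grid()
    x, y = grid.node_xy()
    z = -_biconic_sag(x, y, params)
    if params.zernike_perturbations:
        rho = grid.node_rho() / grid.radii[-1]
        phi = np.arctan2(y, x)
        for n, m, coeff in params.zernike_perturbations:
            z = z + coeff * zernike_term(n, m, rho, phi)
    rng = np.random.default_rng(seed)
    z = z + _correlated_noise(grid, params.noise_sd, params.noise_correlation_mm, rng)
    z = z - z[:, 0:1]  # re-reference the apex to exactly 0
    return CornealSurface(grid, z, laterality)


# ---------------------------------------------------------------------------
# ortho-k treatment
# ---------------------------------------------------------------------------

def _power_change_profile(
    truth: TreatmentGroundTruth, d: np.ndarray, psi: np.ndarray | None = None
) -> np.ndarray:
    """Imposed tangential power change (D) at distance d (mm) from the TZ centre.

    Difference of Gaussians: a central flattening trough of depth
    ``central_flattening`` and an annulus bump of height ``annulus_gain``
    centred half a width beyond the boundary, with the trough width solved in
    closed form so the zero crossing falls exactly at ``tz_radius``.  A
    nonzero ``astig_reduction`` deepens the trough along the steep axis
    (``psi`` is the node angle around the TZ centre), emulating the
    preferential flattening of the steeper meridian that makes a
    well-centred spherical ortho-k lens reduce central corneal cylinder.
    """
    a = truth.central_flattening
    g = truth.annulus_gain
    if a == 0.0:
        return np.zeros_like(d)
    sig_a = truth.annulus_width / _FWHM_TO_SIGMA
    mu = truth.tz_radius + truth.annulus_width / 2.0
    # at d = tz_radius the annulus term equals g/2 (half width from its peak),
    # so the symmetric trough must also equal g/2 there:
    sig_c = truth.tz_radius / np.sqrt(2.0 * np.log(2.0 * a / g))
    trough_env = np.exp(-(d**2) / (2 * sig_c**2))
    out = -a * trough_env + g * np.exp(-((d - mu) ** 2) / (2 * sig_a**2))
    if truth.astig_reduction > 0 and psi is not None:
        out = out - truth.astig_reduction * np.cos(
            2.0 * (psi - np.deg2rad(truth.steep_axis))
        ) * trough_env
    return out


def apply_orthok_treatment(
    pre: CornealSurface, truth: TreatmentGroundTruth, deriv_window: int = 5
) -> CornealSurface:
    """Post-ortho-k surface whose tangential power difference map realises ``truth``.

    The imposed curvature change dK(rho) = dP(d)/337.5 along each meridian is
    integrated exactly through the tangent-angle substitution
    T = Z'/sqrt(1+Z'^2), T' = -Kt: the post tangent angle is the pre tangent
    angle minus the cumulative imposed curvature change, and the height
    change is the integral of the resulting slope change.  The apex height
    and slope are preserved.
    """
    if not pre.is_polar:
        raise ValueError("apply_orthok_treatment expects a polar-grid surface")
    grid: PolarGrid = pre.grid  # type: ignore[assignment]
    if truth.central_flattening == 0.0:
        return pre.copy()
    reach = truth.radius + truth.tz_radius + truth.annulus_width
    if reach > grid.radii[-1]:
        raise ValueError(
            f"treatment (extent {reach:.2f} mm) exceeds the measured area "
            f"({grid.radii[-1]:.2f} mm)"
        )
    dr = grid.radial_spacing
    h = pre.heights.copy()
    if pre.mask.any():
        r = grid.radii
        for i in range(grid.n_angles):
            bad = pre.mask[i]
            if bad.any() and not bad.all():
                h[i, bad] = np.interp(r[bad], r[~bad], h[i, ~bad])
        h = np.nan_to_num(h)

    x, y = grid.node_xy()
    cx = truth.decentration_x if pre.laterality == "OD" else -truth.decentration_x
    cy = truth.decentration_y
    d = np.hypot(x - cx, y - cy)
    psi = np.arctan2(y - cy, x - cx)
    dkappa = _power_change_profile(truth, d, psi) / _POWER_PER_CURVATURE

    dz = savgol_filter(h, deriv_window, 2, deriv=1, delta=dr, axis=1, mode="interp")
    t_pre = dz / np.sqrt(1.0 + dz**2)
    t_post = t_pre - cumulative_trapezoid(dkappa, grid.radii, axis=1, initial=0.0)
    t_post = np.clip(t_post, -0.999, 0.999)

    def slope(t: np.ndarray) -> np.ndarray:
        return t / np.sqrt(1.0 - t**2)

    dslope = slope(t_post) - slope(t_pre)
    dheight = cumulative_trapezoid(dslope, grid.radii, axis=1, initial=0.0)
    z_post = pre.heights + dheight  # NaN propagates at originally masked nodes
    return CornealSurface(grid, z_post, pre.laterality, pre.mask.copy())


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Distributional description of a synthetic ortho-k cohort.

    Defaults emulate a typical myopic ortho-k clinic population: mean decentration about
    0.65 mm with a temporal-inferior directional mode, Sim-K near
    42.6/44.0 D, a roughly 53/47 right/left split, and 2 um correlated
    measurement noise.  ``shape_coupling`` is the baseline tilt coefficient
    (mm per mm of decentration) that ties decentration to a baseline
    asymmetry so that it is predictable from baseline topography;
    ``coma_coupling`` adds the corresponding vertical/horizontal coma share.
    """

    n_eyes: int = 100
    laterality_ratio: float = 132.0 / 249.0  # fraction of right eyes
    seed: int = 0
    # baseline shape distributions
    flat_radius_mean: float = 7.92
    flat_radius_sd: float = 0.24
    k_difference_mean: float = 0.24  # mm of radius between flat and steep
    k_difference_sd: float = 0.10
    flat_axis_sd: float = 20.0  # deg about horizontal (with-the-rule)
    q_mean: float = -0.25
    q_sd: float = 0.10
    noise_sd: float = 0.002
    noise_correlation_mm: float = 0.75
    # decentration distributions (anatomical frame)
    decentration_mean: float = 0.65
    decentration_sd: float = 0.35
    decentration_min: float = 0.0
    decentration_max: float = 2.0
    p_temporal_inferior: float = 0.50
    p_temporal_superior: float = 0.20
    direction_sd: float = 35.0  # deg about each directional mode
    # treatment distributions
    tz_radius_mean: float = 1.8
    tz_radius_sd: float = 0.25
    central_flattening_mean: float = 5.0
    central_flattening_sd: float = 1.5
    annulus_gain_mean: float = 3.0
    annulus_gain_sd: float = 1.0
    annulus_width_mean: float = 1.0
    annulus_width_sd: float = 0.15
    astig_reduction_frac_mean: float = 0.7  # of the baseline corneal cylinder
    astig_reduction_frac_sd: float = 0.2
    # shape->decentration coupling
    shape_coupling: float = 0.010  # mm tilt coefficient per mm decentration
    coma_coupling: float = 0.002  # mm coma coefficient per mm decentration

    def __post_init__(self) -> None:
        if self.n_eyes < 1:
            raise ValueError("n_eyes must be >= 1")
        if not (0.0 <= self.laterality_ratio <= 1.0):
            raise ValueError("laterality_ratio must be in [0, 1]")
        for name in (
            "flat_radius_sd", "k_difference_sd", "flat_axis_sd", "q_sd", "noise_sd",
            "decentration_sd", "direction_sd", "tz_radius_sd", "central_flattening_sd",
            "annulus_gain_sd", "annulus_width_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class CohortEye:
    """One labelled synthetic eye: pre/post surface pair plus ground truth."""

    eye_id: str
    laterality: str
    pre: CornealSurface
    post: CornealSurface
    truth: TreatmentGroundTruth
    baseline: BaselineParams


def _sample_direction(spec: CohortSpec, rng: np.random.Generator) -> float:
    """Anatomical decentration angle (deg CCW from nasal): temporal-inferior-weighted mixture."""
    u = rng.uniform()
    if u < spec.p_temporal_inferior:
        return float(rng.normal(225.0, spec.direction_sd) % 360.0)
    if u < spec.p_temporal_inferior + spec.p_temporal_superior:
        return float(rng.normal(135.0, spec.direction_sd) % 360.0)
    return float(rng.uniform(0.0, 360.0))


def _sample_eye(
    spec: CohortSpec, laterality: str, rng: np.random.Generator
) -> tuple[BaselineParams, TreatmentGroundTruth]:
    flat = float(np.clip(rng.normal(spec.flat_radius_mean, spec.flat_radius_sd), 6.5, 9.5))
    dk = abs(rng.normal(spec.k_difference_mean, spec.k_difference_sd))
    steep = float(np.clip(flat - dk, 6.0, flat))
    axis = float(rng.normal(0.0, spec.flat_axis_sd) % 180.0)
    q = float(np.clip(rng.normal(spec.q_mean, spec.q_sd), -0.8, 0.3))

    radius = abs(rng.normal(spec.decentration_mean, spec.decentration_sd))
    radius = float(np.clip(radius, spec.decentration_min, spec.decentration_max))
    theta = np.deg2rad(_sample_direction(spec, rng))
    dx, dy = radius * np.cos(theta), radius * np.sin(theta)  # anatomical

    tz = float(np.clip(rng.normal(spec.tz_radius_mean, spec.tz_radius_sd), 1.2, 2.4))
    flattening = float(np.clip(
        rng.normal(spec.central_flattening_mean, spec.central_flattening_sd), 2.0, 9.0
    ))
    gain = float(np.clip(
        rng.normal(spec.annulus_gain_mean, spec.annulus_gain_sd), 1.0, 0.9 * flattening
    ))
    width = float(np.clip(rng.normal(spec.annulus_width_mean, spec.annulus_width_sd), 0.6, 1.4))
    cylinder = 337.5 / steep - 337.5 / flat  # baseline corneal astigmatism, D
    ar_frac = float(np.clip(
        rng.normal(spec.astig_reduction_frac_mean, spec.astig_reduction_frac_sd), 0.0, 1.0
    ))
    astig_reduction = float(min(ar_frac * cylinder, 0.5 * flattening))
    steep_axis = (axis + 90.0) % 180.0  # display frame, like the baseline axis

    perts: list[tuple[int, int, float]] = []
    if spec.shape_coupling or spec.coma_coupling:
        # display-frame components of the anatomical decentration vector
        ddx = dx if laterality == "OD" else -dx
        perts = [
            (1, 1, spec.shape_coupling * ddx),
            (1, -1, spec.shape_coupling * dy),
            (3, 1, spec.coma_coupling * ddx),
            (3, -1, spec.coma_coupling * dy),
        ]
    baseline = BaselineParams(
        flat_radius=flat,
        steep_radius=steep,
        flat_axis=axis,
        q=q,
        zernike_perturbations=tuple(perts),
        noise_sd=spec.noise_sd,
        noise_correlation_mm=spec.noise_correlation_mm,
    )
    truth = TreatmentGroundTruth(
        decentration_x=float(dx),
        decentration_y=float(dy),
        tz_radius=tz,
        central_flattening=flattening,
        annulus_gain=gain,
        annulus_width=width,
        astig_reduction=astig_reduction,
        steep_axis=steep_axis,
    )
    return baseline, truth


def separable_cohort_spec(n_eyes: int = 400, seed: int = 0) -> CohortSpec:
    """A noiseless, strongly shape-coupled cohort for predictor benchmarking.

    All eyes are decentred by at least 0.5 mm with directions uniform over
    the four quadrants (balanced classes), no measurement noise, and a
    strong baseline tilt/coma coupling, so decentration is recoverable from
    baseline topography up to interpolation and optimisation error.
    """
    return CohortSpec(
        n_eyes=n_eyes,
        seed=seed,
        noise_sd=0.0,
        shape_coupling=0.08,
        coma_coupling=0.015,
        decentration_min=0.5,
        laterality_ratio=1.0,
        p_temporal_inferior=0.0,
        p_temporal_superior=0.0,
    )


def generate_cohort(
    spec: CohortSpec, grid: PolarGrid | None = None
) -> list[CohortEye]:
    """Generate ``spec.n_eyes`` labelled pre/post pairs, reproducible from ``spec.seed``."""
    if grid is None:
        grid = default_polar_grid()
    rng = np.random.default_rng(spec.seed)
    eyes: list[CohortEye] = []
    for i in range(spec.n_eyes):
        laterality = "OD" if rng.uniform() < spec.laterality_ratio else "OS"
        baseline, truth = _sample_eye(spec, laterality, rng)
        eye_seed = int(rng.integers(0, 2**31 - 1))
        pre = generate_baseline_surface(baseline, grid, seed=eye_seed, laterality=laterality)
        post = apply_orthok_treatment(pre, truth)
        # independent measurement noise on the post-wear acquisition
        if spec.noise_sd > 0:
            noise_rng = np.random.default_rng(eye_seed + 1)
            extra = _correlated_noise(grid, spec.noise_sd, spec.noise_correlation_mm, noise_rng)
            z = post.heights + extra
            z = z - z[:, 0:1]
            post = CornealSurface(grid, z, laterality, post.mask)
        eyes.append(
            CohortEye(
                eye_id=f"eye{i:04d}",
                laterality=laterality,
                pre=pre,
                post=post,
                truth=truth,
                baseline=baseline,
            )
        )
    return eyes
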