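"""End-to-end per-eye analysis: height surfaces in, decentration and astigmatism out.

This is the glue that runs the full map-processing chain on one pre/post
pair: re-mesh onto a common grid, tangential curvature and power, power
difference map, smoothing, treatment-zone boundary detection, circle fit,
decentration, and central-zone astigmatism for both visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .astig import AstigmatismResult, astigmatism_change, quantify_astigmatism
from .power import (
    DifferenceMap,
    PowerMap,
    power_difference_map,
    smooth_map,
    tangential_curvature,
    tangential_power,
)
from .surface import CornealSurface, remesh_to_common_grid
from .tzone import (
    DecentrationResult,
    FittedCircle,
    NoTreatmentZoneError,
    TZBoundary,
    compute_decentration,
    detect_tz_boundary,
    fit_circle,
)

__all__ = ["EyeAnalysis", "analyze_eye"]

#: default smoothing of the difference map before boundary detection (mm)
DEFAULT_SMOOTHING_SIGMA_MM = 0.15


@dataclass
class EyeAnalysis:
    """Full single-eye analysis products."""

    laterality: str
    power_pre: PowerMap
    power_post: PowerMap
    delta: DifferenceMap
    delta_smoothed: DifferenceMap
    astig_pre: AstigmatismResult
    astig_post: AstigmatismResult
    astig_change: float
    boundary: TZBoundary | None
    circle: FittedCircle | None
    decentration: DecentrationResult | None
    no_zone_reason: str | None = None

    def to_record(self, eye_id: str = "") -> dict:
        """Flat per-eye record for cohort tables."""
        rec = {
            "eye_id": eye_id,
            "laterality": self.laterality,
            "pre_astigmatism_D": self.astig_pre.magnitude,
            "post_astigmatism_D": self.astig_post.magnitude,
            "astigmatism_change_D": self.astig_change,
        }
        if self.decentration is not None:
            d = self.decentration
            rec.update(
                {
                    "centre_x_mm": self.circle.centre_x,
                    "centre_y_mm": self.circle.centre_y,
                    "radius_mm": d.radius,
                    "angle_deg_from_nasal": d.angle,
                    "quadrant": d.quadrant,
                    "direction": d.direction_name,
                    "category": d.category,
                    "tz_radius_mm": self.circle.radius,
                    "fit_rms_mm": self.circle.fit_rms,
                    "n_meridians_used": self.boundary.n_points,
                    "on_boundary": d.on_boundary,
                }
            )
        else:
            rec.update({"radius_mm": np.nan, "no_zone_reason": self.no_zone_reason})
        return rec


def analyze_eye(
    pre: CornealSurface,
    post: CornealSurface,
    smoothing_sigma: float = DEFAULT_SMOOTHING_SIGMA_MM,
    deriv_window: int = 5,
) -> EyeAnalysis:
    """Run the full decentration/astigmatism analysis on one pre/post pair.

    A missing treatment zone (e.g. identical pre/post surfaces) is not an
    error at this level: ``decentration`` is None and ``no_zone_reason``
    records why.
    """
    pre, post = remesh_to_common_grid(pre, post)
    curv_pre = tangential_curvature(pre, window=deriv_window)
    curv_post = tangential_curvature(post, window=deriv_window)
    p_pre = tangential_power(curv_pre)
    p_post = tangential_power(curv_post)
    delta = power_difference_map(p_pre, p_post)
    delta_s = smooth_map(delta, smoothing_sigma)

    astig_pre = quantify_astigmatism(p_pre)
    astig_post = quantify_astigmatism(p_post)

    boundary = circle = result = None
    reason = None
    try:
        boundary = detect_tz_boundary(delta_s)
        circle = fit_circle(boundary)
        result = compute_decentration(circle, pre.laterality)
    except (NoTreatmentZoneError, ValueError) as exc:
        reason = str(exc)
    return EyeAnalysis(
        laterality=pre.laterality,
        power_pre=p_pre,
        power_post=p_post,
        delta=delta,
        delta_smoothed=delta_s,
        astig_pre=astig_pre,
        astig_post=astig_post,
        astig_change=astigmatism_change(astig_pre, astig_post),
        boundary=boundary,
        circle=circle,
        decentration=result,
        no_zone_reason=reason,
    )
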