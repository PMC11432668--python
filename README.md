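# okzone

Corneal-topography analysis of **ortho-k treatment-zone decentration**:
from anterior corneal height maps to tangential power maps, treatment-zone
(TZ) detection and decentration, Zernike height aberrations, induced
corneal astigmatism, cohort statistics, and a neural-network predictor of
decentration from baseline corneal shape — plus a synthetic-cornea
generator that produces labelled pre/post ortho-k cohorts for validation.

Overnight orthokeratology flattens the central cornea with a
reverse-geometry rigid lens.  When the lens settles off-centre, the
flattened treatment zone decentrates from the corneal apex, inducing
higher-order aberrations and astigmatism.  `okzone` is for vision
scientists and contact-lens researchers who want a tested, reusable
implementation of this analysis chain.

## The analysis

Given pre- and post-wear height maps `Z(ρ, φ)` on a polar grid:

1. **Tangential power.**  Per meridian,
   `Kt = |∂²Z/∂ρ²| / (1 + (∂Z/∂ρ)²)^{3/2}` (Savitzky–Golay derivatives),
   and `Pt [D] = (n_h − 1)/Rt = 337.5 / Rt [mm]` with the keratometric
   index `n_h = 1.3375`.
2. **Difference map.**  `ΔPt = Pt^post − Pt^pre` after triangulation-cubic
   re-meshing of the post surface onto the pre grid; the ortho-k bullseye
   appears as a negative core (flattening) inside a positive annulus.
3. **Decentration.**  The TZ boundary is the first outward − → + zero
   crossing of `ΔPt` per meridian; a least-RMS circle (Kåsa +
   Gauss–Newton) through the crossings gives the decentration vector
   relative to the apex, reported as radius, angle from the nasal axis
   (CCW for OD, CW for OS), clinical quarter 1–4, and category
   (small ≤ 0.5 mm < moderate ≤ 1.0 mm < large).
4. **Zernike fit.**  Raw (unnormalised) Zernike height coefficients up to
   order 5 (21 terms) over a 5 mm disc, 80/20 fit/validation split with
   held-out RMS.
5. **Astigmatism.**  Steep-minus-flat meridional power over the central
   3 mm at 1° axis resolution; post-minus-pre is the induced change.
6. **Prediction.**  A 10-hidden-layer tanh network (MSE loss, linear
   output, 70/30 split) predicts the decentration quadrant and radius from
   baseline heights sampled at 36 meridians × 26 radii.

## Worked example

```python
import okzone as ok

# a synthetic eye with known ground truth: 0.8 mm decentration at 315 deg
pre = ok.generate_baseline_surface(ok.BaselineParams(noise_sd=0.0), seed=0)
truth = ok.TreatmentGroundTruth(0.57, -0.57, tz_radius=1.8)
post = ok.apply_orthok_treatment(pre, truth)

res = ok.analyze_eye(pre, post)
d = res.decentration
print(f"decentration {d.radius:.3f} mm at {d.angle:.1f} deg from nasal")
print(f"quadrant {d.quadrant} ({d.direction_name}), category {d.category}")
print(f"TZ radius {res.circle.radius:.3f} mm, fit RMS {res.circle.fit_rms:.2e} mm")
print(f"astigmatism change {res.astig_change:+.3f} D")
```

prints

```
decentration 0.803 mm at 315.0 deg from nasal
quadrant 4 (nasal-inferior), category moderate
TZ radius 1.798 mm, fit RMS 1.03e-03 mm
astigmatism change -0.000 D
```

— the pipeline recovers the imposed 0.806 mm / 315° decentration and the
1.8 mm zone radius to within a few thousandths of a millimetre.  At this
moderate decentration the flattening trough still covers the central 3 mm
almost uniformly, so the induced astigmatism is negligible; it grows
steeply once the reverse-curve annulus intrudes into the central zone
(decentrations beyond ~1 mm).

Cohort-scale work goes through the CLI:

```bash
okzone simulate --n 100 --seed 1 --out-dir cohort/      # TOPO-CSV pairs + ground truth
okzone analyze --pre cohort/eye0000_pre.csv --post cohort/eye0000_post.csv --out-dir eye0/
okzone cohort --cohort-dir cohort/ --out-dir summary/   # quadrant tables, violin data, ...
okzone train --task quadrant --cohort-dir cohort/ --eye OD --seed 0 --out model.json
okzone predict --model model.json --in cohort/eye0001_pre.csv
```

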