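# Methods

`okzone` implements a corneal-topography analysis chain for overnight
orthokeratology (ortho-k): from anterior corneal height maps to tangential
refractive power maps, detection and quantification of treatment-zone (TZ)
decentration, Zernike height aberrations, induced corneal astigmatism,
cohort statistics, and a neural-network predictor of decentration from
baseline corneal shape.  Because the clinical height maps such analyses are
developed on are not publicly available, the package ships a synthetic
cornea generator with full ground truth; every pipeline claim is validated
by recovery against that ground truth or against closed-form optics.

## Coordinate conventions

Surfaces live on polar grids (meridian angle x radius from apex; the
default 300 x 333 lattice over 0–6 mm mirrors a Placido topographer's
export grid; uniform radial spacing is assumed and configurable) or uniform
Cartesian grids covering ±6 mm.  Heights follow `Z = -sag`: zero at the
apex, increasingly negative peripherally, so piston/defocus height
coefficients fit negative, as clinical elevation fits report them.

Maps are stored in the display frame (+Y superior; +X the right-hand side
of the displayed map, which is nasal for right eyes and temporal for left
eyes).  `mirror_for_laterality` negates display X and toggles laterality,
which leaves anatomical directions (nasal/temporal) fixed.  Decentration
angles are reported from the nasal axis, counterclockwise for OD and
clockwise for OS; numerically both equal the CCW angle in the
nasal-positive frame, so anatomically mirrored fellow eyes report the same
angle.  Quadrants 1–4 are the display-frame quarters, which makes quarter 3
temporal-inferior for OD and quarter 4 temporal-inferior for OS.

## Tangential power

Tangential (instantaneous) curvature is computed per meridian,
`Kt = |Z''| / (1 + Z'^2)^(3/2)`, with radial derivatives from a
Savitzky–Golay local-quadratic filter (default 5-point window; window and
order configurable).  Least-squares local-polynomial differentiation keeps
smoothing and differentiation mutually consistent on noisy heights.  The
apex node (singular on polar sampling), fringe nodes with incomplete
stencils, and physiologically implausible values (Kt outside
0.05–0.5 mm^-1, power outside 20–80 D) are masked, never clipped.
Curvature is reported as a magnitude (convex positive).

Power uses the keratometric convention `Pt = (n_h - 1)/Rt` with
n_h = 1.3375, i.e. `Pt [D] = 337.5 / Rt [mm]`; the hypothetical index
stands in for the unmeasured posterior surface.  When both surfaces and
thickness are known, `gaussian_net_power` evaluates the thick-lens formula
with Gullstrand indices (1.376 cornea, 1.336 aqueous).  The difference map
is the node-wise post-minus-pre power with mask union, optionally smoothed
by a mask-aware Gaussian kernel of physical width (default sigma 0.15 mm
before boundary detection — well below typical TZ radii, so the detected
boundary is not biased; on polar grids the kernel is applied separably in
radius and, per ring, in angle with width sigma/r, approximating isotropic
plane smoothing).

## Treatment-zone decentration

The TZ boundary is found per meridian as the first outward
negative-to-positive zero crossing of the smoothed power difference,
located by linear interpolation between bracketing nodes.  A crossing only
qualifies after the meridian has dipped below −0.25 D, so meridians that
merely graze zero on noise contribute nothing rather than fabricated
points.  A zone is declared only if the map shows at least 0.25 D of
flattening within 2 mm of the apex and at least 8 meridians yield
crossings.  The crossings are fitted with a least-RMS circle (algebraic
Kåsa solve, then geometric Gauss–Newton refinement); the circle centre
relative to the corneal apex (not the pupil centre) is the decentration
vector.  Decentration categories: small ≤ 0.5 mm, moderate 0.5–1.0 mm
(1.0 inclusive), large > 1.0 mm; centres exactly on an axis are assigned
the lower-numbered adjacent quarter and flagged.

## Zernike fitting

Surfaces are fitted in height space with the raw (unnormalised) Zernike
basis up to radial order 5 (21 terms, OSA ordering; an orthonormalisation
toggle exists but defaults off) over a 5 mm disc — data beyond that radius
are discarded as unreliable.  A seeded random 80% of valid points enters
the linear least-squares fit and the held-out 20% gives the RMS validation
error; `validation_fraction=0` fits on all points, which preserves the
grid's rotational symmetry (useful when testing symmetry properties).
Cohort comparisons report per-term means, SDs and pooled two-sample t
p-values, 15 terms by default, all 21 on request, with no multiple-testing
correction by default (a deliberate mirror of common clinical practice;
Bonferroni/FDR flags are available in the caller's hands via the returned
p-values).

## Astigmatism

Corneal astigmatism is the steep-minus-flat meridional power over the
central 3 mm diameter, with the flat/steep axes searched at 1° resolution.
Meridional power is the mean unmasked tangential power over both opposite
semi-meridians (a semi-meridian mode exists); the apex node is excluded.
Mean (not median) along the meridian is used.  The change post-minus-pre
is the induced corneal astigmatism, under the assumption that lenticular
astigmatism is unchanged between visits.

## Synthetic cornea generator

Baselines are biconic surfaces (flat/steep apical radii defaulting to
7.92/7.68 mm ≈ 42.6/44.0 D Sim-K, shared asphericity Q ≈ −0.25, arbitrary
axis) plus optional raw Zernike perturbations and measurement noise.

Noise is a spatially correlated Gaussian field, default 2 um amplitude
and 0.75 mm correlation length.  Placido devices reconstruct height by
integrating ring slopes and interpolate the dense export grid from a few
dozen rings, so raw-height error is smooth at the 0.018 mm grid scale;
white noise of that amplitude at that spacing would overwhelm the second
derivative behind tangential curvature, which real tangential maps do not
show.  `noise_correlation_mm = 0` gives i.i.d. noise for stress tests.

Ortho-k reshaping is modelled in power space, where the TZ is defined: a
difference-of-Gaussians radial profile around the displaced TZ centre with
a central flattening trough (default 5 D — tangential flattening runs
roughly 1.5–2x the refractive target in practice), a reverse-curve annulus
bump (default 3 D peak term, FWHM 1 mm) half a width beyond the boundary,
and the trough width solved in closed form so the zero crossing falls
exactly at `tz_radius`.  An `astig_reduction` term deepens the trough
along the steep meridian (default ≈ 70% of the baseline cylinder in
cohorts), emulating the preferential flattening that makes well-centred
spherical ortho-k lenses *reduce* central corneal cylinder — without it a
centred treatment could never lower astigmatism.  The imposed curvature
change is integrated to heights exactly via the tangent-angle substitution
`T = Z'/sqrt(1+Z'^2)`, `T' = -Kt` (a first-order double integration biases
the zero crossing by ~0.1 mm at clinical flattening depths, violating the
construction contract), so the measured difference map reproduces the
imposed profile to discretisation error (< 0.15 D in tests).

Cohorts draw per-eye baselines and treatments from configurable
distributions; defaults target a typical myopic ortho-k population: decentration radius |N(0.65, 0.35)| mm (floor/cap
configurable, cap 2.0 mm), a direction mixture favouring temporal-inferior
(50% TI mode, 20% TS mode, 30% uniform), TZ radius N(1.8, 0.25) mm, and a
132:117 right:left ratio.  Because decentration would otherwise be
statistically independent of baseline shape — and hence unpredictable in
principle — cohorts couple the imposed decentration to a baseline
tilt + vertical/horizontal coma asymmetry along the decentration direction
(`shape_coupling`, default 0.010 mm tilt coefficient per mm of
decentration), reflecting the clinical observation that corneal asymmetry
drives where rotationally symmetric lenses settle.  On a default 250-eye
cohort the pipeline shows the clinically expected structure: mean
decentration ≈ 0.65–0.7 mm near 200–210° from nasal, a strictly ordered
small < moderate < large astigmatism-change dose-response with all
pairwise t-tests significant, and weak/moderate/moderate correlations of
decentration with pre-astigmatism, post-astigmatism, and change.
`separable_cohort_spec` gives the predictor benchmark cohort: noiseless,
all decentrations ≥ 0.5 mm, uniform directions (balanced quadrants, so the
label-shuffle control sits at the 25% chance level), and strong coupling
(0.08 mm/mm).

## Decentration predictor

Features are baseline heights re-meshed onto a fixed polar lattice, 36
meridians (10° steps) x 26 radii (0–5 mm at 0.2 mm), in the
nasal-normalised frame (OS mirrored to OD), z-scored by training-set
statistics.  Two independent networks — a 4-class quadrant classifier (MSE
on one-hot targets, argmax decode, matching a fit-style network with a
linear output layer) and a radius regressor (output clamped at 0) — share
the architecture: 10 hidden tanh layers, linear output, 100 training
epochs, seeded 70/30 train/validation split (stratified by quadrant for
classification).

Three training choices matter and are deliberate:

* **Hidden width 16** (not wider): with the fixed 100-epoch budget a
  64-wide 10-layer tanh network does not train to convergence and
  underfits badly; 16 units per layer is still far above the capacity the
  4-class/1-output task needs and trains reliably.  Configurable.
* **Full-batch L-BFGS by default.**  The MSE + tanh + linear recipe
  descends from MATLAB-style `fitnet`/`train` pipelines, whose default
  trainer is full-batch Levenberg–Marquardt — a second-order method for
  which a learning-rate setting is inert.  L-BFGS is the closest available
  analogue; stochastic `adam`/`sgd` (where the 0.01 learning rate applies)
  remain options but train deep tanh stacks poorly within 100 epochs.
* **20 seeded restarts, keeping the lowest training loss.**  Deep tanh
  networks are initialisation-sensitive; restarts remove the variance.
  The validation split is never consulted in the selection.

On the separable 400-eye benchmark the classifier reaches ≥ 95% validation
accuracy and the regressor RMS ≈ 0.05–0.1 mm with Pearson R ≥ 0.95; on
default (noisy, weakly coupled) cohorts performance drops to roughly the
60–75% accuracy regime, which is the realistic operating point.  Models
serialise to JSON (architecture, normalisation constants, row-major
weights) and deserialised models predict bit-identically via an explicit
forward pass.

## Statistics

Pooled-variance two-sample t-tests (Welch optional; two identical constant
samples give t = 0, p = 1 by convention), Pearson correlation with the
weak/moderate/strong banding at |R| = 0.3 and 0.7 (0.3 and 0.7 inclusive
in "moderate"), and KS normality testing against a normal with
sample-estimated mean/SD.  Because the parameters are estimated, p-values
come from the Lilliefors distribution (statsmodels) — the naive KS p-value
is invalid in that setting.  Angle summaries report circular mean/SD
(wrap-around safe) alongside arithmetic ones.  Violin exports provide raw
values, mean/median, and a Silverman-bandwidth Gaussian KDE normalised to
unit integral.

## Problem sizes and numerical defaults

The test suite runs unit tests on reduced grids (the operators are
resolution-independent) and the acceptance suite at the full 300 x 333
density: a 100-eye noiseless recovery cohort, a 250-eye noisy dose-response
cohort, and the 400-eye predictor benchmark — sizes chosen so the full
suite completes in a few minutes on one CPU while keeping every statistical
check well-powered.  Key tolerances: sphere power within 0.05 D of
337.5/R over the 5 mm zone; Zernike recovery to 1e-8 mm; noiseless TZ
centre recovery within 0.1 mm and 10°; basis cross-products < 1e-3 under
trapezoid quadrature.

## Known limitations

* The generator emulates smooth biconic + Zernike corneas; it has no
  epithelial biomechanics, tear film, lens-design geometry, limbal
  topography, or missing-data patterns of real exams (lid shadows, tear
  break-up), so passing recovery tests demonstrates correctness of the
  *pipeline*, not clinical performance on real maps.
* The shape–decentration coupling is an invented, literature-motivated
  mechanism; real predictability from baseline topography is an empirical
  question the synthetic benchmark cannot settle.
* The treatment power profile is an artifact choice (difference of
  Gaussians); no quantitative reshaping model was available to copy.
* Proprietary topographer binaries are out of scope; ingestion is via the
  documented TOPO-CSV text format.
* Axial/sagittal curvature maps and posterior-surface data are not
  implemented.
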