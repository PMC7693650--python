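# Methods

## The measurement model

The package treats 3D myocardial deformation analysis as a measurement chain:
a dynamic two-layer LV mesh (the kind produced by feature-tracking of cine
CMR) is reduced to element-level strain tensors, then to AHA-segmental
features, then to a binary diagnosis. Because clinical 3D-MDA datasets are not
publicly distributable, the chain is driven by a motion phantom whose
deformation is prescribed analytically, so that every downstream number has a
closed-form reference.

## Reference geometry

The left ventricle is a truncated prolate spheroid: endocardial surface
ρ = R·sin v, z = c·cos v for v ∈ [π/2, π(1 − τ)], with equatorial endocardial
radius R = 25 mm, base-to-apex extent 70 mm, and apical truncation τ = 0.1
(removing the pole avoids degenerate elements; patient meshes likewise never
close at the apex). The epicardial layer offsets the endocardium outward along
its meridian normal by a thickness field T(θ, μ) (θ circumferential angle from
the anterior RV insertion, μ ∈ [0, 1] base → apex). The default 30 × 17 grid
gives 510 nodes per layer — the "~500 nodal elements per layer" regime of
clinical 3D-MDA — and 480 hexahedral elements, one element transmurally.

Conventions fixed here (deterministic AHA sectoring requires them): long axis
+z toward the base; θ measured counterclockwise viewed from the base; basal
and mid thirds cut by element-centroid z into six 60° sectors each, the apical
third into four 90° sectors; 16 segments by default (a truncated shell has no
apical cap; with 17 requested, the apical-most ring stands in for the cap and
is intended for thickness only).

## Motion model

Deformation is stretch-prescribed, not force-based: analytic ground truth is
the design priority, so there are no fibers, no pressure, no contact. Per
subject and phase:

- **Timing.** A piecewise raised-cosine activation a(t) rises from 0 at
  end-diastole to 1 at the peak fraction t_peak and decays back to 0 at the
  cycle end; phases sample t = k/30, k = 0..29. Stretches interpolate
  λ(t) = 1 + (λ_peak − 1)·a(t).
- **Endocardium (exact).** The circumferential stretch is imposed through the
  radius ratio ρ′ = λ_c ρ (angle preserved) and the longitudinal stretch
  through meridian chord lengths (base ring pinned; the axial drop of each
  chord follows from its prescribed length and radial change). Both in-plane
  subendocardial stretches are therefore exact at the node level.
- **Epicardium (incompressible, default).** The epicardial layer is placed
  along the reference transmural vector, rotated by the local meridian
  rotation of the deformed endocardium, at a thickness stretch s solving the
  mid-wall incompressibility fixed point s = 1/(λ_c,mid(s)·λ_l,mid(s)). The
  mid-wall stretches are the reference-metric-weighted means of the face
  stretches (radius weights circumferentially, chord-length weights
  longitudinally) — exactly what a trilinear centroid evaluation measures on
  this map. A short element-level correction loop then nudges the nodal
  thickness stretch so the measured centroid volume ratio is 1 (single-point
  quadrature on a curved mesh otherwise sees ~10⁻³ spurious volume change
  near the apex). Subepicardial strains and the transmural gradient are
  emergent — as in real incompressible myocardium — and the reported ground
  truth is the emergent closed form. With amplitudes at the HCM-calibrated
  values this yields a subendo/subepi circumferential gradient close to the
  published layer gradient without any per-layer tuning.
- **Epicardium (prescribed mode).** With incompressibility off,
  `endo_epi_amp_ratio` prescribes the epicardial amplitudes directly and the
  epicardial surface is built by the same exact per-column construction;
  thickness is then emergent.
- **Spatial patterns.** Amplitude modulation fields (apical sparing ≥ 1 for
  CA, septal hypokinesia co-located with the HCM bulge, smooth random
  regional jitter) multiply the peak stretches and are normalized to unit
  mean so the drawn amplitude remains the subject's global value. The jitter
  is a low-order Fourier × cosine random field at roughly segment wavelength:
  a smooth field keeps the stretch-prescribed construction geometrically
  compatible while still giving distinct per-segment features; blocky
  per-segment factors would introduce spurious shear at sector borders.
- **Torsion hook.** `torsion_deg` applies apex-relative twist linear in μ;
  it defaults to 0 and the analytic ground truth is exact only there.

Ground-truth radial stretch is the ideal 1/(λ_c,mid λ_l,mid), so the
ground-truth stretch triple multiplies to 1 to machine precision, while the
realized mesh reproduces it to ≲0.2 strain-points at default resolution.

## Class phenotypes (calibration constants)

Defaults are calibrated to published cohort-level global means for HCM and its
mimics; they are calibration inputs, not claims about physiology beyond those
means. Peak subendocardial amplitudes (circ/long, % with between-subject SD):
HCM −17.8 ± 3.7 / −15.2 ± 3.9; CA −14.2 ± 5.9 / −12.6 ± 5.1; AFD −16.5 ± 2.6 /
−15.3 ± 2.0; HTNcm −17.2 ± 3.5 / −15.3 ± 3.8. Time-to-peak fractions: 0.414,
0.414, 0.424, 0.452 (SDs 0.051–0.065). Wall thickness: HCM 10.4 ± 2.0 mm base
plus a 6 ± 1.5 mm Gaussian basal-septal bulge (σ_θ = 45°, σ_μ = 0.2, centred
at θ = 120°, μ = 0.15), giving a global mean near 11.3 mm; CA 8.5 + 2.2 mm
concentric (10.7 mm); AFD 8.1 ± 1.9 mm uniform; HTNcm 7.8 + 1.5 mm concentric
(9.3 mm). CA carries apical sparing 1.35; HCM carries septal hypokinesia 0.35
inside the bulge footprint. Regional jitter SD 0.06–0.08. Cycle length
1000 ms, so strain rates are %/s on a 1 s cycle. Draws are clipped to
physically valid ranges (amplitudes within (−45, −1)%, peak fraction within
(0.08, 0.92), thickness within (3, 25) mm).

Only global distributions are published; the segmental patterns (bulge
geometry, sparing and hypokinesia profiles, jitter scale) are this package's
constructions and are what make the classes separable regionally.

## Strain engine

- **Tensors.** Hexahedral F by trilinear shape-function derivatives at the
  element centroid (single quadrature point — adequate at this smoothness and
  cheap); face F by bilinear in-surface maps in an orthonormal tangent basis.
  E = ½(FᵀF − I) throughout; rigid motion cancels exactly.
- **Strain scale.** Stretch-based, 100(√(1 + 2η) − 1): this is the engineering
  strain of a material fibre and matches the magnitudes conventionally printed
  for myocardium (radial tens of percent positive, minimum principal around
  −25%); the raw tensor component would understate thickening. The combos
  follow the conventional reporting table: circumferential and longitudinal at
  three layers, minimum principal at three layers, radial and maximum
  principal transmural only (no through-wall direction exists on a face).
- **Temporal metrics.** Systolic peak = signed minimum for shortening combos
  (circ, long, min principal), signed maximum for radial and max principal;
  time to peak = 100·(peak index)/n_phases with one-phase (≈3.3%) resolution
  and ties broken to the earliest phase; rates by central differences with
  Δt = cycle/n_phases, split at the per-combo peak phase into systolic
  (≤ peak) and diastolic (> peak) windows; an all-zero series yields zero
  metrics rather than an error.
- **Global longitudinal shortening** is the percent change of the endocardial
  base-to-apex meridian arc length (column chord sums, averaged over
  meridians) from end-diastole to its minimum — the quantity is not otherwise
  defined by the reporting convention, so this construction is flagged as
  ours.
- **Wall thickness** projects the deformed endo→epi face-centroid vector on
  the reference radial direction; chord-vs-arc discretization biases it by
  about −0.5% at default resolution.

## Features and classifier

16 segments × (11 combos × 4 temporal metrics + thickness) = 720 features,
fixed order, units recorded in the schema sidecar (strain %, time % of cycle,
rates %/s, thickness mm). A published feature count of 917 for this taxonomy
is not reproducible from any enumeration over 16 or 17 segments; the schema is
therefore configurable and 720 is the documented default rather than a
silently patched match. Global summaries are element means (segment means
averaged with element-count weights); an unweighted mean over segments would
under-weight the element-rich apical third.

The network is fixed at 30 and 5 tanh hidden units with a log-sigmoid
read-out, cross-entropy loss and 100 epochs. Training internals are not part
of the published architecture, so they are fixed here for reproducibility:
full-batch Adam (lr 0.01, β = 0.9/0.999), uniform ±1/√fan_in initialization,
zero biases, per-fold z-scoring computed on training rows only (tanh
saturation control; also the leakage boundary), seeded end to end. Folds are
stratified per class by shuffled round-robin — with only 18 CA subjects,
unstratified fifths could go single-class. A tie at exactly 0.5 output is
called non-HCM (strict inequality). Fold summaries are mean and sample SD
(ddof = 1); the median ROC is the pointwise median of fold curves interpolated
on a fixed 101-point FPR grid.

Single-marker baselines use mid-rank Mann–Whitney AUC with a seeded
2000-resample percentile bootstrap for the 95% CI; marker orientation is
auto-flipped so reported AUC ≥ 0.5, with the orientation recorded.
Degenerate single-class resamples are skipped; undefined confusion ratios
(zero denominators) are returned as NaN and flagged, never zeroed.

## Recovery studies and problem sizes

The recovery routines (`cardiostrain.recovery`) simulate 50-subject cohorts
with the parameter of interest drawn per subject from a configured mean ± SD
and re-measure it end to end. Draws use antithetic (+z, −z) pairs: with n = 50
and SDs as large as 18 strain-points the plain sampling error of the cohort
mean would dwarf the recovery error under study, and pairing pins the realized
sample mean at the configured mean while preserving the SD. For the radial
target the subendocardial amplitudes are obtained per subject by a secant
solve (tolerance 10⁻³ strain-points) on the phantom's analytic radial
amplitude, since radial thickening is an emergent quantity under
incompressibility. The minimum-principal target sets the circumferential draw
directly and scales the longitudinal amplitude to 0.547× (the HCM long/circ
ratio), keeping the circumferential axis the in-plane minimum principal
direction in this torsion-free phantom — with in-plane shear absent, the
subendocardial minimum principal strain coincides with the more negative
in-plane axis rather than exceeding it as torsion would allow.

Default problem sizes — 30 × 17 nodes, 30 phases, 50-subject recovery
cohorts, a 163-subject classification cohort (85/18/30/30), 200 permutation
replicates on 10-feature tables — run the full suite in a few minutes on one
CPU; the permutation null is checked at low feature count because the
chance-level property is dimension-free while 720-feature replicates would
dominate runtime.

## What the phantom does not emulate

No imaging: no pixel data, no tracking error, no through-plane motion loss,
no inter-observer contour variability. No torsion by default, hence no
circumferential-longitudinal shear and principal directions aligned with the
anatomical axes. No electrophysiology or regional activation delay beyond the
smooth timing field; no hemodynamics. Class separation is controllable by
construction, so classifier results on synthetic cohorts validate the
*protocol* (no leakage, correct fold bookkeeping, chance-level behaviour under
permutation, ordering of network vs single-marker baselines) — they are not
evidence about diagnostic accuracy on real CMR data.

## Known limitations

- Single transmural element: transmural quantities are mid-wall estimates;
  sub-layer gradients within each half-wall are not resolved.
- One quadrature point per element: strain fields varying within an element
  (bulge edges, jitter extremes) are averaged; the measured global values
  carry a ≲0.2 strain-point discretization bias at default resolution
  (decreasing under refinement).
- Time-to-peak resolution is one phase (≈3.3% of cycle); no sub-frame
  interpolation.
- The incompressibility fixed point assumes a smoothly varying modulation
  field; strongly discontinuous prescribed fields would degrade both the
  volume property and the analytic ground truth.
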