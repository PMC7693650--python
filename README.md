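# cardiostrain

3D myocardial deformation analysis (3D-MDA) on synthetic dynamic left-ventricle
meshes, with a feed-forward neural network that discriminates hypertrophic
cardiomyopathy (HCM) from its mimic states — cardiac amyloidosis (CA),
Anderson–Fabry disease (AFD) and hypertensive cardiomyopathy (HTNcm).

## Who this is for

Researchers in cardiac image analysis and ML-assisted diagnosis who want a
fully testable stand-in for CMR-derived dynamic LV meshes: real 3D-MDA cohorts
are rarely shareable, so this package pairs a motion phantom with analytic
ground truth against the complete measurement-and-classification pipeline, so
every stage (strain tensors, AHA features, cross-validated network) can be
validated end to end.

## What it computes

**Geometry.** The LV is a truncated prolate-spheroid shell with paired
endocardial/epicardial node layers (default 30 × 17 = 510 nodes each) joined by
480 hexahedral elements, tracked over 30 cardiac phases.

**Strain.** From the deformation gradient **F** of each element (trilinear
centroid evaluation; bilinear membrane tensors on the endo/epi faces for
layer-specific values) the Green–Lagrange tensor is **E** = ½(**F**ᵀ**F** − I).
Strain along a direction *d* is reported stretch-based,

    ε(d) = 100 · (√(1 + 2 dᵀE d) − 1)  [%],

for circumferential, longitudinal and radial anatomical directions and for the
minimum/maximum principal directions (eigendecomposition of **E**), at
subendocardial, subepicardial and transmural layers (11 valid combinations).
Per element and combination the pipeline extracts peak systolic amplitude (%),
time to peak (% of cycle), peak systolic/diastolic strain rates (%/s), plus
end-diastolic wall thickness (mm) in the radial direction.

**Features and classifier.** Element metrics are averaged within the 16 AHA
segments: 16 × (11 × 4 + 1) = 720 features per subject. The classifier is a
feed-forward network — two fully connected hidden layers of 30 and 5 tanh
neurons, a log-sigmoid read-out in (0, 1), binary cross-entropy loss, 100
training epochs — evaluated by stratified 5-fold cross-validation (AUC,
sensitivity, specificity, PPV, NPV, accuracy; a subject is called HCM when the
output is strictly > 0.5). Single-marker threshold baselines (Mann–Whitney AUC
with bootstrap 95% CI) provide the non-ML reference.

**Phantom.** Class-conditional motion: subendocardial circumferential and
longitudinal stretches follow a raised-cosine activation toward calibrated
peak amplitudes; the epicardial layer is placed by a self-consistent mid-wall
incompressibility condition, so the transmural strain gradient and radial
thickening emerge from volume conservation. Wall-thickness patterns (HCM
basal-septal bulge, concentric thickening for CA/HTNcm), apical sparing (CA),
septal hypokinesia (HCM) and between-subject Gaussian variation produce
separable but realistic cohorts with analytic ground-truth strain.

## Worked example

```python
from cardiostrain import (CohortSpec, NetworkConfig, simulate_cohort,
                          build_feature_table, cross_validate, marker_baseline)
from cardiostrain.pipeline import global_marker_columns

spec = CohortSpec(counts={"HCM": 12, "CA": 6, "AFD": 8, "HTNcm": 8}, seed=42)
subjects, manifest = simulate_cohort(spec)
table = build_feature_table(subjects)          # 34 x 720
cv = cross_validate(table.matrix, table.labels, NetworkConfig(seed=0))
print("network  AUC {mean:.2f} (SD {sd:.2f})".format(**cv.summary["auc"]))

markers = global_marker_columns(table)
mb = marker_baseline(markers["ed_thickness"].to_numpy(), table.labels,
                     "ed_thickness", seed=0)
print(f"thickness marker AUC {mb.auc:.2f} (95% CI {mb.ci_low:.2f}-{mb.ci_high:.2f})")
```

Output:

```
network  AUC 0.95 (SD 0.07)
thickness marker AUC 0.77 (95% CI 0.59-0.93)
```

The network's cross-validated AUC (0.95) exceeds the best single-marker
baseline (global end-diastolic thickness, 0.77): the regional deformation and
architecture patterns carry class information that no single global marker
captures — the qualitative ordering reported for real 3D-MDA cohorts.

The same pipeline is scriptable from the shell:

```bash
cardiostrain simulate --seed 1 --out-dir subjects --n-per-class 10
cardiostrain features --subjects-dir subjects --out-csv features.csv
cardiostrain evaluate --features-csv features.csv --out-json cv.json
cardiostrain run --seed 1 --out-dir results/full   # all-in-one, resumable
```

## Layout

| module | contents |
| --- | --- |
| `cardiostrain.geometry` | LV shell mesh, local anatomical frames, AHA segmentation, wall thickness |
| `cardiostrain.phantom`  | class phenotypes, activation waveform, cohort simulator with ground truth |
| `cardiostrain.strain`   | deformation gradients, Green–Lagrange/directional/principal strain, temporal metrics |
| `cardiostrain.features` | AHA aggregation, 720-feature schema/table, mean atlases |
| `cardiostrain.network`  | the feed-forward classifier (sklearn-style estimator), stratified k-fold CV |
| `cardiostrain.evaluate` | rank-based AUC, ROC curves, confusion metrics, marker baselines |
| `cardiostrain.recovery` | end-to-end parameter-recovery studies |
| `cardiostrain.pipeline` / `cardiostrain.cli` | orchestration, run manifests, `cardiostrain` command |

See `docs/methods.md` for the model assumptions, calibration constants,
numerical choices and known limitations.
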