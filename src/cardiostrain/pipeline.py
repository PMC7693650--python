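"""End-to-end orchestration: simulate -> extract -> classify -> baselines.

A single YAML/dict config drives the full run; every stochastic stage's seed
is derived from the master seed and recorded, file checksums land in a
deterministic run manifest, and completed stages are reused when their
outputs already exist (resume semantics).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluate import marker_baseline
from .features import FeatureSchema, FeatureTable, build_feature_table
from .geometry import LVGeometryConfig
from .io import file_sha256, load_subject, save_subject
from .network import NetworkConfig, cross_validate
from .phantom import CohortSpec, SubjectRecord, GroundTruth, simulate_cohort

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "global_marker_columns"]

log = logging.getLogger("cardiostrain")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "counts": {"HCM": 85, "CA": 18, "AFD": 30, "HTNcm": 30},
        "incompressible": True,
        "n_phases": 30,
    },
    "geometry": {},
    "network": {"hidden": [30, 5], "epochs": 100, "learning_rate": 0.01, "n_folds": 5},
    "baseline": {"n_boot": 2000},
}

#: canonical global single-marker baselines (mean over the 16 segments)
GLOBAL_MARKERS = (
    "ed_thickness",
    "peak_amp.circumferential.subendocardial",
    "peak_amp.longitudinal.subendocardial",
    "peak_amp.min_principal.subendocardial",
    "peak_amp.radial.transmural",
    "time_to_peak.circumferential.subendocardial",
)


def load_config(path_or_dict) -> dict:
    """Load and complete a pipeline config (missing keys take defaults)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _stage_seed(master: int, stage_index: int) -> int:
    return int(np.random.SeedSequence([int(master), 10_000 + stage_index]).generate_state(1)[0] % (2**31))


def cohort_spec_from_config(cfg: dict) -> CohortSpec:
    geo = LVGeometryConfig(**cfg.get("geometry", {}))
    c = cfg["cohort"]
    return CohortSpec(
        counts=dict(c["counts"]),
        seed=_stage_seed(cfg["seed"], 0),
        geometry=geo,
        incompressible=bool(c.get("incompressible", True)),
        n_phases=int(c.get("n_phases", 30)),
    )


def network_config_from_config(cfg: dict) -> NetworkConfig:
    n = cfg["network"]
    return NetworkConfig(
        hidden=tuple(n.get("hidden", (30, 5))),
        epochs=int(n.get("epochs", 100)),
        learning_rate=float(n.get("learning_rate", 0.01)),
        seed=_stage_seed(cfg["seed"], 2),
        n_folds=int(n.get("n_folds", 5)),
    )


def global_marker_columns(table: FeatureTable) -> pd.DataFrame:
    """Global (segment-mean) marker columns derived from the feature table."""
    df = pd.DataFrame(table.matrix, columns=table.schema.names)
    out = {}
    for marker in GLOBAL_MARKERS:
        cols = [c for c in df.columns if c.rsplit(".seg", 1)[0] == marker]
        if cols:
            out[marker] = df[cols].mean(axis=1)
    return pd.DataFrame(out)


def run_pipeline(config, out_dir, resume: bool = True) -> dict:
    """Run the full pipeline and return the run manifest (also written to
    ``out_dir/run_manifest.json``).

    Stages: simulate (subject containers + cohort manifest), features
    (CSV + schema), cross-validation (CVResult JSON), single-marker
    baselines (CSV). The manifest content is fully deterministic for a given
    config, so re-runs can be compared bit for bit; wall-clock timestamps go
    to the log only.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subj_dir = out / "subjects"
    features_csv = out / "features.csv"
    schema_json = out / "schema.json"
    cohort_csv = out / "cohort_manifest.csv"
    cv_json = out / "cv_result.json"
    baselines_csv = out / "baselines.csv"

    # --- stage 1: simulate -------------------------------------------------
    spec = cohort_spec_from_config(cfg)
    if not (resume and cohort_csv.exists() and subj_dir.exists()):
        log.info("simulating cohort (%d subjects)", sum(spec.counts.values()))
        subj_dir.mkdir(parents=True, exist_ok=True)
        subjects, manifest = simulate_cohort(spec)
        for rec in subjects:
            save_subject(subj_dir / f"{rec.id}.npz", rec.mesh, {"id": rec.id, "label": rec.label})
        manifest.to_csv(cohort_csv, index=False)
    else:
        log.info("reusing existing cohort in %s", subj_dir)
        subjects = None

    # --- stage 2: features -------------------------------------------------
    schema = FeatureSchema()
    if not (resume and features_csv.exists()):
        if subjects is None:
            subjects = _load_cohort(subj_dir, cohort_csv)
        log.info("extracting %d features per subject", schema.n_features)
        table = build_feature_table(subjects, schema)
        table.to_csv(features_csv)
        schema_json.write_text(schema.to_json())
    else:
        log.info("reusing feature table %s", features_csv)
        table = FeatureTable.from_csv(features_csv, schema)

    # --- stage 3: cross-validated network ---------------------------------
    net_cfg = network_config_from_config(cfg)
    if not (resume and cv_json.exists()):
        log.info("cross-validating the network (%d folds)", net_cfg.n_folds)
        cv = cross_validate(table.matrix, table.labels, net_cfg)
        cv_json.write_text(cv.to_json())
    else:
        log.info("reusing CV result %s", cv_json)

    # --- stage 4: single-marker baselines ----------------------------------
    if not (resume and baselines_csv.exists()):
        markers = global_marker_columns(table)
        seed_b = _stage_seed(cfg["seed"], 3)
        rows = []
        for i, name in enumerate(markers.columns):
            mb = marker_baseline(
                markers[name].to_numpy(), table.labels, name,
                n_boot=int(cfg["baseline"].get("n_boot", 2000)), seed=seed_b + i,
            )
            rows.append(
                {"marker": name, "auc": mb.auc, "ci_low": mb.ci_low,
                 "ci_high": mb.ci_high, "higher_is_positive": mb.higher_is_positive}
            )
        pd.DataFrame(rows).to_csv(baselines_csv, index=False)

    manifest = {
        "tool": "cardiostrain",
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "master_seed": cfg["seed"],
        "stage_seeds": {
            "simulate": _stage_seed(cfg["seed"], 0),
            "network": _stage_seed(cfg["seed"], 2),
            "baseline": _stage_seed(cfg["seed"], 3),
        },
        "files": {
            p.name: file_sha256(p)
            for p in (cohort_csv, features_csv, schema_json, cv_json, baselines_csv)
            if p.exists()
        },
        "n_subjects": int(sum(spec.counts.values())),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _load_cohort(subj_dir: Path, cohort_csv: Path) -> list[SubjectRecord]:
    """Rebuild subject records from containers (ground truth not persisted)."""
    manifest = pd.read_csv(cohort_csv)
    subjects = []
    empty_gt = GroundTruth(global_series={}, gls_series=np.zeros(1), thickness_global_ed=0.0, params={})
    for _, row in manifest.iterrows():
        dyn, meta = load_subject(subj_dir / f"{row['id']}.npz")
        subjects.append(
            SubjectRecord(id=str(row["id"]), label=str(row["label"]), mesh=dyn, ground_truth=empty_gt)
        )
    return subjects
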