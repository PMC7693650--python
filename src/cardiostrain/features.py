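"""AHA-segmental feature aggregation and per-subject feature vectors.

Element-level temporal strain metrics are averaged within AHA segments
(unweighted element means) and laid out in a fixed, serialized column order:
for each of the 16 segments, four temporal metrics for each of the 11
(direction, layer) strain combinations plus end-diastolic wall thickness —
16 x (11 x 4 + 1) = 720 features per subject by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AHASegmentMap, assign_aha_segments, compute_local_frames, wall_thickness
from .phantom import SubjectRecord
from .strain import COMBOS, ElementMetrics, strain_time_series, temporal_metrics

__all__ = [
    "TEMPORAL_METRICS",
    "FeatureSchema",
    "FeatureTable",
    "aggregate_to_segments",
    "extract_subject_features",
    "build_feature_table",
    "mean_atlas",
    "StrainFeatureExtractor",
]

TEMPORAL_METRICS = ("peak_amp", "time_to_peak", "peak_systolic_rate", "peak_diastolic_rate")

#: units recorded alongside every feature table
FEATURE_UNITS = {
    "peak_amp": "%",
    "time_to_peak": "% of cycle",
    "peak_systolic_rate": "%/s",
    "peak_diastolic_rate": "%/s",
    "ed_thickness": "mm",
}


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature-name schema.

    Names are ``{metric}.{direction}.{layer}.seg{k}`` for strain metrics and
    ``ed_thickness.seg{k}`` for wall thickness.
    """

    n_segments: int = 16
    combos: tuple[tuple[str, str], ...] = COMBOS
    metrics: tuple[str, ...] = TEMPORAL_METRICS
    include_thickness: bool = True

    @property
    def names(self) -> list[str]:
        out = []
        for seg in range(1, self.n_segments + 1):
            for direction, layer in self.combos:
                for metric in self.metrics:
                    out.append(f"{metric}.{direction}.{layer}.seg{seg}")
            if self.include_thickness:
                out.append(f"ed_thickness.seg{seg}")
        return out

    @property
    def n_features(self) -> int:
        return self.n_segments * (len(self.combos) * len(self.metrics) + int(self.include_thickness))

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_segments": self.n_segments,
                "combos": [list(c) for c in self.combos],
                "metrics": list(self.metrics),
                "include_thickness": self.include_thickness,
                "names": self.names,
                "units": FEATURE_UNITS,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            n_segments=d["n_segments"],
            combos=tuple(tuple(c) for c in d["combos"]),
            metrics=tuple(d["metrics"]),
            include_thickness=d["include_thickness"],
        )


@dataclass
class FeatureTable:
    """Subjects x features matrix with ids, binary labels and the schema."""

    ids: list[str]
    labels: np.ndarray  # 1 = HCM, 0 = other
    matrix: np.ndarray  # (n_subjects, n_features)
    schema: FeatureSchema

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.schema.n_features:
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match schema "
                f"({self.schema.n_features} features)"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary (1 = HCM, 0 = other)")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.schema.names)
        df.insert(0, "subject_id", self.ids)
        df.insert(1, "label", self.labels)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, schema: FeatureSchema | None = None) -> "FeatureTable":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("subject_id", "label")]
        if schema is None:
            schema = _infer_schema(names)
        if names != schema.names:
            raise ValueError("CSV column order does not match the schema")
        return cls(
            ids=df["subject_id"].astype(str).tolist(),
            labels=df["label"].to_numpy(),
            matrix=df[names].to_numpy(float),
            schema=schema,
        )


def _infer_schema(names: list[str]) -> FeatureSchema:
    segs = {int(n.rsplit(".seg", 1)[1]) for n in names}
    combos, metrics = [], []
    for n in names:
        if n.startswith("ed_thickness"):
            continue
        metric, direction, layer, _ = n.rsplit(".", 3)
        if (direction, layer) not in combos:
            combos.append((direction, layer))
        if metric not in metrics:
            metrics.append(metric)
    schema = FeatureSchema(
        n_segments=max(segs),
        combos=tuple(combos),
        metrics=tuple(metrics),
        include_thickness=any(n.startswith("ed_thickness") for n in names),
    )
    return schema


def aggregate_to_segments(
    values: np.ndarray, segment_map: AHASegmentMap
) -> dict[int, float]:
    """Unweighted mean of a per-element field within each AHA segment."""
    values = np.asarray(values, dtype=float)
    out = {}
    for seg, ids in segment_map.segment_elements.items():
        if ids.size == 0:
            raise ValueError(f"AHA segment {seg} is empty")
        out[seg] = float(values[ids].mean())
    return out


def extract_subject_features(
    subject: SubjectRecord,
    schema: FeatureSchema | None = None,
    segment_map: AHASegmentMap | None = None,
) -> tuple[dict[str, float], ElementMetrics]:
    """Full extraction for one subject: strain series -> temporal metrics ->
    segmental means, plus end-diastolic thickness. Returns the named feature
    dict and the per-element metrics (for atlases)."""
    if schema is None:
        schema = FeatureSchema()
    dyn = subject.mesh
    frames = compute_local_frames(dyn.mesh)
    if segment_map is None:
        segment_map = assign_aha_segments(dyn.mesh, schema.n_segments if schema.n_segments <= 16 else 17)
    series = strain_time_series(dyn, frames)
    metrics = temporal_metrics(series)
    metrics.ed_thickness = np.asarray(
        wall_thickness(dyn.mesh, None, None, frames=frames), dtype=float
    )

    feats: dict[str, float] = {}
    for combo in schema.combos:
        if combo not in metrics.metrics:
            raise ValueError(f"subject {subject.id} missing strain combo {combo}")
        for metric in schema.metrics:
            seg_means = aggregate_to_segments(metrics[combo][metric], segment_map)
            d, l = combo
            for seg in range(1, schema.n_segments + 1):
                feats[f"{metric}.{d}.{l}.seg{seg}"] = seg_means[seg]
    if schema.include_thickness:
        seg_means = aggregate_to_segments(metrics.ed_thickness, segment_map)
        for seg in range(1, schema.n_segments + 1):
            feats[f"ed_thickness.seg{seg}"] = seg_means[seg]
    return feats, metrics


def build_feature_table(
    subjects: list[SubjectRecord],
    schema: FeatureSchema | None = None,
    positive_label: str = "HCM",
) -> FeatureTable:
    """Assemble the cohort feature table in deterministic column order."""
    if schema is None:
        schema = FeatureSchema()
    names = schema.names
    rows, ids, labels = [], [], []
    for rec in subjects:
        # segment maps are recomputed per subject: wall-thickness patterns
        # perturb element centroids slightly
        seg_map = assign_aha_segments(rec.mesh.mesh, min(schema.n_segments, 17))
        feats, _ = extract_subject_features(rec, schema, seg_map)
        missing = [n for n in names if n not in feats]
        if missing:
            raise ValueError(f"subject {rec.id} missing features: {missing[:5]}...")
        rows.append([feats[n] for n in names])
        ids.append(rec.id)
        labels.append(1 if rec.label == positive_label else 0)
    matrix = np.asarray(rows, dtype=float) if rows else np.empty((0, schema.n_features))
    return FeatureTable(ids=ids, labels=np.asarray(labels, int), matrix=matrix, schema=schema)


def mean_atlas(
    subjects: list[SubjectRecord],
    combo: tuple[str, str] = ("min_principal", "subendocardial"),
    metric: str = "peak_amp",
) -> np.ndarray:
    """Node-wise cohort-mean atlas of a peak-amplitude (or other metric) map.

    Element metrics are scattered to the 2N mesh nodes (mean over adjacent
    elements) per subject, then averaged across subjects. All subjects must
    share the mesh topology.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    ref = subjects[0].mesh.mesh
    n_nodes = 2 * ref.n_layer_nodes
    acc = np.zeros(n_nodes)
    for rec in subjects:
        mesh = rec.mesh.mesh
        if mesh.hexahedra.shape != ref.hexahedra.shape or not np.array_equal(
            mesh.hexahedra, ref.hexahedra
        ):
            raise ValueError(f"subject {rec.id} has mismatching mesh topology")
        _, metrics = extract_subject_features(rec)
        vals = metrics[combo][metric] if combo in metrics.metrics else None
        if vals is None:
            raise ValueError(f"combo {combo} not available")
        node_sum = np.zeros(n_nodes)
        node_cnt = np.zeros(n_nodes)
        np.add.at(node_sum, mesh.hexahedra.ravel(), np.repeat(vals, 8))
        np.add.at(node_cnt, mesh.hexahedra.ravel(), 1.0)
        acc += node_sum / np.maximum(node_cnt, 1.0)
    return acc / len(subjects)


class StrainFeatureExtractor:
    """Transformer-style wrapper: list of subjects -> feature DataFrame.

    Follows the sklearn transformer protocol (fit/transform/get_params) so the
    extraction step can sit in a pipeline; it is stateless apart from the
    schema.
    """

    def __init__(self, schema: FeatureSchema | None = None, positive_label: str = "HCM"):
        self.schema = schema
        self.positive_label = positive_label

    def get_params(self, deep: bool = True) -> dict:
        return {"schema": self.schema, "positive_label": self.positive_label}

    def set_params(self, **params) -> "StrainFeatureExtractor":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X, y=None) -> "StrainFeatureExtractor":
        return self

    def transform(self, X: list[SubjectRecord]) -> pd.DataFrame:
        table = build_feature_table(X, self.schema, self.positive_label)
        return table.to_frame()

    def fit_transform(self, X, y=None) -> pd.DataFrame:
        return self.fit(X, y).transform(X)
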