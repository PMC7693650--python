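"""Strain computation on deforming hexahedral LV meshes.

Deformation gradients are evaluated at element centroids from trilinear shape
functions (full 3D tensor for transmural quantities) and at face centres from
bilinear surface maps (2D in-plane tensors for the subendocardial and
subepicardial layers). All reported strains are stretch-based,
100*(sqrt(1 + 2*eta) - 1) for a Green-Lagrange measure eta along a direction
or eigendirection, which reduces to the engineering strain of a material
fibre and matches the magnitudes conventionally printed for myocardium
(radial thickening tens of percent positive, shortening negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import (
    HEX_CORNER_SIGNS,
    DynamicLVMesh,
    LocalFrameField,
    compute_local_frames,
)

__all__ = [
    "COMBOS",
    "SHORTENING_DIRECTIONS",
    "StrainSeries",
    "ElementMetrics",
    "deformation_gradient",
    "surface_deformation_gradient",
    "green_lagrange",
    "directional_strain",
    "principal_strains",
    "strain_time_series",
    "temporal_metrics",
    "global_longitudinal_shortening",
]

#: the 11 reported (direction, layer) combinations
COMBOS: tuple[tuple[str, str], ...] = (
    ("circumferential", "subendocardial"),
    ("circumferential", "subepicardial"),
    ("circumferential", "transmural"),
    ("longitudinal", "subendocardial"),
    ("longitudinal", "subepicardial"),
    ("longitudinal", "transmural"),
    ("radial", "transmural"),
    ("min_principal", "subendocardial"),
    ("min_principal", "subepicardial"),
    ("min_principal", "transmural"),
    ("max_principal", "transmural"),
)

#: directions whose systolic peak is the signed minimum (shortening)
SHORTENING_DIRECTIONS = frozenset({"circumferential", "longitudinal", "min_principal"})

# bilinear quad corner signs (xi, eta)
_QUAD_SIGNS = np.array([[-1, -1], [+1, -1], [+1, +1], [-1, +1]], dtype=float)


@dataclass
class StrainSeries:
    """Per-element strain time series, percent, keyed by (direction, layer).

    Each entry has shape (n_elements, n_phases); phase 0 is identically zero.
    """

    series: dict[tuple[str, str], np.ndarray]
    cycle_ms: float

    @property
    def n_phases(self) -> int:
        return next(iter(self.series.values())).shape[1]

    @property
    def n_elements(self) -> int:
        return next(iter(self.series.values())).shape[0]

    def __getitem__(self, combo: tuple[str, str]) -> np.ndarray:
        return self.series[combo]

    def global_series(self, combo: tuple[str, str]) -> np.ndarray:
        """Unweighted element mean, one value per phase."""
        return self.series[combo].mean(axis=0)


@dataclass
class ElementMetrics:
    """Per-element temporal metrics per combo plus end-diastolic thickness.

    ``metrics[combo]`` is a dict with keys ``peak_amp`` (%),
    ``time_to_peak`` (% of cycle), ``peak_systolic_rate`` and
    ``peak_diastolic_rate`` (%/s), each an (n_elements,) array.
    """

    metrics: dict[tuple[str, str], dict[str, np.ndarray]]
    ed_thickness: np.ndarray | None = None

    def __getitem__(self, combo: tuple[str, str]) -> dict[str, np.ndarray]:
        return self.metrics[combo]


def _centroid_ref_grads(ref_corners: np.ndarray) -> np.ndarray:
    """Shape-function gradients w.r.t. reference coordinates at centroids.

    ref_corners: (E, 8, 3) -> (E, 8, 3) gradients dN_k/dX.
    """
    dn = HEX_CORNER_SIGNS / 8.0  # (8, 3) parent-space gradients at centroid
    jac = np.einsum("eki,kj->eij", ref_corners, dn)  # dX/dxi
    det = np.linalg.det(jac)
    if np.any(np.abs(det) < 1e-12):
        bad = int(np.argmin(np.abs(det)))
        raise ValueError(f"singular reference Jacobian in element {bad}")
    jinv = np.linalg.inv(jac)
    return np.einsum("kj,eji->eki", dn, jinv)


def deformation_gradient(ref_nodes: np.ndarray, def_nodes: np.ndarray) -> np.ndarray:
    """Deformation gradient(s) at element centroid(s) of trilinear hexahedra.

    Accepts (8, 3) arrays for a single element or (E, 8, 3) stacks. Exact for
    affine maps.
    """
    ref = np.asarray(ref_nodes, dtype=float)
    dfm = np.asarray(def_nodes, dtype=float)
    single = ref.ndim == 2
    if single:
        ref, dfm = ref[None], dfm[None]
    grads = _centroid_ref_grads(ref)
    f = np.einsum("eki,ekj->eij", dfm, grads)
    return f[0] if single else f


def _face_tangent_basis(quads: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centre tangents a1, a2 of bilinear quads plus an orthonormal basis.

    quads: (Q, 4, 3). Returns (a1, a2, t1, t2) with t1 along a1 and t2 the
    Gram-Schmidt complement.
    """
    a1 = np.einsum("qki,k->qi", quads, _QUAD_SIGNS[:, 0] / 4.0)
    a2 = np.einsum("qki,k->qi", quads, _QUAD_SIGNS[:, 1] / 4.0)
    n1 = np.linalg.norm(a1, axis=1, keepdims=True)
    if np.any(n1 < 1e-12):
        raise ValueError("degenerate tangent basis on a face quad")
    t1 = a1 / n1
    a2p = a2 - np.sum(a2 * t1, axis=1, keepdims=True) * t1
    n2 = np.linalg.norm(a2p, axis=1, keepdims=True)
    if np.any(n2 < 1e-12):
        raise ValueError("degenerate tangent basis on a face quad")
    t2 = a2p / n2
    return a1, a2, t1, t2


def surface_deformation_gradient(ref_quad: np.ndarray, def_quad: np.ndarray) -> np.ndarray:
    """In-plane 2x2 deformation gradient(s) of bilinear surface quads.

    Expressed with rows in an orthonormal basis of the deformed tangent plane
    (first axis along the deformed xi-tangent) and columns in the reference
    tangent basis; F is therefore unique up to a left rotation, and
    F^T F (hence any strain measure) is convention-free. Accepts (4, 3) or
    (Q, 4, 3) input.
    """
    ref = np.asarray(ref_quad, dtype=float)
    dfm = np.asarray(def_quad, dtype=float)
    single = ref.ndim == 2
    if single:
        ref, dfm = ref[None], dfm[None]
    a1, a2, t1, t2 = _face_tangent_basis(ref)
    b1, b2, u1, u2 = _face_tangent_basis(dfm)

    def comps(v1, v2, e1, e2):
        m = np.empty(v1.shape[:1] + (2, 2))
        m[:, 0, 0] = np.sum(v1 * e1, axis=1)
        m[:, 0, 1] = np.sum(v2 * e1, axis=1)
        m[:, 1, 0] = np.sum(v1 * e2, axis=1)
        m[:, 1, 1] = np.sum(v2 * e2, axis=1)
        return m

    a_ref = comps(a1, a2, t1, t2)
    a_def = comps(b1, b2, u1, u2)
    f = a_def @ np.linalg.inv(a_ref)
    return f[0] if single else f


def green_lagrange(f: np.ndarray) -> np.ndarray:
    """E = (F^T F - I) / 2 for a single tensor or a stack."""
    f = np.asarray(f, dtype=float)
    eye = np.eye(f.shape[-1])
    return 0.5 * (np.swapaxes(f, -1, -2) @ f - eye)


def _stretch_strain(eta: np.ndarray) -> np.ndarray:
    """Convert Green-Lagrange measures to percent stretch-based strain."""
    arg = 1.0 + 2.0 * np.asarray(eta, dtype=float)
    if np.any(arg <= 0):
        raise ValueError("unphysical compression: 1 + 2*eta <= 0")
    return 100.0 * (np.sqrt(arg) - 1.0)


def directional_strain(e: np.ndarray, d: np.ndarray) -> np.ndarray | float:
    """Percent strain of a material fibre along unit direction d.

    Supports stacked tensors (..., n, n) with matching (..., n) directions.
    """
    e = np.asarray(e, dtype=float)
    d = np.asarray(d, dtype=float)
    norms = np.linalg.norm(d, axis=-1)
    if not np.allclose(norms, 1.0, atol=1e-8):
        raise ValueError("direction vectors must be unit length")
    eta = np.einsum("...i,...ij,...j->...", d, e, d)
    out = _stretch_strain(eta)
    return float(out) if out.ndim == 0 else out


def _fix_eigvec_signs(vecs: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each vector's first nonzero component is
    positive (deterministic orientation)."""
    v = vecs.copy()
    # vectors are columns
    for col in range(v.shape[-1]):
        w = v[..., :, col]
        flat = w.reshape(-1, w.shape[-1])
        for row in flat:
            nz = np.flatnonzero(np.abs(row) > 1e-12)
            if nz.size and row[nz[0]] < 0:
                row *= -1.0
    return v


def principal_strains(e: np.ndarray, dims: int | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Minimum and maximum principal strain (percent) and eigenvectors of E.

    Returns (min %, max %, eigvecs) where eigvecs columns are sorted by
    eigenvalue ascending. Raises for inputs that are not symmetric to 1e-8.
    """
    e = np.asarray(e, dtype=float)
    if dims is not None and e.shape[-1] != dims:
        raise ValueError(f"expected {dims}x{dims} tensor, got {e.shape}")
    if not np.allclose(e, np.swapaxes(e, -1, -2), atol=1e-8):
        raise ValueError("strain tensor is not symmetric within 1e-8")
    e = 0.5 * (e + np.swapaxes(e, -1, -2))
    vals, vecs = np.linalg.eigh(e)
    strains = _stretch_strain(vals)
    vecs = _fix_eigvec_signs(vecs)
    return strains[..., 0], strains[..., -1], vecs


def _project_unit(vec3: np.ndarray, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Project 3D unit vectors into a tangent basis and renormalize -> (Q, 2)."""
    c = np.stack([np.sum(vec3 * t1, axis=1), np.sum(vec3 * t2, axis=1)], axis=1)
    n = np.linalg.norm(c, axis=1, keepdims=True)
    if np.any(n < 1e-8):
        raise ValueError("anatomical direction orthogonal to face tangent plane")
    return c / n


def strain_time_series(subject: DynamicLVMesh, frames: LocalFrameField | None = None) -> StrainSeries:
    """All 11 (direction, layer) strain series for every element and phase.

    Transmural quantities come from the 3D centroid tensor projected on the
    reference anatomical frame (or eigendecomposed); subendocardial and
    subepicardial quantities from the 2D membrane tensors of the endo and epi
    faces. Radial strain exists transmurally only (no through-wall direction
    on a face), and maximum principal strain is reported transmurally per the
    conventional table structure.
    """
    mesh = subject.mesh
    if frames is None:
        frames = compute_local_frames(mesh)
    ref_corners = mesh.element_corner_coords()
    grads = _centroid_ref_grads(ref_corners)
    n_elem, n_ph = mesh.n_elements, subject.n_phases

    # reference face bases and projected anatomical directions
    endo_ref = ref_corners[:, :4]
    epi_ref = ref_corners[:, 4:]
    face_data = {}
    for layer, quads in (("subendocardial", endo_ref), ("subepicardial", epi_ref)):
        a1, a2, t1, t2 = _face_tangent_basis(quads)
        face_data[layer] = {
            "a_ref_inv": np.linalg.inv(
                np.stack(
                    [
                        np.stack([np.sum(a1 * t1, axis=1), np.sum(a2 * t1, axis=1)], axis=-1),
                        np.stack([np.sum(a1 * t2, axis=1), np.sum(a2 * t2, axis=1)], axis=-1),
                    ],
                    axis=1,
                )
            ),
            "d_c": _project_unit(frames.e_c, t1, t2),
            "d_l": _project_unit(frames.e_l, t1, t2),
        }

    out = {combo: np.zeros((n_elem, n_ph)) for combo in COMBOS}
    for p in range(n_ph):
        nodes = subject.nodes_at_phase(p)
        corners = mesh.element_corner_coords(nodes)
        f3 = np.einsum("eki,ekj->eij", corners, grads)
        det = np.linalg.det(f3)
        if np.any(det <= 0):
            bad = int(np.argmin(det))
            raise ValueError(f"inverted element {bad} at phase {p}")
        e3 = green_lagrange(f3)
        out[("circumferential", "transmural")][:, p] = directional_strain(e3, frames.e_c)
        out[("longitudinal", "transmural")][:, p] = directional_strain(e3, frames.e_l)
        out[("radial", "transmural")][:, p] = directional_strain(e3, frames.e_r)
        vals = np.linalg.eigvalsh(e3)
        ps = _stretch_strain(vals)
        out[("min_principal", "transmural")][:, p] = ps[:, 0]
        out[("max_principal", "transmural")][:, p] = ps[:, -1]

        for layer, sl in (("subendocardial", slice(0, 4)), ("subepicardial", slice(4, 8))):
            fd = face_data[layer]
            quads = corners[:, sl]
            b1, b2, u1, u2 = _face_tangent_basis(quads)
            a_def = np.stack(
                [
                    np.stack([np.sum(b1 * u1, axis=1), np.sum(b2 * u1, axis=1)], axis=-1),
                    np.stack([np.sum(b1 * u2, axis=1), np.sum(b2 * u2, axis=1)], axis=-1),
                ],
                axis=1,
            )
            f2 = a_def @ fd["a_ref_inv"]
            e2 = green_lagrange(f2)
            out[("circumferential", layer)][:, p] = directional_strain(e2, fd["d_c"])
            out[("longitudinal", layer)][:, p] = directional_strain(e2, fd["d_l"])
            vals2 = np.linalg.eigvalsh(e2)
            out[("min_principal", layer)][:, p] = _stretch_strain(vals2[:, 0])

    for combo in COMBOS:
        out[combo][:, 0] = 0.0  # exact by definition (reference configuration)
    return StrainSeries(series=out, cycle_ms=subject.cycle_ms)


def temporal_metrics(series: StrainSeries, cycle_ms: float | None = None) -> ElementMetrics:
    """Peak amplitude, time to peak, and peak systolic/diastolic strain rates.

    The systolic peak is the signed minimum for shortening directions
    (circumferential, longitudinal, minimum principal) and the signed maximum
    for radial and maximum principal. Time to peak is expressed as percent of
    the cardiac cycle with one-phase resolution; rates use central differences
    with dt = cycle / n_phases and are split into the systolic window (phases
    at or before the peak) and diastolic window (after the peak). Ties break
    to the earliest phase; an all-zero series yields all-zero metrics.
    """
    if cycle_ms is None:
        cycle_ms = series.cycle_ms
    n_ph = series.n_phases
    if n_ph < 3:
        raise ValueError("need at least 3 phases for temporal metrics")
    dt_s = (cycle_ms / 1000.0) / n_ph
    phase_idx = np.arange(n_ph)

    metrics: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    for combo, s in series.series.items():
        direction, _ = combo
        shortening = direction in SHORTENING_DIRECTIONS
        peak_i = np.argmin(s, axis=1) if shortening else np.argmax(s, axis=1)
        peak_amp = np.take_along_axis(s, peak_i[:, None], axis=1)[:, 0]
        rate = np.gradient(s, dt_s, axis=1)
        in_sys = phase_idx[None, :] <= peak_i[:, None]
        if shortening:
            sys_rate = np.where(in_sys, rate, np.inf).min(axis=1)
            dia_rate = np.where(~in_sys, rate, -np.inf).max(axis=1)
        else:
            sys_rate = np.where(in_sys, rate, -np.inf).max(axis=1)
            dia_rate = np.where(~in_sys, rate, np.inf).min(axis=1)
        dia_rate = np.where(np.isfinite(dia_rate), dia_rate, 0.0)
        flat = np.all(s == 0.0, axis=1)
        metrics[combo] = {
            "peak_amp": np.where(flat, 0.0, peak_amp),
            "time_to_peak": np.where(flat, 0.0, 100.0 * peak_i / n_ph),
            "peak_systolic_rate": np.where(flat, 0.0, sys_rate),
            "peak_diastolic_rate": np.where(flat, 0.0, dia_rate),
        }
    return ElementMetrics(metrics=metrics)


def global_longitudinal_shortening(subject: DynamicLVMesh) -> tuple[float, np.ndarray]:
    """Global longitudinal shortening (%) and the full per-phase series.

    Defined as the percent change of the endocardial base-to-apex meridian
    arc length (column-wise chord sum, averaged over all meridians) from
    end-diastole to its minimum over the cycle.
    """
    mesh = subject.mesh
    n_long, n_circ = mesh.n_long, mesh.n_circ
    lengths = np.empty(subject.n_phases)
    for p in range(subject.n_phases):
        endo = (mesh.endo_nodes + subject.displacements[p, : mesh.n_layer_nodes]).reshape(
            n_long, n_circ, 3
        )
        chords = np.linalg.norm(np.diff(endo, axis=0), axis=2)  # (n_long-1, n_circ)
        lengths[p] = chords.sum(axis=0).mean()
    series = 100.0 * (lengths - lengths[0]) / lengths[0]
    return float(series.min()), series
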