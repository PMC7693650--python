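"""Subject containers and mesh export.

Each subject is stored as a single-file array container (numpy ``.npz``)
holding the node layers, hexahedral connectivity, per-phase displacements,
cycle duration and metadata. Per-phase legacy-VTK ASCII unstructured-grid
files can be exported for visualization in standard viewers.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .geometry import DynamicLVMesh, LVMesh

__all__ = [
    "save_subject",
    "load_subject",
    "write_vtk_unstructured",
    "write_vtk_series",
    "file_sha256",
]


def save_subject(path, subject: DynamicLVMesh, meta: dict | None = None) -> None:
    """Write a subject container (.npz) with named datasets and metadata."""
    mesh = subject.mesh
    meta = dict(meta or {})
    np.savez_compressed(
        path,
        endo_nodes=mesh.endo_nodes,
        epi_nodes=mesh.epi_nodes,
        hexahedra=mesh.hexahedra,
        n_circ=np.int64(mesh.n_circ),
        n_long=np.int64(mesh.n_long),
        node_theta=mesh.node_theta if mesh.node_theta is not None else np.empty(0),
        node_mu=mesh.node_mu if mesh.node_mu is not None else np.empty(0),
        displacements=subject.displacements,
        cycle_ms=np.float64(subject.cycle_ms),
        meta_json=np.bytes_(json.dumps(meta, sort_keys=True).encode()),
    )


def load_subject(path) -> tuple[DynamicLVMesh, dict]:
    """Read a subject container; returns the dynamic mesh and its metadata."""
    with np.load(path, allow_pickle=False) as z:
        mesh = LVMesh(
            endo_nodes=z["endo_nodes"],
            epi_nodes=z["epi_nodes"],
            hexahedra=z["hexahedra"],
            n_circ=int(z["n_circ"]),
            n_long=int(z["n_long"]),
            node_theta=z["node_theta"] if z["node_theta"].size else None,
            node_mu=z["node_mu"] if z["node_mu"].size else None,
        )
        dyn = DynamicLVMesh(
            mesh=mesh, displacements=z["displacements"], cycle_ms=float(z["cycle_ms"])
        )
        meta = json.loads(bytes(z["meta_json"]).decode())
    return dyn, meta


def write_vtk_unstructured(
    path, points: np.ndarray, hexahedra: np.ndarray, point_data: dict[str, np.ndarray] | None = None
) -> None:
    """Minimal legacy-VTK (ASCII) unstructured-grid writer for hex meshes."""
    points = np.asarray(points, dtype=float)
    hexahedra = np.asarray(hexahedra, dtype=int)
    n_pts, n_cells = points.shape[0], hexahedra.shape[0]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncardiostrain LV mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {n_pts} float\n")
        for p in points:
            fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
        fh.write(f"CELLS {n_cells} {n_cells * 9}\n")
        for cell in hexahedra:
            fh.write("8 " + " ".join(str(i) for i in cell) + "\n")
        fh.write(f"CELL_TYPES {n_cells}\n")
        fh.write("\n".join(["12"] * n_cells) + "\n")  # VTK_HEXAHEDRON
        if point_data:
            fh.write(f"POINT_DATA {n_pts}\n")
            for name, vals in point_data.items():
                vals = np.asarray(vals, dtype=float)
                if vals.shape[0] != n_pts:
                    raise ValueError(f"point data {name!r} length mismatch")
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.6f}" for v in vals) + "\n")


def write_vtk_series(
    out_dir, subject: DynamicLVMesh, basename: str = "phase", point_data: dict | None = None
) -> list[Path]:
    """One legacy-VTK file per cardiac phase."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for p in range(subject.n_phases):
        path = out_dir / f"{basename}_{p:02d}.vtk"
        write_vtk_unstructured(
            path, subject.nodes_at_phase(p), subject.mesh.hexahedra, point_data
        )
        paths.append(path)
    return paths


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
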