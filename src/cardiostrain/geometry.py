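"""Reference left-ventricular geometry, element connectivity and anatomical frames.

The left ventricle is modelled as a truncated prolate-spheroid shell with two
index-matched node layers (endocardial and epicardial, ~500 nodes each) joined
by a single layer of hexahedral elements. The long axis is +z toward the base;
the circumferential angle theta is measured counterclockwise (viewed from the
base) from the anterior right-ventricular insertion, which fixes a
deterministic AHA segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "LVGeometryConfig",
    "LVMesh",
    "DynamicLVMesh",
    "LocalFrameField",
    "AHASegmentMap",
    "build_reference_mesh",
    "compute_local_frames",
    "assign_aha_segments",
    "wall_thickness",
    "element_centroid_jacobians",
    "HEX_CORNER_SIGNS",
]

# Trilinear hexahedron corner signs (xi, eta, zeta) in the conventional
# [-1, 1]^3 parent element; zeta runs endo -> epi.
HEX_CORNER_SIGNS = np.array(
    [
        [-1, -1, -1],
        [+1, -1, -1],
        [+1, +1, -1],
        [-1, +1, -1],
        [-1, -1, +1],
        [+1, -1, +1],
        [+1, +1, +1],
        [-1, +1, +1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class LVGeometryConfig:
    """Parameters of the reference LV shell.

    n_circ / n_long are the node counts around the circumference and from base
    to apex; the default 30 x 17 grid gives 510 nodes per layer. All lengths in
    millimetres. ``apex_truncation`` is the fraction of the prolate pole
    removed to avoid degenerate apex elements.
    """

    n_circ: int = 30
    n_long: int = 17
    endo_radius_eq: float = 25.0
    base_thickness: float = 10.0
    long_axis_length: float = 70.0
    apex_truncation: float = 0.1

    def __post_init__(self) -> None:
        if self.n_circ < 8:
            raise ValueError(f"n_circ must be >= 8, got {self.n_circ}")
        if self.n_long < 4:
            raise ValueError(f"n_long must be >= 4, got {self.n_long}")
        for name in ("endo_radius_eq", "base_thickness", "long_axis_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.apex_truncation < 1.0:
            raise ValueError("apex_truncation must lie in (0, 1)")


@dataclass
class LVMesh:
    """Two-layer structured LV shell mesh.

    Nodes are indexed ``i * n_circ + j`` with i the longitudinal ring
    (0 = base) and j the circumferential position. Global node ids are the
    endocardial layer followed by the epicardial layer. ``hexahedra`` holds
    8 global node ids per element in trilinear corner order.
    """

    endo_nodes: np.ndarray  # (N, 3) mm
    epi_nodes: np.ndarray  # (N, 3) mm
    hexahedra: np.ndarray  # (n_elem, 8) int
    n_circ: int
    n_long: int
    config: LVGeometryConfig | None = None
    # parametric coordinates retained for the motion phantom
    node_theta: np.ndarray | None = None  # (N,) rad
    node_mu: np.ndarray | None = None  # (N,) 0 at base -> 1 at apex ring

    @property
    def n_layer_nodes(self) -> int:
        return self.endo_nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.hexahedra.shape[0]

    def all_nodes(self) -> np.ndarray:
        """Global node array: endo layer then epi layer, shape (2N, 3)."""
        return np.vstack([self.endo_nodes, self.epi_nodes])

    def element_corner_coords(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """(n_elem, 8, 3) corner coordinates, from ``nodes`` or the reference."""
        if nodes is None:
            nodes = self.all_nodes()
        return nodes[self.hexahedra]


@dataclass
class DynamicLVMesh:
    """A reference mesh plus per-phase nodal displacements.

    ``displacements`` has shape (n_phases, 2N, 3) in mm; phase 0 is
    end-diastole and its displacement is identically zero. ``cycle_ms`` is the
    cardiac cycle (R-R) duration.
    """

    mesh: LVMesh
    displacements: np.ndarray
    cycle_ms: float

    def __post_init__(self) -> None:
        disp = np.asarray(self.displacements, dtype=float)
        if disp.ndim != 3 or disp.shape[1] != 2 * self.mesh.n_layer_nodes or disp.shape[2] != 3:
            raise ValueError(f"displacements shape {disp.shape} inconsistent with mesh")
        if not np.all(np.isfinite(disp)):
            raise ValueError("displacements contain non-finite values")
        if np.any(disp[0] != 0.0):
            raise ValueError("displacement at phase 0 (end-diastole) must be zero")
        self.displacements = disp

    @property
    def n_phases(self) -> int:
        return self.displacements.shape[0]

    def nodes_at_phase(self, phase: int) -> np.ndarray:
        return self.mesh.all_nodes() + self.displacements[phase]


@dataclass
class LocalFrameField:
    """Per-element orthonormal anatomical triads (circumferential,
    longitudinal, radial), each of shape (n_elem, 3)."""

    e_c: np.ndarray
    e_l: np.ndarray
    e_r: np.ndarray


@dataclass
class AHASegmentMap:
    """AHA segment assignment: ``element_segment[k]`` in 1..n_segments and the
    inverse per-segment element-id lists."""

    element_segment: np.ndarray  # (n_elem,) int
    segment_elements: dict[int, np.ndarray]
    n_segments: int


def _meridian(config: LVGeometryConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endocardial meridian samples (v, rho, z) from base (v=pi/2) to the
    truncation ring near the apex."""
    v_apex = np.pi * (1.0 - config.apex_truncation)
    v = np.linspace(np.pi / 2.0, v_apex, config.n_long)
    # semi-axis chosen so the truncated base-to-apex extent equals long_axis_length
    c = config.long_axis_length / abs(np.cos(v_apex))
    rho = config.endo_radius_eq * np.sin(v)
    z = c * np.cos(v)
    return v, rho, z


def _meridian_normal(config: LVGeometryConfig, v: np.ndarray) -> np.ndarray:
    """Outward unit normal of the endocardial surface in the meridian (rho, z)
    plane, shape (len(v), 2)."""
    v_apex = np.pi * (1.0 - config.apex_truncation)
    c = config.long_axis_length / abs(np.cos(v_apex))
    d_rho = config.endo_radius_eq * np.cos(v)
    d_z = -c * np.sin(v)
    n = np.stack([-d_z, d_rho], axis=1)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    # orient outward (positive rho component away from axis)
    flip = n[:, 0] < 0
    n[flip] *= -1.0
    return n


def build_reference_mesh(
    config: LVGeometryConfig,
    thickness_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> LVMesh:
    """Build the end-diastolic two-layer mesh.

    ``thickness_field(theta, mu)`` may supply a spatially varying wall
    thickness in mm (theta circumferential angle, mu in [0, 1] base->apex);
    when omitted the wall is uniformly ``config.base_thickness``. The
    epicardial layer is the endocardial surface offset outward along its
    meridian normal by the thickness field.
    """
    v, rho, z = _meridian(config)
    normal = _meridian_normal(config, v)
    theta = 2.0 * np.pi * np.arange(config.n_circ) / config.n_circ
    mu = (v - v[0]) / (v[-1] - v[0])

    th_grid, _ = np.meshgrid(theta, v)  # (n_long, n_circ)
    mu_grid = np.repeat(mu[:, None], config.n_circ, axis=1)
    if thickness_field is None:
        thick = np.full_like(th_grid, config.base_thickness)
    else:
        thick = np.asarray(thickness_field(th_grid, mu_grid), dtype=float)
        if thick.shape != th_grid.shape:
            raise ValueError("thickness_field must return an (n_long, n_circ) array")
    if np.any(thick <= 0):
        i, j = np.unravel_index(np.argmin(thick), thick.shape)
        raise ValueError(
            f"degenerate geometry: non-positive wall thickness at ring {i}, column {j}"
        )

    cos_t, sin_t = np.cos(theta), np.sin(theta)
    endo = np.empty((config.n_long, config.n_circ, 3))
    endo[:, :, 0] = rho[:, None] * cos_t[None, :]
    endo[:, :, 1] = rho[:, None] * sin_t[None, :]
    endo[:, :, 2] = z[:, None]

    rho_epi = rho[:, None] + thick * normal[:, 0][:, None]
    z_epi = z[:, None] + thick * normal[:, 1][:, None]
    if np.any(rho_epi <= rho[:, None]):
        i, j = np.unravel_index(np.argmin(rho_epi - rho[:, None]), rho_epi.shape)
        raise ValueError(f"degenerate geometry: epicardium inside endocardium at ring {i}, column {j}")
    epi = np.empty_like(endo)
    epi[:, :, 0] = rho_epi * cos_t[None, :]
    epi[:, :, 1] = rho_epi * sin_t[None, :]
    epi[:, :, 2] = z_epi

    n_layer = config.n_long * config.n_circ
    hexes = _structured_hexahedra(config.n_long, config.n_circ, n_layer)

    mesh = LVMesh(
        endo_nodes=endo.reshape(-1, 3),
        epi_nodes=epi.reshape(-1, 3),
        hexahedra=hexes,
        n_circ=config.n_circ,
        n_long=config.n_long,
        config=config,
        node_theta=np.tile(theta, config.n_long),
        node_mu=np.repeat(mu, config.n_circ),
    )
    jac = element_centroid_jacobians(mesh)
    if np.any(jac <= 0):
        bad = int(np.argmin(jac))
        raise ValueError(f"non-positive Jacobian in element {bad}")
    return mesh


def _structured_hexahedra(n_long: int, n_circ: int, n_layer: int) -> np.ndarray:
    """Connectivity of the (n_long-1) x n_circ element grid."""
    elems = []
    for i in range(n_long - 1):
        for j in range(n_circ):
            jp = (j + 1) % n_circ
            a = i * n_circ + j
            b = (i + 1) * n_circ + j
            c = (i + 1) * n_circ + jp
            d = i * n_circ + jp
            elems.append([a, b, c, d, a + n_layer, b + n_layer, c + n_layer, d + n_layer])
    return np.asarray(elems, dtype=int)


def element_centroid_jacobians(mesh: LVMesh, nodes: np.ndarray | None = None) -> np.ndarray:
    """det of the trilinear map's Jacobian at every element centroid."""
    corners = mesh.element_corner_coords(nodes)  # (E, 8, 3)
    grad = HEX_CORNER_SIGNS / 8.0  # dN_k/d(xi,eta,zeta) at centroid, (8, 3)
    jac = np.einsum("eki,kj->eij", corners, grad)  # (E, 3, 3)
    return np.linalg.det(jac)


def compute_local_frames(mesh: LVMesh, nodes: np.ndarray | None = None) -> LocalFrameField:
    """Per-element right-handed (e_c, e_l, e_r) triads at the reference
    configuration.

    e_r follows the endo->epi face-centroid vector; e_l is the mid-surface
    tangent toward the base orthogonalized against e_r; e_c = e_l x e_r
    completes the right-handed triad (so that (e_c x e_l) . e_r = +1).
    """
    corners = mesh.element_corner_coords(nodes)  # (E, 8, 3)
    endo_c = corners[:, :4].mean(axis=1)
    epi_c = corners[:, 4:].mean(axis=1)
    r = epi_c - endo_c
    nrm = np.linalg.norm(r, axis=1, keepdims=True)
    if np.any(nrm < 1e-12):
        raise ValueError("zero-length endo->epi vector in local frame computation")
    e_r = r / nrm

    # corners 0 and 3 sit on the basal edge, 1 and 2 on the apical edge
    mid = 0.5 * (corners[:, :4] + corners[:, 4:])
    base_mid = 0.5 * (mid[:, 0] + mid[:, 3])
    apex_mid = 0.5 * (mid[:, 1] + mid[:, 2])
    l_raw = base_mid - apex_mid
    l_raw -= np.sum(l_raw * e_r, axis=1, keepdims=True) * e_r
    l_nrm = np.linalg.norm(l_raw, axis=1, keepdims=True)
    if np.any(l_nrm < 1e-12):
        raise ValueError("degenerate longitudinal direction in local frame computation")
    e_l = l_raw / l_nrm
    e_c = np.cross(e_l, e_r)
    return LocalFrameField(e_c=e_c, e_l=e_l, e_r=e_r)


def assign_aha_segments(mesh: LVMesh, n_segments: int = 16) -> AHASegmentMap:
    """Assign every element to an AHA segment.

    Basal/mid/apical thirds are cut by the long-axis (z) coordinate of element
    centroids; basal and mid thirds use six 60-degree sectors, the apical
    third four 90-degree sectors. Sector 1 (basal anterior) starts at the
    anterior RV-insertion origin theta = 0. With ``n_segments=17`` the
    apical-most element ring stands in for the apical cap (thickness use
    only; the truncated shell has no true cap).
    """
    if n_segments not in (16, 17):
        raise ValueError("n_segments must be 16 or 17")
    corners = mesh.element_corner_coords()
    cent = corners.mean(axis=1)
    theta = np.mod(np.arctan2(cent[:, 1], cent[:, 0]), 2.0 * np.pi)
    zc = cent[:, 2]

    z_hi, z_lo = zc.max(), zc.min()
    # thirds by long-axis coordinate; base has the largest z
    t1 = z_hi - (z_hi - z_lo) / 3.0
    t2 = z_hi - 2.0 * (z_hi - z_lo) / 3.0
    seg = np.empty(mesh.n_elements, dtype=int)

    cap_mask = np.zeros(mesh.n_elements, dtype=bool)
    if n_segments == 17:
        # apical-most element ring serves as the cap surrogate
        n_ring = mesh.n_circ
        cap_mask[-n_ring:] = True

    sextant = np.floor(theta / (np.pi / 3.0)).astype(int)  # 0..5
    quadrant = np.floor(theta / (np.pi / 2.0)).astype(int)  # 0..3
    basal = zc >= t1
    mid = (zc < t1) & (zc >= t2)
    apical = zc < t2
    seg[basal] = 1 + sextant[basal]
    seg[mid] = 7 + sextant[mid]
    seg[apical] = 13 + quadrant[apical]
    seg[cap_mask] = 17

    segment_elements: dict[int, np.ndarray] = {}
    for s in range(1, n_segments + 1):
        ids = np.flatnonzero(seg == s)
        if ids.size == 0:
            raise ValueError(
                f"AHA segment {s} is empty at this mesh resolution; use a finer grid"
            )
        segment_elements[s] = ids
    return AHASegmentMap(element_segment=seg, segment_elements=segment_elements, n_segments=n_segments)


def wall_thickness(
    mesh: LVMesh,
    displacements_at_phase: np.ndarray | None,
    element_id: int | np.ndarray | None = None,
    frames: LocalFrameField | None = None,
) -> np.ndarray | float:
    """Wall thickness (mm): deformed endo->epi face-centroid distance projected
    on the *reference* radial direction e_r.

    ``element_id`` may be an int, an index array, or None for all elements.
    """
    if frames is None:
        frames = compute_local_frames(mesh)
    nodes = mesh.all_nodes()
    if displacements_at_phase is not None:
        nodes = nodes + displacements_at_phase
    corners = mesh.element_corner_coords(nodes)
    endo_c = corners[:, :4].mean(axis=1)
    epi_c = corners[:, 4:].mean(axis=1)
    thick = np.sum((epi_c - endo_c) * frames.e_r, axis=1)
    if np.any(thick <= 0):
        bad = int(np.argmin(thick))
        raise ValueError(f"inverted element {bad}: non-positive projected thickness")
    if element_id is None:
        return thick
    out = thick[element_id]
    return float(out) if np.isscalar(element_id) or np.ndim(element_id) == 0 else out
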