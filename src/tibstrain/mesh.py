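"""Quadratic tetrahedral mesh primitives.

Meshes are built by extruding 2-D cross-section triangulations into wedge
(prism) stacks, splitting each prism into three tetrahedra with the
minimum-global-index diagonal rule (which guarantees conforming faces between
neighbouring prisms), and finally inserting edge midnodes to obtain 10-node
tetrahedra.  Node ordering follows the usual convention (and VTK's
QUADRATIC_TETRA): corners 0-3, then midnodes on edges
(0,1), (1,2), (2,0), (0,3), (1,3), (2,3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

REGION_CORTICAL = 0
REGION_TRABECULAR = 1
REGION_FIBULA = 2
REGION_NAMES = {REGION_CORTICAL: "cortical",
                REGION_TRABECULAR: "trabecular",
                REGION_FIBULA: "fibula"}

TET10_EDGES = ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))

# faces of a positively oriented tet, outward normals; (corner triple)
TET_FACES = ((1, 2, 3), (0, 3, 2), (0, 1, 3), (0, 2, 1))
# midnode slot (index into the 10-node element) for each corner-pair edge
_EDGE_SLOT = {frozenset(e): 4 + i for i, e in enumerate(TET10_EDGES)}


class MeshError(ValueError):
    """Raised for invalid or degenerate mesh input."""


@dataclass
class BoneMesh:
    """10-node tetrahedral mesh with per-element region labels.

    ``nodes`` are coordinates in mm; ``elements`` is (n_elem, 10) int
    connectivity; ``region`` holds REGION_* codes per element.  ``meta`` keeps
    template bookkeeping (node classification, build config) used by the shape
    modes and the shape-model variants; it travels with the mesh through
    deformations because connectivity never changes.
    """

    nodes: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    subject_id: str = "template"
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_elements(self) -> int:
        return int(self.elements.shape[0])

    def with_nodes(self, nodes: np.ndarray, subject_id: str | None = None) -> "BoneMesh":
        """Same connectivity, new coordinates (deformed copy)."""
        if nodes.shape != self.nodes.shape:
            raise MeshError("node array shape mismatch")
        return BoneMesh(np.asarray(nodes, dtype=float), self.elements, self.region,
                        subject_id or self.subject_id, self.meta)

    def corner_volumes(self) -> np.ndarray:
        return tet_corner_volumes(self.nodes, self.elements[:, :4])

    def min_jacobian(self) -> float:
        return float(min_detj_quadratic(self.nodes, self.elements))

    def boundary(self) -> tuple[np.ndarray, np.ndarray]:
        """Boundary faces as (faces (m,6), owner element ids (m,))."""
        return boundary_faces(self.elements)


def tet_corner_volumes(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of linear tetrahedra (corner nodes only)."""
    p = nodes[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


def split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split wedges (n, 6) into tetrahedra (3n, 4), conforming across faces.

    Wedge numbering: 0,1,2 bottom triangle; 3,4,5 top (vertex i below i+3).
    On each quadrilateral face the diagonal through the face's smallest global
    node index is used, so two wedges sharing a face always agree.
    """
    prisms = np.asarray(prisms)
    out = np.empty((len(prisms) * 3, 4), dtype=prisms.dtype)
    rot = ((0, 1, 2, 3, 4, 5), (1, 2, 0, 4, 5, 3), (2, 0, 1, 5, 3, 4))
    for k, pr in enumerate(prisms):
        v = list(pr)
        # bring the globally smallest vertex to local position 0
        m = int(np.argmin(v))
        if m >= 3:                       # flip top/bottom
            v = [v[3], v[4], v[5], v[0], v[1], v[2]]
            m -= 3
        v = [v[i] for i in rot[m]]
        # remaining quad face (1,2,5,4): diagonal via its min vertex
        if min(v[1], v[5]) < min(v[2], v[4]):
            tets = ((v[0], v[1], v[2], v[5]),
                    (v[0], v[1], v[5], v[4]),
                    (v[0], v[4], v[5], v[3]))
        else:
            tets = ((v[0], v[1], v[2], v[4]),
                    (v[0], v[4], v[2], v[5]),
                    (v[0], v[4], v[5], v[3]))
        out[3 * k:3 * k + 3] = tets
    return out


def orient_tets(nodes: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Flip node order where needed so all signed volumes are positive."""
    vol = tet_corner_volumes(nodes, tets)
    if np.any(vol == 0.0):
        raise MeshError("degenerate (zero-volume) tetrahedron produced")
    tets = tets.copy()
    neg = vol < 0
    tets[neg, 1], tets[neg, 2] = tets[neg, 2].copy(), tets[neg, 1].copy()
    return tets


def to_quadratic(nodes: np.ndarray, tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Insert shared edge midnodes, returning (nodes10, elements (n,10))."""
    edge_index: dict[tuple[int, int], int] = {}
    next_id = len(nodes)
    mid_coords: list[np.ndarray] = []
    elems = np.empty((len(tets), 10), dtype=np.int64)
    elems[:, :4] = tets
    for e, tet in enumerate(tets):
        for s, (a, b) in enumerate(TET10_EDGES):
            key = (min(tet[a], tet[b]), max(tet[a], tet[b]))
            idx = edge_index.get(key)
            if idx is None:
                idx = next_id
                edge_index[key] = idx
                next_id += 1
                mid_coords.append(0.5 * (nodes[key[0]] + nodes[key[1]]))
            elems[e, 4 + s] = idx
    all_nodes = np.vstack([nodes, np.array(mid_coords)]) if mid_coords else nodes.copy()
    return all_nodes, elems


# ---------------------------------------------------------------------------
# TET10 shape functions and quadrature

# 4-point Gauss rule on the reference tetrahedron (degree 2)
_GA = 0.585410196624968
_GB = 0.138196601125011
GAUSS4_POINTS = np.array([
    [_GA, _GB, _GB], [_GB, _GA, _GB], [_GB, _GB, _GA], [_GB, _GB, _GB]])
GAUSS4_WEIGHTS = np.full(4, 0.25)


def tet10_shape(xi: np.ndarray) -> np.ndarray:
    """Shape function values N (10,) at reference coords (xi, eta, zeta)."""
    x, y, z = xi
    l1 = 1.0 - x - y - z
    l = np.array([l1, x, y, z])
    n = np.empty(10)
    n[:4] = l * (2 * l - 1)
    for s, (a, b) in enumerate(TET10_EDGES):
        n[4 + s] = 4 * l[a] * l[b]
    return n


def tet10_dshape(xi: np.ndarray) -> np.ndarray:
    """Reference-coordinate gradients dN/dxi, shape (10, 3)."""
    x, y, z = xi
    l = np.array([1.0 - x - y - z, x, y, z])
    # dL/dxi rows: L1, L2, L3, L4
    dl = np.array([[-1.0, -1.0, -1.0],
                   [1.0, 0.0, 0.0],
                   [0.0, 1.0, 0.0],
                   [0.0, 0.0, 1.0]])
    dn = np.empty((10, 3))
    dn[:4] = (4 * l - 1)[:, None] * dl
    for s, (a, b) in enumerate(TET10_EDGES):
        dn[4 + s] = 4 * (l[a] * dl[b] + l[b] * dl[a])
    return dn


_DSHAPE_G4 = np.stack([tet10_dshape(p) for p in GAUSS4_POINTS])  # (4,10,3)


def min_detj_quadratic(nodes: np.ndarray, elements: np.ndarray) -> float:
    """Minimum Jacobian determinant over all elements and Gauss points."""
    coords = nodes[elements]                          # (ne, 10, 3)
    worst = np.inf
    for g in range(len(GAUSS4_POINTS)):
        j = np.einsum("nak,ac->nkc", coords, _DSHAPE_G4[g])  # (ne,3,3)
        worst = min(worst, float(np.linalg.det(j).min()))
    return worst


# ---------------------------------------------------------------------------
# Boundary extraction

def boundary_faces(elements: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Extract boundary faces of a TET10 mesh.

    Returns six-node faces (corner triple then the three edge midnodes) and
    the owning element index of each face.  A face is on the boundary when its
    corner triple occurs in exactly one element.
    """
    elements = np.asarray(elements)
    count: dict[frozenset, tuple[int, int]] = {}
    for e, el in enumerate(elements):
        for f, face in enumerate(TET_FACES):
            key = frozenset((el[face[0]], el[face[1]], el[face[2]]))
            if key in count:
                count[key] = (-1, -1)
            else:
                count[key] = (e, f)
    faces = []
    owners = []
    for (e, f) in count.values():
        if e < 0:
            continue
        el = elements[e]
        i, j, k = TET_FACES[f]
        faces.append((el[i], el[j], el[k],
                      el[_EDGE_SLOT[frozenset((i, j))]],
                      el[_EDGE_SLOT[frozenset((j, k))]],
                      el[_EDGE_SLOT[frozenset((k, i))]]))
        owners.append(e)
    order = np.argsort(owners, kind="stable")
    return np.asarray(faces, dtype=np.int64)[order], np.asarray(owners, dtype=np.int64)[order]


# ---------------------------------------------------------------------------
# Structured box mesh (FE verification geometries)

def box_mesh(nx: int, ny: int, nz: int, lx: float, ly: float, lz: float) -> BoneMesh:
    """Structured TET10 mesh of an ``lx x ly x lz`` box (cortical region).

    Each grid hexahedron is cut into two wedges and each wedge into three
    tetrahedra via the same min-index rule as the bone template, so the mesh
    is conforming by construction.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    nid = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    pts = np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1).reshape(-1, 3)

    prisms = []
    for i in range(nx):
        for j in range(ny):
            # split the (i,j) grid cell quad into two triangles (fixed diagonal:
            # the extrusion makes prisms whose vertical quad faces still get
            # the min-index diagonal treatment, so conformity holds)
            tri_a = ((i, j), (i + 1, j), (i + 1, j + 1))
            tri_b = ((i, j), (i + 1, j + 1), (i, j + 1))
            for tri in (tri_a, tri_b):
                for k in range(nz):
                    bot = [nid[a, b, k] for a, b in tri]
                    top = [nid[a, b, k + 1] for a, b in tri]
                    prisms.append(bot + top)
    tets = orient_tets(pts, split_prisms(np.asarray(prisms)))
    nodes10, elems = to_quadratic(pts, tets)
    region = np.full(len(elems), REGION_CORTICAL, dtype=np.int8)
    return BoneMesh(nodes10, elems, region, subject_id="box",
                    meta={"box": (nx, ny, nz, lx, ly, lz)})
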