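"""Output writers: legacy-ASCII VTK unstructured grids and PLY surfaces.

Only writing is implemented; downstream visualisation (ParaView etc.) is the
consumer.  Quadratic tetrahedra use VTK cell type 24 with the node ordering
already used internally (corners then edge midnodes 01,12,20,03,13,23).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import BoneMesh

VTK_QUADRATIC_TETRA = 24
VTK_QUADRATIC_TRIANGLE = 22


def _write_header(fh, title: str) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")


def _write_points(fh, nodes: np.ndarray) -> None:
    fh.write(f"POINTS {len(nodes)} double\n")
    np.savetxt(fh, nodes, fmt="%.9g")


def _write_cells(fh, cells: np.ndarray, cell_type: int) -> None:
    n, k = cells.shape
    fh.write(f"CELLS {n} {n * (k + 1)}\n")
    block = np.column_stack([np.full(n, k, dtype=np.int64), cells])
    np.savetxt(fh, block, fmt="%d")
    fh.write(f"CELL_TYPES {n}\n")
    np.savetxt(fh, np.full(n, cell_type, dtype=np.int64), fmt="%d")


def _write_cell_data(fh, n_cells: int, data: dict[str, np.ndarray]) -> None:
    if not data:
        return
    fh.write(f"CELL_DATA {n_cells}\n")
    for name, arr in data.items():
        arr = np.asarray(arr)
        if arr.ndim == 1:
            kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
            fh.write(f"SCALARS {name} {kind} 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%d" if kind == "int" else "%.9g")
        else:
            fh.write(f"FIELD perelem 1\n{name} {arr.shape[1]} {len(arr)} double\n")
            np.savetxt(fh, arr, fmt="%.9g")


def write_vtk_mesh(path: str | Path, mesh: BoneMesh,
                   cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write the volumetric mesh with ``region_label`` and extra cell data."""
    path = Path(path)
    data = {"region_label": mesh.region.astype(np.int64)}
    data.update(cell_data or {})
    with path.open("w") as fh:
        _write_header(fh, f"tibstrain mesh {mesh.subject_id}")
        _write_points(fh, mesh.nodes)
        _write_cells(fh, mesh.elements, VTK_QUADRATIC_TETRA)
        _write_cell_data(fh, mesh.n_elements, data)
    return path


def write_vtk_surface(path: str | Path, mesh: BoneMesh, faces: np.ndarray,
                      cell_data: dict[str, np.ndarray] | None = None) -> Path:
    """Write TRI6 surface faces (on the volumetric node set) with cell data."""
    path = Path(path)
    with path.open("w") as fh:
        _write_header(fh, f"tibstrain surface {mesh.subject_id}")
        _write_points(fh, mesh.nodes)
        _write_cells(fh, np.asarray(faces), VTK_QUADRATIC_TRIANGLE)
        _write_cell_data(fh, len(faces), cell_data or {})
    return path


def write_ply_surface(path: str | Path, mesh: BoneMesh, faces: np.ndarray) -> Path:
    """Export the corner triangles of a surface as PLY (via trimesh)."""
    import trimesh

    path = Path(path)
    tri = np.asarray(faces)[:, :3]
    used = np.unique(tri)
    remap = {int(v): i for i, v in enumerate(used)}
    tri_local = np.vectorize(remap.get)(tri)
    surface = trimesh.Trimesh(vertices=mesh.nodes[used], faces=tri_local,
                              process=False)
    surface.export(path)
    return path
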