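"""Periosteal shaft strain-field extraction.

The analysed field lives on the outer (periosteal) surface of the tibial
cortex, restricted to the diaphyseal band spanning 15-75% of tibia length
measured from the distal tip upward, with surface elements near muscle
attachment sites masked out (10 mm around the soleus, 5 mm around each of
the other 15 muscles) because concentrated nodal forces create locally
unphysical strain there.  Each surface element takes the effective strain of
the volumetric element that owns its face; because all cohort meshes share
the template connectivity, fields are corresponded element-by-element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fesolve import FEResult
from .mesh import REGION_CORTICAL, BoneMesh
from .synthgeom import MUSCLE_NAMES, LandmarkSet

__all__ = [
    "DEFAULT_BOUNDS", "DEFAULT_MASK_RADII", "PeriostealSurface",
    "ShaftSelection", "FieldMatrix", "periosteal_surface",
    "select_shaft_surface", "mask_attachments", "build_field_matrix",
    "CorrespondenceError",
]

#: Shaft window as fractions of tibia length (distal -> proximal).
DEFAULT_BOUNDS = (0.15, 0.75)

#: Masking radii in mm: 10 around the soleus, 5 around every other muscle.
DEFAULT_MASK_RADII = {name: (10.0 if name == "soleus" else 5.0)
                      for name in MUSCLE_NAMES}


class CorrespondenceError(ValueError):
    """Subject meshes do not share the template connectivity."""


@dataclass
class PeriostealSurface:
    """Outer tibial cortical surface: TRI6 faces with owning elements."""

    faces: np.ndarray          # (m, 6) node ids
    owners: np.ndarray         # (m,) volumetric element ids
    centroids: np.ndarray      # (m, 3) corner-centroid coordinates
    axial_fraction: np.ndarray  # (m,) centroid fraction of tibia length


def periosteal_surface(mesh: BoneMesh) -> PeriostealSurface:
    """Extract the tibia's outer cortical surface (fibula excluded)."""
    faces, owners = mesh.boundary()
    tibia_cortical = mesh.region[owners] == REGION_CORTICAL
    faces, owners = faces[tibia_cortical], owners[tibia_cortical]
    centroids = mesh.nodes[faces[:, :3]].mean(axis=1)
    z0, z1 = mesh.meta.get("tibia_z_range", (mesh.nodes[:, 2].min(),
                                             mesh.nodes[:, 2].max()))
    # deformed meshes keep template z-range metadata; measure on actual nodes
    tib = mesh.meta.get("node_bone")
    if tib is not None:
        z = mesh.nodes[tib == 0, 2]
        z0, z1 = float(z.min()), float(z.max())
    frac = (centroids[:, 2] - z0) / (z1 - z0)
    return PeriostealSurface(faces=faces, owners=owners, centroids=centroids,
                             axial_fraction=frac)


@dataclass
class ShaftSelection:
    """Masked shaft window over a periosteal surface."""

    surface: PeriostealSurface
    selected: np.ndarray                      # indices into surface arrays
    bounds: tuple[float, float] = DEFAULT_BOUNDS
    masked: dict[int, str] = field(default_factory=dict)  # index -> muscle

    @property
    def element_ids(self) -> np.ndarray:
        """Owning volumetric element ids of the surviving surface elements."""
        return self.surface.owners[self.selected]


def select_shaft_surface(mesh: BoneMesh,
                         bounds: tuple[float, float] = DEFAULT_BOUNDS,
                         surface: PeriostealSurface | None = None) -> ShaftSelection:
    """Select periosteal surface elements whose centroid fraction lies in
    the closed interval ``bounds`` (measured from the distal tip)."""
    lo, hi = bounds
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError("bounds must satisfy 0 <= lo <= hi <= 1")
    surface = surface or periosteal_surface(mesh)
    inside = (surface.axial_fraction >= lo) & (surface.axial_fraction <= hi)
    return ShaftSelection(surface=surface, selected=np.flatnonzero(inside),
                          bounds=(lo, hi))


def mask_attachments(selection: ShaftSelection, landmarks: LandmarkSet,
                     mesh: BoneMesh,
                     radii: dict[str, float] | None = None) -> ShaftSelection:
    """Drop surface elements whose centroid lies within the masking radius of
    any muscle insertion node (3-D Euclidean distance), recording the reason."""
    radii = radii if radii is not None else DEFAULT_MASK_RADII
    if any(r < 0 for r in radii.values()):
        raise ValueError("masking radii must be non-negative")
    surface = selection.surface
    keep = np.ones(len(selection.selected), dtype=bool)
    masked: dict[int, str] = dict(selection.masked)
    cents = surface.centroids[selection.selected]
    for name, radius in radii.items():
        if radius <= 0:
            continue
        p = mesh.nodes[landmarks.muscle_insertions[name]]
        d = np.linalg.norm(cents - p, axis=1)
        hit = d < radius
        for idx in np.flatnonzero(hit & keep):
            masked[int(selection.selected[idx])] = name
        keep &= ~hit
    return ShaftSelection(surface=surface, selected=selection.selected[keep],
                          bounds=selection.bounds, masked=masked)


@dataclass
class FieldMatrix:
    """Subjects x elements effective-strain matrix on the corresponded,
    masked shaft surface."""

    values: np.ndarray         # (n_subjects, m)
    element_ids: np.ndarray    # (m,) owning volumetric element ids
    subject_ids: list[str]

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.values)):
            raise ValueError("field matrix contains non-finite values")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_elements(self) -> int:
        return self.values.shape[1]


def build_field_matrix(results: list[FEResult], selection: ShaftSelection,
                       meshes: list[BoneMesh] | None = None,
                       subject_ids: list[str] | None = None) -> FieldMatrix:
    """Assemble the cohort field matrix over the masked shaft selection.

    All subjects must share connectivity; the element order of every row is
    identical by construction.
    """
    if meshes is not None:
        ref = meshes[0].elements
        for m in meshes[1:]:
            if m.elements.shape != ref.shape or not np.array_equal(m.elements, ref):
                raise CorrespondenceError(
                    f"subject {m.subject_id} connectivity differs from cohort")
    owners = selection.element_ids
    rows = [res.effective[owners] for res in results]
    ids = subject_ids or ([m.subject_id for m in meshes] if meshes is not None
                          else [f"subj{i:03d}" for i in range(len(results))])
    return FieldMatrix(values=np.stack(rows), element_ids=owners,
                       subject_ids=list(ids))
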