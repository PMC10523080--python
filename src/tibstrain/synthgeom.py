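"""Synthetic tibia-fibula cohort generation.

The template is a parametric tube-with-caps: the tibia is a two-region
(cortical shell + trabecular core) circular-section column whose outer radius
and cortical thickness vary along the axis (condylar flare proximally,
malleolar flare distally); the fibula is a slender single-region column offset
laterally and posteriorly.  This deliberately non-anatomical geometry gives
analytic ground truth for every shape mode and exact node correspondence
across subjects — every cohort member shares the template's connectivity and
differs only by documented analytic displacement fields.

Coordinate convention: axis 1 (x) = medial-lateral (+x lateral), axis 2 (y) =
anterior-posterior (+y anterior), axis 3 (z) = axial, distal -> proximal
positive.  Lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .mesh import (
    REGION_CORTICAL,
    REGION_FIBULA,
    REGION_TRABECULAR,
    BoneMesh,
    MeshError,
    orient_tets,
    split_prisms,
    to_quadratic,
)

__all__ = [
    "TemplateConfig", "LandmarkSet", "ShapeModeSpec", "SubjectCovariates",
    "Cohort", "MUSCLE_NAMES", "LIGAMENT_NAMES", "build_template",
    "default_mode_specs", "apply_shape_modes", "generate_cohort",
    "DegenerateGeometryError", "InvalidDeformationError",
]

#: The 16 muscles whose forces load the tibia/fibula.
MUSCLE_NAMES = (
    "semimembranosus", "semitendinosus",
    "biceps_femoris_long_head", "biceps_femoris_short_head",
    "sartorius", "tensor_fasciae_latae", "gracilis", "soleus",
    "tibialis_posterior", "tibialis_anterior",
    "flexor_digitorum", "flexor_hallucis",
    "peroneus_brevis", "peroneus_longus", "peroneus_tertius",
    "extensor_digitorum",
)

LIGAMENT_NAMES = ("proximal_anterior", "proximal_posterior",
                  "distal_anterior", "distal_posterior")

# muscle attachment sites on the template: (bone, axial fraction, angle deg)
# angle measured from +x (lateral) anticlockwise; 90 = anterior, 180 = medial,
# 270 = posterior.  Fractions are of the owning bone's length.
_MUSCLE_SITES: dict[str, tuple[str, float, float]] = {
    "semimembranosus": ("tibia", 0.93, 230.0),
    "semitendinosus": ("tibia", 0.90, 200.0),
    "biceps_femoris_long_head": ("fibula", 0.97, 0.0),
    "biceps_femoris_short_head": ("fibula", 0.94, 30.0),
    "sartorius": ("tibia", 0.89, 150.0),
    "tensor_fasciae_latae": ("tibia", 0.92, 45.0),
    "gracilis": ("tibia", 0.91, 170.0),
    "soleus": ("tibia", 0.68, 250.0),
    "tibialis_posterior": ("tibia", 0.55, 280.0),
    "tibialis_anterior": ("tibia", 0.60, 70.0),
    "flexor_digitorum": ("tibia", 0.50, 240.0),
    "flexor_hallucis": ("fibula", 0.45, 290.0),
    "peroneus_brevis": ("fibula", 0.40, 350.0),
    "peroneus_longus": ("fibula", 0.75, 10.0),
    "peroneus_tertius": ("fibula", 0.25, 60.0),
    "extensor_digitorum": ("fibula", 0.80, 70.0),
}


class DegenerateGeometryError(MeshError):
    """Template configuration produces an empty or inverted geometry."""


class InvalidDeformationError(MeshError):
    """A shape-mode displacement inverts at least one element."""


class TooFewSubjectsError(ValueError):
    """Cohort size below the minimum of three subjects."""


@dataclass
class TemplateConfig:
    """Parametric tibia-fibula template geometry.

    Radius/thickness profiles are sampled at equally spaced axial fractions
    (0 = distal tip, 1 = proximal end) and interpolated linearly in between.
    """

    axial_sections: int = 20
    circumferential_sections: int = 14
    tibia_length: float = 360.0
    outer_radius_profile: tuple[float, ...] = (16.0, 13.0, 11.0, 10.0, 11.0, 15.0, 19.0)
    cortical_thickness_profile: tuple[float, ...] = (2.5, 3.5, 5.0, 5.5, 5.0, 3.0, 2.5)
    fibula_length: float = 330.0
    fibula_radius: float = 7.0
    fibula_offset_lateral: float = 28.0
    fibula_offset_posterior: float = 12.0
    fibula_z0: float = -8.0

    def __post_init__(self) -> None:
        if self.axial_sections < 8 or self.circumferential_sections < 8:
            raise DegenerateGeometryError(
                "need >= 8 axial and circumferential sections for a usable field")
        if self.tibia_length <= 0 or self.fibula_length <= 0 or self.fibula_radius <= 0:
            raise DegenerateGeometryError("lengths and radii must be positive")
        r = np.asarray(self.outer_radius_profile, dtype=float)
        t = np.asarray(self.cortical_thickness_profile, dtype=float)
        if len(r) != len(t):
            raise DegenerateGeometryError("radius and thickness profiles differ in length")
        if np.any(r <= 0):
            raise DegenerateGeometryError("outer radii must be positive")
        if np.any(t <= 0) or np.any(t >= r):
            raise DegenerateGeometryError(
                "cortical thickness must satisfy 0 < thickness < outer radius everywhere")

    def outer_radius(self, zf: np.ndarray | float) -> np.ndarray:
        f = np.linspace(0.0, 1.0, len(self.outer_radius_profile))
        return np.interp(zf, f, self.outer_radius_profile)

    def cortical_thickness(self, zf: np.ndarray | float) -> np.ndarray:
        f = np.linspace(0.0, 1.0, len(self.cortical_thickness_profile))
        return np.interp(zf, f, self.cortical_thickness_profile)

    def inner_radius(self, zf: np.ndarray | float) -> np.ndarray:
        return self.outer_radius(zf) - self.cortical_thickness(zf)

    def fibula_outer_radius(self, zf: np.ndarray | float) -> np.ndarray:
        # slight head/malleolar flares
        prof = np.array([1.25, 1.0, 1.0, 1.0, 1.0, 1.3]) * self.fibula_radius
        f = np.linspace(0.0, 1.0, len(prof))
        return np.interp(zf, f, prof)


@dataclass
class LandmarkSet:
    """Template-defined node indices for constraints, loads and ligaments."""

    plateau_nodes: np.ndarray
    malleolus_node: int
    ankle_centre_node: int
    muscle_insertions: dict[str, int]
    ligament_pairs: dict[str, tuple[int, int]]
    tie_pairs: list[tuple[int, int]] = field(default_factory=list)

    def validate(self, mesh: BoneMesh) -> None:
        n = mesh.n_nodes
        idx = np.concatenate([
            self.plateau_nodes,
            [self.malleolus_node, self.ankle_centre_node],
            list(self.muscle_insertions.values()),
            np.asarray(list(self.ligament_pairs.values())).ravel(),
        ])
        if idx.min() < 0 or idx.max() >= n:
            raise MeshError("landmark index out of range")
        if len(self.plateau_nodes) == 0:
            raise MeshError("plateau node set is empty")
        if set(self.muscle_insertions) != set(MUSCLE_NAMES):
            raise MeshError("muscle insertion names must match the canonical 16")
        zb = mesh.meta["tibia_z_range"]
        z = mesh.nodes[self.plateau_nodes, 2]
        if np.any((z - zb[0]) / (zb[1] - zb[0]) < 0.95):
            raise MeshError("plateau nodes must lie in the top 5% of the tibia")


@dataclass
class ShapeModeSpec:
    """One analytic deformation mode of the template.

    ``displacement(meta, score) -> (n_nodes, 3)`` evaluates the displacement
    field at the template's node metadata; the field is the identity at
    score 0 and smooth in the score.  ``sd`` is the mode standard deviation in
    the mode's natural units (mm or dimensionless fraction, per mode docs).
    """

    name: str
    sd: float
    displacement: Callable[[dict, float], np.ndarray]
    units: str = "mm"


@dataclass
class SubjectCovariates:
    body_mass: float      # kg
    height: float         # cm
    true_mode_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.height <= 0:
            raise ValueError("body mass and height must be positive")


@dataclass
class Cohort:
    template: BoneMesh
    landmarks: LandmarkSet
    meshes: list[BoneMesh]
    covariates: list[SubjectCovariates]
    mode_specs: list[ShapeModeSpec]
    seed: int

    def __len__(self) -> int:
        return len(self.meshes)

    def manifest(self) -> pd.DataFrame:
        rows = []
        for mesh, cov in zip(self.meshes, self.covariates):
            row = {"subject_id": mesh.subject_id,
                   "body_mass_kg": cov.body_mass,
                   "height_cm": cov.height,
                   "seed": self.seed}
            for spec, s in zip(self.mode_specs, cov.true_mode_scores):
                row[f"score_{spec.name}"] = s
            rows.append(row)
        return pd.DataFrame(rows)

    def true_scores(self) -> np.ndarray:
        return np.array([c.true_mode_scores for c in self.covariates])


# ---------------------------------------------------------------------------
# Template construction

def _section_triangles(c: int, with_ring: bool) -> tuple[np.ndarray, np.ndarray]:
    """Cross-section triangulation in local per-station indices.

    Station node layout: 0 = centre, 1..c = inner ring, c+1..2c = outer ring
    (tibia, ``with_ring``) or just 0 = centre, 1..c = ring (fibula).
    Returns (triangles (m,3), is_ring_triangle (m,) bool).
    """
    tris: list[tuple[int, int, int]] = []
    ring_flag: list[bool] = []
    for j in range(c):
        j1 = (j + 1) % c
        tris.append((0, 1 + j, 1 + j1))
        ring_flag.append(False)
    if with_ring:
        for j in range(c):
            j1 = (j + 1) % c
            quad = (1 + j, 1 + j1, 1 + c + j1, 1 + c + j)   # in, in, out, out
            # min-index diagonal (local indices repeat identically per station)
            if min(quad[0], quad[2]) < min(quad[1], quad[3]):
                tris += [(quad[0], quad[1], quad[2]), (quad[0], quad[2], quad[3])]
            else:
                tris += [(quad[0], quad[1], quad[3]), (quad[1], quad[2], quad[3])]
            ring_flag += [True, True]
    return np.asarray(tris), np.asarray(ring_flag)


def _extrude(tris: np.ndarray, n_sections: int, stride: int, base: int) -> np.ndarray:
    """Stack cross-section triangles into wedges between consecutive stations."""
    prisms = []
    for i in range(n_sections):
        b0 = base + i * stride
        b1 = base + (i + 1) * stride
        for t in tris:
            prisms.append([b0 + t[0], b0 + t[1], b0 + t[2],
                           b1 + t[0], b1 + t[1], b1 + t[2]])
    return np.asarray(prisms)


def build_template(config: TemplateConfig | None = None) -> tuple[BoneMesh, LandmarkSet]:
    """Build the two-region tibia + one-region fibula template mesh.

    Node and element counts are closed-form in the section counts: with A
    axial and C circumferential sections the tibia has (A+1)(2C+1) corner
    nodes and 9AC tetrahedra (3C wedges per layer, 3 tets per wedge); the
    fibula adds (A+1)(C+1) corner nodes and 3AC tetrahedra.  The first and
    last tibia element layers are labelled cortical so the cortical set forms
    a closed shell around the trabecular core.
    """
    config = config or TemplateConfig()
    a = config.axial_sections
    c = config.circumferential_sections
    theta = 2 * np.pi * np.arange(c) / c
    ct, st = np.cos(theta), np.sin(theta)

    # --- tibia nodes: per station [centre, inner ring, outer ring]
    zf = np.linspace(0.0, 1.0, a + 1)
    zs = zf * config.tibia_length
    r_out = config.outer_radius(zf)
    r_in = config.inner_radius(zf)
    tib_stride = 1 + 2 * c
    tib_nodes = np.empty(((a + 1) * tib_stride, 3))
    for i in range(a + 1):
        b = i * tib_stride
        tib_nodes[b] = (0.0, 0.0, zs[i])
        tib_nodes[b + 1:b + 1 + c] = np.column_stack(
            [r_in[i] * ct, r_in[i] * st, np.full(c, zs[i])])
        tib_nodes[b + 1 + c:b + 1 + 2 * c] = np.column_stack(
            [r_out[i] * ct, r_out[i] * st, np.full(c, zs[i])])

    tris, is_ring = _section_triangles(c, with_ring=True)
    tib_prisms = _extrude(tris, a, tib_stride, 0)
    # region per wedge: ring wedges cortical, core wedges trabecular,
    # end layers all cortical (closed shell)
    wedge_region = np.where(np.tile(is_ring, a), REGION_CORTICAL, REGION_TRABECULAR)
    layer = np.repeat(np.arange(a), len(tris))
    wedge_region[(layer == 0) | (layer == a - 1)] = REGION_CORTICAL

    # --- fibula nodes: per station [centre, ring]
    fz = config.fibula_z0 + np.linspace(0.0, 1.0, a + 1) * config.fibula_length
    fr = config.fibula_outer_radius(np.linspace(0.0, 1.0, a + 1))
    fib_base = len(tib_nodes)
    fib_stride = 1 + c
    fib_nodes = np.empty(((a + 1) * fib_stride, 3))
    fx, fy = config.fibula_offset_lateral, -config.fibula_offset_posterior
    for i in range(a + 1):
        b = i * fib_stride
        fib_nodes[b] = (fx, fy, fz[i])
        fib_nodes[b + 1:b + 1 + c] = np.column_stack(
            [fx + fr[i] * ct, fy + fr[i] * st, np.full(c, fz[i])])
    ftris, _ = _section_triangles(c, with_ring=False)
    fib_prisms = _extrude(ftris, a, fib_stride, fib_base)

    nodes = np.vstack([tib_nodes, fib_nodes])
    prisms = np.vstack([tib_prisms, fib_prisms])
    tets = split_prisms(prisms)
    # each wedge yields 3 tets in order
    region = np.empty(len(tets), dtype=np.int8)
    region[:len(tib_prisms) * 3] = np.repeat(wedge_region, 3)
    region[len(tib_prisms) * 3:] = REGION_FIBULA
    tets = orient_tets(nodes, tets)
    nodes10, elements = to_quadratic(nodes, tets)

    # node classification (corner nodes; midnodes classified by interpolation)
    n_lin = len(nodes)
    node_bone = np.zeros(len(nodes10), dtype=np.int8)       # 0 tibia, 1 fibula
    node_bone[fib_base:n_lin] = 1
    lin_kind = np.zeros(n_lin, dtype=np.int8)                # 0 centre,1 inner,2 outer
    for i in range(a + 1):
        b = i * tib_stride
        lin_kind[b + 1:b + 1 + c] = 1
        lin_kind[b + 1 + c:b + 1 + 2 * c] = 2
    lin_kind[fib_base:] = 2
    for i in range(a + 1):
        lin_kind[fib_base + i * fib_stride] = 0
    # midnodes: bone of either endpoint (edges never cross bones)
    for e, (p, q) in _midnode_edges(elements, n_lin):
        node_bone[e] = node_bone[p]

    tibia_outer = np.concatenate(
        [i * tib_stride + 1 + c + np.arange(c) for i in range(a + 1)])
    tibia_inner = np.concatenate(
        [i * tib_stride + 1 + np.arange(c) for i in range(a + 1)])
    fibula_ring = np.concatenate(
        [fib_base + i * fib_stride + 1 + np.arange(c) for i in range(a + 1)])

    meta = {
        "config": config,
        "n_linear_nodes": n_lin,
        "node_bone": node_bone,
        "tibia_z_range": (0.0, config.tibia_length),
        "fibula_axis_xy": (fx, fy),
        "fibula_z_range": (fz[0], fz[-1]),
        "tibia_outer_nodes": tibia_outer,
        "tibia_inner_nodes": tibia_inner,
        "fibula_ring_nodes": fibula_ring,
        "sections": (a, c),
    }
    mesh = BoneMesh(nodes10, elements, region, subject_id="template", meta=meta)
    landmarks = _build_landmarks(mesh, config)
    landmarks.validate(mesh)
    return mesh, landmarks


def _midnode_edges(elements: np.ndarray, n_lin: int):
    """Yield (midnode id, (corner a, corner b)) for every quadratic midnode."""
    seen = set()
    from .mesh import TET10_EDGES
    for el in elements:
        for s, (i, j) in enumerate(TET10_EDGES):
            m = el[4 + s]
            if m not in seen:
                seen.add(m)
                yield m, (el[i], el[j])


def _nearest_node(mesh: BoneMesh, candidates: np.ndarray, point: np.ndarray) -> int:
    d = np.linalg.norm(mesh.nodes[candidates] - point, axis=1)
    # lowest node index wins ties
    best = np.flatnonzero(d == d.min())
    return int(candidates[best.min()]) if len(best) > 1 else int(candidates[np.argmin(d)])


def _build_landmarks(mesh: BoneMesh, config: TemplateConfig) -> LandmarkSet:
    nodes = mesh.nodes
    a, c = mesh.meta["sections"]
    lt = config.tibia_length
    # plateau: every node at the proximal tibia station (cap surface)
    tib_mask = mesh.meta["node_bone"] == 0
    plateau = np.flatnonzero(tib_mask & (np.abs(nodes[:, 2] - lt) < 1e-9))

    outer = mesh.meta["tibia_outer_nodes"]
    fib_ring = mesh.meta["fibula_ring_nodes"]

    # ankle centre: distal tibia cap centre node (node 0 by construction)
    ankle_centre = 0
    # malleolus: most medial (-x) outer node at the distal tibia
    distal_outer = outer[nodes[outer, 2] < 0.05 * lt]
    malleolus = int(distal_outer[np.lexsort((distal_outer, nodes[distal_outer, 0]))][0])

    insertions: dict[str, int] = {}
    for name, (bone, frac, ang) in _MUSCLE_SITES.items():
        th = np.deg2rad(ang)
        if bone == "tibia":
            zf = frac
            r = config.outer_radius(zf)
            target = np.array([r * np.cos(th), r * np.sin(th), zf * lt])
            insertions[name] = _nearest_node(mesh, outer, target)
        else:
            fx, fy = mesh.meta["fibula_axis_xy"]
            z0, z1 = mesh.meta["fibula_z_range"]
            r = config.fibula_outer_radius(frac)
            target = np.array([fx + r * np.cos(th), fy + r * np.sin(th),
                               z0 + frac * (z1 - z0)])
            insertions[name] = _nearest_node(mesh, fib_ring, target)

    fx, fy = mesh.meta["fibula_axis_xy"]
    z0, z1 = mesh.meta["fibula_z_range"]
    lig: dict[str, tuple[int, int]] = {}
    for name, frac, ang in (("proximal_anterior", 0.96, 90.0),
                            ("proximal_posterior", 0.96, 270.0),
                            ("distal_anterior", 0.06, 90.0),
                            ("distal_posterior", 0.06, 270.0)):
        th = np.deg2rad(ang)
        zf_fib = frac
        zfib = z0 + zf_fib * (z1 - z0)
        r = config.fibula_outer_radius(zf_fib)
        fib_node = _nearest_node(
            mesh, fib_ring, np.array([fx + r * np.cos(th), fy + r * np.sin(th), zfib]))
        tib_node = _nearest_node(mesh, outer, nodes[fib_node])
        lig[name] = (tib_node, fib_node)

    # tied-contact pairs: nearest tibia node for each fibula ring node in the
    # proximal and distal joint bands of the fibula
    ties: list[tuple[int, int]] = []
    fib_zf = (nodes[fib_ring, 2] - z0) / (z1 - z0)
    for band in ((0.0, 0.08), (0.92, 1.0)):
        in_band = fib_ring[(fib_zf >= band[0]) & (fib_zf <= band[1])]
        for fn in in_band:
            ties.append((_nearest_node(mesh, outer, nodes[fn]), int(fn)))

    return LandmarkSet(plateau_nodes=plateau, malleolus_node=malleolus,
                       ankle_centre_node=ankle_centre,
                       muscle_insertions=insertions, ligament_pairs=lig,
                       tie_pairs=ties)


# ---------------------------------------------------------------------------
# Shape modes

def _node_frame(mesh: BoneMesh) -> dict:
    """Per-node cylindrical template coordinates used by the analytic modes."""
    cfg: TemplateConfig = mesh.meta["config"]
    nodes = mesh.nodes
    bone = mesh.meta["node_bone"]
    fx, fy = mesh.meta["fibula_axis_xy"]
    x = nodes[:, 0] - np.where(bone == 1, fx, 0.0)
    y = nodes[:, 1] - np.where(bone == 1, fy, 0.0)
    zf_t = nodes[:, 2] / cfg.tibia_length
    return {
        "mesh": mesh, "config": cfg, "bone": bone,
        "x": x, "y": y, "z": nodes[:, 2],
        "r": np.hypot(x, y), "theta": np.arctan2(y, x),
        "zf_tibia": zf_t,
    }


def _mode_length(meta: dict, s: float) -> np.ndarray:
    """Axial scaling: extent multiplies by exactly (1 + s). s dimensionless."""
    u = np.zeros((len(meta["z"]), 3))
    u[:, 2] = s * meta["z"]
    return u


def _mode_overall_width(meta: dict, s: float) -> np.ndarray:
    """In-plane scaling about the tibial axis (both bones). s dimensionless."""
    u = np.zeros((len(meta["z"]), 3))
    u[:, 0] = s * meta["mesh"].nodes[:, 0]
    u[:, 1] = s * meta["mesh"].nodes[:, 1]
    return u


def _mode_upper_thickness(meta: dict, s: float) -> np.ndarray:
    """Mid-upper tibia widening with a condylar bump (tibia only).

    Radial scaling weighted by a smooth axial profile rising over the upper
    half plus a Gaussian condyle prominence near the plateau; emulates a
    'thicker mid-upper tibia with increased condyle prominence' mode.
    """
    zf = meta["zf_tibia"]
    ramp = np.clip((zf - 0.40) / 0.35, 0.0, 1.0)
    w = ramp * ramp * (3 - 2 * ramp) + 1.0 * np.exp(-((zf - 1.0) / 0.08) ** 2)
    w = np.where(meta["bone"] == 0, w, 0.0)
    u = np.zeros((len(zf), 3))
    u[:, 0] = s * w * meta["x"]
    u[:, 1] = s * w * meta["y"]
    return u


def _mode_cortical_thickness(meta: dict, s: float) -> np.ndarray:
    """Midshaft cortical thickening at fixed outer surface (tibia only).

    Moves the endosteal interface radially inward by ``s * g(zf)`` mm
    (g a midshaft Gaussian window), tapering linearly to zero at the axis and
    at the periosteal surface, so positive scores thicken the cortex and
    shrink the medullary cavity without changing the outer shape.
    """
    cfg: TemplateConfig = meta["config"]
    zf = np.clip(meta["zf_tibia"], 0.0, 1.0)
    r = meta["r"]
    r_in = np.maximum(cfg.inner_radius(zf), 1e-9)
    r_out = cfg.outer_radius(zf)
    g = np.exp(-(((zf - 0.5) / 0.25) ** 2))
    inward = np.where(r <= r_in + 1e-9, r / r_in,
                      np.clip((r_out - r) / np.maximum(r_out - r_in, 1e-9), 0.0, 1.0))
    amp = -s * g * inward * (meta["bone"] == 0)
    u = np.zeros((len(zf), 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        cx = np.where(r > 1e-12, meta["x"] / np.maximum(r, 1e-12), 0.0)
        cy = np.where(r > 1e-12, meta["y"] / np.maximum(r, 1e-12), 0.0)
    u[:, 0] = amp * cx
    u[:, 1] = amp * cy
    return u


def _mode_ap_curvature(meta: dict, s: float) -> np.ndarray:
    """Anterior bow of the tibia: u_y = s * sin(pi * zf), zero at both ends.

    The maximum offset of the deformed mid-axis from the endpoint chord is
    exactly ``s`` mm (at mid-length), giving an analytic ground truth.
    """
    zf = meta["zf_tibia"]
    u = np.zeros((len(zf), 3))
    u[:, 1] = np.where(meta["bone"] == 0, s * np.sin(np.pi * np.clip(zf, 0, 1)), 0.0)
    return u


def _mode_fibula_offset(meta: dict, s: float) -> np.ndarray:
    """Posterior translation of the whole fibula by s mm."""
    u = np.zeros((len(meta["z"]), 3))
    u[:, 1] = np.where(meta["bone"] == 1, -s, 0.0)
    return u


def default_mode_specs() -> list[ShapeModeSpec]:
    """The six planted template modes with their cohort standard deviations.

    SDs are chosen to emulate realistic adult tibia-fibula variability on the
    template scale: ~3% length SD, ~4-5% width SDs, ~0.4 mm endosteal SD,
    ~2 mm anterior-bow SD and ~1.5 mm fibula position SD; all modes remain
    inversion-free out to |score| = 3 SD.
    """
    return [
        ShapeModeSpec("length", 0.03, _mode_length, units="fraction"),
        ShapeModeSpec("overall_width", 0.04, _mode_overall_width, units="fraction"),
        ShapeModeSpec("upper_thickness_condyle", 0.05, _mode_upper_thickness,
                      units="fraction"),
        ShapeModeSpec("cortical_thickness", 0.4, _mode_cortical_thickness, units="mm"),
        ShapeModeSpec("ap_curvature", 2.0, _mode_ap_curvature, units="mm"),
        ShapeModeSpec("fibula_offset", 1.5, _mode_fibula_offset, units="mm"),
    ]


def apply_shape_modes(template: BoneMesh, specs: Sequence[ShapeModeSpec],
                      scores: Sequence[float],
                      subject_id: str | None = None) -> BoneMesh:
    """Deform the template by the summed analytic mode displacements.

    Preconditions: |score| <= 3 sd per mode.  Raises
    :class:`InvalidDeformationError` naming the offending mode if the summed
    field inverts any element.
    """
    scores = np.asarray(scores, dtype=float)
    if len(scores) != len(specs):
        raise ValueError("one score per mode spec required")
    for spec, s in zip(specs, scores):
        if spec.sd > 0 and abs(s) > 3 * spec.sd + 1e-12:
            raise ValueError(f"|score| for mode '{spec.name}' exceeds 3 sd")
    meta = _node_frame(template)
    disp = np.zeros_like(template.nodes)
    for spec, s in zip(specs, scores):
        if s != 0.0:
            disp = disp + spec.displacement(meta, float(s))
    out = template.with_nodes(template.nodes + disp, subject_id=subject_id)
    if out.min_jacobian() <= 0.0:
        culprit = _find_inverting_mode(template, specs, scores, meta)
        raise InvalidDeformationError(
            f"deformation inverts elements (offending mode: {culprit})")
    return out


def _find_inverting_mode(template, specs, scores, meta) -> str:
    for spec, s in zip(specs, scores):
        if s == 0.0:
            continue
        single = template.with_nodes(template.nodes + spec.displacement(meta, float(s)))
        if single.min_jacobian() <= 0.0:
            return spec.name
    return "combination of modes"


# ---------------------------------------------------------------------------
# Cohort generation

#: Emulated study-population covariate moments (kg, cm).
BODY_MASS_MEAN, BODY_MASS_SD = 70.22, 11.36
HEIGHT_MEAN, HEIGHT_SD = 176.06, 11.61


def _default_covariate_model(rng: np.random.Generator, n: int,
                             specs: Sequence[ShapeModeSpec]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (mass, height, scores) with size-covariate coupling.

    A latent body-size factor loads on height, mass and the ``length`` mode so
    that height and mass jointly explain roughly two-thirds of the variance in
    overall bone size, mirroring a strongly size-driven population; all other
    modes are independent.  Scores are clipped at +/- 3 sd (the template's
    validity envelope).
    """
    size = rng.standard_normal(n)
    height = HEIGHT_MEAN + HEIGHT_SD * (0.9 * size + np.sqrt(1 - 0.81) * rng.standard_normal(n))
    mass = BODY_MASS_MEAN + BODY_MASS_SD * (0.8 * size + 0.6 * rng.standard_normal(n))
    mass = np.maximum(mass, 35.0)
    height = np.maximum(height, 120.0)
    scores = np.empty((n, len(specs)))
    for k, spec in enumerate(specs):
        if spec.name == "length":
            raw = 0.8 * size + 0.6 * rng.standard_normal(n)
        else:
            raw = rng.standard_normal(n)
        scores[:, k] = np.clip(raw * spec.sd, -3 * spec.sd, 3 * spec.sd)
    return mass, height, scores


def generate_cohort(n: int, specs: Sequence[ShapeModeSpec] | None = None,
                    covariate_model: Callable | None = None,
                    seed: int = 0,
                    config: TemplateConfig | None = None) -> Cohort:
    """Generate an in-correspondence synthetic cohort of ``n`` subjects.

    The seed fully determines the output; identical connectivity is shared by
    every subject because all meshes are deformations of one template.
    """
    if n < 3:
        raise TooFewSubjectsError("a cohort needs at least 3 subjects")
    specs = list(specs) if specs is not None else default_mode_specs()
    template, landmarks = build_template(config)
    rng = np.random.default_rng(seed)
    model = covariate_model or _default_covariate_model
    mass, height, scores = model(rng, n, specs)
    meshes = []
    covs = []
    for i in range(n):
        mesh = apply_shape_modes(template, specs, scores[i],
                                 subject_id=f"subj{i:03d}")
        meshes.append(mesh)
        covs.append(SubjectCovariates(body_mass=float(mass[i]),
                                      height=float(height[i]),
                                      true_mode_scores=scores[i].copy()))
    return Cohort(template=template, landmarks=landmarks, meshes=meshes,
                  covariates=covs, mode_specs=specs, seed=seed)
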