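"""Linear orthotropic finite elements on 10-node tetrahedra.

Implements the bone loading model: orthotropic linear elasticity with
constant-anisotropy constants tied to the axial modulus (cortical 18.6 GPa,
trabecular 10.4 GPa, fibula treated as cortical), tibial plateau fixation,
anterior-posterior constraint of the medial malleolus node, tibio-fibular
ligament springs, stiff node-pair ties approximating tied contact at the
tibio-fibular joints, and concentrated nodal forces for the ankle joint
contact force and 16 muscle forces.

Units: mm / N / MPa.  Voigt order (xx, yy, zz, xy, yz, zx) with engineering
shear strains, matching the subscript convention G12/G23/G31 where 1 =
medial-lateral, 2 = anterior-posterior, 3 = axial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .loads import LoadSet
from .mesh import GAUSS4_POINTS, GAUSS4_WEIGHTS, BoneMesh, MeshError, tet10_dshape
from .synthgeom import LIGAMENT_NAMES, MUSCLE_NAMES, LandmarkSet

__all__ = [
    "OrthotropicMaterial", "StiffnessSystem", "FEResult",
    "CORTICAL_E3_MPA", "TRABECULAR_E3_MPA", "ANISOTROPY_RATIOS",
    "DEFAULT_LIGAMENT_STIFFNESS", "DEFAULT_TIE_STIFFNESS",
    "assign_materials", "assemble", "apply_boundary_conditions",
    "add_ligament_springs", "add_tie_constraints", "apply_loads", "solve",
    "effective_strain", "solve_subject", "surface_traction_load",
    "SingularSystemError", "UnconstrainedSystemError",
]

#: Axial elastic moduli (MPa): 18.6 GPa cortical, 10.4 GPa trabecular.
CORTICAL_E3_MPA = 18600.0
TRABECULAR_E3_MPA = 10400.0

#: Constant-anisotropy ratios tying every constant to the axial modulus E3.
ANISOTROPY_RATIOS = {
    "E1": 0.574, "E2": 0.577,
    "G12": 0.195, "G23": 0.265, "G31": 0.216,
    "nu12": 0.427, "nu23": 0.234, "nu31": 0.405,
}

#: Ligament spring stiffnesses, N/mm.
DEFAULT_LIGAMENT_STIFFNESS = {
    "proximal_anterior": 133.0, "proximal_posterior": 166.0,
    "distal_anterior": 78.0, "distal_posterior": 101.0,
}

#: Penalty stiffness (N/mm) for the tied tibio-fibular joint node pairs.
DEFAULT_TIE_STIFFNESS = 1e5


class SingularSystemError(RuntimeError):
    """Constrained stiffness system is singular (zero-energy modes remain)."""


class UnconstrainedSystemError(ValueError):
    """No plateau nodes available to anchor the model."""


@dataclass(frozen=True)
class OrthotropicMaterial:
    """Orthotropic elastic constants (MPa, dimensionless Poisson ratios).

    Minor Poisson ratios follow from symmetry of the compliance matrix:
    nu21 = nu12 * E2 / E1 and cyclically.
    """

    E1: float
    E2: float
    E3: float
    G12: float
    G23: float
    G31: float
    nu12: float
    nu23: float
    nu31: float

    @classmethod
    def from_axial_modulus(cls, e3_mpa: float) -> "OrthotropicMaterial":
        r = ANISOTROPY_RATIOS
        return cls(E1=r["E1"] * e3_mpa, E2=r["E2"] * e3_mpa, E3=e3_mpa,
                   G12=r["G12"] * e3_mpa, G23=r["G23"] * e3_mpa,
                   G31=r["G31"] * e3_mpa,
                   nu12=r["nu12"], nu23=r["nu23"], nu31=r["nu31"])

    @classmethod
    def cortical(cls) -> "OrthotropicMaterial":
        return cls.from_axial_modulus(CORTICAL_E3_MPA)

    @classmethod
    def trabecular(cls) -> "OrthotropicMaterial":
        return cls.from_axial_modulus(TRABECULAR_E3_MPA)

    @classmethod
    def isotropic(cls, e_mpa: float, nu: float) -> "OrthotropicMaterial":
        g = e_mpa / (2 * (1 + nu))
        return cls(E1=e_mpa, E2=e_mpa, E3=e_mpa, G12=g, G23=g, G31=g,
                   nu12=nu, nu23=nu, nu31=nu)

    @property
    def nu21(self) -> float:
        return self.nu12 * self.E2 / self.E1

    @property
    def nu32(self) -> float:
        return self.nu23 * self.E3 / self.E2

    @property
    def nu13(self) -> float:
        return self.nu31 * self.E1 / self.E3

    def compliance(self) -> np.ndarray:
        s = np.zeros((6, 6))
        s[0, 0], s[1, 1], s[2, 2] = 1 / self.E1, 1 / self.E2, 1 / self.E3
        s[0, 1] = s[1, 0] = -self.nu12 / self.E1
        s[1, 2] = s[2, 1] = -self.nu23 / self.E2
        s[2, 0] = s[0, 2] = -self.nu31 / self.E3
        s[3, 3], s[4, 4], s[5, 5] = 1 / self.G12, 1 / self.G23, 1 / self.G31
        return s

    def stiffness(self) -> np.ndarray:
        s = self.compliance()
        if np.min(np.linalg.eigvalsh(s)) <= 0:
            raise ValueError("compliance matrix is not positive definite")
        return np.linalg.inv(s)


def assign_materials(mesh: BoneMesh) -> dict[int, OrthotropicMaterial]:
    """Region-code -> material map: cortical & fibula 18.6 GPa, trabecular 10.4."""
    from .mesh import REGION_CORTICAL, REGION_FIBULA, REGION_TRABECULAR
    mats = {}
    for code in np.unique(mesh.region):
        if code == REGION_CORTICAL or code == REGION_FIBULA:
            mats[int(code)] = OrthotropicMaterial.cortical()
        elif code == REGION_TRABECULAR:
            mats[int(code)] = OrthotropicMaterial.trabecular()
        else:
            raise MeshError(f"unknown region label {code}")
    return mats


@dataclass
class StiffnessSystem:
    """Global sparse stiffness with constraint bookkeeping."""

    mesh: BoneMesh
    K: sp.csr_matrix
    fixed: np.ndarray = field(default=None)  # bool (3N,)

    def __post_init__(self) -> None:
        if self.fixed is None:
            self.fixed = np.zeros(self.K.shape[0], dtype=bool)

    @property
    def n_dof(self) -> int:
        return self.K.shape[0]

    def with_added(self, K_extra: sp.spmatrix) -> "StiffnessSystem":
        return replace(self, K=(self.K + K_extra).tocsr())


_DSHAPE = np.stack([tet10_dshape(p) for p in GAUSS4_POINTS])  # (4,10,3)


def _element_b_matrices(coords: np.ndarray):
    """Yield (B (ne,6,30), weight*detJ (ne,)) per Gauss point."""
    ne = coords.shape[0]
    for g in range(len(GAUSS4_POINTS)):
        dn = _DSHAPE[g]                                   # (10,3)
        jac = np.einsum("nak,ac->nkc", coords, dn)        # (ne,3,3)
        detj = np.linalg.det(jac)
        if np.any(detj <= 0):
            bad = int(np.argmin(detj))
            raise MeshError(f"inverted element {bad} (detJ <= 0)")
        inv = np.linalg.inv(jac)
        grad = np.einsum("ac,nck->nak", dn, inv)          # (ne,10,3)
        b = np.zeros((ne, 6, 30))
        gx, gy, gz = grad[:, :, 0], grad[:, :, 1], grad[:, :, 2]
        b[:, 0, 0::3] = gx
        b[:, 1, 1::3] = gy
        b[:, 2, 2::3] = gz
        b[:, 3, 0::3] = gy
        b[:, 3, 1::3] = gx
        b[:, 4, 1::3] = gz
        b[:, 4, 2::3] = gy
        b[:, 5, 0::3] = gz
        b[:, 5, 2::3] = gx
        yield b, detj * (GAUSS4_WEIGHTS[g] / 6.0)


def assemble(mesh: BoneMesh,
             materials: dict[int, OrthotropicMaterial] | None = None) -> StiffnessSystem:
    """Assemble the symmetric global stiffness matrix (3N x 3N, CSR).

    Before constraints the matrix has exactly the six rigid-body zero-energy
    modes of a free solid.
    """
    materials = materials or assign_materials(mesh)
    cmats = {code: m.stiffness() for code, m in materials.items()}
    c_per_elem = np.stack([cmats[int(code)] for code in mesh.region])  # (ne,6,6)

    coords = mesh.nodes[mesh.elements]                    # (ne,10,3)
    ne = coords.shape[0]
    ke = np.zeros((ne, 30, 30))
    for b, w in _element_b_matrices(coords):
        ke += np.einsum("nja,njk,nkb,n->nab", b, c_per_elem, b, w, optimize=True)

    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(ne, 30)
    rows = np.repeat(edof, 30, axis=1).ravel()
    cols = np.tile(edof, (1, 30)).ravel()
    n_dof = 3 * mesh.n_nodes
    K = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_dof, n_dof)).tocsr()
    return StiffnessSystem(mesh=mesh, K=K)


def apply_boundary_conditions(system: StiffnessSystem,
                              landmarks: LandmarkSet) -> StiffnessSystem:
    """Fix plateau nodes in translation; fix the malleolus AP component."""
    if len(landmarks.plateau_nodes) == 0:
        raise UnconstrainedSystemError("plateau node set is empty")
    fixed = system.fixed.copy()
    for n in landmarks.plateau_nodes:
        fixed[3 * n:3 * n + 3] = True
    fixed[3 * landmarks.malleolus_node + 1] = True        # y = anterior-posterior
    return replace(system, fixed=fixed)


def _pair_spring(n_dof: int, pairs, axes, stiffnesses) -> sp.csr_matrix:
    rows, cols, vals = [], [], []
    for (a, b), n, k in zip(pairs, axes, stiffnesses):
        block = k * np.outer(n, n)
        dofs = np.concatenate([3 * a + np.arange(3), 3 * b + np.arange(3)])
        sgn = np.array([[1.0, -1.0], [-1.0, 1.0]])
        full = np.kron(sgn, block)
        rows.append(np.repeat(dofs, 6))
        cols.append(np.tile(dofs, 6))
        vals.append(full.ravel())
    return sp.coo_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))),
                         shape=(n_dof, n_dof)).tocsr()


def add_ligament_springs(system: StiffnessSystem, ligament_pairs: dict,
                         stiffnesses: dict | None = None) -> StiffnessSystem:
    """Add the four tibio-fibular ligament springs along their pair axes.

    Each spring couples its node pair along the undeformed pair axis; a unit
    relative extension stores energy k/2.
    """
    stiffnesses = stiffnesses or DEFAULT_LIGAMENT_STIFFNESS
    nodes = system.mesh.nodes
    pairs, axes, ks = [], [], []
    for name in LIGAMENT_NAMES:
        a, b = ligament_pairs[name]
        d = nodes[b] - nodes[a]
        norm = np.linalg.norm(d)
        if norm == 0:
            raise MeshError(f"ligament '{name}' connects coincident nodes")
        k = float(stiffnesses[name])
        if k < 0:
            raise ValueError("spring stiffness must be >= 0")
        if k == 0:
            continue
        pairs.append((a, b))
        axes.append(d / norm)
        ks.append(k)
    if not pairs:
        return system
    return system.with_added(_pair_spring(system.n_dof, pairs, axes, ks))


def add_tie_constraints(system: StiffnessSystem, tie_pairs,
                        stiffness: float = DEFAULT_TIE_STIFFNESS) -> StiffnessSystem:
    """Stiff isotropic penalty ties approximating tied-elastic contact."""
    if not tie_pairs or stiffness == 0:
        return system
    eye = np.eye(3)
    pairs, axes, ks = [], [], []
    for (a, b) in tie_pairs:
        for i in range(3):
            pairs.append((a, b))
            axes.append(eye[i])
            ks.append(stiffness)
    return system.with_added(_pair_spring(system.n_dof, pairs, axes, ks))


def apply_loads(system: StiffnessSystem, loadset: LoadSet,
                landmarks: LandmarkSet) -> np.ndarray:
    """Concentrated nodal force vector: ankle JCF + 16 muscle forces (N)."""
    f = np.zeros(system.n_dof)
    missing = [m for m in MUSCLE_NAMES if m not in loadset.muscle_forces]
    if missing:
        raise ValueError(f"load set missing muscle entries: {missing}")
    n = landmarks.ankle_centre_node
    f[3 * n:3 * n + 3] += loadset.ankle_jcf
    for name in MUSCLE_NAMES:
        mag, d = loadset.muscle_forces[name]
        node = landmarks.muscle_insertions[name]
        if system.fixed[3 * node:3 * node + 3].all():
            warnings.warn(f"muscle '{name}' inserts on a fully constrained node",
                          stacklevel=2)
        f[3 * node:3 * node + 3] += mag * np.asarray(d)
    return f


@dataclass
class FEResult:
    """Displacements (mm), per-element strain (Voigt, engineering shears),
    per-element effective strain (dimensionless), and the relative residual of
    the constrained solve."""

    displacements: np.ndarray
    element_strain: np.ndarray
    effective: np.ndarray
    residual: float

    @property
    def effective_microstrain(self) -> np.ndarray:
        return self.effective * 1e6


class FactorizedSystem:
    """LU-factorized constrained system solving many load vectors cheaply."""

    def __init__(self, system: StiffnessSystem):
        self.system = system
        self.free = ~system.fixed
        kff = system.K[self.free][:, self.free].tocsc()
        try:
            self.lu = spla.splu(kff)
        except RuntimeError as exc:
            raise SingularSystemError(
                f"constrained system is singular ({exc}); "
                "check plateau fixation and rigid-body modes") from exc
        self.kff = kff

    def solve(self, f: np.ndarray) -> FEResult:
        ff = f[self.free]
        u_f = self.lu.solve(ff)
        # one step of iterative refinement guards the 1e-8 residual contract
        r = ff - self.kff @ u_f
        u_f = u_f + self.lu.solve(r)
        nf = np.linalg.norm(ff)
        residual = float(np.linalg.norm(ff - self.kff @ u_f) / nf) if nf > 0 else 0.0
        u = np.zeros(self.system.n_dof)
        u[self.free] = u_f
        strain = element_strains(self.system.mesh, u)
        return FEResult(displacements=u.reshape(-1, 3), element_strain=strain,
                        effective=effective_strain_voigt(strain),
                        residual=residual)


def solve(system: StiffnessSystem, loads: np.ndarray) -> FEResult:
    """Solve the constrained linear system for one load vector."""
    return FactorizedSystem(system).solve(loads)


def element_strains(mesh: BoneMesh, u: np.ndarray) -> np.ndarray:
    """Volume-averaged small-strain Voigt vectors per element."""
    coords = mesh.nodes[mesh.elements]
    edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(len(coords), 30)
    ue = u[edof]                                          # (ne,30)
    acc = np.zeros((len(coords), 6))
    wsum = np.zeros(len(coords))
    for b, w in _element_b_matrices(coords):
        acc += np.einsum("nij,nj,n->ni", b, ue, w)
        wsum += w
    return acc / wsum[:, None]


def effective_strain_voigt(strain: np.ndarray) -> np.ndarray:
    """Von Mises-equivalent strain sqrt(2/3 e_dev : e_dev) from Voigt input."""
    strain = np.atleast_2d(strain)
    tr = strain[:, :3].sum(axis=1) / 3.0
    dn = strain[:, :3] - tr[:, None]
    sh = strain[:, 3:] / 2.0                              # tensor shear components
    dd = np.einsum("ni,ni->n", dn, dn) + 2 * np.einsum("ni,ni->n", sh, sh)
    return np.sqrt(2.0 / 3.0 * dd)


def effective_strain(tensors: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Effective strain from full (..., 3, 3) symmetric strain tensors.

    Zero exactly when the deviatoric part vanishes (pure volumetric strain).
    """
    t = np.asarray(tensors, dtype=float)
    single = t.ndim == 2
    t = t.reshape(-1, 3, 3)
    if not np.allclose(t, np.swapaxes(t, 1, 2), atol=atol):
        raise ValueError("strain tensors must be symmetric")
    voigt = np.stack([t[:, 0, 0], t[:, 1, 1], t[:, 2, 2],
                      2 * t[:, 0, 1], 2 * t[:, 1, 2], 2 * t[:, 2, 0]], axis=1)
    out = effective_strain_voigt(voigt)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Convenience drivers

def build_system(mesh: BoneMesh, landmarks: LandmarkSet,
                 ligament_stiffness: dict | None = None,
                 tie_stiffness: float = DEFAULT_TIE_STIFFNESS) -> StiffnessSystem:
    system = assemble(mesh)
    system = add_ligament_springs(system, landmarks.ligament_pairs,
                                  ligament_stiffness)
    system = add_tie_constraints(system, landmarks.tie_pairs, tie_stiffness)
    return apply_boundary_conditions(system, landmarks)


def solve_subject(mesh: BoneMesh, landmarks: LandmarkSet,
                  loadsets: list[LoadSet],
                  ligament_stiffness: dict | None = None,
                  tie_stiffness: float = DEFAULT_TIE_STIFFNESS) -> list[FEResult]:
    """Factorize one subject's system once and solve all its load sets."""
    system = build_system(mesh, landmarks, ligament_stiffness, tie_stiffness)
    fact = FactorizedSystem(system)
    return [fact.solve(apply_loads(system, ls, landmarks)) for ls in loadsets]


# ---------------------------------------------------------------------------
# Surface tractions (verification loads)

_TRI6_MIDPTS = np.array([[0.5, 0.0], [0.5, 0.5], [0.0, 0.5]])


def _tri6_shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x, y = xi
    l = np.array([1 - x - y, x, y])
    n = np.empty(6)
    n[:3] = l * (2 * l - 1)
    n[3] = 4 * l[0] * l[1]
    n[4] = 4 * l[1] * l[2]
    n[5] = 4 * l[2] * l[0]
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    dn = np.empty((6, 2))
    dn[:3] = (4 * l - 1)[:, None] * dl
    dn[3] = 4 * (l[0] * dl[1] + l[1] * dl[0])
    dn[4] = 4 * (l[1] * dl[2] + l[2] * dl[1])
    dn[5] = 4 * (l[2] * dl[0] + l[0] * dl[2])
    return n, dn


def surface_traction_load(mesh: BoneMesh, faces: np.ndarray,
                          traction: np.ndarray) -> np.ndarray:
    """Consistent nodal loads for a uniform traction (N/mm^2) on TRI6 faces."""
    f = np.zeros(3 * mesh.n_nodes)
    traction = np.asarray(traction, dtype=float)
    for face in np.atleast_2d(faces):
        coords = mesh.nodes[face]
        for xi in _TRI6_MIDPTS:            # 3-point midedge rule, degree 2
            n, dn = _tri6_shape(xi)
            tx = coords.T @ dn             # (3,2) tangents
            da = np.linalg.norm(np.cross(tx[:, 0], tx[:, 1]))
            w = da / 6.0                   # weight 1/3 on reference area 1/2
            for a, node in enumerate(face):
                f[3 * node:3 * node + 3] += w * n[a] * traction
    return f
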