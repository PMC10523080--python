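"""Orthotropic FE solver: materials, assembly, constraints, loads, solves."""

import dataclasses

import numpy as np
import pytest

from tibstrain.fesolve import (
    CORTICAL_E3_MPA,
    DEFAULT_LIGAMENT_STIFFNESS,
    TRABECULAR_E3_MPA,
    FactorizedSystem,
    OrthotropicMaterial,
    UnconstrainedSystemError,
    add_ligament_springs,
    add_tie_constraints,
    apply_boundary_conditions,
    apply_loads,
    assemble,
    assign_materials,
    build_system,
    effective_strain,
    effective_strain_voigt,
    solve,
    solve_subject,
    surface_traction_load,
)
from tibstrain.loads import generate_loadset, per_kg_loadset
from tibstrain.mesh import (
    REGION_CORTICAL,
    REGION_FIBULA,
    REGION_TRABECULAR,
    BoneMesh,
    MeshError,
    boundary_faces,
    box_mesh,
)
from tibstrain.synthgeom import SubjectCovariates


class TestMaterials:
    def test_region_moduli(self, coarse_template):
        mesh, _ = coarse_template
        mats = assign_materials(mesh)
        assert mats[REGION_CORTICAL].E3 == CORTICAL_E3_MPA == 18600.0
        assert mats[REGION_TRABECULAR].E3 == TRABECULAR_E3_MPA == 10400.0
        assert mats[REGION_FIBULA] == mats[REGION_CORTICAL]
        # ratio-derived constant: E1 = 0.574 * 18600
        assert mats[REGION_CORTICAL].E1 == pytest.approx(10676.4)

    def test_unknown_region_rejected(self, coarse_template):
        mesh, _ = coarse_template
        bad = dataclasses.replace(mesh, region=np.full(mesh.n_elements, 7, np.int8))
        with pytest.raises(MeshError):
            assign_materials(bad)

    def test_compliance_symmetric_and_stiffness_pd(self):
        for mat in (OrthotropicMaterial.cortical(), OrthotropicMaterial.trabecular()):
            s = mat.compliance()
            assert np.abs(s - s.T).max() == 0
            assert np.linalg.eigvalsh(mat.stiffness()).min() > 0
            # minor-Poisson completion
            assert mat.nu21 == pytest.approx(mat.nu12 * mat.E2 / mat.E1)
            assert mat.nu13 == pytest.approx(mat.nu31 * mat.E1 / mat.E3)


@pytest.fixture(scope="module")
def box():
    mesh = box_mesh(2, 2, 3, 8.0, 8.0, 12.0)
    return mesh, assemble(mesh, {0: OrthotropicMaterial.cortical()})


@pytest.fixture(scope="module")
def patch_setup():
    """Uniaxial patch test setup: isotropic-degenerate constants."""
    mesh = box_mesh(2, 2, 4, 10, 10, 20)
    e_mod, nu, sigma = 1000.0, 0.3, 5.0
    system = assemble(mesh, {0: OrthotropicMaterial.isotropic(e_mod, nu)})
    fixed = np.zeros(system.n_dof, bool)
    z0 = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12)
    for n in z0:
        fixed[3 * n + 2] = True
    # minimal statically determinate in-plane restraints
    order = z0[np.lexsort((z0, mesh.nodes[z0, 1], mesh.nodes[z0, 0]))]
    n0 = int(order[0])
    fixed[3 * n0] = fixed[3 * n0 + 1] = True
    same_y = [n for n in z0 if n != n0
              and abs(mesh.nodes[n, 1] - mesh.nodes[n0, 1]) < 1e-12]
    fixed[3 * same_y[0] + 1] = True
    system = dataclasses.replace(system, fixed=fixed)
    faces, _ = boundary_faces(mesh.elements)
    top = np.array([f for f in faces if np.allclose(mesh.nodes[f, 2], 20.0)])
    f = surface_traction_load(mesh, top, [0, 0, sigma])
    return mesh, system, f, e_mod, sigma


class TestAssembly:
    def test_symmetry(self, box):
        _, system = box
        d = system.K - system.K.T
        assert abs(d).max() < 1e-8 * abs(system.K).max()

    def test_rigid_modes_are_null_vectors(self, box):
        mesh, system = box
        kmax = abs(system.K).max()
        for axis in range(3):
            t = np.zeros(3 * mesh.n_nodes)
            t[axis::3] = 1.0
            assert np.abs(system.K @ t).max() < 1e-8 * kmax
        c = mesh.nodes.mean(axis=0)
        for axis in np.eye(3):
            rot = np.cross(np.broadcast_to(axis, (mesh.n_nodes, 3)),
                           mesh.nodes - c).ravel()
            assert np.abs(system.K @ rot).max() < 1e-8 * kmax * np.abs(rot).max()

    def test_single_element_energy_matches_exact_integral(self, rng):
        """u^T K u for one 10-node tet equals the exact strain energy of the
        interpolated quadratic displacement field, computed independently via
        closed-form barycentric monomial integrals."""
        corners = np.array([[0.0, 0, 0], [9.0, 1, 0], [2.0, 8, 1], [1.0, 2, 7]])
        mids = np.array([(corners[a] + corners[b]) / 2
                         for a, b in ((0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3))])
        nodes = np.vstack([corners, mids])
        elem = np.arange(10, dtype=np.int64)[None]
        mesh = BoneMesh(nodes, elem, np.array([0], np.int8))
        mat = OrthotropicMaterial.cortical()
        system = assemble(mesh, {0: mat})

        # quadratic displacement field u_i(x) = a_i + B_i.x + x^T C_i x
        a = rng.normal(size=3)
        B = rng.normal(size=(3, 3))
        C = rng.normal(size=(3, 3, 3))
        C = 0.5 * (C + np.swapaxes(C, 1, 2))

        def u_field(x):
            return a + B @ x + np.einsum("ijk,j,k->i", C, x, x)

        def grad_u(x):
            return B + 2 * np.einsum("ijk,k->ij", C, x)

        u_nodal = np.array([u_field(p) for p in nodes]).ravel()
        fe_energy = 0.5 * u_nodal @ (system.K @ u_nodal)

        # exact energy: eps(x) linear in x -> energy integrand quadratic;
        # integrate with int L_a = V/4, int L_a L_b = V(1+delta)/20
        d = mat.stiffness()

        def voigt(g):
            e = 0.5 * (g + g.T)
            return np.array([e[0, 0], e[1, 1], e[2, 2],
                             2 * e[0, 1], 2 * e[1, 2], 2 * e[2, 0]])

        vol = np.linalg.det(corners[1:] - corners[0]) / 6.0
        # eps(x) = eps0 + sum_k x_k eps_k (Voigt); expand via corners:
        # x = sum_a L_a p_a with the 4 corners
        eps0 = voigt(grad_u(np.zeros(3)) - grad_u(np.zeros(3)) + B)
        eps_lin = [voigt(2 * C[:, :, k]) for k in range(3)]  # d eps/dx_k

        def eps_at(x):
            return eps0 + sum(x[k] * eps_lin[k] for k in range(3))

        e_corner = [eps_at(p) for p in corners]
        exact = 0.0
        for ai in range(4):
            for bi in range(4):
                w = vol * (2.0 if ai == bi else 1.0) / 20.0
                exact += 0.5 * w * (e_corner[ai] @ d @ e_corner[bi])
        assert fe_energy == pytest.approx(exact, rel=1e-9)

    def test_inverted_element_rejected(self):
        mesh = box_mesh(1, 1, 1, 1, 1, 1)
        bad_nodes = mesh.nodes.copy()
        bad_nodes[:, 2] *= -1.0   # mirror -> negative Jacobians
        bad = mesh.with_nodes(bad_nodes)
        with pytest.raises(MeshError, match="inverted"):
            assemble(bad, {0: OrthotropicMaterial.cortical()})


class TestConstraintsAndSprings:
    def test_boundary_conditions_fix_expected_dofs(self, coarse_template):
        mesh, lm = coarse_template
        system = assemble(mesh)
        con = apply_boundary_conditions(system, lm)
        for n in lm.plateau_nodes:
            assert con.fixed[3 * n:3 * n + 3].all()
        m = lm.malleolus_node
        assert con.fixed[3 * m + 1] and not con.fixed[3 * m] and not con.fixed[3 * m + 2]

    def test_empty_plateau_rejected(self, coarse_template):
        mesh, lm = coarse_template
        system = assemble(mesh)
        bad = dataclasses.replace(lm, plateau_nodes=np.array([], dtype=int))
        with pytest.raises(UnconstrainedSystemError):
            apply_boundary_conditions(system, bad)

    def test_constrained_system_positive_definite(self):
        from scipy.sparse.linalg import eigsh
        mesh = box_mesh(2, 2, 3, 5, 5, 9)
        system = assemble(mesh, {0: OrthotropicMaterial.isotropic(1000, 0.3)})
        fixed = np.zeros(system.n_dof, bool)
        base = np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12)
        for n in base:
            fixed[3 * n:3 * n + 3] = True
        con = dataclasses.replace(system, fixed=fixed)
        kff = con.K[~fixed][:, ~fixed]
        lam = eigsh(kff.tocsc(), k=1, sigma=0, return_eigenvectors=False)[0]
        assert lam > 0

    def test_spring_free_body_reaction(self, coarse_template):
        """Stretching one ligament by delta with both ends prescribed gives a
        reaction force k*delta along the pair axis."""
        mesh, lm = coarse_template
        system = assemble(mesh)
        k = 133.0
        name = "proximal_anterior"
        a, b = lm.ligament_pairs[name]
        with_spring = add_ligament_springs(
            system, lm.ligament_pairs,
            {n: (k if n == name else 0.0) for n in DEFAULT_LIGAMENT_STIFFNESS})
        dk = (with_spring.K - system.K).tocsr()
        axis = mesh.nodes[b] - mesh.nodes[a]
        axis /= np.linalg.norm(axis)
        delta = 0.37
        u = np.zeros(system.n_dof)
        u[3 * b:3 * b + 3] = delta * axis          # extend the pair by delta
        reaction = dk @ u
        f_b = reaction[3 * b:3 * b + 3]
        assert np.linalg.norm(f_b) == pytest.approx(k * delta, rel=1e-12)
        assert f_b @ axis == pytest.approx(k * delta, rel=1e-12)
        # energy of a unit relative extension is k/2
        u_unit = np.zeros(system.n_dof)
        u_unit[3 * b:3 * b + 3] = axis
        assert 0.5 * u_unit @ (dk @ u_unit) == pytest.approx(k / 2)

    def test_default_stiffness_map(self):
        assert DEFAULT_LIGAMENT_STIFFNESS == {
            "proximal_anterior": 133.0, "proximal_posterior": 166.0,
            "distal_anterior": 78.0, "distal_posterior": 101.0}

    def test_zero_stiffness_leaves_system_unchanged(self, coarse_template):
        mesh, lm = coarse_template
        system = assemble(mesh)
        zeroed = add_ligament_springs(system, lm.ligament_pairs,
                                      {n: 0.0 for n in DEFAULT_LIGAMENT_STIFFNESS})
        assert zeroed.K is system.K
        assert add_tie_constraints(system, lm.tie_pairs, 0.0).K is system.K


class TestLoadsVector:
    def test_total_force_conserved(self, coarse_template):
        mesh, lm = coarse_template
        system = apply_boundary_conditions(assemble(mesh), lm)
        cov = SubjectCovariates(body_mass=72.0, height=178.0)
        ls = generate_loadset(4, cov)
        f = apply_loads(system, ls, lm)
        total = f.reshape(-1, 3).sum(axis=0)
        assert np.allclose(total, ls.total_force(), atol=1e-9)
        loaded = np.flatnonzero(np.abs(f.reshape(-1, 3)).sum(axis=1) > 0)
        expected_nodes = {lm.ankle_centre_node} | set(lm.muscle_insertions.values())
        assert set(loaded) <= expected_nodes

    def test_zero_loadset_gives_zero_vector(self, coarse_template):
        mesh, lm = coarse_template
        system = apply_boundary_conditions(assemble(mesh), lm)
        ls = per_kg_loadset(3).scaled(0.0)
        assert not apply_loads(system, ls, lm).any()

    def test_missing_muscle_named(self, coarse_template):
        mesh, lm = coarse_template
        system = apply_boundary_conditions(assemble(mesh), lm)
        ls = per_kg_loadset(3)
        del ls.muscle_forces["soleus"]
        with pytest.raises(ValueError, match="soleus"):
            apply_loads(system, ls, lm)


class TestSolve:
    def test_zero_load_zero_solution(self, patch_setup):
        _, system, _, _, _ = patch_setup
        res = solve(system, np.zeros(system.n_dof))
        assert not res.displacements.any()
        assert not res.effective.any()

    def test_uniaxial_patch_exact(self, patch_setup):
        _, system, f, e_mod, sigma = patch_setup
        res = solve(system, f)
        assert np.abs(res.element_strain[:, 2] / (sigma / e_mod) - 1).max() < 1e-10
        assert res.residual < 1e-8

    def test_linearity_of_solutions(self, patch_setup, rng):
        _, system, f, _, _ = patch_setup
        fact = FactorizedSystem(system)
        g = np.zeros_like(f)
        free = np.flatnonzero(~system.fixed)
        g[rng.choice(free, 5, replace=False)] = rng.normal(scale=10, size=5)
        ua = fact.solve(f).displacements
        ub = fact.solve(g).displacements
        uab = fact.solve(f + g).displacements
        assert np.abs(uab - (ua + ub)).max() < 1e-8 * max(1.0, np.abs(uab).max())

    def test_cantilever_matches_beam_theory(self):
        """Slender cantilever (L/d = 20): tip deflection within 5% of
        Euler-Bernoulli P L^3 / 3EI."""
        L, d, e_mod, P = 200.0, 10.0, 1000.0, 1.0
        mesh = box_mesh(2, 2, 40, d, d, L)
        system = assemble(mesh, {0: OrthotropicMaterial.isotropic(e_mod, 0.3)})
        fixed = np.zeros(system.n_dof, bool)
        for n in np.flatnonzero(np.abs(mesh.nodes[:, 2]) < 1e-12):
            fixed[3 * n:3 * n + 3] = True
        system = dataclasses.replace(system, fixed=fixed)
        faces, _ = boundary_faces(mesh.elements)
        tip = np.array([f for f in faces if np.allclose(mesh.nodes[f, 2], L)])
        f = surface_traction_load(mesh, tip, [0, P / d ** 2, 0])
        res = solve(system, f)
        tip_nodes = np.flatnonzero(np.abs(mesh.nodes[:, 2] - L) < 1e-12)
        deflection = res.displacements[tip_nodes, 1].mean()
        euler = P * L ** 3 / (3 * e_mod * (d ** 4 / 12))
        assert deflection == pytest.approx(euler, rel=0.05)

    def test_mass_doubling_doubles_strain(self, coarse_template):
        mesh, lm = coarse_template
        cov1 = SubjectCovariates(body_mass=70.0, height=176.0)
        cov2 = SubjectCovariates(body_mass=140.0, height=176.0)
        r1, = solve_subject(mesh, lm, [generate_loadset(3, cov1)])
        r2, = solve_subject(mesh, lm, [generate_loadset(3, cov2)])
        assert np.abs(r2.effective - 2 * r1.effective).max() < 1e-12 + 1e-8 * r1.effective.max()

    def test_speed_monotone_mean_shaft_strain(self, coarse_template):
        from tibstrain.strainfield import mask_attachments, select_shaft_surface
        mesh, lm = coarse_template
        cov = SubjectCovariates(body_mass=70.0, height=176.0)
        results = solve_subject(mesh, lm, [generate_loadset(s, cov) for s in (3, 4, 5)])
        sel = mask_attachments(select_shaft_surface(mesh), lm, mesh)
        means = [r.effective[sel.element_ids].mean() for r in results]
        assert means[0] <= means[1] <= means[2]


class TestEffectiveStrain:
    def test_hydrostatic_is_zero(self):
        assert effective_strain(np.eye(3) * 0.004) == pytest.approx(0.0, abs=1e-15)

    def test_uniaxial_closed_form(self):
        """diag(e,0,0): deviator diag(2e/3,-e/3,-e/3) gives (2/3)|e|."""
        e = 1.3e-3
        t = np.diag([e, 0.0, 0.0])
        assert effective_strain(t) == pytest.approx(2 * e / 3, rel=1e-12)
        # independent tensor-algebra route
        dev = t - np.trace(t) / 3 * np.eye(3)
        expected = np.sqrt(2 / 3 * np.sum(dev * dev))
        assert effective_strain(t) == pytest.approx(expected, rel=1e-12)

    def test_homogeneity(self, rng):
        t = rng.normal(size=(3, 3)) * 1e-3
        t = 0.5 * (t + t.T)
        for c in (-2.0, 0.5, 3.7):
            assert effective_strain(c * t) == pytest.approx(
                abs(c) * effective_strain(t), rel=1e-12)

    def test_voigt_tensor_consistency(self, rng):
        t = rng.normal(size=(5, 3, 3)) * 1e-3
        t = 0.5 * (t + np.swapaxes(t, 1, 2))
        voigt = np.stack([t[:, 0, 0], t[:, 1, 1], t[:, 2, 2],
                          2 * t[:, 0, 1], 2 * t[:, 1, 2], 2 * t[:, 2, 0]], axis=1)
        assert np.allclose(effective_strain(t), effective_strain_voigt(voigt))

    def test_nonsymmetric_rejected(self):
        bad = np.array([[0.0, 1e-3, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            effective_strain(bad)
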