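"""Element-level verification: patch test, rigid modes, beam oracle."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from fetalkick.fe import elements
from fetalkick.fe.mesh import (FEMesh, Material, _orient_ccw,
                               _structured_quads)
from fetalkick.fe.solver import assemble


def grid_mesh(nx, ny, lx=1.0, ly=1.0, distort=0.0, seed=0):
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel()], axis=1)
    if distort:
        rng = np.random.default_rng(seed)
        interior = ((nodes[:, 0] > 0) & (nodes[:, 0] < lx)
                    & (nodes[:, 1] > 0) & (nodes[:, 1] < ly))
        nodes[interior] += rng.uniform(-distort, distort,
                                       size=(interior.sum(), 2))
    elems = _orient_ccw(nodes, _structured_quads(nx, ny))
    return FEMesh(nodes=nodes, elems=elems,
                  regions=np.array(["m"] * len(elems)))


class TestPatchTest:
    @pytest.mark.parametrize("reduced", [True, False])
    def test_linear_field_reproduced_exactly(self, reduced):
        """Irregular quads under a linear boundary displacement field must
        reproduce the field (hence constant stress) exactly."""
        mesh = grid_mesh(3, 3, distort=0.08, seed=4)
        mat = {"m": Material(2.0e6, 0.3)}
        C = elements.plane_stress_matrix(2.0e6, 0.3)
        ke = elements.linear_stiffness(mesh.nodes[mesh.elems], C, 1.0,
                                       reduced_shear=reduced)
        K = assemble(mesh, mat)  # default element
        A = np.array([[1e-3, 4e-4], [-2e-4, 6e-4]])
        u_exact = (mesh.nodes @ A.T).reshape(-1)

        boundary = ((mesh.nodes[:, 0] < 1e-12) | (mesh.nodes[:, 0] > 1 - 1e-12)
                    | (mesh.nodes[:, 1] < 1e-12) | (mesh.nodes[:, 1] > 1 - 1e-12))
        fixed = np.repeat(boundary, 2)
        free = ~fixed
        u = u_exact.copy()
        Kd = K.toarray()
        u[free] = np.linalg.solve(Kd[np.ix_(free, free)],
                                  -Kd[np.ix_(free, fixed)] @ u_exact[fixed])
        assert np.allclose(u, u_exact, atol=1e-12)

    def test_single_element_rigid_modes(self):
        coords = np.array([[[0.0, 0], [1.1, 0.1], [1.0, 1.2], [-0.1, 0.9]]])
        C = elements.plane_stress_matrix(1e6, 0.25)
        for reduced in (True, False):
            ke = elements.linear_stiffness(coords, C, 1.0, reduced)[0]
            assert np.allclose(ke, ke.T, atol=1e-6 * np.abs(ke).max())
            w = np.linalg.eigvalsh(ke)
            tol = 1e-9 * w[-1]
            assert int(np.sum(np.abs(w) < tol)) == 3

    def test_unconstrained_patch_has_three_rigid_modes(self):
        mesh = grid_mesh(3, 2, distort=0.05, seed=1)
        K = assemble(mesh, {"m": Material(1e6, 0.3)}).toarray()
        w = np.linalg.eigvalsh(K)
        tol = 1e-9 * w[-1]
        assert int(np.sum(np.abs(w) < tol)) == 3


class TestBeamOracle:
    def test_slender_cantilever_tip_deflection(self):
        E, nu = 1e6, 0.0
        L, h, P = 1.0, 0.05, 1.0   # L/h = 20
        exact = P * L**3 / (3 * E * h**3 / 12)
        mesh = grid_mesh(40, 4, lx=L, ly=h)
        K = assemble(mesh, {"m": Material(E, nu)})
        idx = np.arange(41 * 5).reshape(41, 5)
        fixed = np.array([2 * n + d for n in idx[0, :] for d in (0, 1)])
        free = np.setdiff1d(np.arange(2 * mesh.n_nodes), fixed)
        f = np.zeros(2 * mesh.n_nodes)
        f[2 * idx[-1, :] + 1] = P / 5
        u = np.zeros(2 * mesh.n_nodes)
        u[free] = spla.spsolve(K[free][:, free].tocsc(), f[free])
        tip = u[2 * idx[-1, 2] + 1]
        assert abs(tip - exact) / exact <= 0.05

    def test_rotated_beam_matches_axis_aligned(self):
        """The local-frame shear treatment must be orientation-invariant."""
        E, nu = 1e6, 0.3
        L, h, P = 1.0, 0.05, 1.0
        tips = []
        for ang in (0.0, 0.7):
            R = np.array([[np.cos(ang), -np.sin(ang)],
                          [np.sin(ang), np.cos(ang)]])
            mesh = grid_mesh(40, 4, lx=L, ly=h)
            mesh = FEMesh(nodes=mesh.nodes @ R.T, elems=mesh.elems,
                          regions=mesh.regions)
            K = assemble(mesh, {"m": Material(E, nu)})
            idx = np.arange(41 * 5).reshape(41, 5)
            fixed = np.array([2 * n + d for n in idx[0, :] for d in (0, 1)])
            free = np.setdiff1d(np.arange(2 * mesh.n_nodes), fixed)
            load = R @ np.array([0.0, 1.0])
            f = np.zeros(2 * mesh.n_nodes)
            for n in idx[-1, :]:
                f[2 * n : 2 * n + 2] = load * P / 5
            u = np.zeros(2 * mesh.n_nodes)
            u[free] = spla.spsolve(K[free][:, free].tocsc(), f[free])
            tips.append(u[2 * idx[-1, 2] : 2 * idx[-1, 2] + 2] @ load)
        assert tips[1] == pytest.approx(tips[0], rel=1e-9)


class TestTotalLagrangian:
    def test_matches_linear_operator_for_small_strains(self):
        mesh = grid_mesh(3, 3, distort=0.05, seed=2)
        C = elements.plane_stress_matrix(1e6, 0.3)
        coords = mesh.nodes[mesh.elems]
        rng = np.random.default_rng(0)
        u = 1e-8 * rng.standard_normal((mesh.n_nodes, 2))
        fint, _ = elements.internal_forces_tl(coords, u[mesh.elems], C, 1.0)
        ke = elements.linear_stiffness(coords, C, 1.0)
        f_lin = np.einsum("nab,nb->na", ke, u[mesh.elems].reshape(-1, 8))
        assert np.allclose(fint, f_lin, atol=1e-8 * np.abs(f_lin).max() + 1e-20,
                           rtol=1e-4)

    def test_tangent_consistent_with_forces(self):
        """Finite-difference check of the TL tangent stiffness."""
        coords = np.array([[[0.0, 0], [1.0, 0.1], [1.1, 1.0], [0.0, 0.9]]])
        C = elements.plane_stress_matrix(1e6, 0.3)
        rng = np.random.default_rng(3)
        u = 0.05 * rng.standard_normal((1, 4, 2))
        f0, k0 = elements.internal_forces_tl(coords, u, C, 1.0)
        h = 1e-7
        for dof in range(8):
            du = np.zeros((1, 4, 2))
            du.reshape(1, 8)[0, dof] = h
            fp, _ = elements.internal_forces_tl(coords, u + du, C, 1.0)
            fd = (fp - f0)[0] / h
            assert np.allclose(fd, k0[0][:, dof],
                               atol=5e-5 * np.abs(k0).max())

    def test_rigid_rotation_produces_no_force(self):
        coords = np.array([[[0.0, 0], [1.0, 0], [1.0, 1.0], [0.0, 1.0]]])
        ang = 0.4
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        u = coords @ R.T - coords
        C = elements.plane_stress_matrix(1e6, 0.3)
        fint, _ = elements.internal_forces_tl(coords, u, C, 1.0)
        assert np.allclose(fint, 0.0, atol=1e-6)
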