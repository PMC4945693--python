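"""Incremental Newton solver with frictionless node-to-segment penalty contact.

Displacement-driven: the probe control nodes carry a prescribed displacement
ramped in equal increments; contact between the probe tip and the cavity
surface transmits the load into the wall.  Geometric nonlinearity is active
(total-Lagrangian elements); the material is linear elastic, so a solve is
path-independent and forces scale exactly with a global modulus factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ..errors import ConvergenceError
from . import elements
from .mesh import FEMesh, Material


@dataclass
class BoundaryConditions:
    """Fixed dofs and the displacement-driven (control) dofs.

    ``fixed``: list of (node, dof) held at zero.
    ``driven``: (nodes, direction) — every node in ``nodes`` moves rigidly
    along the unit ``direction`` by the ramped target displacement.
    """

    fixed: list = field(default_factory=list)
    driven_nodes: np.ndarray | None = None
    driven_direction: np.ndarray | None = None


@dataclass
class FEModel:
    mesh: FEMesh
    materials: dict                      # region tag -> Material
    bcs: BoundaryConditions
    penalty_stiffness: float | None = None  # N/m per slave node, auto if None

    def constitutive(self) -> np.ndarray:
        """Per-element plane-stress matrices, shape (E, 3, 3)."""
        mats = {tag: elements.plane_stress_matrix(m.elastic_modulus,
                                                  m.poisson_ratio)
                for tag, m in self.materials.items()}
        return np.stack([mats[tag] for tag in self.mesh.regions])

    def default_penalty(self) -> float:
        # softest material's E times depth per mm of penetration, scaled
        # down 100x: penetrations stay ~1% of the indentation while the
        # Newton iteration remains well conditioned
        soft = min(m.elastic_modulus for m in self.materials.values())
        return 0.01 * soft * self.mesh.out_of_plane_thickness / 1e-3


@dataclass
class FESolution:
    """Converged state and per-increment reaction history."""

    displacements: np.ndarray        # (N, 2) metres at final increment
    reactions: np.ndarray            # (N, 2) nodal reaction forces, N
    total_contact_force: float       # N (magnitude of probe contact resultant)
    max_nodal_reaction: float        # N, over the displacement-driven nodes
    history: list                    # dicts per increment
    converged: bool = True


def _contact_forces(mesh: FEMesh, x: np.ndarray, kp: float):
    """Penalty forces and tangent triplets for node-to-segment contact.

    ``x`` is the current (deformed) node position array.  Returns
    (f (ndof,), rows, cols, vals, resultant (2,)) where ``resultant`` is the
    total contact force acting on the slave (probe) side.
    """
    ndof = 2 * len(x)
    f = np.zeros(ndof)
    rows, cols, vals = [], [], []
    resultant = np.zeros(2)
    if mesh.slave_nodes is None or mesh.master_chain is None:
        return f, rows, cols, vals, resultant

    chain = mesh.master_chain
    a_idx, b_idx = chain[:-1], chain[1:]
    xa, xb = x[a_idx], x[b_idx]
    seg = xb - xa
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    # cavity-facing segment normals: perpendicular, signed toward the origin
    perp = np.stack([-seg[:, 1], seg[:, 0]], axis=1)
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    mid = 0.5 * (xa + xb)
    sign = np.sign(np.einsum("ij,ij->i", -mid, perp))
    sign[sign == 0] = 1.0
    normals = perp * sign[:, None]
    # node-averaged normals give a continuous normal field along the chain,
    # avoiding active-set chatter at segment boundaries
    node_normals = np.zeros((len(chain), 2))
    node_normals[:-1] += normals
    node_normals[1:] += normals
    node_normals /= np.linalg.norm(node_normals, axis=1, keepdims=True)

    for s in mesh.slave_nodes:
        xs = x[s]
        d = xs - xa
        t = np.clip(np.einsum("ij,ij->i", d, seg) / seg_len2, 0.0, 1.0)
        proj = xa + t[:, None] * seg
        dist2 = np.einsum("ij,ij->i", (xs - proj), (xs - proj))
        j = int(np.argmin(dist2))
        tj0 = float(t[j])
        n = (1.0 - tj0) * node_normals[j] + tj0 * node_normals[j + 1]
        n = n / np.linalg.norm(n)
        gap = float((xs - proj[j]) @ n)
        if gap >= 0.0:          # slave on the cavity side: no contact
            continue
        tj = float(t[j])
        pen = -gap
        # C1-regularized penalty: quadratic ramp over g0, linear beyond;
        # removes the stiffness kink at activation so Newton converges tightly
        g0 = 2e-6
        if pen < g0:
            fmag = kp * pen * pen / (2.0 * g0)
            keff = kp * pen / g0
        else:
            fmag = kp * (pen - 0.5 * g0)
            keff = kp
        force = fmag * n        # pushes the slave back toward the cavity
        f[2 * s : 2 * s + 2] += force
        f[2 * a_idx[j] : 2 * a_idx[j] + 2] -= (1.0 - tj) * force
        f[2 * b_idx[j] : 2 * b_idx[j] + 2] -= tj * force
        resultant += force

        nodes3 = [s, a_idx[j], b_idx[j]]
        w3 = [1.0, -(1.0 - tj), -tj]
        nn = np.outer(n, n)
        for p, wp in zip(nodes3, w3):
            for q, wq in zip(nodes3, w3):
                block = keff * wp * wq * nn
                for i in range(2):
                    for k in range(2):
                        rows.append(2 * p + i)
                        cols.append(2 * q + k)
                        vals.append(block[i, k])
    return f, rows, cols, vals, resultant


def _assemble_system(model: FEModel, u: np.ndarray, C: np.ndarray):
    """Internal force vector and tangent matrix (sparse) at state ``u``."""
    mesh = model.mesh
    coords = mesh.nodes[mesh.elems]
    disp = u.reshape(-1, 2)[mesh.elems]
    fint_e, ktan_e = elements.internal_forces_tl(
        coords, disp, C, mesh.out_of_plane_thickness
    )
    edof = (2 * mesh.elems[:, :, None] + np.array([0, 1])).reshape(-1, 8)

    fint = np.zeros(2 * mesh.n_nodes)
    np.add.at(fint, edof.ravel(), fint_e.ravel())

    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    return fint, rows, cols, ktan_e.ravel()


def solve(model: FEModel, target_displacement_mm: float, n_increments: int = 10,
          rtol: float = 1e-8, max_iter: int = 50) -> FESolution:
    """Ramp the driven displacement and solve each increment by Newton."""
    mesh = model.mesh
    ndof = 2 * mesh.n_nodes
    C = model.constitutive()
    kp = model.penalty_stiffness or model.default_penalty()

    fixed_dofs = sorted({2 * n + d for n, d in model.bcs.fixed})
    driven = model.bcs.driven_nodes
    direction = model.bcs.driven_direction
    driven_dofs = []
    if driven is not None:
        driven_dofs = [2 * n + d for n in driven for d in (0, 1)]
    presc = np.array(sorted(set(fixed_dofs) | set(driven_dofs)), dtype=int)
    free = np.setdiff1d(np.arange(ndof), presc)

    u = np.zeros(ndof)
    history = []
    target_m = target_displacement_mm * 1e-3
    if target_displacement_mm == 0:
        n_increments = 1

    for inc in range(1, n_increments + 1):
        ramp = target_m * inc / n_increments
        if driven is not None:
            for n in driven:
                u[2 * n : 2 * n + 2] = ramp * direction
        u[fixed_dofs] = 0.0

        resultant = np.zeros(2)
        converged = False
        r_free_norm = np.inf
        history_norms: list[float] = []
        for it in range(max_iter):
            x = mesh.nodes + u.reshape(-1, 2)
            fint, krows, kcols, kvals = _assemble_system(model, u, C)
            fc, crows, ccols, cvals, resultant = _contact_forces(mesh, x, kp)
            r = fint - fc
            r_free = r[free]
            scale = max(np.abs(fint).max(), np.abs(fc).max(), kp * 1e-9)
            r_free_norm = np.linalg.norm(r_free)
            history_norms.append(r_free_norm)
            if r_free_norm <= rtol * scale * max(len(free), 1) ** 0.5:
                converged = True
                break
            K = sp.coo_matrix(
                (np.concatenate([kvals, np.array(cvals)]),
                 (np.concatenate([krows, np.array(crows, dtype=int)]),
                  np.concatenate([kcols, np.array(ccols, dtype=int)]))),
                shape=(ndof, ndof),
            ).tocsr()
            Kff = K[free][:, free]
            du = spla.spsolve(Kff.tocsc(), -r_free)
            # damped step when the iteration stagnates or cycles (contact
            # active-set flicker); otherwise backtracking line search
            stagnant = (len(history_norms) >= 4
                        and history_norms[-1] > 0.7 * history_norms[-4])
            step = 0.5 if stagnant else 1.0
            for _ in range(8):
                u_try = u.copy()
                u_try[free] += step * du
                x_try = mesh.nodes + u_try.reshape(-1, 2)
                fint_t, *_ = _assemble_system(model, u_try, C)
                fc_t, *_rest, _res = _contact_forces(mesh, x_try, kp)
                if np.linalg.norm((fint_t - fc_t)[free]) < r_free_norm or step < 0.02:
                    break
                step *= 0.5
            u[free] += step * du
        if not converged:
            # accept a stagnated iterate that still satisfies the global
            # equilibrium requirement (residual <= 1e-6 relative)
            if r_free_norm <= 1e-6 * scale * max(len(free), 1) ** 0.5:
                converged = True
            else:
                raise ConvergenceError(inc, float(r_free_norm))

        x = mesh.nodes + u.reshape(-1, 2)
        fint, *_ = _assemble_system(model, u, C)
        fc, *_rest, resultant = _contact_forces(mesh, x, kp)
        reactions = (fint - fc).reshape(-1, 2)
        if driven is not None and len(driven):
            max_nodal = float(np.linalg.norm(reactions[driven], axis=1).max())
        else:
            max_nodal = float(np.linalg.norm(reactions, axis=1).max())
        history.append({
            "increment": inc,
            "displacement_mm": ramp * 1e3,
            "total_contact_N": float(np.linalg.norm(resultant)),
            "max_nodal_N": max_nodal,
            "iterations": it + 1,
        })

    reactions = (fint - fc).reshape(-1, 2)
    # zero out reaction entries at genuinely free dofs (numerical residue)
    mask = np.zeros(ndof, bool)
    mask[presc] = True
    reactions_flat = reactions.reshape(-1)
    reactions_flat[~mask] = 0.0
    return FESolution(
        displacements=u.reshape(-1, 2),
        reactions=reactions_flat.reshape(-1, 2),
        total_contact_force=float(np.linalg.norm(resultant)),
        max_nodal_reaction=history[-1]["max_nodal_N"] if history else 0.0,
        history=history,
    )


def assemble(mesh: FEMesh, materials: dict) -> sp.csr_matrix:
    """Global small-strain stiffness matrix (for linear checks and solves)."""
    mats = {tag: elements.plane_stress_matrix(m.elastic_modulus,
                                              m.poisson_ratio)
            for tag, m in materials.items()}
    C = np.stack([mats[tag] for tag in mesh.regions])
    coords = mesh.nodes[mesh.elems]
    det = elements.jacobians(coords)
    if np.any(det <= 0):
        bad = int(np.argwhere(np.any(det <= 0, axis=1))[0, 0])
        raise ValueError(f"inverted element {bad}")
    ke = np.empty((mesh.n_elems, 8, 8))
    # group by region tag so each group shares one constitutive matrix
    for tag in np.unique(mesh.regions):
        sel = mesh.regions == tag
        ke[sel] = elements.linear_stiffness(
            coords[sel], mats[tag], mesh.out_of_plane_thickness
        )
    edof = (2 * mesh.elems[:, :, None] + np.array([0, 1])).reshape(-1, 8)
    rows = np.repeat(edof, 8, axis=1).ravel()
    cols = np.tile(edof, (1, 8)).ravel()
    K = sp.coo_matrix((ke.ravel(), (rows, cols)),
                      shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes))
    return K.tocsr()
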