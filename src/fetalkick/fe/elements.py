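"""Bilinear (4-node) quadrilateral plane-stress elements.

Small-strain operators for linear analyses (patch test, modal checks) and a
total-Lagrangian formulation with Green-Lagrange strain and a St. Venant-
Kirchhoff material for the geometrically nonlinear indentation solves.
Element forces scale with the assumed out-of-plane thickness.

Shear is integrated with selective reduced integration (SRI) by default:
normal strain energy at the 2x2 Gauss points, shear at the centroid,
evaluated in a per-element local frame aligned with the element's first
parametric direction.  SRI suppresses the parasitic shear that makes fully
integrated bilinear quads lock in thin-wall bending, while the 2x2 normal
terms keep full rank (no hourglass modes) and constant-strain states are
integrated exactly (the patch test is unaffected).  The constitutive law is
isotropic, so the material matrix is frame-invariant.

All element routines are vectorized over the element axis: node coordinate
arrays have shape (nelem, 4, 2).
"""

from __future__ import annotations

import numpy as np

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = [(-_G, -_G), (_G, -_G), (_G, _G), (-_G, _G)]

# (xi, eta, weight, Voigt mask)
_SRI_SCHEME = (
    [(xi, eta, 1.0, np.array([1.0, 1.0, 0.0])) for xi, eta in GAUSS_POINTS]
    + [(0.0, 0.0, 4.0, np.array([0.0, 0.0, 1.0]))]
)
_FULL_SCHEME = [(xi, eta, 1.0, np.array([1.0, 1.0, 1.0]))
                for xi, eta in GAUSS_POINTS]


def plane_stress_matrix(E: float, nu: float) -> np.ndarray:
    """Plane-stress constitutive matrix in Voigt order (xx, yy, xy)."""
    c = E / (1.0 - nu * nu)
    return c * np.array([
        [1.0, nu, 0.0],
        [nu, 1.0, 0.0],
        [0.0, 0.0, 0.5 * (1.0 - nu)],
    ])


def shape_gradients(xi: float, eta: float) -> np.ndarray:
    """dN/d(xi, eta) for the 4 bilinear shape functions, shape (4, 2)."""
    return 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])


def _grad_operators(coords: np.ndarray, xi: float, eta: float):
    """Reference-configuration shape gradients dN/dX and Jacobian dets."""
    dN = shape_gradients(xi, eta)                       # (4, 2)
    J = np.einsum("ai,naj->nij", dN, coords)            # (n, 2, 2)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ /= detJ[:, None, None]
    # J[i, j] = dx_j/dxi_i, so dN/dx_j = dN/dxi_i * (J^-1)[j, i]
    dN_dX = np.einsum("ai,nji->naj", dN, invJ)          # (n, 4, 2)
    return dN_dX, detJ


def jacobians(coords: np.ndarray) -> np.ndarray:
    """detJ at every Gauss point, shape (nelem, 4)."""
    return np.stack(
        [_grad_operators(coords, xi, eta)[1] for xi, eta in GAUSS_POINTS], axis=1
    )


def _element_frames(coords: np.ndarray) -> np.ndarray:
    """Reference local frame per element: columns are the local axes.

    Local coordinates are x_local = x_global @ E with E orthonormal; the
    first axis follows the element's xi direction at the centroid.
    """
    e1 = coords[:, 1] + coords[:, 2] - coords[:, 0] - coords[:, 3]
    e1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.stack([-e1[:, 1], e1[:, 0]], axis=1)
    return np.stack([e1, e2], axis=2)


def _rotate_back_k(E: np.ndarray, ke: np.ndarray) -> np.ndarray:
    k5 = ke.reshape(-1, 4, 2, 4, 2)
    return np.einsum("nip,napbq,nkq->naibk", E, k5, E).reshape(-1, 8, 8)


def linear_stiffness(coords: np.ndarray, C: np.ndarray, thickness: float,
                     reduced_shear: bool = True) -> np.ndarray:
    """Small-strain element stiffness matrices, shape (nelem, 8, 8)."""
    if reduced_shear:
        E = _element_frames(coords)
        cl = np.einsum("nai,nij->naj", coords, E)
        kl = _linear_core(cl, C, thickness, _SRI_SCHEME)
        return _rotate_back_k(E, kl)
    return _linear_core(coords, C, thickness, _FULL_SCHEME)


def _linear_core(coords, C, thickness, scheme):
    n = coords.shape[0]
    C = np.asarray(C)
    ke = np.zeros((n, 8, 8))
    for xi, eta, w, mask in scheme:
        dN_dX, detJ = _grad_operators(coords, xi, eta)
        B = np.zeros((n, 3, 8))
        B[:, 0, 0::2] = dN_dX[:, :, 0]
        B[:, 1, 1::2] = dN_dX[:, :, 1]
        B[:, 2, 0::2] = dN_dX[:, :, 1]
        B[:, 2, 1::2] = dN_dX[:, :, 0]
        mm = np.outer(mask, mask)
        if C.ndim == 2:
            ke += np.einsum("nia,ij,njb,n->nab", B, C * mm, B, detJ) \
                * (w * thickness)
        else:
            ke += np.einsum("nia,nij,njb,n->nab", B, C * mm[None], B, detJ) \
                * (w * thickness)
    return ke


def internal_forces_tl(coords: np.ndarray, disp: np.ndarray, C: np.ndarray,
                       thickness: float, reduced_shear: bool = True):
    """Total-Lagrangian internal forces and tangent stiffness.

    coords, disp: (nelem, 4, 2) reference coordinates and displacements.
    Returns (fint (nelem, 8), ktan (nelem, 8, 8)).  Raises ValueError when
    an element's reference Jacobian is non-positive.
    """
    n = coords.shape[0]
    C = np.asarray(C)
    if C.ndim == 2:
        C = np.broadcast_to(C, (n, 3, 3))
    if reduced_shear:
        E = _element_frames(coords)
        cl = np.einsum("nai,nij->naj", coords, E)
        dl = np.einsum("nai,nij->naj", disp, E)
        fl, kl = _tl_core(cl, dl, C, thickness, _SRI_SCHEME)
        fint = np.einsum("nip,nap->nai", E, fl.reshape(n, 4, 2)).reshape(n, 8)
        return fint, _rotate_back_k(E, kl)
    return _tl_core(coords, disp, C, thickness, _FULL_SCHEME)


def _tl_core(coords, disp, C, thickness, scheme):
    n = coords.shape[0]
    fint = np.zeros((n, 8))
    ktan = np.zeros((n, 8, 8))
    eye = np.eye(2)
    for xi, eta, gw, mask in scheme:
        dN_dX, detJ = _grad_operators(coords, xi, eta)
        if np.any(detJ <= 0):
            bad = int(np.argmax(detJ <= 0))
            raise ValueError(f"non-positive reference Jacobian in element {bad}")
        w = detJ * thickness * gw

        G = np.einsum("nai,naj->nij", disp, dN_dX)       # grad u
        F = eye[None] + G                                # deformation gradient
        Egl = 0.5 * (np.einsum("nki,nkj->nij", F, F) - eye[None])
        Evec = np.stack([Egl[:, 0, 0], Egl[:, 1, 1], 2.0 * Egl[:, 0, 1]], axis=1)
        Cm = C * np.outer(mask, mask)[None]
        Svec = np.einsum("nij,nj->ni", Cm, Evec)         # PK2 stress (Voigt)

        # nonlinear strain-displacement operator B_L (n, 3, 8)
        BL = np.zeros((n, 3, 8))
        BL[:, 0, 0::2] = F[:, 0, 0, None] * dN_dX[:, :, 0]
        BL[:, 0, 1::2] = F[:, 1, 0, None] * dN_dX[:, :, 0]
        BL[:, 1, 0::2] = F[:, 0, 1, None] * dN_dX[:, :, 1]
        BL[:, 1, 1::2] = F[:, 1, 1, None] * dN_dX[:, :, 1]
        BL[:, 2, 0::2] = (F[:, 0, 0, None] * dN_dX[:, :, 1]
                          + F[:, 0, 1, None] * dN_dX[:, :, 0])
        BL[:, 2, 1::2] = (F[:, 1, 0, None] * dN_dX[:, :, 1]
                          + F[:, 1, 1, None] * dN_dX[:, :, 0])

        fint += np.einsum("nia,ni,n->na", BL, Svec, w)
        kmat = np.einsum("nia,nij,njb,n->nab", BL, Cm, BL, w)

        # geometric stiffness: (dN_a . S . dN_b) I2
        S = np.empty((n, 2, 2))
        S[:, 0, 0] = Svec[:, 0]
        S[:, 1, 1] = Svec[:, 1]
        S[:, 0, 1] = S[:, 1, 0] = Svec[:, 2]
        g = np.einsum("nai,nij,nbj,n->nab", dN_dX, S, dN_dX, w)  # (n, 4, 4)
        kgeo = np.zeros((n, 8, 8))
        kgeo[:, 0::2, 0::2] = g
        kgeo[:, 1::2, 1::2] = g
        ktan += kmat + kgeo
    return fint, ktan
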