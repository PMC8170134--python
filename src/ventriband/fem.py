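"""Low-level total-Lagrangian finite-element kernels (trilinear hexahedra).

Everything here is vectorized over elements and Gauss points; the arrays
follow the shapes

    coords, u_e : (ne, 8, 3)      element node coordinates / displacements
    dNdX        : (ne, 8, 8, 3)   reference shape-function gradients per GP
    detJ        : (ne, 8)         reference Jacobian determinants per GP

with the 2x2x2 Gauss rule (unit weights).  Degenerate (wedge-collapsed)
hexahedra are admitted as long as the Jacobian stays positive at the Gauss
points, which is how the crescent RV free wall closes onto the septum.
"""

from __future__ import annotations

import numpy as np

from .materials import material_tangent_batch, pk2_stress_batch

_G = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [(x, y, z) for z in (-_G, _G) for y in (-_G, _G) for x in (-_G, _G)]
)

# VTK_HEXAHEDRON node order: bottom quad CCW then top quad CCW
_CORNERS = np.array(
    [
        (-1, -1, -1),
        (1, -1, -1),
        (1, 1, -1),
        (-1, 1, -1),
        (-1, -1, 1),
        (1, -1, 1),
        (1, 1, 1),
        (-1, 1, 1),
    ],
    dtype=float,
)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) at points xi of shape (m, 3)."""
    xi = np.atleast_2d(xi)
    return 0.125 * np.prod(1.0 + xi[:, None, :] * _CORNERS[None, :, :], axis=2)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi at points xi -> shape (m, 8, 3)."""
    xi = np.atleast_2d(xi)
    m = xi.shape[0]
    grads = np.empty((m, 8, 3))
    for d in range(3):
        terms = 1.0 + xi[:, None, :] * _CORNERS[None, :, :]
        terms[:, :, d] = _CORNERS[None, :, d]
        grads[:, :, d] = 0.125 * np.prod(terms, axis=2)
    return grads


_DN_GAUSS = shape_gradients(GAUSS_POINTS)  # (8 gp, 8 nodes, 3)


def reference_gradients(coords: np.ndarray):
    """Reference-configuration gradients and Jacobians at the Gauss points.

    Returns ``dNdX`` of shape (ne, ngp, 8, 3) and ``detJ`` (ne, ngp).
    Raises ValueError if any Gauss-point Jacobian is non-positive.
    """
    # J[e,g,i,j] = d x_i / d xi_j = sum_a coords[e,a,i] dN[g,a,j]
    J = np.einsum("eai,gaj->egij", coords, _DN_GAUSS)
    detJ = np.linalg.det(J)
    if np.any(detJ <= 0):
        bad = int(np.argwhere(detJ <= 0)[0][0])
        raise ValueError(f"non-positive Jacobian in element {bad}")
    Jinv = np.linalg.inv(J)
    dNdX = np.einsum("gaj,egji->egai", _DN_GAUSS, Jinv)
    return dNdX, detJ


def scaled_jacobians(coords: np.ndarray) -> np.ndarray:
    """Per-element minimum scaled Jacobian (Gauss-point based quality)."""
    J = np.einsum("eai,gaj->egij", coords, _DN_GAUSS)
    detJ = np.linalg.det(J)
    norms = np.linalg.norm(J, axis=2)  # column norms (e, g, 3)
    scale = np.prod(norms, axis=-1)
    return np.min(detJ / np.maximum(scale, 1e-300), axis=1)


def element_volumes(coords: np.ndarray) -> np.ndarray:
    J = np.einsum("eai,gaj->egij", coords, _DN_GAUSS)
    return np.linalg.det(J).sum(axis=1)


class HexBlock:
    """Assembled quantities for one homogeneous-treatment block of hexes.

    Parameters are per-element arrays of the six material constants plus the
    bulk penalty; fibers are per-element unit vectors (reference config).
    """

    def __init__(self, nodes: np.ndarray, elements: np.ndarray):
        self.elements = np.asarray(elements, dtype=np.int64)
        coords = nodes[self.elements]
        self.dNdX, self.detJ = reference_gradients(coords)
        self.V0 = self.detJ.sum(axis=1)  # reference element volumes
        self.ne = self.elements.shape[0]

    def deformation(self, u: np.ndarray):
        """F at every Gauss point from the global displacement array (n, 3)."""
        u_e = u[self.elements]  # (ne, 8, 3)
        F = np.einsum("eai,egaJ->egiJ", u_e, self.dNdX)
        F += np.eye(3)
        return F

    def stress_state(self, u, mats, fibers, kappa):
        """F, C, S and the mean-dilatation penalty pressure at Gauss points.

        The volumetric penalty acts on the element-averaged Jacobian
        (mean dilatation): p_vol = kappa (Jbar - 1) with
        Jbar = int J dV0 / V0, which keeps trilinear hexahedra from
        volumetric locking under near-incompressibility.
        """
        F = self.deformation(u)
        C = np.einsum("egki,egkj->egij", F, F)
        J = np.linalg.det(F)
        Jbar = (self.detJ * J).sum(axis=1) / self.V0
        pvol = (kappa * (Jbar - 1.0))[:, None]
        nf = np.broadcast_to(fibers[:, None, :], (self.ne, 8, 3))
        S = pk2_stress_batch(
            C,
            nf,
            mats["c1"][:, None],
            mats["c2"][:, None],
            mats["D1"][:, None],
            mats["D2"][:, None],
            mats["K1"][:, None],
            mats["K2"][:, None],
            kappa[:, None],
            pvol=pvol,
        )
        return F, C, S, pvol

    def internal_force(self, u, mats, fibers, kappa):
        F, _, S, _ = self.stress_state(u, mats, fibers, kappa)
        P = np.einsum("egiM,egMJ->egiJ", F, S)
        f_e = np.einsum("eg,egaJ,egiJ->eai", self.detJ, self.dNdX, P)
        return f_e

    def force_and_stiffness(self, u, mats, fibers, kappa):
        """Element internal forces (ne,8,3) and consistent tangents (ne,24,24)."""
        F, C, S, pvol = self.stress_state(u, mats, fibers, kappa)
        P = np.einsum("egiM,egMJ->egiJ", F, S)
        f_e = np.einsum("eg,egaJ,egiJ->eai", self.detJ, self.dNdX, P)

        nf = np.broadcast_to(fibers[:, None, :], (self.ne, 8, 3))
        D = material_tangent_batch(
            C,
            nf,
            mats["c1"][:, None],
            mats["c2"][:, None],
            mats["D1"][:, None],
            mats["D2"][:, None],
            mats["K1"][:, None],
            mats["K2"][:, None],
            kappa[:, None],
            S0=S,
            pvol=pvol,
        )
        # dP_iJ/dF_kL = delta_ik S_JL + 2 F_iM F_kP D_MJPL  (p_vol held fixed)
        A = 2.0 * np.einsum("egiM,egkP,egMJPL->egiJkL", F, F, D, optimize=self._pathA(F, D))
        A += np.einsum("ik,egJL->egiJkL", np.eye(3), S)
        wdN = self.dNdX * self.detJ[:, :, None, None]
        K = np.einsum(
            "egaJ,egiJkL,egbL->eaibk", wdN, A, self.dNdX, optimize=self._pathK(wdN, A)
        ).reshape(self.ne, 24, 24)
        # rank-one mean-dilatation coupling: K += kappa V0 g g^T with
        # g = dJbar/du = (1/V0) sum_g w detJ0 J F^{-T} dN
        J = np.linalg.det(F)
        FinvT = np.linalg.inv(F).transpose(0, 1, 3, 2)
        g = np.einsum(
            "eg,egiJ,egaJ->eai", self.detJ * J, FinvT, self.dNdX
        ) / self.V0[:, None, None]
        g = g.reshape(self.ne, 24)
        K += (kappa * self.V0)[:, None, None] * g[:, :, None] * g[:, None, :]
        return f_e, K

    def _pathA(self, F, D):
        if not hasattr(self, "_cached_pathA"):
            self._cached_pathA = np.einsum_path(
                "egiM,egkP,egMJPL->egiJkL", F, F, D, optimize="optimal"
            )[0]
        return self._cached_pathA

    def _pathK(self, wdN, A):
        if not hasattr(self, "_cached_pathK"):
            self._cached_pathK = np.einsum_path(
                "egaJ,egiJkL,egbL->eaibk", wdN, A, self.dNdX, optimize="optimal"
            )[0]
        return self._cached_pathK

    def gauss_cauchy(self, u, mats, fibers, kappa):
        """Cauchy stress and Green-Lagrange strain tensors at Gauss points."""
        F, C, S, _ = self.stress_state(u, mats, fibers, kappa)
        J = np.linalg.det(F)
        sig = np.einsum("egiM,egMN,egjN->egij", F, S, F) / J[..., None, None]
        E = 0.5 * (C - np.eye(3))
        return sig, E


def pressure_forces(nodes_def: np.ndarray, quads: np.ndarray, p: float):
    """Follower pressure load on quad faces of the deformed surface.

    ``quads`` are (m, 4) node indices oriented so the right-hand normal
    points out of the pressurized cavity (into the wall); a positive ``p``
    therefore inflates the cavity.  Returns (node_ids, forces) with one row
    per face corner (caller scatters with np.add.at).
    """
    x = nodes_def[quads]  # (m, 4, 3)
    # split each quad into two triangles sharing the diagonal 0-2
    f_nodes = np.zeros_like(x)
    for tri in ((0, 1, 2), (0, 2, 3)):
        a, b, c = (x[:, i, :] for i in tri)
        n2 = 0.5 * np.cross(b - a, c - a)  # area-weighted normal
        for i in tri:
            f_nodes[:, i, :] += (p / 3.0) * n2
    return quads.reshape(-1), f_nodes.reshape(-1, 3)


def _cross_matrices(v: np.ndarray) -> np.ndarray:
    """[v]_x for a batch of vectors: (m, 3) -> (m, 3, 3)."""
    m = np.zeros(v.shape[:-1] + (3, 3))
    m[..., 0, 1] = -v[..., 2]
    m[..., 0, 2] = v[..., 1]
    m[..., 1, 0] = v[..., 2]
    m[..., 1, 2] = -v[..., 0]
    m[..., 2, 0] = -v[..., 1]
    m[..., 2, 1] = v[..., 0]
    return m


def pressure_load_stiffness(nodes_def: np.ndarray, quads: np.ndarray, p: float):
    """d f_ext / d u of the follower pressure load (unsymmetric).

    Returns COO triplets (rows, cols, vals); the caller subtracts them from
    the tangent.  For each triangle with vertices (a, b, c) the area normal
    n2 = (b - a) x (c - a) / 2 has derivatives [c-b]_x/2, [a-c]_x/2 and
    [b-a]_x/2 w.r.t. a, b, c, identical for all three receiving nodes.
    """
    x = nodes_def[quads]
    rows, cols, vals = [], [], []
    for tri in ((0, 1, 2), (0, 2, 3)):
        ia, ib, ic = tri
        a, b, c = (x[:, i, :] for i in tri)
        dn = {
            ia: 0.5 * _cross_matrices(c - b),
            ib: 0.5 * _cross_matrices(a - c),
            ic: 0.5 * _cross_matrices(b - a),
        }
        for i in tri:  # receiving node
            for j in tri:  # moving node
                blk = (p / 3.0) * dn[j]  # (m, 3, 3)
                ri = (3 * quads[:, i])[:, None, None] + np.arange(3)[None, :, None]
                cj = (3 * quads[:, j])[:, None, None] + np.arange(3)[None, None, :]
                rows.append(np.broadcast_to(ri, blk.shape).reshape(-1))
                cols.append(np.broadcast_to(cj, blk.shape).reshape(-1))
                vals.append(blk.reshape(-1))
    return np.concatenate(rows), np.concatenate(cols), np.concatenate(vals)


def surface_volume(nodes_def: np.ndarray, tris: np.ndarray) -> float:
    """Signed volume enclosed by an outward-oriented closed triangle surface."""
    a = nodes_def[tris[:, 0]]
    b = nodes_def[tris[:, 1]]
    c = nodes_def[tris[:, 2]]
    return float(np.einsum("ij,ij->", a, np.cross(b, c))) / 6.0
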