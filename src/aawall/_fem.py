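"""Vectorized P1 (linear triangle) finite-element kernels.

Minimal assembly routines on raw (coords, tris) arrays; everything returns
scipy CSR matrices or dense vectors.  Element quantities are exact for
piecewise-linear fields: with P1 displacement the deformation gradient is
constant per element, so one-point and three-point triangle quadrature
coincide for all the integrands assembled here (coefficients entering as
element means of affine fields).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = [
    "tri_geometry",
    "element_areas",
    "element_gradients_of",
    "mass_matrix",
    "stiffness_matrix",
    "scaled_mass_matrix",
    "edge_lengths",
    "edge_mass_matrix",
    "edge_load_vector",
]


def tri_geometry(coords: np.ndarray, tris: np.ndarray):
    """Signed areas (E,) and P1 basis gradients (E, 3, 2) per element."""
    p = coords[tris]                      # (E, 3, 2)
    v1 = p[:, 1] - p[:, 0]
    v2 = p[:, 2] - p[:, 0]
    area2 = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]   # 2 * signed area
    grads = np.empty((tris.shape[0], 3, 2))
    # grad phi_a = perp(edge opposite a) / (2 A), with perp (y, -x) sign
    for a in range(3):
        b, c = (a + 1) % 3, (a + 2) % 3
        grads[:, a, 0] = p[:, b, 1] - p[:, c, 1]
        grads[:, a, 1] = p[:, c, 0] - p[:, b, 0]
    grads /= area2[:, None, None]
    return 0.5 * area2, grads


def element_areas(coords, tris):
    return tri_geometry(coords, tris)[0]


def element_gradients_of(coords, tris, u_nodal):
    """Constant per-element gradient of a P1 field, shape (E, 2)."""
    _, grads = tri_geometry(coords, tris)
    return np.einsum("ea,eak->ek", u_nodal[tris], grads)


def _assemble_tri(tris, local, n):
    """Scatter (E, 3, 3) local matrices into an (n, n) CSR matrix."""
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


_M_LOC = (np.ones((3, 3)) + np.eye(3)) / 12.0


def mass_matrix(coords, tris, n=None):
    n = coords.shape[0] if n is None else n
    areas = element_areas(coords, tris)
    local = areas[:, None, None] * _M_LOC
    return _assemble_tri(tris, local, n)


def scaled_mass_matrix(coords, tris, coeff_e, n=None):
    """Mass matrix weighted by an elementwise-constant coefficient."""
    n = coords.shape[0] if n is None else n
    areas = element_areas(coords, tris)
    local = (areas * np.asarray(coeff_e))[:, None, None] * _M_LOC
    return _assemble_tri(tris, local, n)


def stiffness_matrix(coords, tris, coeff_e=None, n=None):
    n = coords.shape[0] if n is None else n
    areas, grads = tri_geometry(coords, tris)
    w = areas if coeff_e is None else areas * np.asarray(coeff_e)
    local = np.einsum("e,eak,ebk->eab", w, grads, grads)
    return _assemble_tri(tris, local, n)


def edge_lengths(coords, edges):
    d = coords[edges[:, 1]] - coords[edges[:, 0]]
    return np.hypot(d[:, 0], d[:, 1])


_E_LOC = np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0


def edge_mass_matrix(coords, edges, coeff=1.0, n=None, col_edges=None, ncols=None):
    """Boundary mass matrix sum_edges coeff * L * [[2,1],[1,2]]/6.

    ``coeff`` may be scalar or per-edge.  With ``col_edges`` the columns use
    a second edge list (same geometry, different numbering), producing the
    rectangular interface-coupling block between two one-sided fields.
    """
    n = coords.shape[0] if n is None else n
    L = edge_lengths(coords, edges) * np.asarray(coeff)
    local = L[:, None, None] * _E_LOC
    ce = edges if col_edges is None else col_edges
    nc = n if ncols is None else ncols
    rows = np.repeat(edges, 2, axis=1).ravel()
    cols = np.tile(ce, (1, 2)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, nc)).tocsr()


def edge_load_vector(coords, edges, coeff=1.0, n=None):
    """Boundary load sum_edges coeff * L/2 at each edge endpoint."""
    n = coords.shape[0] if n is None else n
    L = edge_lengths(coords, edges) * np.asarray(coeff)
    out = np.zeros(n)
    np.add.at(out, edges[:, 0], 0.5 * L)
    np.add.at(out, edges[:, 1], 0.5 * L)
    return out
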