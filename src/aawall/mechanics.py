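"""Hyperelastic wall mechanics.

Energy density W = beta1 (I_B - 3) + beta2 (I_B - 3)^2 with moduli that
degrade affinely with smooth-muscle-cell loss, Cauchy stress
sigma = -p(rho) I + (2 beta1 + 4 beta2 (I_B - 3)) B, and the total-Lagrangian
equilibrium residual on the reference mesh, including the blood-pressure
follower load on Gamma_B and surface tension on Gamma_B and Gamma_M.

2D convention: the section is treated in plane strain with unit out-of-plane
stretch, so I_B = tr(B_2d) + 1 and the (I_B - 3) terms vanish in the
undeformed state.

The residual is assembled variationally from the potential
Pi(u) = int [ W(I_B) - p (J - 1) ] dOmega_ref (p frozen from the previous
step), giving the first Piola stress P = -p J F^{-T} + c F with
c = 2 beta1 + 4 beta2 (I_B - 3), using dW/dF = c F and the identity
B F^{-T} = F.  This coincides with the Piola transform of the pointwise
Cauchy law up to the nearly-incompressible factor J on the elastic part;
the exact tangent is assembled analytically.  A config switch reproduces
the halved elastic coefficient (c = beta1 + 2 beta2 (I_B - 3)) that some
write-ups use for the pulled-back stress.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import tri_geometry
from .params import MechanicalParams

__all__ = [
    "MechanicsError",
    "DeformationState",
    "elastic_moduli",
    "ecm_pressure",
    "deformation_state",
    "cauchy_stress",
    "strain_energy_density",
    "first_piola",
    "piola_tangent",
    "surface_tension_term",
    "surface_tension_tangent",
    "pressure_load",
    "edge_orientation_signs",
    "assemble_residual",
    "solve_equilibrium",
]


class MechanicsError(RuntimeError):
    """Constitutive or solver failure (non-positive modulus, inversion,
    Newton breakdown)."""


def elastic_moduli(S, mech: MechanicalParams):
    """(beta1, beta2) in N/cm^2 from the SMC density via the affine law
    beta_i = beta_i0 + k_i (S/S0 - 1).  Aborts if either modulus is
    non-positive anywhere (the constitutive model leaves its validity
    range there)."""
    S = np.asarray(S, dtype=float)
    rel = S / mech.S_0 - 1.0
    b1 = mech.beta_10 + mech.k_1 * rel
    b2 = mech.beta_20 + mech.k_2 * rel
    if np.any(b1 <= 0) or np.any(b2 <= 0):
        bad = float(np.min(S))
        raise MechanicsError(
            f"elastic modulus non-positive at S = {bad:.4g} g/cm^3 "
            f"(S/S0 = {bad / mech.S_0:.4f})"
        )
    return b1, b2


def ecm_pressure(rho, mech: MechanicalParams):
    """Hydrostatic pressure p(rho) = p* - beta_p (1 - rho/rho*), N/cm^2."""
    rho = np.asarray(rho, dtype=float)
    return mech.p_star - mech.beta_p * (1.0 - rho / mech.rho_star)


@dataclass
class DeformationState:
    """Per-point kinematics: F = I + grad u, B = F F^T, J = det F,
    I_B = tr(B) + 1 (plane-strain augmentation)."""

    F: np.ndarray
    B: np.ndarray
    J: np.ndarray
    I_B: np.ndarray


def deformation_state(grad_u) -> DeformationState:
    g = np.asarray(grad_u, dtype=float)
    F = g + np.eye(2)
    B = F @ np.swapaxes(F, -1, -2)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    I_B = B[..., 0, 0] + B[..., 1, 1] + 1.0
    return DeformationState(F=F, B=B, J=np.asarray(J), I_B=np.asarray(I_B))


def _stress_coefficient(I_B, beta1, beta2, full=True):
    c = 2.0 * beta1 + 4.0 * beta2 * (I_B - 3.0)
    return c if full else 0.5 * c


def cauchy_stress(defstate: DeformationState, p, beta1, beta2, full=True):
    """sigma = -p I + (2 b1 + 4 b2 (I_B - 3)) B; symmetric by construction."""
    if np.any(defstate.J <= 0):
        raise MechanicsError("inverted element (J <= 0)")
    c = _stress_coefficient(defstate.I_B, beta1, beta2, full)
    return -np.asarray(p)[..., None, None] * np.eye(2) \
        + np.asarray(c)[..., None, None] * defstate.B


def strain_energy_density(defstate: DeformationState, beta1, beta2):
    x = defstate.I_B - 3.0
    return beta1 * x + beta2 * x * x


def first_piola(F, p, beta1, beta2, full=True):
    """P = dW/dF - p dJ/dF = -p J F^{-T} + c F, vectorized (..., 2, 2)."""
    F = np.asarray(F, dtype=float)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        raise MechanicsError("inverted element (J <= 0)")
    trB = np.einsum("...ij,...ij->...", F, F)
    c = _stress_coefficient(trB + 1.0, beta1, beta2, full)
    Finv = np.linalg.inv(F)
    FinvT = np.swapaxes(Finv, -1, -2)
    return (-np.asarray(p) * J)[..., None, None] * FinvT \
        + np.asarray(c)[..., None, None] * F


def piola_tangent(F, p, beta1, beta2, full=True):
    """Exact material tangent A_ijkl = dP_ij/dF_kl, shape (..., 2,2,2,2)."""
    F = np.asarray(F, dtype=float)
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    trB = np.einsum("...ij,...ij->...", F, F)
    s = 1.0 if full else 0.5
    c = s * (2.0 * np.asarray(beta1) + 4.0 * np.asarray(beta2) * (trB - 2.0))
    Fi = np.linalg.inv(F)
    p = np.asarray(p)
    b2 = np.asarray(beta2)
    eye = np.eye(2)
    A = -(p * J)[..., None, None, None, None] * (
        np.einsum("...lk,...ji->...ijkl", Fi, Fi)
        - np.einsum("...jk,...li->...ijkl", Fi, Fi)
    )
    A += (8.0 * s * b2 * np.ones_like(J))[..., None, None, None, None] * np.einsum(
        "...kl,...ij->...ijkl", F, F
    )
    A += c[..., None, None, None, None] * np.einsum("ik,jl->ijkl", eye, eye)
    return A


# ---------------------------------------------------------------------------
# boundary terms
# ---------------------------------------------------------------------------

def edge_orientation_signs(coords, tris, edges):
    """+1/-1 per edge so that sign * (e_y, -e_x) is the outward normal.

    Outwardness is judged against the adjacent triangle's centroid on the
    reference configuration (orientation is topological, so it is computed
    once)."""
    edge_map = {}
    cent = coords[tris].mean(axis=1)
    for t, tri in enumerate(tris):
        for a in range(3):
            key = tuple(sorted((tri[a], tri[(a + 1) % 3])))
            edge_map[key] = t
    signs = np.empty(len(edges))
    for k, (a, b) in enumerate(edges):
        t = edge_map[tuple(sorted((a, b)))]
        e = coords[b] - coords[a]
        nvec = np.array([e[1], -e[0]])
        mid = 0.5 * (coords[a] + coords[b])
        signs[k] = 1.0 if nvec @ (mid - cent[t]) > 0 else -1.0
    return signs


def pressure_load(current, edges, signs, p_B):
    """Consistent follower load of the blood traction sigma_B = -p_B I.

    Returns (residual contribution (N,2), list of (node pair, 2x2 tangent
    blocks)); the load is linear in the current positions, so the tangent
    is exact and constant."""
    n = current.shape[0]
    r = np.zeros((n, 2))
    e = current[edges[:, 1]] - current[edges[:, 0]]
    nvecL = signs[:, None] * np.stack([e[:, 1], -e[:, 0]], axis=1)  # n * L
    # residual -= <t, w> with t = -p_B n  =>  += p_B/2 * n L per endpoint
    contrib = 0.5 * p_B * nvecL
    np.add.at(r, edges[:, 0], contrib)
    np.add.at(r, edges[:, 1], contrib)
    return r


def pressure_load_tangent_blocks(edges, signs, p_B):
    """Per-edge 2x2 blocks dR/dx for the follower pressure load."""
    R90 = np.array([[0.0, 1.0], [-1.0, 0.0]])
    return [0.5 * p_B * s * R90 for s in signs]


def surface_tension_term(current, edges, gamma, n=None):
    """Variation of the surface energy gamma * |Gamma(t)|.

    This is the exact discrete form of the Lagrangian pull-back of the
    curvature traction <gamma kappa n, w>: for piecewise-linear boundaries
    the pulled-back integrand (the surface divergence of the test field)
    integrates per edge to the gradient of the current edge length.  At
    u = 0 it reduces to the Eulerian tangential-divergence form on the
    reference curve."""
    n = current.shape[0] if n is None else n
    d = current[edges[:, 1]] - current[edges[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    if np.any(L == 0):
        raise MechanicsError("degenerate (zero-length) boundary edge")
    t = d / L[:, None]
    r = np.zeros((n, 2))
    np.add.at(r, edges[:, 0], -gamma * t)
    np.add.at(r, edges[:, 1], gamma * t)
    return r


def surface_tension_tangent(current, edges, gamma):
    """Per-edge 2x2 blocks gamma/L (I - t t^T) of the length Hessian."""
    d = current[edges[:, 1]] - current[edges[:, 0]]
    L = np.hypot(d[:, 0], d[:, 1])
    t = d / L[:, None]
    eye = np.eye(2)
    return [(gamma / L[k]) * (eye - np.outer(t[k], t[k])) for k in range(len(edges))]


# ---------------------------------------------------------------------------
# global residual / tangent and Newton solve
# ---------------------------------------------------------------------------

@dataclass
class BoundaryLoads:
    """Boundary data for the equilibrium solve (merged-mesh numbering)."""

    pressure_edges: np.ndarray | None = None
    pressure_signs: np.ndarray | None = None
    p_B: float = 0.0
    tension_groups: tuple = ()        # iterable of (edges, gamma)


def assemble_residual(ref_coords, tris, u, beta1_e, beta2_e, p_e,
                      loads: BoundaryLoads | None = None,
                      body_force=None, full=True,
                      _geo_cache=None):
    """Residual vector R(u) of the Lagrangian equilibrium weak form.

    R.w = (J sigma F^-T, grad_ref w) - <blood traction, w> + surface
    tension - (f, w).  ``u`` is (N,2) total displacement on reference
    nodes; coefficients are per element.  Raises on inverted elements."""
    areas, grads = tri_geometry(ref_coords, tris) if _geo_cache is None else _geo_cache
    gu = np.einsum("eak,eai->eik", grads, u[tris])
    F = gu + np.eye(2)
    P = first_piola(F, p_e, beta1_e, beta2_e, full)
    relem = np.einsum("e,eik,eak->eai", areas, P, grads)
    r = np.zeros_like(u)
    np.add.at(r, tris.ravel(), relem.reshape(-1, 2))

    current = ref_coords + u
    if loads is not None:
        if loads.pressure_edges is not None and loads.p_B != 0.0:
            r += pressure_load(current, loads.pressure_edges,
                               loads.pressure_signs, loads.p_B)
        for edges, gamma in loads.tension_groups:
            if gamma != 0.0:
                r += surface_tension_term(current, edges, gamma, n=len(r))
    if body_force is not None:
        cent = ref_coords[tris].mean(axis=1)
        f = np.asarray(body_force(cent))          # (E, 2)
        w = (areas / 3.0)[:, None] * f
        fe = np.repeat(w[:, None, :], 3, axis=1)
        np.add.at(r, tris.ravel(), -fe.reshape(-1, 2))
    return r


def _assemble_tangent(ref_coords, tris, u, beta1_e, beta2_e, p_e,
                      loads, full, geo):
    areas, grads = geo
    n = ref_coords.shape[0]
    gu = np.einsum("eak,eai->eik", grads, u[tris])
    F = gu + np.eye(2)
    A = piola_tangent(F, p_e, beta1_e, beta2_e, full)
    k_local = np.einsum("e,eikjl,eak,ebl->eaibj", areas, A, grads, grads)

    dof = (2 * tris[:, :, None] + np.arange(2)[None, None, :]).reshape(-1, 6)
    rows = np.repeat(dof, 6, axis=1).ravel()
    cols = np.tile(dof, (1, 6)).ravel()
    vals = k_local.reshape(-1, 6, 6).ravel()
    blocks = [(rows, cols, vals)]

    current = ref_coords + u
    extra_rows, extra_cols, extra_vals = [], [], []

    def _add_block(i, j, M):
        ii, jj = np.meshgrid([2 * i, 2 * i + 1], [2 * j, 2 * j + 1], indexing="ij")
        extra_rows.append(ii.ravel())
        extra_cols.append(jj.ravel())
        extra_vals.append(M.ravel())

    if loads is not None:
        if loads.pressure_edges is not None and loads.p_B != 0.0:
            Bks = pressure_load_tangent_blocks(loads.pressure_edges,
                                               loads.pressure_signs, loads.p_B)
            for k, (a, b) in enumerate(loads.pressure_edges):
                Bk = Bks[k]
                # contrib to nodes a and b is p_B/2 * s * R90 (x_b - x_a)
                _add_block(a, b, Bk); _add_block(a, a, -Bk)
                _add_block(b, b, Bk); _add_block(b, a, -Bk)
        for edges, gamma in loads.tension_groups:
            if gamma == 0.0:
                continue
            Hks = surface_tension_tangent(current, edges, gamma)
            for k, (a, b) in enumerate(edges):
                H = Hks[k]
                _add_block(a, a, H); _add_block(b, b, H)
                _add_block(a, b, -H); _add_block(b, a, -H)
    if extra_rows:
        blocks.append((np.concatenate(extra_rows), np.concatenate(extra_cols),
                       np.concatenate(extra_vals)))
    rows = np.concatenate([b[0] for b in blocks])
    cols = np.concatenate([b[1] for b in blocks])
    vals = np.concatenate([b[2] for b in blocks])
    return sp.coo_matrix((vals, (rows, cols)), shape=(2 * n, 2 * n)).tocsr()


def solve_equilibrium(ref_coords, tris, fixed_nodes, beta1_e, beta2_e, p_e,
                      loads: BoundaryLoads | None = None, u0=None,
                      body_force=None, dirichlet_values=None, full=True,
                      tol_rel=1e-10, tol_abs=1e-12, max_iter=25):
    """Newton solve of the hyperelastic equilibrium on the reference mesh.

    ``fixed_nodes`` are clamped (to zero, or to ``dirichlet_values`` rows
    if given).  Returns (u, info) where info carries the residual-norm
    history; raises :class:`MechanicsError` on non-convergence so callers
    can halve the time step.
    """
    n = ref_coords.shape[0]
    u = np.zeros((n, 2)) if u0 is None else np.array(u0, dtype=float)
    if dirichlet_values is not None:
        u[fixed_nodes] = dirichlet_values
    else:
        u[fixed_nodes] = 0.0
    free = np.ones(2 * n, dtype=bool)
    free[2 * np.asarray(fixed_nodes)] = False
    free[2 * np.asarray(fixed_nodes) + 1] = False
    geo = tri_geometry(ref_coords, tris)

    def _res(uu):
        return assemble_residual(ref_coords, tris, uu, beta1_e, beta2_e, p_e,
                                 loads, body_force, full, _geo_cache=geo)

    r = _res(u)
    norm0 = np.linalg.norm(r.ravel()[free])
    norms = [norm0]
    tol = max(tol_abs, tol_rel * norm0)
    for it in range(max_iter):
        if norms[-1] <= tol:
            break
        K = _assemble_tangent(ref_coords, tris, u, beta1_e, beta2_e, p_e,
                              loads, full, geo)
        Kff = K[free][:, free]
        du = spla.spsolve(Kff.tocsc(), -r.ravel()[free])
        step = 1.0
        for _ in range(8):
            u_try = u.copy()
            u_try.ravel()[free] += step * du
            try:
                r_try = _res(u_try)
            except MechanicsError:
                step *= 0.5
                continue
            nrm = np.linalg.norm(r_try.ravel()[free])
            if nrm <= (1.0 - 1e-4 * step) * norms[-1] or nrm <= tol:
                break
            step *= 0.5
        else:
            raise MechanicsError(
                f"Newton line search stalled at iteration {it} "
                f"(residual {norms[-1]:.3e})"
            )
        u, r = u_try, r_try
        norms.append(nrm)
    else:
        if norms[-1] > tol:
            raise MechanicsError(
                f"Newton failed to converge in {max_iter} iterations "
                f"(residual {norms[-1]:.3e}, tol {tol:.3e})"
            )
    return u, {"iterations": len(norms) - 1, "residual_norms": norms,
               "converged": norms[-1] <= tol}
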