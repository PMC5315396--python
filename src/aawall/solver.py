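"""Decoupled time stepping for the coupled biology/mechanics system.

Each step of size k (days):

1. Newton-solve the total-Lagrangian hyperelastic equilibrium on the
   reference mesh, with moduli beta_i(S^{n-1}) and pressure p(rho^{n-1})
   frozen from the previous step (explicit coefficients);
2. move the mesh by the flow map x = x_ref + u^n and form the discrete
   velocity v^n = (u^n - u^{n-1})/k;
3. advance all 12 species on the moved mesh with implicit diffusion and
   linear-loss terms, explicit (lagged) productions and chemotaxis, the
   (div v) Z term, Robin blood/interface exchange, and periodicity in y;
   media and adventitia fields are coupled per species through the
   interface terms and solved as one block system.

Nodal values follow the flow map, so the material derivative needs no
interpolation.  Failures (element inversion, Newton breakdown) trigger
time-step halving, up to 5 levels, then abort with the partial trajectory
attached.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import _fem, geometry, kinetics, mechanics
from .geometry import GeometryError, WallGeometry, build_initial_geometry, measure_diameter, move_mesh
from .kinetics import SPECIES, SPECIES_INDEX
from .mechanics import BoundaryLoads, MechanicsError
from .params import ParameterSet, load_parameters

__all__ = [
    "SolverOptions",
    "SimulationState",
    "Trajectory",
    "SimulationAbort",
    "initialize_state",
    "newton_solve_displacement",
    "advance_species",
    "step",
    "run_simulation",
]

_S_IDX = SPECIES_INDEX["smc"]
_RHO_IDX = SPECIES_INDEX["ecm"]
_MAC_IDX = SPECIES_INDEX["mac"]
_P_IDX = SPECIES_INDEX["mcp1"]
_I6_IDX = SPECIES_INDEX["il6"]


@dataclass
class SolverOptions:
    """Numerical knobs (defaults are the reported desk-scale settings)."""

    k: float = 0.5                    # time step, days
    mesh_size: float = 0.05           # target element size, cm
    newton_tol_rel: float = 1e-10
    newton_tol_abs: float = 1e-12
    newton_max_iter: int = 25
    max_halvings: int = 5
    clamp_warn_fraction: float = 0.01  # negative-mass warning threshold
    equilibrate_passes: int = 2        # initial R0-rescaling passes
    snapshot_times: tuple = ()
    store_fields: bool = False


@dataclass
class SimulationState:
    """Time-indexed simulator state."""

    geom: WallGeometry
    z_media: np.ndarray               # (12, n_media) nodal fields
    z_adv: np.ndarray                 # (12, n_adv)
    u: np.ndarray                     # (n_merged, 2) displacement at t_n
    u_prev: np.ndarray
    t: float = 0.0
    n: int = 0
    diagnostics: dict = field(default_factory=dict)

    def velocity(self, k: float) -> np.ndarray:
        return (self.u - self.u_prev) / k


class SimulationAbort(RuntimeError):
    """Unrecoverable step failure; carries the partial trajectory."""

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class Trajectory:
    """Time series of diameter and per-layer species averages."""

    times: list = field(default_factory=list)
    diameters: list = field(default_factory=list)
    averages: list = field(default_factory=list)      # dicts per record
    diagnostics: list = field(default_factory=list)
    final_state: SimulationState | None = None

    def record(self, state: SimulationState, params: ParameterSet):
        self.times.append(state.t)
        self.diameters.append(measure_diameter(state.geom))
        self.averages.append(_layer_averages(state))
        self.diagnostics.append(dict(state.diagnostics))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t, d, avg in zip(self.times, self.diameters, self.averages):
            rows.append({"time": t, "diameter": d, **avg})
        return pd.DataFrame(rows)

    def average(self, species: str, layer: str = "media") -> np.ndarray:
        key = f"avg_{species}_{layer}"
        return np.array([a[key] for a in self.averages])

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.diameters)


def _layer_averages(state: SimulationState) -> dict:
    geom = state.geom
    out = {}
    for layer, coords, tris, z in (
        ("media", geom.current_media(), geom.media.tris, state.z_media),
        ("adventitia", geom.current_adventitia(), geom.adventitia.tris, state.z_adv),
    ):
        areas = _fem.element_areas(coords, tris)
        total = areas.sum()
        nodal_mean = z[:, tris].mean(axis=2)          # (12, E) element means
        for i, s in enumerate(SPECIES):
            if s == "smc" and layer == "adventitia":
                continue
            out[f"avg_{s}_{layer}"] = float((nodal_mean[i] * areas).sum() / total)
    return out


# ---------------------------------------------------------------------------
# mechanics step
# ---------------------------------------------------------------------------

def _element_coefficients(state: SimulationState, params: ParameterSet):
    """Per-merged-element (beta1, beta2, p) from the previous-step fields.

    The moduli law applies in the media; the adventitia (no SMCs) keeps the
    baseline moduli.  The pressure law applies in both layers.
    """
    kin, mech = params.kinetic, params.mechanical
    geom = state.geom
    nm = len(geom.media.tris)
    S_e = state.z_media[_S_IDX][geom.media.tris].mean(axis=1)
    b1_m, b2_m = mechanics.elastic_moduli(S_e, mech)
    b1 = np.concatenate([b1_m, np.full(len(geom.adventitia.tris), mech.beta_10)])
    b2 = np.concatenate([b2_m, np.full(len(geom.adventitia.tris), mech.beta_20)])
    rho_m = state.z_media[_RHO_IDX][geom.media.tris].mean(axis=1)
    rho_a = state.z_adv[_RHO_IDX][geom.adventitia.tris].mean(axis=1)
    p_e = mechanics.ecm_pressure(np.concatenate([rho_m, rho_a]), mech)
    return b1, b2, p_e


def _boundary_loads(geom: WallGeometry, params: ParameterSet) -> BoundaryLoads:
    mech = params.mechanical
    eB = geom.media_to_merged[geom.edges_B]
    eM = geom.media_to_merged[geom.edges_M_media]
    signs = mechanics.edge_orientation_signs(geom.merged_coords, geom.merged_tris, eB)
    return BoundaryLoads(
        pressure_edges=eB, pressure_signs=signs, p_B=mech.p_B,
        tension_groups=((eB, mech.gamma_surf), (eM, mech.gamma_surf)),
    )


def newton_solve_displacement(state: SimulationState, params: ParameterSet,
                              opts: SolverOptions | None = None):
    """Solve the equilibrium for u^n with explicit (previous-step)
    biological coefficients; returns (u, info)."""
    opts = opts or SolverOptions()
    geom = state.geom
    b1, b2, p_e = _element_coefficients(state, params)
    loads = _boundary_loads(geom, params)
    u, info = mechanics.solve_equilibrium(
        geom.merged_coords, geom.merged_tris, geom.clamp_nodes(),
        b1, b2, p_e, loads=loads, u0=state.u,
        full=params.mechanical.full_stress_coefficient,
        tol_rel=opts.newton_tol_rel, tol_abs=opts.newton_tol_abs,
        max_iter=opts.newton_max_iter,
    )
    return u, info


# ---------------------------------------------------------------------------
# species step
# ---------------------------------------------------------------------------

def _submesh_operators(coords, tris, divv_e, n):
    M = _fem.mass_matrix(coords, tris, n)
    K = _fem.stiffness_matrix(coords, tris, n=n)
    Mdiv = _fem.scaled_mass_matrix(coords, tris, divv_e, n)
    return M, K, Mdiv


def _element_div(coords, tris, v_nodal):
    _, grads = _fem.tri_geometry(coords, tris)
    return np.einsum("eak,eak->e", grads, v_nodal[tris])


def advance_species(state: SimulationState, v: np.ndarray,
                    params: ParameterSet, k: float,
                    opts: SolverOptions | None = None):
    """One implicit transport/reaction update on the current (moved) mesh.

    Returns (z_media, z_adv, diagnostics).  Productions, chemotaxis and the
    nonlinear loss coefficients are lagged to the previous step so every
    species solve is linear; diffusion, linear losses, the (div v) Z term
    and all Robin exchanges are implicit.
    """
    opts = opts or SolverOptions()
    kin = params.kinetic
    geom = state.geom
    cm = geom.current_media()
    ca = geom.current_adventitia()
    nm, na = geom.media.nnodes, geom.adventitia.nnodes
    v_m = v[geom.media_to_merged]
    v_a = v[geom.adv_to_merged]

    divv_m = _element_div(cm, geom.media.tris, v_m)
    divv_a = _element_div(ca, geom.adventitia.tris, v_a)
    Mm, Km, Mdm = _submesh_operators(cm, geom.media.tris, divv_m, nm)
    Ma, Ka, Mda = _submesh_operators(ca, geom.adventitia.tris, divv_a, na)

    prod_m, loss_m = kinetics.split_rates(state.z_media, kin, chi_A=0)
    prod_a, loss_a = kinetics.split_rates(state.z_adv, kin, chi_A=1)

    # interface coupling (media rows vs adventitia cols share edge geometry)
    eMm, eMa = geom.edges_M_media, geom.edges_M_adv
    Imm = _fem.edge_mass_matrix(cm, eMm, 1.0, n=nm)
    Ima = _fem.edge_mass_matrix(cm, eMm, 1.0, n=nm, col_edges=eMa, ncols=na)
    Iaa = _fem.edge_mass_matrix(ca, eMa, 1.0, n=na)
    Iam = _fem.edge_mass_matrix(ca, eMa, 1.0, n=na, col_edges=eMm, ncols=nm)

    _, Pm = geom.periodic_reduction("media")
    _, Pa = geom.periodic_reduction("adventitia")
    _, Pg = geom.periodic_reduction("merged")

    z_new_m = state.z_media.copy()
    z_new_a = state.z_adv.copy()
    clamped = {}

    def _loss_mass(coords, tris, loss_nodal, n):
        coeff = loss_nodal[tris].mean(axis=1)
        return _fem.scaled_mass_matrix(coords, tris, coeff, n)

    def _chemo_rhs(coords, tris, z_prev, n):
        # + (M_prev chi_C grad(P + I6)_prev, grad W)
        areas, grads = _fem.tri_geometry(coords, tris)
        g = np.einsum("ea,eak->ek", (z_prev[_P_IDX] + z_prev[_I6_IDX])[tris], grads)
        Me = z_prev[_MAC_IDX][tris].mean(axis=1)
        q = (kin.chi_C * Me * areas)[:, None] * g
        out = np.zeros(n)
        contrib = np.einsum("ek,eak->ea", q, grads)
        np.add.at(out, tris.ravel(), contrib.ravel())
        return out

    for i, s in enumerate(SPECIES):
        if s in ("smc", "ecm"):
            continue
        D = getattr(kin, f"D_{s}")
        gam = kin.gamma_cell if s in kinetics.CELLS else kin.gamma_cytokine

        A_mm = Mm / k + Mdm + D * Km + gam * Imm + _loss_mass(cm, geom.media.tris, loss_m[i], nm)
        A_aa = Ma / k + Mda + D * Ka + gam * Iaa + _loss_mass(ca, geom.adventitia.tris, loss_a[i], na)
        A_ma = -gam * Ima
        A_am = -gam * Iam
        b_m = Mm @ (state.z_media[i] / k + prod_m[i])
        b_a = Ma @ (state.z_adv[i] / k + prod_a[i])

        # blood-side Robin exchange
        for bdry, edges, coords_, nloc, z_prev in (
            ("Gamma_B", geom.edges_B, cm, nm, state.z_media),
            ("Gamma_A", geom.edges_A, ca, na, state.z_adv),
        ):
            if s == "mac":
                Pn = z_prev[_P_IDX]
                rate_n, ext = kinetics.robin_coefficients(s, bdry, z_local=Pn, kin=kin)
                rate_e = 0.5 * (rate_n[edges[:, 0]] + rate_n[edges[:, 1]])
            else:
                rate_e, ext = kinetics.robin_coefficients(s, bdry, z_local=0.0, kin=kin)
            if np.all(np.asarray(rate_e) == 0.0):
                continue
            Rmat = _fem.edge_mass_matrix(coords_, edges, rate_e, n=nloc)
            load = _fem.edge_load_vector(coords_, edges, rate_e, n=nloc) * ext
            if bdry == "Gamma_B":
                A_mm = A_mm + Rmat
                b_m = b_m + load
            else:
                A_aa = A_aa + Rmat
                b_a = b_a + load

        if s == "mac":
            b_m = b_m + _chemo_rhs(cm, geom.media.tris, state.z_media, nm)
            b_a = b_a + _chemo_rhs(ca, geom.adventitia.tris, state.z_adv, na)

        A = sp.bmat([[Pm.T @ A_mm @ Pm, Pm.T @ A_ma @ Pa],
                     [Pa.T @ A_am @ Pm, Pa.T @ A_aa @ Pa]], format="csc")
        b = np.concatenate([Pm.T @ b_m, Pa.T @ b_a])
        try:
            x = spla.spsolve(A, b)
        except Exception as exc:  # singular system
            raise SimulationAbort(f"species solve failed for {s!r}: {exc}") from exc
        nred = Pm.shape[1]
        z_new_m[i] = Pm @ x[:nred]
        z_new_a[i] = Pa @ x[nred:]

    # SMCs: media only, no-flux everywhere
    D = kin.D_smc
    A = Mm / k + Mdm + D * Km + _loss_mass(cm, geom.media.tris, loss_m[_S_IDX], nm)
    b = Mm @ (state.z_media[_S_IDX] / k + prod_m[_S_IDX])
    A = (Pm.T @ A @ Pm).tocsc()
    z_new_m[_S_IDX] = Pm @ spla.spsolve(A, Pm.T @ b)
    z_new_a[_S_IDX] = 0.0

    # ECM: continuous field on the merged mesh, assembled per subdomain
    cg = geom.current_merged()
    ng = geom.n_merged
    D = kin.D_ecm
    A = sp.csr_matrix((ng, ng))
    b = np.zeros(ng)
    rho_prev = np.zeros(ng)
    rho_prev[geom.media_to_merged] = state.z_media[_RHO_IDX]
    rho_prev[geom.adv_to_merged] = state.z_adv[_RHO_IDX]
    for coords_, tris_loc, mapping, prod, loss in (
        (cm, geom.media.tris, geom.media_to_merged, prod_m[_RHO_IDX], loss_m[_RHO_IDX]),
        (ca, geom.adventitia.tris, geom.adv_to_merged, prod_a[_RHO_IDX], loss_a[_RHO_IDX]),
    ):
        tris_g = mapping[tris_loc]
        Mg = _fem.mass_matrix(cg, tris_g, ng)
        Kg = _fem.stiffness_matrix(cg, tris_g, n=ng)
        dv = _element_div(cg, tris_g, v)
        Mdg = _fem.scaled_mass_matrix(cg, tris_g, dv, ng)
        loss_g = np.zeros(ng)
        loss_g[mapping] = loss
        Lg = _fem.scaled_mass_matrix(cg, tris_g, loss_g[tris_g].mean(axis=1), ng)
        prod_g = np.zeros(ng)
        prod_g[mapping] = prod
        A = A + Mg / k + Mdg + D * Kg + Lg
        b = b + Mg @ (rho_prev / k + prod_g)
    A = (Pg.T @ A @ Pg).tocsc()
    rho_new = Pg @ spla.spsolve(A, Pg.T @ b)
    z_new_m[_RHO_IDX] = rho_new[geom.media_to_merged]
    z_new_a[_RHO_IDX] = rho_new[geom.adv_to_merged]

    # clamp undershoots (linear FEM with chemotaxis can go slightly negative)
    for name, z, coords_, tris_loc in (
        ("media", z_new_m, cm, geom.media.tris),
        ("adventitia", z_new_a, ca, geom.adventitia.tris),
    ):
        neg = np.minimum(z, 0.0)
        if np.any(neg < 0):
            areas = _fem.element_areas(coords_, tris_loc)
            mass = -(neg[:, tris_loc].mean(axis=2) * areas).sum(axis=1)
            tot = (np.abs(z)[:, tris_loc].mean(axis=2) * areas).sum(axis=1)
            # fields that are numerically zero produce dust-level undershoot;
            # report the fraction only where the species carries real mass
            floor = 1e-16 * areas.sum()
            clamped[name] = float(np.max(mass / np.maximum(tot, floor)))
            np.maximum(z, 0.0, out=z)
    return z_new_m, z_new_a, {"clamped_fraction": clamped}


# ---------------------------------------------------------------------------
# stepping and the full run
# ---------------------------------------------------------------------------

def step(state: SimulationState, params: ParameterSet,
         opts: SolverOptions | None = None, k: float | None = None,
         _depth: int = 0) -> SimulationState:
    """Advance one time step (mechanics -> mesh motion -> species).

    On Newton failure or element inversion the step is retried as two half
    steps, up to ``opts.max_halvings`` levels deep.
    """
    opts = opts or SolverOptions()
    k = opts.k if k is None else k
    try:
        u_new, info = newton_solve_displacement(state, params, opts)
        geom_new = move_mesh(state.geom, u_new)
    except (MechanicsError, GeometryError) as exc:
        if _depth >= opts.max_halvings:
            raise SimulationAbort(
                f"step failed after {_depth} halvings at t = {state.t}: {exc}"
            ) from exc
        half = step(state, params, opts, k=k / 2, _depth=_depth + 1)
        return step(half, params, opts, k=k / 2, _depth=_depth + 1)

    moved = dataclasses.replace(
        state, geom=geom_new, u=u_new, u_prev=state.u,
    )
    v = moved.velocity(k)
    z_m, z_a, diag = advance_species(moved, v, params, k, opts)
    return dataclasses.replace(
        moved, z_media=z_m, z_adv=z_a, t=state.t + k, n=state.n + 1,
        diagnostics={"newton_iterations": info["iterations"], **diag},
    )


def initialize_state(R0: float, params: ParameterSet,
                     opts: SolverOptions | None = None,
                     equilibrate: bool = True) -> SimulationState:
    """Build the geometry, set initial fields, and pre-equilibrate.

    The reference section carries residual stress (p(rho_init) != 2 beta1
    in general), so a pre-step equilibrium solve defines t = 0; the
    reference geometry is rescaled so the equilibrated lumen diameter
    equals R0.
    """
    opts = opts or SolverOptions()
    kin = params.kinetic
    geom = build_initial_geometry(R0, mesh_size=opts.mesh_size)
    state = _fresh_state(geom, kin)
    if not equilibrate:
        return state
    for _ in range(opts.equilibrate_passes):
        u_eq, _info = newton_solve_displacement(state, params, opts)
        geom2 = move_mesh(state.geom, u_eq)
        R_eq = measure_diameter(geom2)
        factor = R0 / R_eq
        geom = _rescale(state.geom, factor)
        state = _fresh_state(geom, kin)
        state.u = u_eq * factor
    u_eq, _info = newton_solve_displacement(state, params, opts)
    state = dataclasses.replace(
        state, geom=move_mesh(state.geom, u_eq), u=u_eq, u_prev=u_eq,
    )
    return state


def _fresh_state(geom: WallGeometry, kin) -> SimulationState:
    z_m = np.zeros((12, geom.media.nnodes))
    z_a = np.zeros((12, geom.adventitia.nnodes))
    for z, chi in ((z_m, 0), (z_a, 1)):
        z[SPECIES_INDEX["il6"]] = kin.I6_0 / 2.0
        z[SPECIES_INDEX["mmp"]] = 3.0e-8
        z[SPECIES_INDEX["timp"]] = 1.0e-8
        z[SPECIES_INDEX["ecm"]] = 3.43e-4
    z_m[_S_IDX] = kin.S_0
    u0 = np.zeros((geom.n_merged, 2))
    return SimulationState(geom=geom, z_media=z_m, z_adv=z_a,
                           u=u0, u_prev=u0.copy())


def _rescale(geom: WallGeometry, factor: float) -> WallGeometry:
    g = dataclasses.replace(geom)
    g.media = dataclasses.replace(geom.media, coords=geom.media.coords * factor)
    g.adventitia = dataclasses.replace(geom.adventitia,
                                       coords=geom.adventitia.coords * factor)
    g.merged_coords = geom.merged_coords * factor
    g.scale = geom.scale * factor
    g.disp = np.zeros_like(g.merged_coords)
    return g


def run_simulation(R0: float, I60: float, T_end: float,
                   params: ParameterSet | None = None,
                   opts: SolverOptions | None = None,
                   progress=None) -> Trajectory:
    """Simulate diameter growth R(t) for initial diameter R0 (cm) and serum
    IL-6 level I60 (g/cm^3) over T_end days; returns the trajectory of
    R(t) and layer-averaged species."""
    opts = opts or SolverOptions()
    if params is None:
        params = load_parameters({"I6_0": I60})
    elif params.kinetic.I6_0 != I60:
        over = {k: v["value"] for k, v in params.dump().items()
                if v["provenance"] == "override"}
        over["I6_0"] = I60
        over.pop("lam_S", None)
        params = load_parameters(over)
    if T_end < 0:
        raise ValueError("T_end must be nonnegative")

    state = initialize_state(R0, params, opts)
    traj = Trajectory()
    traj.record(state, params)
    n_steps = int(round(T_end / opts.k))
    try:
        for istep in range(n_steps):
            state = step(state, params, opts)
            traj.record(state, params)
            if progress is not None:
                progress(state)
    except SimulationAbort as exc:
        exc.trajectory = traj
        raise
    traj.final_state = state
    return traj
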