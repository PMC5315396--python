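"""Constitutive law, stress/tangent consistency, surface tension, and the
Newton equilibrium solver (patch test, frame indifference, manufactured
solution)."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aawall import _fem
from aawall.mechanics import (
    BoundaryLoads,
    MechanicsError,
    assemble_residual,
    cauchy_stress,
    deformation_state,
    ecm_pressure,
    edge_orientation_signs,
    elastic_moduli,
    first_piola,
    piola_tangent,
    solve_equilibrium,
    strain_energy_density,
    surface_tension_term,
)
from aawall.params import MechanicalParams


def unit_square(n):
    xs = np.linspace(0.0, 1.0, n + 1)
    X, Y = np.meshgrid(xs, xs, indexing="xy")
    coords = np.stack([X.ravel(), Y.ravel()], axis=1)
    tris = []
    for j in range(n):
        for i in range(n):
            a = j * (n + 1) + i
            b, c, d = a + 1, a + n + 2, a + n + 1
            tris += [(a, b, c), (a, c, d)]
    bnd = np.unique(np.concatenate([
        np.arange(n + 1), n * (n + 1) + np.arange(n + 1),
        np.arange(n + 1) * (n + 1), np.arange(n + 1) * (n + 1) + n,
    ]))
    return coords, np.asarray(tris), bnd


class TestConstitutiveLaws:
    def test_moduli_at_reference(self, mech):
        b1, b2 = elastic_moduli(mech.S_0, mech)
        assert (b1, b2) == (pytest.approx(17.4), pytest.approx(188.1))

    def test_moduli_at_disease_state(self, mech):
        b1, b2 = elastic_moduli(mech.S_0 / 2, mech)
        assert b1 == pytest.approx(17.4 - 30.4 / 2, rel=1e-12)   # 0.022 N/mm^2
        assert b2 == pytest.approx(188.1 - 84.0 / 2, rel=1e-12)  # 1.461 N/mm^2

    def test_moduli_abort_below_validity(self, mech):
        with pytest.raises(MechanicsError, match="S/S0"):
            elastic_moduli(0.3 * mech.S_0, mech)

    def test_pressure_law_points(self, mech):
        assert ecm_pressure(mech.rho_star, mech) == pytest.approx(37.0)
        assert ecm_pressure(0.75 * mech.rho_star, mech) == pytest.approx(32.5)
        assert ecm_pressure(0.0, mech) == pytest.approx(19.0)

    @given(s=st.floats(0.5, 1.5), t=st.floats(0.5, 1.5), w=st.floats(0.0, 1.0))
    def test_affine_laws_interpolate_exactly(self, s, t, w, mech):
        """Both laws are affine: any convex combination maps exactly."""
        S0 = mech.S_0
        b1a, _ = elastic_moduli(s * S0, mech)
        b1b, _ = elastic_moduli(t * S0, mech)
        b1m, _ = elastic_moduli((w * s + (1 - w) * t) * S0, mech)
        assert b1m == pytest.approx(w * b1a + (1 - w) * b1b, rel=1e-12)
        pa = ecm_pressure(s * mech.rho_star, mech)
        pb = ecm_pressure(t * mech.rho_star, mech)
        pm = ecm_pressure((w * s + (1 - w) * t) * mech.rho_star, mech)
        assert pm == pytest.approx(w * pa + (1 - w) * pb, rel=1e-12)


class TestCauchyStress:
    def test_calibrated_stress_free_reference(self):
        d = deformation_state(np.zeros((2, 2)))
        sig = cauchy_stress(d, p=2 * 17.4, beta1=17.4, beta2=188.1)
        np.testing.assert_allclose(sig, 0.0, atol=1e-12)

    def test_identity_with_zero_pressure(self):
        d = deformation_state(np.zeros((2, 2)))
        sig = cauchy_stress(d, p=0.0, beta1=17.4, beta2=188.1)
        np.testing.assert_allclose(sig, 34.8 * np.eye(2), rtol=1e-12)

    def test_inverted_element_rejected(self):
        d = deformation_state(np.diag([-2.0, 0.0]))
        with pytest.raises(MechanicsError):
            cauchy_stress(d, 0.0, 17.4, 188.1)

    def test_symmetry_random_states(self, rng):
        g = 0.1 * rng.standard_normal((50, 2, 2))
        d = deformation_state(g)
        keep = d.J > 0.1
        sig = cauchy_stress(
            deformation_state(g[keep]), p=3.0, beta1=17.4, beta2=188.1
        )
        np.testing.assert_allclose(sig, np.swapaxes(sig, -1, -2), atol=1e-12)

    def test_isochoric_stretch_energy_consistency(self):
        """P(p=0) equals dW/dF by central finite differences."""
        lam = 1.1
        F = np.diag([lam, 1.0 / lam])
        b1, b2 = 17.4, 188.1
        P = first_piola(F, 0.0, b1, b2)

        def W(F):
            d = deformation_state(F - np.eye(2))
            return strain_energy_density(d, b1, b2)

        h = 1e-6
        for k in range(2):
            for l in range(2):
                dF = np.zeros((2, 2))
                dF[k, l] = h
                num = (W(F + dF) - W(F - dF)) / (2 * h)
                assert P[k, l] == pytest.approx(num, rel=1e-5, abs=1e-8)

    def test_piola_tangent_is_exact(self, rng):
        F = np.eye(2) + 0.1 * rng.standard_normal((5, 2, 2))
        p, b1, b2 = 3.0, 17.4, 188.1
        A = piola_tangent(F, p, b1, b2)
        h = 1e-6
        for k in range(2):
            for l in range(2):
                dF = np.zeros((2, 2))
                dF[k, l] = h
                num = (first_piola(F + dF, p, b1, b2)
                       - first_piola(F - dF, p, b1, b2)) / (2 * h)
                np.testing.assert_allclose(num, A[..., k, l], rtol=1e-4, atol=1e-6)

    def test_halved_coefficient_variant(self):
        F = np.eye(2) * 1.05
        full = first_piola(F, 0.0, 17.4, 188.1, full=True)
        half = first_piola(F, 0.0, 17.4, 188.1, full=False)
        np.testing.assert_allclose(half, 0.5 * full, rtol=1e-12)


class TestSurfaceTension:
    def test_straight_segment_constant_field_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        edges = np.array([[0, 1], [1, 2]])
        r = surface_tension_term(pts, edges, gamma=1e-2)
        # interior node of a straight polyline carries no curvature force
        np.testing.assert_allclose(r[1], 0.0, atol=1e-15)
        # endpoint forces are tangential (length gradient), equal/opposite
        np.testing.assert_allclose(r[0] + r[2], 0.0, atol=1e-15)

    def test_degenerate_edge_rejected(self):
        pts = np.array([[0.0, 0.0], [0.0, 0.0]])
        with pytest.raises(MechanicsError):
            surface_tension_term(pts, np.array([[0, 1]]), 1e-2)

    @pytest.mark.parametrize("n", [64, 128, 256])
    def test_discrete_circle_curvature_force(self, n):
        """Nodal contributions approach gamma*(1/R)*n_out*(edge mass) with
        O(n^-2) error on a discrete circle."""
        R, gamma = 2.0, 1e-2
        th = np.linspace(0.0, 2 * np.pi, n + 1)[:-1]
        pts = R * np.stack([np.cos(th), np.sin(th)], axis=1)
        edges = np.stack([np.arange(n), (np.arange(n) + 1) % n], axis=1)
        r = surface_tension_term(pts, edges, gamma)
        ds = 2 * R * np.sin(np.pi / n)      # edge mass per node
        expect = gamma * (1.0 / R) * pts / R * ds
        err = np.abs(r - expect).max() / np.abs(expect).max()
        assert err < 20.0 / n**2


class TestEquilibriumSolve:
    B1, B2 = 17.4, 188.1

    def test_stress_free_state_converges_immediately(self):
        coords, tris, bnd = unit_square(4)
        e = len(tris)
        u, info = solve_equilibrium(
            coords, tris, bnd, np.full(e, self.B1), np.full(e, self.B2),
            np.full(e, 2 * self.B1) * 0.0, loads=None,
        )
        assert info["iterations"] <= 1
        np.testing.assert_allclose(u, 0.0, atol=1e-12)

    def test_homogeneous_stretch_patch(self):
        """Affine Dirichlet data reproduces the homogeneous deformation
        exactly (interior residual rows vanish for constant stress)."""
        coords, tris, bnd = unit_square(3)
        e = len(tris)
        G = np.array([[0.08, 0.02], [-0.01, 0.05]])
        ue = coords @ G.T
        u, info = solve_equilibrium(
            coords, tris, bnd, np.full(e, self.B1), np.full(e, self.B2),
            np.full(e, 1.0), dirichlet_values=ue[bnd],
        )
        np.testing.assert_allclose(u, ue, atol=1e-10)

    def test_frame_indifference(self, rng):
        """Rigid rotation of reference and displacement leaves the residual
        norm unchanged."""
        coords, tris, bnd = unit_square(4)
        e = len(tris)
        u = 0.05 * coords + 0.01 * rng.standard_normal(coords.shape)
        b1 = np.full(e, self.B1)
        b2 = np.full(e, self.B2)
        p = np.full(e, 2.0)
        r0 = np.linalg.norm(assemble_residual(coords, tris, u, b1, b2, p))
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            Q = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            x_rot = coords @ Q.T
            u_rot = (coords + u) @ Q.T - x_rot
            r = np.linalg.norm(assemble_residual(x_rot, tris, u_rot, b1, b2, p))
            assert r == pytest.approx(r0, rel=1e-10)

    def test_newton_quadratic_convergence(self):
        """Residual norms contract quadratically in the final iterations of
        a smooth loaded solve."""
        coords, tris, bnd = unit_square(8)
        e = len(tris)
        lam0 = 0.06

        def bf(cent):
            return 40.0 * np.stack([np.sin(np.pi * cent[:, 0]),
                                    np.cos(np.pi * cent[:, 1])], axis=1)

        ue = lam0 * coords
        _u, info = solve_equilibrium(
            coords, tris, bnd, np.full(e, self.B1), np.full(e, self.B2),
            np.full(e, 2.0), body_force=bf, dirichlet_values=ue[bnd],
        )
        norms = info["residual_norms"]
        assert info["converged"]
        # the last full step before convergence should at least square the
        # residual up to a moderate constant
        r_prev, r_last = norms[-2], norms[-1]
        assert r_last <= 100.0 * r_prev**2 / max(norms[0], 1.0)

    def test_manufactured_solution_second_order(self):
        """L2 displacement error decays ~O(h^2) against a manufactured
        solution around a pre-tensioned base state."""
        sympy = pytest.importorskip("sympy")
        x, y = sympy.symbols("x y")
        lam0, a, pv = 0.06, 0.02, 2.0
        u1 = lam0 * x + a * sympy.sin(sympy.pi * x) * sympy.sin(sympy.pi * y)
        u2 = lam0 * y + a * x * (1 - x) * y * (1 - y)
        F = sympy.Matrix([
            [1 + sympy.diff(u1, x), sympy.diff(u1, y)],
            [sympy.diff(u2, x), 1 + sympy.diff(u2, y)],
        ])
        J = F.det()
        trB = sum(F.multiply_elementwise(F))
        c = 2 * self.B1 + 4 * self.B2 * (trB + 1 - 3)
        P = -pv * J * F.inv().T + c * F
        f = (-(sympy.diff(P[0, 0], x) + sympy.diff(P[0, 1], y)),
             -(sympy.diff(P[1, 0], x) + sympy.diff(P[1, 1], y)))
        flam = sympy.lambdify((x, y), f, "numpy")
        ulam = sympy.lambdify((x, y), (u1, u2), "numpy")

        errs = []
        for n in (8, 16, 32):
            coords, tris, bnd = unit_square(n)
            e = len(tris)
            ue = np.stack(ulam(coords[:, 0], coords[:, 1]), axis=1)
            u, _ = solve_equilibrium(
                coords, tris, bnd, np.full(e, self.B1), np.full(e, self.B2),
                np.full(e, pv),
                body_force=lambda cent: np.stack(
                    flam(cent[:, 0], cent[:, 1]), axis=1),
                dirichlet_values=ue[bnd],
            )
            M = _fem.mass_matrix(coords, tris)
            d = u - ue
            errs.append(np.sqrt(sum(d[:, i] @ (M @ d[:, i]) for i in range(2))))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(2)]
        assert min(orders) > 1.5
        assert errs[-1] < errs[0] / 8

    def test_pressure_load_inflates_annulus(self):
        """A pressurized inner boundary pushes the wall outward (follower
        load direction check on the real geometry)."""
        from aawall.geometry import build_initial_geometry, measure_diameter, move_mesh

        geom = build_initial_geometry(2.0, n_y=16, nx_media=3, nx_adv=2)
        e = len(geom.merged_tris)
        eB = geom.media_to_merged[geom.edges_B]
        signs = edge_orientation_signs(geom.merged_coords, geom.merged_tris, eB)
        loads = BoundaryLoads(pressure_edges=eB, pressure_signs=signs, p_B=1.4665)
        u, info = solve_equilibrium(
            geom.merged_coords, geom.merged_tris, geom.clamp_nodes(),
            np.full(e, self.B1), np.full(e, self.B2),
            np.full(e, 2 * self.B1),   # stress-free bulk: only p_B acts
            loads=loads,
        )
        assert info["converged"]
        assert measure_diameter(move_mesh(geom, u)) > 2.0
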