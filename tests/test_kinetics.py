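"""Reaction network: source terms, chemotaxis, Robin exchange laws, and
equivalence with an independent literal transcription of the equations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aawall.kinetics import (
    CELLS,
    CYTOKINES,
    SPECIES,
    SPECIES_INDEX,
    SpeciesState,
    chemotactic_flux,
    reaction_rates,
    robin_coefficients,
    split_rates,
    wellmixed_rhs,
)

conc = st.floats(0.0, 1e-2)


def idx(name):
    return SPECIES_INDEX[name]


# ---------------------------------------------------------------------------
# independent oracle: a plain, term-by-term transcription of the governing
# equations, written without reference to the implementation's factoring
# ---------------------------------------------------------------------------

def literal_rhs(z, kin, chi_A):
    P, M, T, S, I6, I10, I12, Ta, Ig, Q, Qr, rho = z
    F = np.zeros(12)
    F[0] = kin.lam_PS * (M / (M + kin.K_M)) * S \
        - kin.d_PM * (P / (P + kin.K_P)) * M - kin.d_P * P
    F[1] = kin.lam_MIg * M * (Ig / (Ig + kin.K_Ig)) \
        * (1 + kin.lam_MTa * Ta / (Ta + kin.K_Ta)) - kin.d_M * M
    F[2] = kin.lam_T * (I12 / (1 + I10 / kin.K_I10)) * M - kin.d_T * T
    if chi_A == 0:
        F[3] = kin.lam_S - kin.d_SM * (M / (M + kin.K_M)) * S - kin.d_S * S
    F[4] = kin.lam_I6M * M + kin.lam_I6S * S - kin.d_I6 * I6
    F[5] = kin.lam_I10M * M - kin.d_I10 * I10
    F[6] = kin.lam_I12M * M / (1 + I10 / kin.K_I10) - kin.d_I12 * I12
    F[7] = kin.lam_TaM * M / (1 + I10 / kin.K_I10) - kin.d_Ta * Ta
    F[8] = kin.lam_IgT * T - kin.d_Ig * Ig
    F[9] = (kin.lam_QM * M + kin.lam_QS * S) \
        * (1 + kin.lam_QTa * Ta / (Ta + kin.K_Ta)) \
        - kin.d_QQr * Qr * Q - kin.d_Q * Q
    F[10] = kin.lam_QrM * M - kin.d_QrQ * Q * Qr - kin.d_Qr * Qr
    F[11] = (kin.lam_rf * chi_A + kin.lam_rS * S) * max(1 - rho / kin.rho_0, 0.0) \
        - kin.d_r * rho - kin.d_rQ * Q * rho
    return F


class TestReactionRates:
    def test_zero_state_media(self, kin):
        F = reaction_rates(np.zeros(12), kin, chi_A=0)
        expect = np.zeros(12)
        expect[idx("smc")] = kin.lam_S
        np.testing.assert_allclose(F, expect, rtol=0, atol=0)

    def test_zero_state_adventitia_has_fibroblast_ecm_source(self, kin):
        F = reaction_rates(np.zeros(12), kin, chi_A=1)
        assert F[idx("smc")] == 0.0
        assert F[idx("ecm")] == pytest.approx(kin.lam_rf)

    def test_il6_calibration_steady_state(self, kin):
        """The assay state lam_I6M*M = d_I6*I6 has exactly zero IL-6 rate."""
        z = np.zeros(12)
        z[idx("mac")] = 1e-3
        z[idx("il6")] = 1e-8
        F = reaction_rates(z, kin, chi_A=0)
        assert F[idx("il6")] == pytest.approx(0.0, abs=1e-20)

    def test_mmp_timp_binding_arithmetic(self, kin):
        z = np.zeros(12)
        z[idx("mmp")] = 3e-8
        z[idx("timp")] = 1e-8
        F = reaction_rates(z, kin, chi_A=0)
        assert F[idx("mmp")] == pytest.approx(-2.790e-7, rel=1e-3)

    def test_negative_input_rejected(self, kin):
        z = np.zeros(12)
        z[idx("mac")] = -1e-9
        with pytest.raises(ValueError):
            reaction_rates(z, kin, chi_A=0)

    def test_adventitia_state_forces_smc_zero(self):
        s = SpeciesState(np.full(12, 1e-5), subdomain="adventitia")
        assert s.values[idx("smc")] == 0.0
        assert s.chi_A == 1

    @given(z=st.lists(conc, min_size=12, max_size=12), chi=st.sampled_from([0, 1]))
    def test_matches_literal_transcription(self, z, chi, kin):
        z = np.asarray(z)
        if chi == 1:
            z[idx("smc")] = 0.0
        F = reaction_rates(z, kin, chi_A=chi)
        np.testing.assert_allclose(F, literal_rhs(z, kin, chi), rtol=1e-12, atol=1e-30)

    def test_oracle_equivalence_bulk(self, kin, rng):
        """1000 random states agree with the literal transcription to 12
        digits in each subdomain."""
        Z = rng.uniform(0.0, 1e-2, size=(1000, 12))
        for chi in (0, 1):
            ZZ = Z.copy()
            if chi:
                ZZ[:, idx("smc")] = 0.0
            F = reaction_rates(ZZ.T, kin, chi_A=chi).T
            expect = np.array([literal_rhs(z, kin, chi) for z in ZZ])
            np.testing.assert_allclose(F, expect, rtol=1e-12, atol=1e-30)

    @given(z=st.lists(conc, min_size=12, max_size=12))
    def test_binding_terms_never_create_mass(self, z, kin):
        """The MMP-TIMP binding parts of both rates are nonpositive."""
        z = np.asarray(z)
        prod, loss = split_rates(z, kin, chi_A=0)
        q, qr = z[idx("mmp")], z[idx("timp")]
        assert -kin.d_QQr * qr * q <= 0
        assert -kin.d_QrQ * q * qr <= 0
        # and the implicit-split losses include them with positive sign
        assert loss[idx("mmp")] >= kin.d_Q
        assert loss[idx("timp")] >= kin.d_Qr

    @given(rho=st.floats(0.0, 5e-3), S=st.floats(0.0, 1e-2))
    def test_ecm_production_clamps_at_saturation(self, rho, S, kin):
        z = np.zeros(12)
        z[idx("ecm")] = rho
        z[idx("smc")] = S
        prod, _ = split_rates(z, kin, chi_A=0)
        if rho >= kin.rho_0:
            assert prod[idx("ecm")] == 0.0
        else:
            assert prod[idx("ecm")] >= 0.0

    @given(
        M=st.floats(0, 1e-3), S=st.floats(0, 1e-2),
        scale=st.floats(0.1, 10.0),
    )
    def test_il6_zero_set_is_exact(self, M, S, scale, kin):
        """F_I6 = 0 exactly on the surface lam_I6M M + lam_I6S S = d_I6 I6."""
        z = np.zeros(12)
        z[idx("mac")] = M
        z[idx("smc")] = S
        I6_star = (kin.lam_I6M * M + kin.lam_I6S * S) / kin.d_I6
        z[idx("il6")] = I6_star
        F = reaction_rates(z, kin, chi_A=0)
        assert abs(F[idx("il6")]) <= 1e-18
        z[idx("il6")] = I6_star * scale
        F2 = reaction_rates(z, kin, chi_A=0)
        if scale > 1:
            assert F2[idx("il6")] <= 0
        elif scale < 1:
            assert F2[idx("il6")] >= 0


class TestChemotacticFlux:
    def test_zero_macrophages(self):
        assert np.all(chemotactic_flux(0.0, [1e-8, 0], [0, 0], 10.0) == 0)

    def test_cancellation(self):
        g = np.array([1e-8, -2e-8])
        assert np.all(chemotactic_flux(5e-5, g, -g, 10.0) == 0)

    def test_direct_product(self):
        f = chemotactic_flux(5e-5, [1e-8, 0.0], [0.0, 0.0], 10.0)
        np.testing.assert_allclose(f, [5e-12, 0.0])

    def test_nonfinite_gradient_rejected(self):
        with pytest.raises(ValueError):
            chemotactic_flux(1e-5, [np.nan, 0.0], [0.0, 0.0], 10.0)


class TestRobinCoefficients:
    def test_macrophage_influx_half_saturation(self, kin):
        rate, ext = robin_coefficients("mac", "Gamma_B", z_local=kin.K_P, kin=kin)
        assert rate == pytest.approx(kin.alpha_M / 2)
        assert ext == kin.M_0

    def test_mcp1_serum_exchange(self, kin):
        rate, ext = robin_coefficients("mcp1", "Gamma_B", kin=kin)
        assert (rate, ext) == (pytest.approx(0.2), pytest.approx(3e-10))

    def test_unlisted_species_default_zero_flux(self, kin):
        assert robin_coefficients("mmp", "Gamma_A", kin=kin) == (0.0, 0.0)
        assert robin_coefficients("il6", "Gamma_A", kin=kin) == (0.0, 0.0)
        # IL-6 influx is endothelial: inner boundary only
        assert robin_coefficients("il6", "Gamma_B", kin=kin)[0] == pytest.approx(0.2)

    def test_interface_uses_species_class_coefficients(self, kin):
        r_cell, across = robin_coefficients("mac", "Gamma_M_media",
                                            z_across=1.5e-5, kin=kin)
        assert r_cell == kin.gamma_cell and across == 1.5e-5
        r_cyt, _ = robin_coefficients("tnfa", "Gamma_M_adventitia",
                                      z_across=0.0, kin=kin)
        assert r_cyt == kin.gamma_cytokine
        assert robin_coefficients("smc", "Gamma_M_media", kin=kin) == (0.0, 0.0)

    def test_unknown_pair_rejected(self, kin):
        with pytest.raises(ValueError):
            robin_coefficients("collagen", "Gamma_B", kin=kin)
        with pytest.raises(ValueError):
            robin_coefficients("mac", "Gamma_X", kin=kin)

    def test_species_partition(self):
        assert CELLS | CYTOKINES | {"smc", "ecm"} == set(SPECIES)
        assert not CELLS & CYTOKINES


class TestWellmixedRhs:
    SV = {"B_media": 5.0, "M_media": 6.0, "M_adv": 12.0, "A_adv": 12.0}

    def test_equal_states_have_zero_exchange(self, kin):
        z = np.full(12, 1e-6)
        z[idx("smc")] = 0.0
        Fm, Fa = wellmixed_rhs(z, z, kin, self.SV)
        Fm_pure = reaction_rates(z, kin, chi_A=0)
        # interface terms vanish; only the blood-side exchange remains
        for s in set(SPECIES) - {"mac", "tcell", "mcp1", "il6"}:
            assert Fm[idx(s)] == pytest.approx(Fm_pure[idx(s)], rel=1e-12, abs=1e-25)

    def test_il10_clamped_macrophage_steady_level(self, kin):
        """I10 relaxes to lam_I10M*M/d_I10 when M is held fixed."""
        assert kin.lam_I10M * 5e-5 / kin.d_I10 == pytest.approx(6.01e-9, rel=1e-3)

    def test_nonpositive_sv_rejected(self, kin):
        z = np.zeros(12)
        with pytest.raises(ValueError):
            wellmixed_rhs(z, z, kin, {**self.SV, "M_adv": 0.0})
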