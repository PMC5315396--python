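"""Pointwise reaction sources, chemotactic flux, and Robin exchange laws
for the 12-species wall network.

Species (stable string ids, fixed order)::

    mcp1  (P)    monocyte chemoattractant protein-1
    mac   (M)    macrophages
    tcell (T)    Th1 cells
    smc   (S)    smooth muscle cells          -- media only
    il6, il10, il12                            interleukins
    tnfa  (T_a)  TNF-alpha
    ifng  (I_g)  IFN-gamma
    mmp   (Q)    matrix metalloproteinases
    timp  (Q_r)  tissue inhibitor of MMP
    ecm   (rho)  extracellular matrix          -- continuous across the interface

All concentrations/densities are g/cm^3, rates g/cm^3/day.  The fibroblast
population is not a state variable: it is folded into the constant
adventitial ECM source via the indicator chi_A (1 in adventitia, 0 in media).

Functions are vectorized: a "state" is an array of shape (12, ...) in the
order above, e.g. nodal fields stacked along axis 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import KineticParams

__all__ = [
    "SPECIES",
    "SPECIES_INDEX",
    "CELLS",
    "CYTOKINES",
    "SpeciesState",
    "reaction_rates",
    "split_rates",
    "chemotactic_flux",
    "robin_coefficients",
    "wellmixed_rhs",
]

SPECIES = (
    "mcp1", "mac", "tcell", "smc", "il6", "il10",
    "il12", "tnfa", "ifng", "mmp", "timp", "ecm",
)
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: species exchanged across the interface with the cellular coefficient
CELLS = frozenset({"mac", "tcell"})
#: species exchanged across the interface with the cytokine coefficient
#: (MMP/TIMP are diffusible proteins and belong here)
CYTOKINES = frozenset({"mcp1", "il6", "il10", "il12", "tnfa", "ifng", "mmp", "timp"})

_P, _M, _T, _S, _I6, _I10, _I12, _TA, _IG, _Q, _QR, _RHO = range(12)


@dataclass
class SpeciesState:
    """A species vector tagged with its subdomain.

    ``values`` has shape (12, ...); ``subdomain`` is "media" or
    "adventitia".  In the adventitia the SMC slot is carried as zero.
    """

    values: np.ndarray
    subdomain: str = "media"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 12:
            raise ValueError("species state must have 12 components on axis 0")
        if self.subdomain not in ("media", "adventitia"):
            raise ValueError(f"unknown subdomain {self.subdomain!r}")
        if self.subdomain == "adventitia":
            self.values[_S] = 0.0

    @property
    def chi_A(self) -> int:
        return 1 if self.subdomain == "adventitia" else 0


def _as_values(z) -> tuple[np.ndarray, int | None]:
    if isinstance(z, SpeciesState):
        return z.values, z.chi_A
    return np.asarray(z, dtype=float), None


def split_rates(z, kin: KineticParams, chi_A: int | None = None):
    """Split the reaction right-hand side into production and linear loss.

    Returns ``(prod, loss)`` with F(Z) = prod - loss * Z componentwise, both
    evaluated at the given state.  The split is exact (no approximation): it
    is how the implicit transport solver lags the nonlinear coefficients
    while keeping each species update linear, and
    :func:`reaction_rates` is defined through it.
    """
    v, tag = _as_values(z)
    if chi_A is None:
        chi_A = 0 if tag is None else tag
    if np.any(v < 0):
        raise ValueError("reaction rates are defined for nonnegative states only; clamp first")

    P, M, T, S = v[_P], v[_M], v[_T], v[_S]
    I6, I10, I12, Ta = v[_I6], v[_I10], v[_I12], v[_TA]
    Ig, Q, Qr, rho = v[_IG], v[_Q], v[_QR], v[_RHO]

    m_sat = M / (M + kin.K_M)                 # M=0 -> 0, K_M > 0
    i10_inh = 1.0 / (1.0 + I10 / kin.K_I10)
    ta_enh_Q = 1.0 + kin.lam_QTa * Ta / (Ta + kin.K_Ta)
    ta_enh_M = 1.0 + kin.lam_MTa * Ta / (Ta + kin.K_Ta)

    prod = np.zeros_like(v)
    loss = np.zeros_like(v)

    # MCP-1: secreted by apoptotic SMCs, internalized by macrophages, decays
    prod[_P] = kin.lam_PS * m_sat * S
    loss[_P] = kin.d_PM * M / (P + kin.K_P) + kin.d_P

    # macrophages: IFN-gamma activation enhanced by TNF-alpha, death
    prod[_M] = kin.lam_MIg * M * Ig / (Ig + kin.K_Ig) * ta_enh_M
    loss[_M] = kin.d_M

    # T cells: activation by macrophage contact in IL-12 (IL-10 inhibited)
    prod[_T] = kin.lam_T * I12 * i10_inh * M
    loss[_T] = kin.d_T

    # SMCs: source, macrophage-induced apoptosis, death (media only)
    if not chi_A:
        prod[_S] = kin.lam_S
        loss[_S] = kin.d_SM * m_sat + kin.d_S

    # cytokines
    prod[_I6] = kin.lam_I6M * M + kin.lam_I6S * S
    loss[_I6] = kin.d_I6
    prod[_I10] = kin.lam_I10M * M
    loss[_I10] = kin.d_I10
    prod[_I12] = kin.lam_I12M * M * i10_inh
    loss[_I12] = kin.d_I12
    prod[_TA] = kin.lam_TaM * M * i10_inh
    loss[_TA] = kin.d_Ta
    prod[_IG] = kin.lam_IgT * T
    loss[_IG] = kin.d_Ig

    # MMP / TIMP with mutual binding depletion
    prod[_Q] = (kin.lam_QM * M + kin.lam_QS * S) * ta_enh_Q
    loss[_Q] = kin.d_QQr * Qr + kin.d_Q
    prod[_QR] = kin.lam_QrM * M
    loss[_QR] = kin.d_QrQ * Q + kin.d_Qr

    # ECM: logistic production clamped at saturation, MMP-mediated loss
    prod[_RHO] = (kin.lam_rf * chi_A + kin.lam_rS * S) * np.maximum(1.0 - rho / kin.rho_0, 0.0)
    loss[_RHO] = kin.d_r + kin.d_rQ * Q

    return prod, loss


def reaction_rates(z, kin: KineticParams, chi_A: int | None = None) -> np.ndarray:
    """All non-transport right-hand-side terms F(Z) of the species network.

    ``z`` is a :class:`SpeciesState` or a (12, ...) array (then ``chi_A``
    selects the subdomain).  Negative inputs are rejected; the transport
    solver clamps before calling.
    """
    v, tag = _as_values(z)
    prod, loss = split_rates(z, kin, chi_A)
    return prod - loss * v


def chemotactic_flux(M, grad_P, grad_I6, chi_C: float) -> np.ndarray:
    """Keller-Segel-type macrophage flux M * chi_C * (grad P + grad I6).

    ``grad_P``/``grad_I6`` are gradient vectors (components on the last
    axis); the transport operator subtracts the divergence of the returned
    flux (g cm^-2 day^-1).
    """
    M = np.asarray(M, dtype=float)
    g = np.asarray(grad_P, dtype=float) + np.asarray(grad_I6, dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("chemoattractant gradients must be finite")
    return (M[..., None] * chi_C * g) if M.ndim else M * chi_C * g


_BOUNDARIES = ("Gamma_B", "Gamma_A", "Gamma_M_media", "Gamma_M_adventitia")


def robin_coefficients(species_id, boundary_id, z_local=None, z_across=None,
                       kin: KineticParams | None = None):
    """Exchange law for one (species, boundary) pair.

    Encodes every boundary/interface condition as an outgoing flux
    ``-rate * (X - external)`` used directly in the weak form:

    * macrophages on Gamma_B / Gamma_A: MCP-1-gated influx
      rate = alpha_M * P/(P+K_P) against blood density M_0 (``z_local``
      supplies the local MCP-1 value, scalar or array);
    * T cells on Gamma_B / Gamma_A: rate alpha_T against T_0;
    * MCP-1 and IL-6 on Gamma_B only: rates alpha_P, alpha_I6 against the
      serum levels P_0, I6_0;
    * media/adventitia interface: gamma_cell for cells, gamma_cytokine for
      cytokines and MMP/TIMP, against the one-sided value across
      (``z_across``); SMCs are no-flux there;
    * ECM is continuous across the interface (handled structurally as a
      single shared field, so no Robin jump: returns zero-flux here);
    * every other pair is zero-flux.

    Returns ``(rate, external_value)``; rate has cm^-1 units acting as an
    exchange velocity in the discrete weak form.
    """
    if kin is None:
        kin = KineticParams()
    if species_id not in SPECIES_INDEX:
        raise ValueError(f"unknown species id {species_id!r}")
    if boundary_id not in _BOUNDARIES:
        raise ValueError(f"unknown boundary id {boundary_id!r}")

    interface = boundary_id.startswith("Gamma_M")
    if interface:
        if species_id in CELLS:
            across = 0.0 if z_across is None else z_across
            return kin.gamma_cell, across
        if species_id in CYTOKINES:
            across = 0.0 if z_across is None else z_across
            return kin.gamma_cytokine, across
        # smc: no-flux; ecm: continuous (shared field, no jump term)
        return 0.0, 0.0

    if species_id == "mac":
        if z_local is None:
            raise ValueError("macrophage influx needs the local MCP-1 value (z_local)")
        P = np.asarray(z_local, dtype=float)
        rate = kin.alpha_M * P / (P + kin.K_P)
        return (float(rate) if rate.ndim == 0 else rate), kin.M_0
    if species_id == "tcell":
        return kin.alpha_T, kin.T_0
    if boundary_id == "Gamma_B":
        if species_id == "mcp1":
            return kin.alpha_P, kin.P_0
        if species_id == "il6":
            return kin.alpha_I6, kin.I6_0
    return 0.0, 0.0


def wellmixed_rhs(z_media, z_adventitia, kin: KineticParams,
                  sv: dict[str, float]):
    """Two-compartment (media, adventitia) reduction of the species network.

    Diffusion is replaced by interface exchange gamma*(X_other - X) and
    boundary exchange rate*(X_0 - X), each scaled by the compartment's
    surface-to-volume ratio.  ``sv`` supplies those ratios (cm^-1):
    ``B_media`` (= |Gamma_B|/area(media)), ``M_media``, ``M_adv``,
    ``A_adv``.  Returns the paired source vectors (media, adventitia).
    """
    for key in ("B_media", "M_media", "M_adv", "A_adv"):
        if sv.get(key, 0.0) <= 0:
            raise ValueError(f"surface-to-volume ratio {key!r} must be positive")
    zm, _ = _as_values(z_media)
    za, _ = _as_values(z_adventitia)
    Fm = reaction_rates(zm, kin, chi_A=0)
    Fa = reaction_rates(za, kin, chi_A=1)

    def _gamma(s: str) -> float:
        if s in CELLS or s == "ecm":
            return kin.gamma_cell
        if s in CYTOKINES:
            return kin.gamma_cytokine
        return 0.0  # smc: no interface exchange

    for i, s in enumerate(SPECIES):
        g = _gamma(s)
        Fm[i] += sv["M_media"] * g * (za[i] - zm[i])
        Fa[i] += sv["M_adv"] * g * (zm[i] - za[i])

    # blood-side exchange: media sees Gamma_B, adventitia sees Gamma_A
    for s in ("mac", "tcell", "mcp1", "il6"):
        i = SPECIES_INDEX[s]
        rate, ext = robin_coefficients(s, "Gamma_B", z_local=zm[_P], kin=kin)
        Fm[i] += sv["B_media"] * rate * (ext - zm[i])
    for s in ("mac", "tcell"):
        i = SPECIES_INDEX[s]
        rate, ext = robin_coefficients(s, "Gamma_A", z_local=za[_P], kin=kin)
        Fa[i] += sv["A_adv"] * rate * (ext - za[i])
    return Fm, Fa
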