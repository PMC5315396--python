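"""Model constants: kinetic network rates, transport/exchange coefficients,
and wall material parameters, with the literature-to-parameter arithmetic
used to derive the non-tabulated ones.

All kinetic quantities are in the (g, cm, day) system; mechanical moduli and
pressures are in N/cm^2 (see :mod:`aawall.units`).  A handful of constants
are not available in the source literature and are closed by explicit,
documented assumptions; they are flagged with provenance ``"assumed"`` in
:func:`load_parameters` output and are ordinary config keys.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from typing import Any, Mapping

from . import units
from .units import convert_pressure

__all__ = [
    "KineticParams",
    "MechanicalParams",
    "ParameterSet",
    "ParameterError",
    "load_parameters",
    "derive_il6_production_rates",
    "derive_elastic_coefficients",
    "derive_pressure_params",
    "close_smc_source",
    "parameter_report",
]


class ParameterError(ValueError):
    """Unknown parameter name, or a value violating a sign/positivity rule."""


# cellular diffusivity shared by macrophages, T cells, SMCs (cm^2/day)
_D_CELL = 8.64e-7


@dataclass
class KineticParams:
    """Kinetic, transport and boundary-exchange constants.

    Rates are day^-1 unless the hosting equation dictates otherwise
    (binding rates cm^3 g^-1 day^-1, lam_S g cm^-3 day^-1, chemotaxis
    cm^5 g^-1 day^-1, exchange coefficients cm^-1 acting as written in the
    discrete weak form).
    """

    # --- diffusion coefficients, cm^2/day ---
    D_mcp1: float = 1.728e-1
    D_mac: float = _D_CELL
    D_tcell: float = _D_CELL
    D_smc: float = _D_CELL
    D_il6: float = 1.08e-2
    D_il10: float = 1.08e-2
    D_il12: float = 1.08e-2
    D_tnfa: float = 1.29e-2
    D_ifng: float = 1.08e-2
    D_mmp: float = 4.32e-2
    D_timp: float = 4.32e-2
    # ECM is quasi-immobile; no literature value, set to the cellular scale.
    D_ecm: float = _D_CELL

    # --- production / activation rates ---
    lam_PS: float = 3.0e-3       # MCP-1 from apoptotic SMCs
    lam_MIg: float = 0.005       # macrophage activation by IFN-gamma
    lam_MTa: float = 1.0         # TNF-alpha enhancement amplitude (assumed)
    lam_T: float = 6.0e-4        # Th1 activation by IL-12 + macrophage contact
    lam_S: float | None = None   # SMC source; closed as d_S*S0 if left None
    lam_I6M: float = 1.73e-6
    lam_I6S: float = 1.73e-5
    lam_I10M: float = 2.0e-3
    lam_I12M: float = 3.78e-3
    lam_TaM: float = 2.86e-3
    lam_IgT: float = 2.34e-6
    lam_QM: float = 3.0e-4
    lam_QS: float = 2.16e-5
    lam_QTa: float = 2.0
    lam_QrM: float = 6.0e-5
    lam_rf: float = 3.0e-4       # ECM from fibroblasts (adventitia)
    lam_rS: float = 1.0e-1       # ECM from SMCs (media)

    # --- degradation / death / internalization rates ---
    d_P: float = 1.73
    d_PM: float = 2.08e-4
    d_M: float = 0.015
    d_T: float = 0.197           # T-cell death rate (assumed; not tabulated)
    d_S: float = 0.86
    d_SM: float = 1.72
    d_I6: float = 0.173
    d_I10: float = 16.64
    d_I12: float = 1.188
    d_Ta: float = 55.45
    d_Ig: float = 0.69
    d_Q: float = 4.32
    d_Qr: float = 21.6
    d_r: float = 0.37
    # binding rates, cm^3 g^-1 day^-1
    d_QQr: float = 4.98e8
    d_QrQ: float = 1.04e9
    d_rQ: float = 2.59e7

    # --- saturation constants, g/cm^3 ---
    K_M: float = 5.0e-5
    K_P: float = 5.0e-9
    K_Ig: float = 1.0e-11
    K_I10: float = 2.0e-7
    K_Ta: float = 5.0e-7

    # --- chemotaxis, carrying capacity ---
    chi_C: float = 10.0          # cm^5 g^-1 day^-1, shared by MCP-1 and IL-6
    rho_0: float = 1.0e-3        # ECM saturation, g/cm^3

    # --- boundary sources, g/cm^3 ---
    M_0: float = 5.0e-5
    T_0: float = 1.0e-3
    P_0: float = 3.0e-10
    I6_0: float = 6.0e-9         # serum IL-6 (the biomarker input)
    S_0: float = 6.0e-3

    # --- influx / transmission coefficients (cm^-1 in the weak form) ---
    alpha_M: float = 0.2
    alpha_T: float = 0.2
    alpha_P: float = 0.2
    alpha_I6: float = 0.2
    # species-class-specific transmission across the media/adventitia
    # membrane (the tabulated generic 0.1 cm^-1 is superseded by these).
    gamma_cell: float = 50.0
    gamma_cytokine: float = 500.0

    def __post_init__(self) -> None:
        if self.lam_S is None:
            self.lam_S = close_smc_source(self.d_S, self.S_0)
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ParameterError(f"parameter {f.name} must be nonnegative, got {v}")
        for f in fields(self):
            if f.name.startswith("D_") and getattr(self, f.name) <= 0:
                raise ParameterError(f"diffusion coefficient {f.name} must be positive")
        if self.gamma_cell <= 0 or self.gamma_cytokine <= 0:
            raise ParameterError("interface transmission coefficients must be positive")


@dataclass
class MechanicalParams:
    """Hyperelastic wall constants (N/cm^2) and the surface-tension scale.

    The moduli law beta_i(S) = beta_i0 + k_i (S/S0 - 1) must stay positive
    over the simulated S range; positivity at the disease calibration point
    S = S0/2 is enforced at load time, positivity along a run is enforced by
    the solver.
    """

    beta_10: float = 17.4
    beta_20: float = 188.1
    k_1: float = 30.4
    k_2: float = 84.0
    beta_p: float = 18.0
    p_star: float = 37.0
    # reference ECM density in the pressure law; taken equal to the initial
    # ECM value (distinct from the saturation rho_0)
    rho_star: float = 3.43e-4
    p_B_mmHg: float = 110.0
    # surface tension on the free boundaries, N/cm (assumed; not tabulated)
    gamma_surf: float = 1.0e-2
    S_0: float = 6.0e-3
    # use the variationally consistent stress coefficient 2*beta1+4*beta2(.)
    # (False reproduces the halved coefficient printed with the pulled-back
    # stress in the source's numerical-methods section)
    full_stress_coefficient: bool = True

    def __post_init__(self) -> None:
        if self.p_B_mmHg <= 0:
            raise ParameterError("blood pressure must be positive")
        if self.beta_10 - self.k_1 / 2 <= 0 or self.beta_20 - self.k_2 / 2 <= 0:
            raise ParameterError(
                "elastic moduli must stay positive at the disease state S = S0/2"
            )

    @property
    def p_B(self) -> float:
        """Blood pressure in N/cm^2."""
        return convert_pressure(self.p_B_mmHg, "mmHg", "N/cm^2")


@dataclass
class ParameterSet:
    """A fully populated parameter set with override provenance.

    Unpacks as ``kin, mech = params`` for convenience.
    """

    kinetic: KineticParams = field(default_factory=KineticParams)
    mechanical: MechanicalParams = field(default_factory=MechanicalParams)
    provenance: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter((self.kinetic, self.mechanical))

    def dump(self) -> dict[str, dict[str, Any]]:
        """Machine-readable dump: name -> {value, provenance}."""
        out: dict[str, dict[str, Any]] = {}
        for obj in (self.kinetic, self.mechanical):
            for f in fields(obj):
                out[f.name] = {
                    "value": getattr(obj, f.name),
                    "provenance": self.provenance.get(f.name, "default"),
                }
        return out

    def to_json(self) -> str:
        return json.dumps(self.dump(), indent=1, sort_keys=True)


_KIN_FIELDS = {f.name for f in fields(KineticParams)}
_MECH_FIELDS = {f.name for f in fields(MechanicalParams)}
# S_0 lives in both dataclasses; overrides are applied to both.


def load_parameters(config: Mapping[str, Any] | None = None) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from defaults plus overrides.

    ``config`` maps parameter names (dataclass field names) to values; any
    unknown key or sign violation raises :class:`ParameterError` naming the
    offending key.
    """
    config = dict(config or {})
    kin_over: dict[str, Any] = {}
    mech_over: dict[str, Any] = {}
    for key, value in config.items():
        known = False
        if key in _KIN_FIELDS:
            kin_over[key] = value
            known = True
        if key in _MECH_FIELDS:
            mech_over[key] = value
            known = True
        if not known:
            raise ParameterError(f"unknown parameter name: {key!r}")
    try:
        kin = KineticParams(**kin_over)
        mech = MechanicalParams(**mech_over)
    except ParameterError:
        raise
    except TypeError as exc:  # pragma: no cover - defensive
        raise ParameterError(str(exc)) from exc
    prov = {k: "override" for k in config}
    for name in ("lam_MTa", "d_T", "D_ecm", "gamma_surf"):
        prov.setdefault(name, "assumed")
    prov.setdefault("lam_S", "derived (steady-state closure d_S*S_0)")
    return ParameterSet(kin, mech, prov)


# ---------------------------------------------------------------------------
# literature-to-parameter derivations
# ---------------------------------------------------------------------------

def derive_il6_production_rates(
    assay_M: tuple[float, float],
    assay_S: tuple[float, float],
    d_I6: float,
) -> tuple[float, float]:
    """IL-6 production rates from cell-culture assays at steady state.

    Each assay is ``(cell_density, il6_level)`` in g/cm^3 (the caller applies
    the 1e6 cells/ml = 1e-3 g/cm^3 convention).  Steady state of the IL-6
    balance, lam*X - d_I6*I6 = 0, gives lam = d_I6 * I6 / X per assay.
    """
    rates = []
    for cell, il6 in (assay_M, assay_S):
        if cell <= 0:
            raise ParameterError("assay cell density must be strictly positive")
        rates.append(d_I6 * il6 / cell)
    return rates[0], rates[1]


def derive_elastic_coefficients(
    beta_dis: float, beta_healthy: float, S_fraction: float
) -> float:
    """Modulus degradation slope k from healthy/diseased moduli (N/mm^2 in).

    Solves beta_dis = beta_healthy + k (S_fraction - 1) for k, then converts
    the result to N/cm^2.  ``S_fraction`` is the diseased SMC density as a
    fraction of its healthy value (the calibration uses 1/2).
    """
    if not 0 < S_fraction < 1:
        raise ParameterError("S_fraction must lie strictly between 0 and 1")
    k_n_mm2 = (beta_healthy - beta_dis) / (1.0 - S_fraction)
    return convert_pressure(k_n_mm2, "N/mm^2", "N/cm^2")


def derive_pressure_params(
    stress_range_healthy: tuple[float, float],
    stress_range_aaa: tuple[float, float],
    ecm_fraction: float,
) -> tuple[float, float]:
    """(p*, beta_p) from peak-wall-stress ranges (N/cm^2).

    p* is the midpoint of the healthy range; beta_p solves
    p* - beta_p (1 - ecm_fraction) = midpoint of the AAA range, where
    ``ecm_fraction`` is the diseased ECM as a fraction of reference.
    """
    if not 0 < ecm_fraction < 1:
        raise ParameterError("ecm_fraction must lie strictly between 0 and 1")
    p_star = 0.5 * (stress_range_healthy[0] + stress_range_healthy[1])
    p_aaa = 0.5 * (stress_range_aaa[0] + stress_range_aaa[1])
    beta_p = (p_star - p_aaa) / (1.0 - ecm_fraction)
    return p_star, beta_p


def close_smc_source(d_S: float, S_0: float) -> float:
    """SMC source lam_S = d_S * S_0 (g cm^-3 day^-1).

    Chosen so that S = S_0 is the macrophage-free steady state of the SMC
    balance: with M = 0 the apoptosis term vanishes and
    lam_S - d_S S = 0 at S = S_0.
    """
    return d_S * S_0


def parameter_report() -> dict[str, float]:
    """Recompute the derived constants from their printed literature inputs.

    Returns the quantities exactly as the derivation arithmetic produces
    them; used by the ``check-params`` CLI subcommand.
    """
    lam_I6M, lam_I6S = derive_il6_production_rates(
        assay_M=(
            units.cells_per_ml_to_g_per_cm3(1.0e6),
            units.ng_per_ml_to_g_per_cm3(10.0),
        ),
        assay_S=(
            units.cells_per_ml_to_g_per_cm3(4.0e4),
            units.ng_per_ml_to_g_per_cm3(4.0),
        ),
        d_I6=0.173,
    )
    k_1 = derive_elastic_coefficients(0.022, 0.174, 0.5)
    k_2 = derive_elastic_coefficients(1.461, 1.881, 0.5)
    p_star, beta_p = derive_pressure_params((30.0, 44.0), (28.0, 37.0), 0.75)
    kin = KineticParams()
    return {
        "lam_I6M": lam_I6M,
        "lam_I6S": lam_I6S,
        "k_1": k_1,
        "k_2": k_2,
        "p_star": p_star,
        "beta_p": beta_p,
        "lam_S": close_smc_source(kin.d_S, kin.S_0),
        "p_B_N_per_cm2": convert_pressure(110.0, "mmHg", "N/cm^2"),
    }
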