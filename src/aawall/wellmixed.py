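"""Spatially homogeneous two-compartment reduction of the wall network.

Used for fast verification of the kinetics, steady-state analysis and
parameter sanity checks: diffusion is replaced by interface/boundary
exchange scaled by surface-to-volume ratios of the reference geometry,
and the 24 coupled ODEs are integrated with a stiff implicit scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import root

from . import geometry
from .kinetics import SPECIES, SPECIES_INDEX, wellmixed_rhs
from .params import KineticParams, ParameterSet

__all__ = [
    "CompartmentState",
    "default_sv_ratios",
    "integrate_wellmixed",
    "find_steady_state",
    "initial_conditions",
]


@dataclass
class CompartmentState:
    """Paired (media, adventitia) species vectors with exchange geometry."""

    z_media: np.ndarray
    z_adv: np.ndarray
    sv: dict = field(default_factory=dict)

    def __post_init__(self):
        self.z_media = np.asarray(self.z_media, dtype=float)
        self.z_adv = np.asarray(self.z_adv, dtype=float)
        if self.z_media.shape != (12,) or self.z_adv.shape != (12,):
            raise ValueError("compartment states must be 12-vectors")
        if np.any(self.z_media < 0) or np.any(self.z_adv < 0):
            raise ValueError("species must be nonnegative")
        self.z_adv[SPECIES_INDEX["smc"]] = 0.0

    def stacked(self):
        return np.concatenate([self.z_media, self.z_adv])


def default_sv_ratios(R0: float = 2.0) -> dict:
    """Boundary-length/area ratios of the reference bulge geometry."""
    geom = geometry.build_initial_geometry(R0)
    return geometry.surface_to_volume_ratios(geom)


def initial_conditions(kin: KineticParams, sv: dict | None = None) -> CompartmentState:
    """Healthy-wall initial state: S = S0, ECM/MMP/TIMP at their reference
    values, IL-6 at half the serum level, all immune fields zero."""
    sv = sv or default_sv_ratios()
    z = np.zeros(12)
    z[SPECIES_INDEX["il6"]] = kin.I6_0 / 2.0
    z[SPECIES_INDEX["mmp"]] = 3.0e-8
    z[SPECIES_INDEX["timp"]] = 1.0e-8
    z[SPECIES_INDEX["ecm"]] = 3.43e-4
    zm = z.copy()
    zm[SPECIES_INDEX["smc"]] = kin.S_0
    return CompartmentState(zm, z.copy(), sv)


def _rhs_stacked(y, kin, sv, frozen=None):
    # clamp to the physical range so root-finder excursions stay finite
    zm = np.clip(y[:12], 0.0, 1e3)
    za = np.clip(y[12:], 0.0, 1e3)
    Fm, Fa = wellmixed_rhs(zm, za, kin, sv)
    if frozen:
        for name in frozen:
            i = SPECIES_INDEX[name]
            Fm[i] = 0.0
            Fa[i] = 0.0
    return np.concatenate([Fm, Fa])


def integrate_wellmixed(z0: CompartmentState, params, T_end: float,
                        k: float = 1.0, frozen=None) -> pd.DataFrame:
    """Integrate the two-compartment ODEs to ``T_end`` days.

    ``k`` sets the output sampling interval (days); integration itself is
    adaptive stiff (BDF).  ``frozen`` names species held constant (used by
    verification tests).  Returns a tidy frame with one column per species
    per layer, same schema as the full Trajectory minus the diameter.
    """
    kin = params.kinetic if isinstance(params, ParameterSet) else params
    if k <= 0:
        raise ValueError("sampling interval k must be positive")
    t_eval = np.arange(0.0, T_end + 0.5 * k, k)
    sol = solve_ivp(
        lambda t, y: _rhs_stacked(y, kin, z0.sv, frozen),
        (0.0, float(T_end)), z0.stacked(), method="BDF",
        t_eval=t_eval, rtol=1e-8, atol=1e-16,
    )
    if not sol.success:
        raise RuntimeError(f"stiff integration failed: {sol.message}")
    data = {"time": sol.t}
    for i, s in enumerate(SPECIES):
        data[f"avg_{s}_media"] = np.maximum(sol.y[i], 0.0)
        if s != "smc":
            data[f"avg_{s}_adventitia"] = np.maximum(sol.y[12 + i], 0.0)
    return pd.DataFrame(data)


def find_steady_state(params, z_guess: CompartmentState,
                      frozen: dict[str, float] | None = None) -> CompartmentState:
    """Root of the two-compartment right-hand side.

    ``frozen`` maps species names to clamped values (the corresponding
    equations are removed); the returned state is verified nonnegative with
    residual below 1e-12 relative to the largest rate scale.
    """
    kin = params.kinetic if isinstance(params, ParameterSet) else params
    frozen = frozen or {}
    y0 = z_guess.stacked().copy()
    for name, val in frozen.items():
        i = SPECIES_INDEX[name]
        y0[i] = val
        y0[12 + i] = val

    idx_frozen = [SPECIES_INDEX[n] for n in frozen] + \
                 [12 + SPECIES_INDEX[n] for n in frozen]
    mask = np.ones(24, dtype=bool)
    mask[idx_frozen] = False

    # relax toward the attractor first: the network spans ~10 orders of
    # magnitude, which defeats a cold Newton start
    relax = solve_ivp(
        lambda t, y: _rhs_stacked(y, kin, z_guess.sv, frozen=list(frozen)),
        (0.0, 5000.0), y0, method="BDF", rtol=1e-10, atol=1e-20,
    )
    if relax.success:
        y0[mask] = np.maximum(relax.y[:, -1], 0.0)[mask]

    def fun(x):
        y = y0.copy()
        y[mask] = x
        return _rhs_stacked(y, kin, z_guess.sv)[mask]

    sol = root(fun, y0[mask], method="hybr", tol=1e-14)
    y = y0.copy()
    y[mask] = np.maximum(sol.x, 0.0)
    res = np.max(np.abs(_rhs_stacked(y, kin, z_guess.sv)[mask]))
    scale = max(np.max(np.abs(y)), 1.0e-12)
    if res > 1e-10 * scale:
        raise RuntimeError(
            f"steady-state search did not converge (residual {res:.3e}); "
            "try a different initial guess"
        )
    y = np.where(np.abs(y) < 1e-30, 0.0, y)
    if np.any(y < -1e-20):
        raise RuntimeError("steady state has negative components")
    return CompartmentState(np.maximum(y[:12], 0.0), np.maximum(y[12:], 0.0),
                            z_guess.sv)
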