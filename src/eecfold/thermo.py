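"""Entropy-enthalpy compensation arithmetic.

Hydrogen-bond energies are stored as positive magnitudes in kcal/mol (the
bound state is negative; formulas apply the signs).  Entropies are molar,
in J mol^-1 K^-1.  The water-water term is a calibrated default chosen so
that the hydrogen-bond swap at the documented defaults gives 2.70 kcal/mol;
it is exposed like every other parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "J_PER_KCAL",
    "ThermoParams",
    "CompensationResult",
    "hbond_swap_enthalpy",
    "collapse_entropy_gain",
    "compensation",
    "compensation_ledger",
]

J_PER_KCAL = 4184.0


@dataclass(frozen=True)
class ThermoParams:
    """Bond-energy magnitudes, molar entropies and temperature.

    Attributes
    ----------
    e_nh_oc : float
        Backbone N-H to C=O hydrogen bond, kcal/mol (magnitude).
    e_nh_water : float
        Backbone N-H to water hydrogen bond, kcal/mol (magnitude).
    e_co_water : float
        Backbone C=O to water hydrogen bond, kcal/mol (magnitude).
    e_water_water : float
        Water-water hydrogen bond, kcal/mol (magnitude); calibrated default.
    s_liquid_water : float
        Standard molar entropy of bulk liquid water, J mol^-1 K^-1.
    s_ordered_water : float
        Standard molar entropy of hydration-shell (solid-like) water.
    temperature : float
        Kelvin.
    """

    e_nh_oc: float = 3.47
    e_nh_water: float = 7.65
    e_co_water: float = 4.7
    e_water_water: float = 6.18
    s_liquid_water: float = 70.0
    s_ordered_water: float = 45.0
    temperature: float = 298.0

    def __post_init__(self) -> None:
        for name in ("e_nh_oc", "e_nh_water", "e_co_water", "e_water_water"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} is a magnitude and must be >= 0")
        if self.s_liquid_water <= self.s_ordered_water:
            raise ValueError("s_liquid_water must exceed s_ordered_water")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def signed_bond_energies(self) -> dict[str, float]:
        """Bond energies with the bound-state-negative sign convention."""
        return {
            "nh_oc": -self.e_nh_oc,
            "nh_water": -self.e_nh_water,
            "co_water": -self.e_co_water,
            "water_water": -self.e_water_water,
        }


@dataclass(frozen=True)
class CompensationResult:
    """Outcome of a Gibbs compensation evaluation (energies in kcal/mol)."""

    delta_h: float
    delta_s: float  # kcal mol^-1 K^-1
    delta_g: float
    spontaneous: bool


def hbond_swap_enthalpy(p: ThermoParams | None = None) -> float:
    """Net enthalpy of forming one backbone N-H...O=C bond in water, kcal/mol.

    Bookkeeping: break the N-H/water and C=O/water bonds, form the backbone
    bond, and let the two released waters form one water-water bond.
    """
    p = p or ThermoParams()
    return p.e_nh_water + p.e_co_water - p.e_nh_oc - p.e_water_water


def collapse_entropy_gain(n_waters: int, p: ThermoParams | None = None) -> float:
    """Entropy released by expelling ordered shell waters, J mol^-1 K^-1."""
    p = p or ThermoParams()
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    return n_waters * (p.s_liquid_water - p.s_ordered_water)


def compensation(
    delta_h: float, delta_s_joules: float, p: ThermoParams | None = None
) -> CompensationResult:
    """Evaluate dG = dH - T dS with dS supplied in J mol^-1 K^-1."""
    p = p or ThermoParams()
    if not (math.isfinite(delta_h) and math.isfinite(delta_s_joules)):
        raise ValueError("compensation inputs must be finite")
    delta_s = delta_s_joules / J_PER_KCAL
    delta_g = delta_h - p.temperature * delta_s
    return CompensationResult(
        delta_h=delta_h,
        delta_s=delta_s,
        delta_g=delta_g,
        spontaneous=delta_g < 0,
    )


def compensation_ledger(
    n_waters: int = 12, p: ThermoParams | None = None
) -> dict[str, float | bool]:
    """The full swap-plus-collapse account for one backbone bond formation."""
    p = p or ThermoParams()
    dh = hbond_swap_enthalpy(p)
    ds_joules = collapse_entropy_gain(n_waters, p)
    result = compensation(dh, ds_joules, p)
    return {
        "e_nh_oc": -p.e_nh_oc,
        "e_nh_water": -p.e_nh_water,
        "e_co_water": -p.e_co_water,
        "e_water_water": -p.e_water_water,
        "delta_h_kcal": dh,
        "n_waters": n_waters,
        "delta_s_joules": ds_joules,
        "t_delta_s_kcal": p.temperature * result.delta_s,
        "delta_g_kcal": result.delta_g,
        "temperature": p.temperature,
        "spontaneous": result.spontaneous,
    }
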