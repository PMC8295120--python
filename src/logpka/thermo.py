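"""Physical constants and the two thermodynamic cycles.

The package predicts two observables from continuum-solvation free energies:

* the n-octanol/water partition coefficient of a neutral solute,

  .. math:: \\log P = -\\Delta\\Delta G^{w\\to o} / (RT\\ln 10),
            \\qquad \\Delta\\Delta G^{w\\to o} = \\Delta G_{solv}^{o} - \\Delta G_{hyd}^{w}

* the acid dissociation constant of a titratable solute via the aqueous
  deprotonation cycle HX -> X⁻ + H⁺,

  .. math:: pK_a = \\Delta G_{aq}/(RT\\ln 10),
            \\qquad \\Delta G_{aq} = G_{aq}(X^-) + G_{aq}(H^+) - G_{aq}(HX)

All free energies are in kcal/mol throughout the package; no unit detection
is attempted.  The sign convention makes positive log P octanol-preferring
(lipophilic) and ΔΔG^{w→o} negative for octanol-favoured solutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import InvalidValueError

__all__ = [
    "GAS_CONSTANT_KCAL",
    "STANDARD_TEMPERATURE",
    "ThermoConditions",
    "ProtonParameters",
    "transfer_free_energy",
    "logp_from_transfer",
    "pka_from_deprotonation",
]

#: Molar gas constant in kcal mol⁻¹ K⁻¹ (CODATA R = 8.31446 J mol⁻¹ K⁻¹).
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Conventional thermochemical temperature, kelvin.
STANDARD_TEMPERATURE = 298.15


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and gas constant defining the thermal energy scale.

    Parameters
    ----------
    temperature:
        Absolute temperature in kelvin. Default 298.15 K.
    gas_constant:
        Molar gas constant in kcal mol⁻¹ K⁻¹.
    """

    temperature: float = STANDARD_TEMPERATURE
    gas_constant: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise InvalidValueError(f"temperature must be > 0 K, got {self.temperature!r}")
        if not (math.isfinite(self.gas_constant) and self.gas_constant > 0):
            raise InvalidValueError(f"gas_constant must be > 0, got {self.gas_constant!r}")

    @property
    def rt(self) -> float:
        """Thermal energy RT in kcal/mol (0.5925 at 298.15 K)."""
        return self.gas_constant * self.temperature

    @property
    def rt_ln10(self) -> float:
        """RT·ln10 in kcal/mol: 1.3642 at 298.15 K, the free energy per log10 unit."""
        return self.rt * math.log(10.0)


@dataclass(frozen=True)
class ProtonParameters:
    """Aqueous free energy of the proton, decomposed as gas-phase free energy
    plus the 1 atm → 1 M standard-state correction plus the hydration free
    energy, all in kcal/mol.  The defaults sum to −270.29 kcal/mol, the
    experimental consensus value at 298 K.
    """

    gas_phase_free_energy: float = -6.28
    standard_state_correction: float = 1.89
    hydration_free_energy: float = -265.9

    def __post_init__(self) -> None:
        for name in ("gas_phase_free_energy", "standard_state_correction", "hydration_free_energy"):
            _require_finite(name, getattr(self, name))

    def total(self) -> float:
        """G_aq(H⁺) in kcal/mol; −270.29 with the default decomposition."""
        return (
            self.gas_phase_free_energy
            + self.standard_state_correction
            + self.hydration_free_energy
        )


def transfer_free_energy(dg_solv_octanol: float, dg_hyd_water: float) -> float:
    """Water → n-octanol transfer free energy ΔΔG^{w→o} in kcal/mol.

    ΔΔG^{w→o} = ΔG_solv(octanol) − ΔG_hyd(water).  Negative values mean the
    solute is better solvated in octanol (lipophilic).
    """
    o = _require_finite("dg_solv_octanol", dg_solv_octanol)
    w = _require_finite("dg_hyd_water", dg_hyd_water)
    return o - w


def logp_from_transfer(ddg_transfer: float, cond: ThermoConditions | None = None) -> float:
    """log10 partition coefficient from the transfer free energy.

    log P = −ΔΔG^{w→o} / (RT·ln10).  Antisymmetric in its argument and
    strictly decreasing: more negative transfer free energy, higher log P.
    """
    ddg = _require_finite("ddg_transfer", ddg_transfer)
    cond = cond or ThermoConditions()
    return -ddg / cond.rt_ln10


def pka_from_deprotonation(
    g_aq_acid: float,
    g_aq_base: float,
    proton: ProtonParameters | None = None,
    cond: ThermoConditions | None = None,
) -> float:
    """pKa from aqueous free energies of the acid (HX) and base (X⁻) species.

    ΔG_aq = G_aq(X⁻) + G_aq(H⁺) − G_aq(HX);  pKa = ΔG_aq / (RT·ln10).

    Pass ``proton=None`` with *relative* deprotonation free energies that
    already fold in the proton term (``g_aq_acid`` then typically 0).
    """
    acid = _require_finite("g_aq_acid", g_aq_acid)
    base = _require_finite("g_aq_base", g_aq_base)
    cond = cond or ThermoConditions()
    proton_total = proton.total() if proton is not None else 0.0
    dg_aq = base + proton_total - acid
    return dg_aq / cond.rt_ln10
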