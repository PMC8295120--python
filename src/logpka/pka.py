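"""Microscopic and macroscopic pKa from protonation microstates.

A *microstate* is one protonation/tautomeric form of a compound at a defined
formal charge (SAMPL nomenclature, e.g. ``SM25_micro001``), carrying the
aqueous free energies of its conformers.  A microscopic pKa connects one
acid microstate (charge q) to one base microstate (charge q−1) through the
deprotonation cycle.  The *macroscopic* (observable) pKa aggregates all
tautomers of each total-charge state through their partition functions:

.. math:: G_{macro}(q) = -RT\\ln\\!\\!\\sum_{m:\\,q_m=q}\\ \\sum_{c\\in m} e^{-G_{mc}/RT},
          \\qquad
          pK_a = \\frac{G_{macro}(q-1) + G_{aq}(H^+) - G_{macro}(q)}{RT\\ln 10}.

Pooling all conformers of a charge state flatly is algebraically identical
to first collapsing each microstate and then pooling microstates — an
invariant the test suite checks.

Two input dialects are supported.  With *absolute aqueous* free energies the
proton term :class:`~logpka.thermo.ProtonParameters` enters the cycle.  With
*relative transition* free energies (the SAMPL microstate-file dialect, each
value a deprotonation free energy relative to a reference microstate with
the proton term already folded in) the proton term is bypassed: pass
``proton=None``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .ensemble import ensemble_free_energy
from .exceptions import (
    ChargeMismatchError,
    EmptyEnsembleError,
    InvalidValueError,
    MissingChargeStateError,
)
from .thermo import ProtonParameters, ThermoConditions

__all__ = [
    "Microstate",
    "MicrostateSet",
    "PkaResult",
    "ValidationReport",
    "microstate_free_energy",
    "micro_pka",
    "macro_pka",
    "validate_microstate_table",
]


@dataclass(frozen=True)
class Microstate:
    """One protonation microstate with its conformer aqueous free energies."""

    microstate_id: str
    compound_id: str
    formal_charge: int
    conformer_free_energies: tuple[float, ...]

    def __init__(
        self,
        microstate_id: str,
        compound_id: str,
        formal_charge: int,
        conformer_free_energies: Iterable[float],
    ):
        object.__setattr__(self, "microstate_id", microstate_id)
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "formal_charge", int(formal_charge))
        g = tuple(float(x) for x in conformer_free_energies)
        object.__setattr__(self, "conformer_free_energies", g)
        if not microstate_id:
            raise InvalidValueError("microstate_id must be non-empty")
        if not g:
            raise EmptyEnsembleError(
                f"microstate {microstate_id!r} has no conformer free energies"
            )
        if not np.all(np.isfinite(g)):
            raise InvalidValueError(
                f"microstate {microstate_id!r} has non-finite free energies"
            )


@dataclass(frozen=True)
class MicrostateSet:
    """All microstates of one compound.

    ``dialect`` records how the free energies are to be read:
    ``"absolute_aqueous"`` (cycle applied with proton parameters) or
    ``"relative_transition"`` (proton bypassed, energies relative to
    ``reference_microstate``).
    """

    compound_id: str
    microstates: tuple[Microstate, ...]
    dialect: str = "absolute_aqueous"
    reference_microstate: str | None = None

    def __init__(
        self,
        compound_id: str,
        microstates: Iterable[Microstate],
        dialect: str = "absolute_aqueous",
        reference_microstate: str | None = None,
    ):
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "microstates", tuple(microstates))
        object.__setattr__(self, "dialect", dialect)
        object.__setattr__(self, "reference_microstate", reference_microstate)
        if not self.microstates:
            raise EmptyEnsembleError(f"compound {compound_id!r} has no microstates")
        ids = [m.microstate_id for m in self.microstates]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidValueError(
                f"compound {compound_id!r} has duplicate microstate ids: {dup}"
            )
        if dialect not in ("absolute_aqueous", "relative_transition"):
            raise InvalidValueError(f"unknown microstate dialect {dialect!r}")

    def charges(self) -> list[int]:
        return sorted({m.formal_charge for m in self.microstates})

    def at_charge(self, charge: int) -> list[Microstate]:
        return [m for m in self.microstates if m.formal_charge == charge]

    def get(self, microstate_id: str) -> Microstate:
        for m in self.microstates:
            if m.microstate_id == microstate_id:
                return m
        raise KeyError(f"compound {self.compound_id!r}: no microstate {microstate_id!r}")


@dataclass(frozen=True)
class PkaResult:
    """Macroscopic pKa with its microscopic and charge-state breakdown."""

    compound_id: str
    macro_pka: float
    micro_pkas: dict[tuple[str, str], float]
    charge_state_free_energies: dict[int, float]


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of recomputing a macroscopic pKa from a microstate table."""

    compound_id: str
    recomputed_macro_pka: float
    reported_macro_pka: float
    discrepancy: float
    flagged: bool
    tolerance: float
    microstate_free_energies: dict[str, float] = field(default_factory=dict)


def microstate_free_energy(m: Microstate, cond: ThermoConditions | None = None) -> float:
    """Boltzmann (log-sum-exp) ensemble free energy over the microstate's
    conformers; equals the single value for one conformer and G − RT·ln n
    for n degenerate conformers."""
    return ensemble_free_energy(m.conformer_free_energies, cond)


def micro_pka(
    acid: Microstate,
    base: Microstate,
    proton: ProtonParameters | None = None,
    cond: ThermoConditions | None = None,
) -> float:
    """Microscopic pKa between one acid and one base microstate.

    The base must carry exactly one fewer positive charge than the acid.
    Each microstate enters through its conformer-ensemble free energy, so
    adding a degenerate conformer to the base lowers the pKa by log10 of the
    degeneracy gain.
    """
    if base.formal_charge != acid.formal_charge - 1:
        raise ChargeMismatchError(
            f"base {base.microstate_id!r} (q={base.formal_charge}) must have charge "
            f"one below acid {acid.microstate_id!r} (q={acid.formal_charge})"
        )
    cond = cond or ThermoConditions()
    g_acid = microstate_free_energy(acid, cond)
    g_base = microstate_free_energy(base, cond)
    proton_total = proton.total() if proton is not None else 0.0
    return (g_base + proton_total - g_acid) / cond.rt_ln10


def _charge_state_free_energy(
    ms: MicrostateSet, charge: int, cond: ThermoConditions
) -> float:
    pool = [g for m in ms.at_charge(charge) for g in m.conformer_free_energies]
    if not pool:
        raise MissingChargeStateError(ms.compound_id, charge)
    return ensemble_free_energy(pool, cond)


def macro_pka(
    ms: MicrostateSet,
    acid_charge: int = 0,
    proton: ProtonParameters | None = None,
    cond: ThermoConditions | None = None,
) -> PkaResult:
    """Macroscopic pKa between charge states ``acid_charge`` and
    ``acid_charge − 1``.

    The free energy of each charge state is the log-sum-exp pool over all
    conformers of all its microstates (flat pooling, identical to collapsing
    microstates first).  ``micro_pkas`` is populated for every acid/base
    microstate pair.  For the absolute-aqueous dialect pass the proton
    parameters; for the relative-transition dialect pass ``proton=None``.
    """
    cond = cond or ThermoConditions()
    if ms.dialect == "relative_transition" and proton is not None:
        raise InvalidValueError(
            "relative_transition free energies already include the proton term; "
            "pass proton=None"
        )
    g_acid_state = _charge_state_free_energy(ms, acid_charge, cond)
    g_base_state = _charge_state_free_energy(ms, acid_charge - 1, cond)
    proton_total = proton.total() if proton is not None else 0.0
    macro = (g_base_state + proton_total - g_acid_state) / cond.rt_ln10
    micro = {
        (a.microstate_id, b.microstate_id): micro_pka(a, b, proton, cond)
        for a in ms.at_charge(acid_charge)
        for b in ms.at_charge(acid_charge - 1)
    }
    return PkaResult(
        compound_id=ms.compound_id,
        macro_pka=macro,
        micro_pkas=micro,
        charge_state_free_energies={
            acid_charge: g_acid_state,
            acid_charge - 1: g_base_state,
        },
    )


def validate_microstate_table(
    ms: MicrostateSet,
    reported_macro_pka: float,
    tol: float = 0.10,
    acid_charge: int = 0,
    proton: ProtonParameters | None = None,
    cond: ThermoConditions | None = None,
) -> ValidationReport:
    """Recompute the macroscopic pKa from a microstate table and flag a
    discrepancy larger than ``tol`` pKa units against the reported value.

    This is the consistency check a challenge organiser runs on a submitted
    microstate file: a swapped or misweighted microstate shows up as a
    recomputed macroscopic pKa that disagrees with the submitted one.  The
    report carries both values and the per-microstate ensemble free
    energies; it never raises on a discrepancy.
    """
    if not tol > 0:
        raise InvalidValueError(f"tol must be > 0, got {tol}")
    cond = cond or ThermoConditions()
    result = macro_pka(ms, acid_charge, proton, cond)
    discrepancy = result.macro_pka - float(reported_macro_pka)
    return ValidationReport(
        compound_id=ms.compound_id,
        recomputed_macro_pka=result.macro_pka,
        reported_macro_pka=float(reported_macro_pka),
        discrepancy=discrepancy,
        flagged=abs(discrepancy) > tol,
        tolerance=tol,
        microstate_free_energies={
            m.microstate_id: microstate_free_energy(m, cond) for m in ms.microstates
        },
    )
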