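"""Boltzmann statistics over conformer ensembles.

A compound's observable free energy in a solvent is not that of its best
conformer but of the whole low-energy ensemble,

.. math:: G_{ens} = -RT \\ln \\sum_i e^{-G_i/RT},

the log-sum-exp (partition-function) aggregate of the per-conformer total
free energies G_i = E_gas + G_therm(solvent) + ΔG_solv(solvent).  log P of a
compound is then the difference of its water and octanol ensemble free
energies divided by RT·ln10.  All log-sum-exp evaluations are max-shifted
(via :func:`scipy.special.logsumexp`) so any finite input is safe from
overflow; this is a documented contract, not a caller burden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .exceptions import (
    EmptyEnsembleError,
    InvalidValueError,
    MissingComponentError,
)
from .thermo import ThermoConditions, logp_from_transfer

__all__ = [
    "WATER",
    "OCTANOL",
    "ConformerRecord",
    "CompoundEnsemble",
    "BoltzmannResult",
    "LogPResult",
    "total_free_energy",
    "boltzmann_weights",
    "ensemble_free_energy",
    "compound_logp",
    "prune_redundant",
]

WATER = "water"
OCTANOL = "octanol"

AggregationMode = Literal["free_energy", "weighted_mean"]


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer's free-energy components, per solvent, in kcal/mol.

    ``thermal_correction`` and ``solvation_free_energy`` map a solvent label
    (``"water"``, ``"octanol"``) to the thermal correction computed in that
    solvent and the solvation free energy from the gas-phase single point.
    A solvent may be absent from both maps (e.g. octanol in a pKa-only
    dataset) but must be present in both when it is used.
    """

    conformer_id: str
    gas_energy: float
    thermal_correction: Mapping[str, float] = field(default_factory=dict)
    solvation_free_energy: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.conformer_id:
            raise InvalidValueError("conformer_id must be non-empty")
        values = [self.gas_energy]
        values += list(self.thermal_correction.values())
        values += list(self.solvation_free_energy.values())
        if not np.all(np.isfinite(values)):
            raise InvalidValueError(
                f"conformer {self.conformer_id!r} has non-finite free-energy components"
            )

    def has_solvent(self, solvent: str) -> bool:
        return solvent in self.thermal_correction and solvent in self.solvation_free_energy


@dataclass(frozen=True)
class CompoundEnsemble:
    """A compound's set of conformers (at least one, ids unique)."""

    compound_id: str
    conformers: tuple[ConformerRecord, ...]

    def __init__(self, compound_id: str, conformers: Iterable[ConformerRecord]):
        object.__setattr__(self, "compound_id", compound_id)
        object.__setattr__(self, "conformers", tuple(conformers))
        if not self.conformers:
            raise EmptyEnsembleError(f"compound {compound_id!r} has no conformers")
        ids = [c.conformer_id for c in self.conformers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise InvalidValueError(
                f"compound {compound_id!r} has duplicate conformer ids: {dup}"
            )

    def __len__(self) -> int:
        return len(self.conformers)


@dataclass(frozen=True)
class BoltzmannResult:
    """Per-conformer populations and the ensemble free energy in one solvent."""

    weights: dict[str, float]
    ensemble_free_energy: float


@dataclass(frozen=True)
class LogPResult:
    """Compound log P with the per-solvent Boltzmann analysis attached."""

    compound_id: str
    logp: float
    water: BoltzmannResult
    octanol: BoltzmannResult


def total_free_energy(conf: ConformerRecord, solvent: str, compound_id: str = "?") -> float:
    """Total free energy of one conformer in a solvent:
    gas-phase energy + thermal correction(solvent) + ΔG_solv(solvent)."""
    if not conf.has_solvent(solvent):
        raise MissingComponentError(compound_id, conf.conformer_id, solvent)
    return (
        conf.gas_energy
        + conf.thermal_correction[solvent]
        + conf.solvation_free_energy[solvent]
    )


def _as_energy_array(free_energies: Sequence[float]) -> np.ndarray:
    g = np.asarray(free_energies, dtype=float)
    if g.size == 0:
        raise EmptyEnsembleError("ensemble has no conformers")
    if not np.all(np.isfinite(g)):
        raise InvalidValueError("conformer free energies must be finite")
    return g


def boltzmann_weights(
    free_energies: Sequence[float], cond: ThermoConditions | None = None
) -> np.ndarray:
    """Boltzmann populations w_i = exp(−G_i/RT) / Σ_j exp(−G_j/RT).

    Order-preserving; computed through a max-shifted softmax so any finite
    input is overflow-safe.  The weights sum to 1 to machine precision.
    """
    g = _as_energy_array(free_energies)
    cond = cond or ThermoConditions()
    x = -g / cond.rt
    x -= x.max()
    w = np.exp(x)
    return w / w.sum()


def ensemble_free_energy(
    free_energies: Sequence[float], cond: ThermoConditions | None = None
) -> float:
    """Ensemble (partition-function) free energy −RT·ln Σ exp(−G_i/RT).

    Equals G for a single conformer and G − RT·ln n for n degenerate
    conformers; always ≤ the minimum conformer free energy.
    """
    g = _as_energy_array(free_energies)
    cond = cond or ThermoConditions()
    return float(-cond.rt * logsumexp(-g / cond.rt))


def _phase_result(
    ens: CompoundEnsemble,
    solvent: str,
    cond: ThermoConditions,
    aggregation: AggregationMode,
) -> BoltzmannResult:
    g = np.array(
        [total_free_energy(c, solvent, ens.compound_id) for c in ens.conformers]
    )
    w = boltzmann_weights(g, cond)
    if aggregation == "free_energy":
        g_ens = ensemble_free_energy(g, cond)
    elif aggregation == "weighted_mean":
        # population-weighted mean total free energy; lacks the -RT ln n
        # mixing-entropy term of the partition-function aggregate
        g_ens = float(w @ g)
    else:
        raise InvalidValueError(f"unknown aggregation mode {aggregation!r}")
    weights = {c.conformer_id: float(wi) for c, wi in zip(ens.conformers, w)}
    return BoltzmannResult(weights=weights, ensemble_free_energy=g_ens)


def compound_logp(
    ens: CompoundEnsemble,
    cond: ThermoConditions | None = None,
    aggregation: AggregationMode = "free_energy",
) -> LogPResult:
    """log P of a compound from its water and octanol conformer families.

    Each phase is aggregated separately with its own Boltzmann weights
    (geometries are optimised per solvent, so no cross-phase weight sharing);
    log P = (G_ens^water − G_ens^octanol)/(RT·ln10).

    ``aggregation="weighted_mean"`` replaces the log-sum-exp aggregate with
    the population-weighted mean conformer free energy, a sensitivity check
    on the aggregation rule; the default is the partition-function-consistent
    free-energy rule.
    """
    cond = cond or ThermoConditions()
    water = _phase_result(ens, WATER, cond, aggregation)
    octanol = _phase_result(ens, OCTANOL, cond, aggregation)
    ddg = octanol.ensemble_free_energy - water.ensemble_free_energy
    return LogPResult(
        compound_id=ens.compound_id,
        logp=logp_from_transfer(ddg, cond),
        water=water,
        octanol=octanol,
    )


def prune_redundant(
    ens: CompoundEnsemble, solvent: str, energy_tol: float = 1e-6
) -> CompoundEnsemble:
    """Drop energetically redundant conformers.

    Conformers whose total free energies in ``solvent`` fall within
    ``energy_tol`` of each other (groups with max−min ≤ tol, formed upward
    from the global minimum) are collapsed to one representative: the
    lowest-energy member, ties broken by lexicographically smallest
    conformer id.  The global minimum is never removed.  ``energy_tol = 0``
    returns the ensemble unchanged.  This is an energy-window surrogate for
    visual/geometric redundancy pruning; geometries are not part of the data
    model.
    """
    if energy_tol < 0:
        raise InvalidValueError(f"energy_tol must be >= 0, got {energy_tol}")
    if energy_tol == 0 or len(ens) == 1:
        return ens
    energies = {
        c.conformer_id: total_free_energy(c, solvent, ens.compound_id)
        for c in ens.conformers
    }
    # sort by (energy, id) so each group's first member is its representative
    ordered = sorted(ens.conformers, key=lambda c: (energies[c.conformer_id], c.conformer_id))
    keep_ids: set[str] = set()
    group_min: float | None = None
    for conf in ordered:
        e = energies[conf.conformer_id]
        if group_min is None or e - group_min > energy_tol:
            keep_ids.add(conf.conformer_id)
            group_min = e
    kept = [c for c in ens.conformers if c.conformer_id in keep_ids]
    return CompoundEnsemble(ens.compound_id, kept)
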