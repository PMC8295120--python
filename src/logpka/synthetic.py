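"""Synthetic conformer/microstate free-energy datasets with known truth.

The quantum-chemistry stage that would normally produce per-conformer free
energies is expensive and out of scope; this module emits datasets with the
same shape — multi-conformer ensembles in water and n-octanol, multi-tautomer
protonation microstates in water — whose Boltzmann aggregates hit exact,
known log P and macroscopic pKa targets, so the full downstream pipeline can
be exercised and checked to machine precision.

Truth embedding works by shift covariance of the log-sum-exp free energy:
after drawing all components at plausible magnitudes, the octanol solvation
column (for log P) and the anion aqueous free energies (for pKa) are
translated by the analytically solved constant that places the ensemble
aggregate exactly on target.  Gaussian noise of a chosen standard deviation
is then added to every emitted component, mimicking method error in the
underlying free energies.

Validation-scenario builders at the bottom reproduce, with synthetic
energies, the two bookkeeping error classes that matter in blind-challenge
submissions: a pair of microstates whose free energies are flipped in the
submitted file, and conformer Boltzmann weights computed with the wrong
sign.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import ensemble_free_energy
from .exceptions import GenerationError
from .pka import Microstate, MicrostateSet, macro_pka
from .thermo import ProtonParameters, ThermoConditions

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "corrupt_microstates",
    "flipped_microstate_scenario",
    "weight_sign_error_scenario",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    Ranges are inclusive ``(low, high)`` bounds.  Defaults mirror the shape
    of a small blind-challenge benchmark: a few dozen drug-like compounds,
    up to 20 conformers each, log P targets spanning roughly −0.5 to 4.5 log
    units and pKa targets 4–12.5, with component magnitudes typical of
    B3LYP-scale gas energies (−50–0 kcal/mol), thermal corrections
    (0–5 kcal/mol) and continuum solvation free energies (−15–0 kcal/mol).
    ``energy_noise_sd`` (kcal/mol) perturbs every emitted component.
    """

    n_compounds: int = 22
    conformers_per_compound: tuple[int, int] = (1, 20)
    target_logp_range: tuple[float, float] = (-0.5, 4.5)
    target_pka_range: tuple[float, float] = (4.0, 12.5)
    tautomers_per_charge: tuple[int, int] = (1, 3)
    energy_noise_sd: float = 0.0
    seed: int = 0
    gas_energy_range: tuple[float, float] = (-50.0, 0.0)
    thermal_range: tuple[float, float] = (0.0, 5.0)
    solvation_range: tuple[float, float] = (-15.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise GenerationError("n_compounds must be >= 1")
        lo, hi = self.conformers_per_compound
        if not (1 <= lo <= hi <= 20):
            raise GenerationError(
                f"conformers_per_compound must lie within [1, 20], got {self.conformers_per_compound}"
            )
        tl, th = self.tautomers_per_charge
        if not (1 <= tl <= th):
            raise GenerationError(
                f"tautomers_per_charge must be a non-empty positive range, got {self.tautomers_per_charge}"
            )
        for name in ("target_logp_range", "target_pka_range", "gas_energy_range",
                     "thermal_range", "solvation_range"):
            a, b = getattr(self, name)
            if not (math.isfinite(a) and math.isfinite(b) and a <= b):
                raise GenerationError(f"{name} must be a finite non-empty range, got {(a, b)}")
        if not (math.isfinite(self.energy_noise_sd) and self.energy_noise_sd >= 0):
            raise GenerationError(f"energy_noise_sd must be >= 0, got {self.energy_noise_sd}")


@dataclass(frozen=True)
class GroundTruth:
    """Exact targets embedded in a synthetic dataset, per compound."""

    true_logp: dict[str, float]
    true_macro_pka: dict[str, float]
    microstate_free_energies: dict[str, dict[str, float]] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticDataset:
    """One generated dataset: the three emitted tables plus the truth."""

    conformer_table: pd.DataFrame
    microstate_table: pd.DataFrame
    reference_table: pd.DataFrame
    ground_truth: GroundTruth
    spec: SyntheticSpec


def _uniform(rng: np.random.Generator, lo_hi: tuple[float, float], n: int) -> np.ndarray:
    lo, hi = lo_hi
    return rng.uniform(lo, hi, n) if hi > lo else np.full(n, float(lo))


def generate(
    spec: SyntheticSpec,
    cond: ThermoConditions | None = None,
    proton: ProtonParameters | None = None,
) -> SyntheticDataset:
    """Draw a dataset whose noise-free aggregates hit the targets exactly.

    For each compound a target log P and macroscopic pKa are drawn uniformly
    from the spec ranges.  Conformer components are drawn at the spec's
    magnitudes; the octanol solvation column is then translated so the
    water/octanol ensemble free-energy gap equals −(log P)·RT·ln10, and the
    anionic microstates' aqueous free energies are translated so the
    deprotonation cycle yields the pKa target.  With ``energy_noise_sd = 0``
    the downstream pipeline recovers every target to machine precision;
    with noise, errors propagate through the Boltzmann aggregates.

    Deterministic: the same spec (including seed) reproduces the tables
    byte-for-byte.
    """
    cond = cond or ThermoConditions()
    proton = proton or ProtonParameters()
    rng = np.random.default_rng(spec.seed)
    lam = cond.rt_ln10

    conf_rows: list[dict] = []
    micro_rows: list[dict] = []
    ref_rows: list[dict] = []
    true_logp: dict[str, float] = {}
    true_pka: dict[str, float] = {}
    true_micro_fe: dict[str, dict[str, float]] = {}

    for i in range(spec.n_compounds):
        cid = f"SYN{i + 1:04d}"
        n_conf = int(rng.integers(spec.conformers_per_compound[0],
                                  spec.conformers_per_compound[1] + 1))
        gas = _uniform(rng, spec.gas_energy_range, n_conf)
        th_w = _uniform(rng, spec.thermal_range, n_conf)
        th_o = _uniform(rng, spec.thermal_range, n_conf)
        sv_w = _uniform(rng, spec.solvation_range, n_conf)
        sv_o = _uniform(rng, spec.solvation_range, n_conf)

        target_logp = float(_uniform(rng, spec.target_logp_range, 1)[0])
        g_w = ensemble_free_energy(gas + th_w + sv_w, cond)
        g_o_raw = ensemble_free_energy(gas + th_o + sv_o, cond)
        # place the octanol ensemble exactly at G_w - logP*RTln10
        sv_o = sv_o + (g_w - target_logp * lam - g_o_raw)
        true_logp[cid] = target_logp

        for k in range(n_conf):
            conf_rows.append({
                "compound_id": cid,
                "conformer_id": f"conf{k + 1:03d}",
                "gas_energy_kcal": gas[k],
                "thermal_water_kcal": th_w[k],
                "thermal_octanol_kcal": th_o[k],
                "dgsolv_water_kcal": sv_w[k],
                "dgsolv_octanol_kcal": sv_o[k],
            })
        ref_rows.append({"compound_id": cid, "property": "logp", "value": target_logp})

        # protonation microstates: tautomers at charge 0 (acid) and -1 (base),
        # aqueous total free energies at gas+thermal+solvation magnitudes
        target_pka = float(_uniform(rng, spec.target_pka_range, 1)[0])
        n_acid = int(rng.integers(spec.tautomers_per_charge[0], spec.tautomers_per_charge[1] + 1))
        n_base = int(rng.integers(spec.tautomers_per_charge[0], spec.tautomers_per_charge[1] + 1))
        micro_energies: dict[str, np.ndarray] = {}
        charges: dict[str, int] = {}
        idx = 0
        for charge, count in ((0, n_acid), (-1, n_base)):
            for _ in range(count):
                idx += 1
                mid = f"{cid}_micro{idx:03d}"
                nc = int(rng.integers(spec.conformers_per_compound[0],
                                      min(spec.conformers_per_compound[1], 10) + 1))
                g = (_uniform(rng, spec.gas_energy_range, nc)
                     + _uniform(rng, spec.thermal_range, nc)
                     + _uniform(rng, spec.solvation_range, nc))
                micro_energies[mid] = g
                charges[mid] = charge

        acid_pool = np.concatenate([g for m, g in micro_energies.items() if charges[m] == 0])
        base_pool = np.concatenate([g for m, g in micro_energies.items() if charges[m] == -1])
        g_acid = ensemble_free_energy(acid_pool, cond)
        g_base_raw = ensemble_free_energy(base_pool, cond)
        # translate the anion energies so the cycle yields the pKa target
        shift = target_pka * lam - proton.total() + g_acid - g_base_raw
        for mid in micro_energies:
            if charges[mid] == -1:
                micro_energies[mid] = micro_energies[mid] + shift
        true_pka[cid] = target_pka
        true_micro_fe[cid] = {
            mid: ensemble_free_energy(g, cond) for mid, g in micro_energies.items()
        }

        for mid, g in micro_energies.items():
            for k, gk in enumerate(g):
                micro_rows.append({
                    "compound_id": cid,
                    "microstate_id": mid,
                    "formal_charge": charges[mid],
                    "conformer_id": f"conf{k + 1:03d}",
                    "free_energy_kcal": gk,
                })
        ref_rows.append({"compound_id": cid, "property": "pka", "value": target_pka})

    conformers = pd.DataFrame(conf_rows)
    microstates = pd.DataFrame(micro_rows)
    if spec.energy_noise_sd > 0:
        for col in ("gas_energy_kcal", "thermal_water_kcal", "thermal_octanol_kcal",
                    "dgsolv_water_kcal", "dgsolv_octanol_kcal"):
            conformers[col] += rng.normal(0.0, spec.energy_noise_sd, len(conformers))
        microstates["free_energy_kcal"] += rng.normal(
            0.0, spec.energy_noise_sd, len(microstates)
        )

    return SyntheticDataset(
        conformer_table=conformers,
        microstate_table=microstates,
        reference_table=pd.DataFrame(ref_rows),
        ground_truth=GroundTruth(
            true_logp=true_logp,
            true_macro_pka=true_pka,
            microstate_free_energies=true_micro_fe,
        ),
        spec=spec,
    )


def corrupt_microstates(
    table: pd.DataFrame, swap_pair: tuple[str, str]
) -> pd.DataFrame:
    """Return a copy of a microstate table with two microstates' free-energy
    columns exchanged — the bookkeeping error class of a mislabelled
    submission file.

    The swap relabels the free-energy rows of the two microstates (each
    keeps its own formal charge), so swapping twice restores the original
    table.  Swapping two microstates of equal charge leaves the macroscopic
    pKa invariant (the charge-state partition sum is permutation-invariant);
    the consequential corruption is a flip across charge states, which
    shifts the recomputed macroscopic pKa and is what
    :func:`~logpka.pka.validate_microstate_table` exists to catch.
    """
    a, b = swap_pair
    for mid in (a, b):
        if mid not in set(table["microstate_id"]):
            raise KeyError(f"microstate {mid!r} not present in table")
    out = table.copy()
    mask_a = out["microstate_id"] == a
    mask_b = out["microstate_id"] == b
    ga = out.loc[mask_a, "free_energy_kcal"].to_numpy()
    gb = out.loc[mask_b, "free_energy_kcal"].to_numpy()
    if len(ga) != len(gb):
        raise KeyError(
            f"cannot swap free-energy columns of {a!r} ({len(ga)} conformers) "
            f"and {b!r} ({len(gb)} conformers)"
        )
    out.loc[mask_a, "free_energy_kcal"] = gb
    out.loc[mask_b, "free_energy_kcal"] = ga
    return out


def flipped_microstate_scenario(
    discrepancy: float = 3.90,
    cond: ThermoConditions | None = None,
) -> tuple[MicrostateSet, MicrostateSet, float]:
    """Synthetic flipped-file scenario: (correct set, corrupted set, reported pKa).

    Builds a compound in the relative-transition dialect — one neutral
    reference microstate (ΔG = 0) and two anionic tautomers — with synthetic
    free energies (the real values behind the historical flip were never
    published), then flips the reference's value with the dominant anion's:
    the cross-charge mix-up of a submission file.  The flip negates the
    deprotonation free energy, so the recomputed macroscopic pKa differs
    from the reported one by ``discrepancy`` = 2 × (reported pKa); energies
    are placed to make that exact.  Evaluate with ``proton=None`` (the
    dialect folds the proton term in).
    """
    cond = cond or ThermoConditions()
    lam = cond.rt_ln10
    # flipping reference and dominant anion negates the transition free
    # energy: discrepancy = 2*dg_b1/lam
    dg_b1 = discrepancy * lam / 2.0
    dg_b2 = dg_b1 + 12.0  # minor tautomer, negligible population
    compound = "SYNFLIP"

    def build(e_ref: float, e_b1: float) -> MicrostateSet:
        return MicrostateSet(
            compound,
            [
                Microstate(f"{compound}_micro001", compound, 0, [e_ref]),
                Microstate(f"{compound}_micro002", compound, -1, [e_b1]),
                Microstate(f"{compound}_micro003", compound, -1, [dg_b2]),
            ],
            dialect="relative_transition",
            reference_microstate=f"{compound}_micro001",
        )

    correct = build(0.0, dg_b1)
    corrupted = build(dg_b1, 0.0)
    reported = macro_pka(correct, 0, None, cond).macro_pka
    return correct, corrupted, reported


def weight_sign_error_scenario(
    pka_drop: float = 3.94,
    cond: ThermoConditions | None = None,
    proton: ProtonParameters | None = None,
) -> tuple[MicrostateSet, float, float]:
    """Synthetic conformer-misweighting scenario: (microstates, buggy pKa, correct pKa).

    Reproduces, with synthetic energies, the error class where conformer
    Boltzmann factors are evaluated with the wrong sign (exp(+G/RT) instead
    of exp(−G/RT)), so the *highest*-energy conformer of each microstate
    dominates its aggregate.  Energies are placed so correcting the weights
    lowers the macroscopic pKa by ``pka_drop`` units (the historical SM25
    revision was a 3.94-unit drop, 7.24 → 3.30).
    """
    cond = cond or ThermoConditions()
    proton = proton or ProtonParameters()
    lam = cond.rt_ln10
    compound = "SYNWT"
    # base anion: two well-separated conformers; with sign-flipped weights
    # the high conformer dominates, inflating G(base) and hence the pKa
    gap = pka_drop * lam
    acid = Microstate(f"{compound}_micro001", compound, 0, [-25.0])
    base = Microstate(f"{compound}_micro002", compound, -1, [-33.0, -33.0 + gap])
    ms = MicrostateSet(compound, [acid, base])

    def buggy_fe(g: np.ndarray) -> float:
        # wrong-sign Boltzmann factors: weights concentrate on the maximum,
        # and the "ensemble" free energy is the misweighted mean
        g = np.asarray(g, float)
        x = g / cond.rt
        w = np.exp(x - x.max())
        w /= w.sum()
        return float(w @ g)

    proton_total = proton.total()
    buggy = (buggy_fe(np.array(base.conformer_free_energies)) + proton_total
             - buggy_fe(np.array(acid.conformer_free_energies))) / lam
    correct = macro_pka(ms, 0, proton, cond).macro_pka
    return ms, buggy, correct
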