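"""Prediction-versus-experiment statistics and secondary analyses.

Errors are always signed as calculated − experimental.  Experimental values
reported only as bounds ("> 12.00", "< 2") are *censored*: they are parsed,
kept in the record set for bookkeeping, and excluded from every statistic,
outlier flag and matched-pair shift.  Metrics are computed at full precision;
comparisons against published two-decimal tables are the caller's concern.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .exceptions import InsufficientDataError, InvalidValueError

__all__ = [
    "PredictionRecord",
    "StatsSummary",
    "PairShift",
    "parse_experimental",
    "summarize",
    "flag_outliers",
    "summarize_excluding",
    "pair_shifts",
]

_CENSOR_RE = re.compile(r"^\s*([<>])\s*([+-]?\d+(?:\.\d+)?)\s*$")


def parse_experimental(value) -> tuple[float | None, str | None, float | None]:
    """Parse an experimental entry into (value, censor_op, censor_threshold).

    Accepts a number, a numeric string, or a censored bound such as
    ``"> 12.00"``; censored entries return ``(None, op, threshold)``.
    """
    if isinstance(value, (int, float)):
        return float(value), None, None
    s = str(value).strip()
    m = _CENSOR_RE.match(s)
    if m:
        return None, m.group(1), float(m.group(2))
    try:
        return float(s), None, None
    except ValueError:
        raise InvalidValueError(f"cannot parse experimental value {value!r}") from None


@dataclass(frozen=True)
class PredictionRecord:
    """One compound's calculated value paired with its experimental reference.

    ``experimental`` is None for censored entries, which then carry
    ``censor_op`` in {``">"``, ``"<"``} and ``censor_threshold`` and are
    automatically excluded from all statistics.  ``annotation`` carries
    free-form provenance (e.g. a post-submission corrected value).
    """

    compound_id: str
    calculated: float
    experimental: float | None = None
    censor_op: str | None = None
    censor_threshold: float | None = None
    excluded: bool = False
    exclusion_reason: str | None = None
    annotation: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.calculated):
            raise InvalidValueError(
                f"{self.compound_id}: calculated value must be finite"
            )
        if self.censored:
            if self.censor_op not in (">", "<") or self.censor_threshold is None:
                raise InvalidValueError(
                    f"{self.compound_id}: censored record needs operator and threshold"
                )
            if not self.excluded:
                object.__setattr__(self, "excluded", True)
                object.__setattr__(
                    self,
                    "exclusion_reason",
                    f"censored experimental ({self.censor_op} {self.censor_threshold:g})",
                )
        elif not math.isfinite(self.experimental):
            raise InvalidValueError(
                f"{self.compound_id}: experimental value must be finite or censored"
            )

    @property
    def censored(self) -> bool:
        return self.experimental is None

    @classmethod
    def from_raw(cls, compound_id: str, calculated: float, experimental, **kw) -> "PredictionRecord":
        """Build a record parsing ``experimental`` as number or censored bound."""
        value, op, thr = parse_experimental(experimental)
        return cls(
            compound_id=compound_id,
            calculated=float(calculated),
            experimental=value,
            censor_op=op,
            censor_threshold=thr,
            **kw,
        )

    @property
    def delta(self) -> float | None:
        """Signed error calculated − experimental; None when censored."""
        if self.censored:
            return None
        return self.calculated - self.experimental


@dataclass(frozen=True)
class StatsSummary:
    """Paired error statistics over the non-excluded records.

    rmsd = sqrt(mean Δ²), mse = mean Δ, mue = mean |Δ| with
    Δ = calculated − experimental; ``pearson_r`` is the sample Pearson
    correlation of calculated against experimental.  These satisfy
    rmsd ≥ mue ≥ |mse| on every input.
    """

    n: int
    rmsd: float
    mse: float
    mue: float
    pearson_r: float
    excluded_ids: tuple[str, ...] = field(default_factory=tuple)


def _active(records: Iterable[PredictionRecord]) -> list[PredictionRecord]:
    return [r for r in records if not r.excluded]


def summarize(records: Sequence[PredictionRecord]) -> StatsSummary:
    """Compute rmsd / mse / mue / Pearson r over the non-excluded records.

    Requires at least one active record for the error metrics and two for
    the correlation (r is NaN when fewer, or when either column is
    constant).
    """
    active = _active(records)
    if not active:
        raise InsufficientDataError("all records are excluded or censored")
    calc = np.array([r.calculated for r in active])
    expt = np.array([r.experimental for r in active])
    delta = calc - expt
    if len(active) >= 2 and np.ptp(calc) > 0 and np.ptp(expt) > 0:
        pearson_r = float(_scipy_stats.pearsonr(calc, expt).statistic)
    else:
        pearson_r = float("nan")
    return StatsSummary(
        n=len(active),
        rmsd=float(np.sqrt(np.mean(delta**2))),
        mse=float(np.mean(delta)),
        mue=float(np.mean(np.abs(delta))),
        pearson_r=pearson_r,
        excluded_ids=tuple(r.compound_id for r in records if r.excluded),
    )


def flag_outliers(
    records: Sequence[PredictionRecord], threshold: float = 1.50
) -> set[str]:
    """Compound ids with |calculated − experimental| strictly above
    ``threshold``; censored or excluded records are never flagged."""
    if not threshold > 0:
        raise InvalidValueError(f"threshold must be > 0, got {threshold}")
    return {
        r.compound_id
        for r in _active(records)
        if abs(r.delta) > threshold
    }


def summarize_excluding(
    records: Sequence[PredictionRecord], exclude_ids: set[str]
) -> StatsSummary:
    """Statistics after additionally excluding ``exclude_ids`` (recorded as
    the exclusion reason); with an empty set this equals :func:`summarize`."""
    marked = [
        replace(r, excluded=True, exclusion_reason="excluded by analysis")
        if r.compound_id in exclude_ids and not r.excluded
        else r
        for r in records
    ]
    return summarize(marked)


@dataclass(frozen=True)
class PairShift:
    """Experimental property shift of one matched substituent pair
    (substituted − base), e.g. the effect of a methyl → phenyl replacement."""

    base_compound_id: str
    substituted_compound_id: str
    delta: float


def pair_shifts(
    records: Sequence[PredictionRecord],
    pairs: Sequence[tuple[str, str]],
) -> tuple[list[PairShift], float]:
    """Experimental shifts for matched compound pairs and their mean.

    Every referenced compound must be present and uncensored; a missing or
    censored member raises a KeyError naming the pair.
    """
    by_id = {r.compound_id: r for r in records}
    shifts: list[PairShift] = []
    for base_id, sub_id in pairs:
        for cid in (base_id, sub_id):
            if cid not in by_id:
                raise KeyError(f"pair ({base_id}, {sub_id}): no record for {cid!r}")
            if by_id[cid].censored:
                raise KeyError(
                    f"pair ({base_id}, {sub_id}): {cid!r} has a censored experimental value"
                )
        shifts.append(
            PairShift(
                base_compound_id=base_id,
                substituted_compound_id=sub_id,
                delta=by_id[sub_id].experimental - by_id[base_id].experimental,
            )
        )
    mean = float(np.mean([s.delta for s in shifts])) if shifts else float("nan")
    return shifts, mean
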