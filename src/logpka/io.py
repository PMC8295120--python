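"""Readers and writers for the package's CSV table dialects.

Three dialects are defined (all plain CSV, kcal/mol):

conformer table
    one row per conformer: ``compound_id, conformer_id, gas_energy_kcal,
    thermal_water_kcal, thermal_octanol_kcal, dgsolv_water_kcal,
    dgsolv_octanol_kcal``.  The octanol columns may be absent for pKa-only
    datasets.

microstate table
    a mandatory metadata first line ``# dialect: absolute_aqueous`` or
    ``# dialect: relative_transition reference=<microstate_id>``, then one
    row per (microstate, conformer): ``compound_id, microstate_id,
    formal_charge, conformer_id, free_energy_kcal``.  The dialect is never
    guessed.

reference table
    ``compound_id, property, value`` with property in {``logp``, ``pka``}
    and value either a number or a censored bound such as ``"> 12.00"``.

Every parse error is a :class:`~logpka.exceptions.TableFormatError` naming
the file and offending line; duplicate keys are rejected, never silently
dropped.  Predictions are written as CSV (4 decimal places) with a
full-precision JSON sidecar, or as a simplified versioned SAMPL-style
submission block per compound.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .ensemble import OCTANOL, WATER, CompoundEnsemble, ConformerRecord
from .evaluation import PredictionRecord
from .exceptions import TableFormatError
from .pka import Microstate, MicrostateSet

__all__ = [
    "read_conformer_table",
    "write_conformer_table",
    "ensembles_from_dataframe",
    "read_microstate_table",
    "write_microstate_table",
    "microstate_sets_from_dataframe",
    "read_reference_table",
    "write_predictions",
]

_CONFORMER_REQUIRED = (
    "compound_id",
    "conformer_id",
    "gas_energy_kcal",
    "thermal_water_kcal",
    "dgsolv_water_kcal",
)
_CONFORMER_OCTANOL = ("thermal_octanol_kcal", "dgsolv_octanol_kcal")
_MICROSTATE_COLUMNS = (
    "compound_id",
    "microstate_id",
    "formal_charge",
    "conformer_id",
    "free_energy_kcal",
)

SAMPL_FORMAT_VERSION = "1.0"


def _parse_float(value, column: str, path, line: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableFormatError(
            f"malformed number {value!r} in column {column!r}", path, line
        ) from None


def _check_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(f"missing column(s) {missing}", path, 1)


def ensembles_from_dataframe(df: pd.DataFrame, path=None, header_lines: int = 1) -> list[CompoundEnsemble]:
    """Build :class:`CompoundEnsemble` objects from a conformer table.

    ``header_lines`` is the number of file lines preceding the first data
    row (for line-numbered diagnostics).  Compound order follows first
    appearance; duplicate (compound, conformer) pairs are an error.
    """
    _check_columns(df, _CONFORMER_REQUIRED, path)
    has_octanol = all(c in df.columns for c in _CONFORMER_OCTANOL)
    per_compound: dict[str, list[ConformerRecord]] = {}
    seen: set[tuple[str, str]] = set()
    for pos, row in enumerate(df.itertuples(index=False)):
        line = header_lines + 1 + pos
        cid = str(row.compound_id)
        conf_id = str(row.conformer_id)
        key = (cid, conf_id)
        if key in seen:
            raise TableFormatError(
                f"duplicate conformer row for compound {cid!r}, conformer {conf_id!r}",
                path, line,
            )
        seen.add(key)
        thermal = {WATER: _parse_float(row.thermal_water_kcal, "thermal_water_kcal", path, line)}
        solv = {WATER: _parse_float(row.dgsolv_water_kcal, "dgsolv_water_kcal", path, line)}
        if has_octanol and not (
            pd.isna(row.thermal_octanol_kcal) or pd.isna(row.dgsolv_octanol_kcal)
        ):
            thermal[OCTANOL] = _parse_float(
                row.thermal_octanol_kcal, "thermal_octanol_kcal", path, line
            )
            solv[OCTANOL] = _parse_float(
                row.dgsolv_octanol_kcal, "dgsolv_octanol_kcal", path, line
            )
        record = ConformerRecord(
            conformer_id=conf_id,
            gas_energy=_parse_float(row.gas_energy_kcal, "gas_energy_kcal", path, line),
            thermal_correction=thermal,
            solvation_free_energy=solv,
        )
        per_compound.setdefault(cid, []).append(record)
    return [CompoundEnsemble(cid, confs) for cid, confs in per_compound.items()]


def read_conformer_table(path: str | Path) -> list[CompoundEnsemble]:
    """Read a conformer free-energy table (see module docstring)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"compound_id": str, "conformer_id": str})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TableFormatError(f"unreadable conformer table: {exc}", path) from exc
    return ensembles_from_dataframe(df, path)


def write_conformer_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a conformer table DataFrame in the package dialect."""
    _check_columns(df, _CONFORMER_REQUIRED, path)
    df.to_csv(path, index=False)


def microstate_sets_from_dataframe(
    df: pd.DataFrame,
    dialect: str,
    reference_microstate: str | None = None,
    path=None,
    header_lines: int = 2,
) -> list[MicrostateSet]:
    """Build :class:`MicrostateSet` objects from a microstate table."""
    _check_columns(df, _MICROSTATE_COLUMNS, path)
    energies: dict[str, dict[str, list[float]]] = {}
    charges: dict[str, dict[str, int]] = {}
    seen: set[tuple[str, str, str]] = set()
    for pos, row in enumerate(df.itertuples(index=False)):
        line = header_lines + 1 + pos
        cid, mid, conf_id = str(row.compound_id), str(row.microstate_id), str(row.conformer_id)
        key = (cid, mid, conf_id)
        if key in seen:
            raise TableFormatError(
                f"duplicate row for compound {cid!r}, microstate {mid!r}, conformer {conf_id!r}",
                path, line,
            )
        seen.add(key)
        try:
            charge = int(row.formal_charge)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"malformed formal_charge {row.formal_charge!r}", path, line
            ) from None
        prev = charges.setdefault(cid, {})
        if mid in prev and prev[mid] != charge:
            raise TableFormatError(
                f"microstate {mid!r} has inconsistent formal charges", path, line
            )
        prev[mid] = charge
        energies.setdefault(cid, {}).setdefault(mid, []).append(
            _parse_float(row.free_energy_kcal, "free_energy_kcal", path, line)
        )
    sets = []
    for cid, micro in energies.items():
        microstates = [
            Microstate(mid, cid, charges[cid][mid], g) for mid, g in micro.items()
        ]
        sets.append(
            MicrostateSet(cid, microstates, dialect=dialect,
                          reference_microstate=reference_microstate)
        )
    return sets


def _parse_dialect_header(first_line: str, path) -> tuple[str, str | None]:
    stripped = first_line.strip()
    if not stripped.startswith("#") or "dialect:" not in stripped:
        raise TableFormatError(
            "microstate table must declare its dialect on line 1, e.g. "
            "'# dialect: absolute_aqueous' (the dialect is never guessed)",
            path, 1,
        )
    body = stripped.lstrip("#").strip()
    tokens = body.split()
    # tokens like: ['dialect:', 'absolute_aqueous'] or
    # ['dialect:', 'relative_transition', 'reference=SM25_micro001']
    try:
        dialect = tokens[tokens.index("dialect:") + 1]
    except (ValueError, IndexError):
        raise TableFormatError("malformed dialect declaration", path, 1) from None
    if dialect not in ("absolute_aqueous", "relative_transition"):
        raise TableFormatError(f"unknown dialect {dialect!r}", path, 1)
    reference = None
    for tok in tokens:
        if tok.startswith("reference="):
            reference = tok.split("=", 1)[1]
    if dialect == "relative_transition" and not reference:
        raise TableFormatError(
            "relative_transition dialect requires 'reference=<microstate_id>'", path, 1
        )
    return dialect, reference


def read_microstate_table(path: str | Path) -> list[MicrostateSet]:
    """Read a microstate table; the dialect header line is mandatory."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        dialect, reference = _parse_dialect_header(first, path)
        try:
            df = pd.read_csv(fh, dtype={"compound_id": str, "microstate_id": str,
                                        "conformer_id": str})
        except Exception as exc:
            raise TableFormatError(f"unreadable microstate table: {exc}", path) from exc
    return microstate_sets_from_dataframe(df, dialect, reference, path)


def write_microstate_table(
    df: pd.DataFrame,
    path: str | Path,
    dialect: str = "absolute_aqueous",
    reference_microstate: str | None = None,
) -> None:
    """Write a microstate table with its dialect header line."""
    if dialect not in ("absolute_aqueous", "relative_transition"):
        raise TableFormatError(f"unknown dialect {dialect!r}", path)
    if dialect == "relative_transition" and not reference_microstate:
        raise TableFormatError("relative_transition requires a reference microstate", path)
    _check_columns(df, _MICROSTATE_COLUMNS, path)
    header = f"# dialect: {dialect}"
    if reference_microstate:
        header += f" reference={reference_microstate}"
    with open(path, "w") as fh:
        fh.write(header + "\n")
        df.to_csv(fh, index=False)


def read_reference_table(path: str | Path) -> dict[str, list[tuple[str, str]]]:
    """Read experimental references, keyed by property (``logp``/``pka``).

    References carry only the experimental side (possibly censored, e.g.
    ``"> 12.00"``); they are returned as (compound_id, raw value) pairs per
    property and joined with calculated values by
    :func:`pair_with_references`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "property": str, "value": str})
    _check_columns(df, ("compound_id", "property", "value"), path)
    out: dict[str, list[tuple[str, str]]] = {}
    for pos, row in enumerate(df.itertuples(index=False)):
        prop = str(row.property).strip().lower()
        if prop not in ("logp", "pka"):
            raise TableFormatError(
                f"unknown property {row.property!r}", path, pos + 2
            )
        out.setdefault(prop, []).append((str(row.compound_id), str(row.value)))
    return out


def pair_with_references(
    calculated: dict[str, float], references: Iterable[tuple[str, str]]
) -> list[PredictionRecord]:
    """Join calculated values with (compound_id, experimental) reference pairs."""
    records = []
    for cid, expt in references:
        if cid in calculated:
            records.append(PredictionRecord.from_raw(cid, calculated[cid], expt))
    return records


def write_predictions(
    results: Sequence[dict],
    path: str | Path,
    format: str = "csv",
) -> None:
    """Write prediction results deterministically ordered by compound id.

    Each result is a mapping with at least ``compound_id``, ``property`` and
    ``value``; optional ``uncertainty`` and ``breakdown`` (a flat mapping,
    e.g. per-microstate pKa contributions) ride along.  ``format="csv"``
    rounds to 4 decimals and writes a full-precision JSON sidecar next to
    the file; ``format="sampl"`` writes one simplified submission block per
    compound.
    """
    if not results:
        raise TableFormatError("no prediction results to write", path)
    path = Path(path)
    ordered = sorted(results, key=lambda r: (str(r["compound_id"]), str(r.get("property", ""))))
    if format == "csv":
        rows = []
        for r in ordered:
            row = {
                "compound_id": r["compound_id"],
                "property": r.get("property", ""),
                "value": f"{float(r['value']):.4f}",
            }
            breakdown = r.get("breakdown") or {}
            row["breakdown"] = ";".join(
                f"{k}={float(v):.4f}" for k, v in sorted(breakdown.items())
            )
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(
            [{k: v for k, v in r.items()} for r in ordered], indent=2, default=float
        ))
    elif format == "sampl":
        lines = [f"# logpka SAMPL-style predictions v{SAMPL_FORMAT_VERSION}"]
        for r in ordered:
            unc = r.get("uncertainty")
            unc_s = f"{float(unc):.2f}" if unc is not None else "NA"
            lines.append(f"{r['compound_id']},{float(r['value']):.2f},{unc_s}")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise TableFormatError(f"unknown prediction format {format!r}", path)
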