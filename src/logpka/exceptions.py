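"""Exception hierarchy for logpka.

All errors raised by the library derive from :class:`LogPkaError` so callers
can catch the package's failures with a single except clause.  Parsing errors
carry the offending file line where one is known.
"""


class LogPkaError(Exception):
    """Base class for all logpka errors."""


class InvalidValueError(LogPkaError, ValueError):
    """A free energy or derived quantity is non-finite or out of domain."""


class EmptyEnsembleError(LogPkaError, ValueError):
    """An operation requiring at least one conformer received none."""


class MissingComponentError(LogPkaError, KeyError):
    """A conformer lacks a thermal or solvation component for a solvent."""

    def __init__(self, compound_id: str, conformer_id: str, solvent: str):
        self.compound_id = compound_id
        self.conformer_id = conformer_id
        self.solvent = solvent
        super().__init__(
            f"compound {compound_id!r}, conformer {conformer_id!r}: "
            f"missing free-energy component(s) for solvent {solvent!r}"
        )


class ChargeMismatchError(LogPkaError, ValueError):
    """Acid/base microstates do not differ by exactly one proton charge."""


class MissingChargeStateError(LogPkaError, ValueError):
    """A requested total-charge state has no microstates."""

    def __init__(self, compound_id: str, charge: int):
        self.compound_id = compound_id
        self.charge = charge
        super().__init__(
            f"compound {compound_id!r}: no microstates with formal charge {charge}"
        )


class InsufficientDataError(LogPkaError, ValueError):
    """Too few non-excluded records to compute the requested statistic."""


class TableFormatError(LogPkaError, ValueError):
    """A CSV table violates its dialect (bad header, value, or duplicate key)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f"{path}"
            if line is not None:
                where += f":{line}"
            where = f" [{where}]"
        super().__init__(f"{message}{where}")


class GenerationError(LogPkaError, ValueError):
    """Synthetic-data specification is infeasible or inconsistent."""
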