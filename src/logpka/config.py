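"""Run configuration: constants, aggregation mode, thresholds.

A :class:`RunConfig` gathers every tunable the pipeline exposes — the
thermodynamic conditions, the proton free-energy decomposition, the
conformer aggregation rule, the outlier threshold for evaluation and the
validation tolerance — with the package defaults.  Configs round-trip
through YAML so a run is reproducible from its echoed config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .exceptions import InvalidValueError
from .thermo import ProtonParameters, ThermoConditions

__all__ = ["RunConfig"]

_AGGREGATIONS = ("free_energy", "weighted_mean")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings with their defaults.

    ``aggregation`` selects the conformer-ensemble rule: ``"free_energy"``
    (partition-function log-sum-exp, the default) or ``"weighted_mean"``
    (population-weighted mean, for sensitivity analysis).
    ``outlier_threshold`` is in the units of the evaluated property;
    ``validation_tolerance`` in pKa units.
    """

    temperature: float = 298.15
    gas_constant: float = 1.98720425e-3
    proton_gas_phase_free_energy: float = -6.28
    proton_standard_state_correction: float = 1.89
    proton_hydration_free_energy: float = -265.9
    aggregation: str = "free_energy"
    outlier_threshold: float = 1.50
    validation_tolerance: float = 0.10
    seed: int = 0
    energy_tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.aggregation not in _AGGREGATIONS:
            raise InvalidValueError(
                f"aggregation must be one of {_AGGREGATIONS}, got {self.aggregation!r}"
            )
        if not self.outlier_threshold > 0:
            raise InvalidValueError("outlier_threshold must be > 0")
        if not self.validation_tolerance > 0:
            raise InvalidValueError("validation_tolerance must be > 0")

    @property
    def conditions(self) -> ThermoConditions:
        return ThermoConditions(self.temperature, self.gas_constant)

    @property
    def proton(self) -> ProtonParameters:
        return ProtonParameters(
            self.proton_gas_phase_free_energy,
            self.proton_standard_state_correction,
            self.proton_hydration_free_energy,
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = cls.__dataclass_fields__
        unknown = sorted(set(data) - set(known))
        if unknown:
            raise InvalidValueError(f"unknown config keys: {unknown}")
        return cls(**data)

    def with_overrides(self, **kw) -> "RunConfig":
        merged = {**asdict(self), **{k: v for k, v in kw.items() if v is not None}}
        return RunConfig(**merged)
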