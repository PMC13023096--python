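"""Human-editable YAML configuration for a full analysis run.

The embedded defaults are the base case: a 10,000-patient cohort followed
for 96 monthly cycles, the published transition probabilities for each arm,
the two cost inputs, the one-way sensitivity grids, and the stress-test
ranges with 500 draws.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .model import CostParameters, StrategyParameters
from .sensitivity import DsaGrid, PsaRanges


class ConfigError(ValueError):
    """Configuration does not validate; the message names the field."""


@dataclass(frozen=True)
class ModelConfig:
    n_patients: float = 10_000
    n_cycles: int = 96
    seed: int = 20_260_320
    noboost: StrategyParameters = field(
        default_factory=StrategyParameters.no_boost_base_case
    )
    boost: StrategyParameters = field(
        default_factory=StrategyParameters.boost_base_case
    )
    costs: CostParameters = field(default_factory=CostParameters)
    dsa_grid: DsaGrid = field(default_factory=DsaGrid)
    psa_ranges: PsaRanges = field(default_factory=PsaRanges)
    psa_n_draws: int = 500
    calibration_os_target: float = 0.84
    calibration_at_month: int = 12
    run_microsim: bool = False

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be > 0")
        if self.n_cycles < 1:
            raise ConfigError("n_cycles must be >= 1")
        if self.psa_n_draws < 1:
            raise ConfigError("psa_n_draws must be >= 1")
        if not (0 < self.calibration_os_target <= 1):
            raise ConfigError("calibration_os_target must lie in (0, 1]")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["dsa_grid"] = {
            k: [list(v) if isinstance(v, tuple) else v for v in vals]
            for k, vals in asdict(self.dsa_grid).items()
        }
        d["psa_ranges"] = {k: list(v) for k, v in asdict(self.psa_ranges).items()}
        return d

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "ModelConfig":
        known = {
            "n_patients", "n_cycles", "seed", "noboost", "boost", "costs",
            "dsa_grid", "psa_ranges", "psa_n_draws", "calibration_os_target",
            "calibration_at_month", "run_microsim",
        }
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown configuration field: {key!r}")
        kwargs: dict[str, Any] = {}
        try:
            if "noboost" in raw:
                kwargs["noboost"] = StrategyParameters(**raw["noboost"])
            if "boost" in raw:
                kwargs["boost"] = StrategyParameters(**raw["boost"])
            if "costs" in raw:
                kwargs["costs"] = CostParameters(**raw["costs"])
            if "dsa_grid" in raw:
                kwargs["dsa_grid"] = DsaGrid(
                    **{
                        k: tuple(tuple(v) if isinstance(v, list) else v for v in vals)
                        for k, vals in raw["dsa_grid"].items()
                    }
                )
            if "psa_ranges" in raw:
                kwargs["psa_ranges"] = PsaRanges(
                    **{k: tuple(v) for k, v in raw["psa_ranges"].items()}
                )
        except TypeError as exc:  # unexpected nested field
            raise ConfigError(str(exc)) from exc
        for key in known - {"noboost", "boost", "costs", "dsa_grid", "psa_ranges"}:
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8"
        )

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(raw)
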