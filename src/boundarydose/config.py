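"""Run configuration: sectioned key-value (TOML) files with strict keys.

All model constants are configuration defaults, never hard-coded in
computation paths.  Unknown keys are rejected by name so a typo cannot
silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .errors import ConfigError
from .synthetic import DM_DEFAULT_MODEL, DW_DEFAULT_MODEL, CohortConfig, PerturbationModel

__all__ = [
    "RadiobiologyConfig",
    "DVHConfig",
    "ReportConfig",
    "RunConfig",
    "load_config",
]


@dataclass(frozen=True)
class RadiobiologyConfig:
    d50_bed_gy: float = 75.5
    gamma: float = 1.22
    alpha_beta_gy: float = 10.0
    n_fractions: int = 5
    coverage_percent: float = 95.0


@dataclass(frozen=True)
class DVHConfig:
    bin_width_gy: float = 0.05


@dataclass(frozen=True)
class ReportConfig:
    percent_decimals: int = 1


@dataclass(frozen=True)
class RunConfig:
    radiobiology: RadiobiologyConfig = field(default_factory=RadiobiologyConfig)
    dvh: DVHConfig = field(default_factory=DVHConfig)
    synthetic: CohortConfig = field(default_factory=CohortConfig)
    report: ReportConfig = field(default_factory=ReportConfig)

    def echo(self) -> dict:
        """JSON-serialisable dump of the effective configuration."""
        return dataclasses.asdict(self)


def _build(cls, data: dict[str, Any], section: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(fields))
    if unknown:
        raise ConfigError(f"unknown key(s) in [{section}]: {', '.join(unknown)}")
    kwargs = {}
    for key, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid value in [{section}]: {exc}") from exc


def _build_synthetic(data: dict[str, Any]) -> CohortConfig:
    data = dict(data)
    model_dm = _build(
        PerturbationModel,
        {**dataclasses.asdict(DM_DEFAULT_MODEL), **data.pop("dm", {})},
        "synthetic.dm",
    )
    model_dw = _build(
        PerturbationModel,
        {**dataclasses.asdict(DW_DEFAULT_MODEL), **data.pop("dw", {})},
        "synthetic.dw",
    )
    data["model_dm"] = model_dm
    data["model_dw"] = model_dw
    return _build(CohortConfig, data, "synthetic")


def from_dict(data: dict[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from nested dictionaries (TOML shape)."""
    known = {"radiobiology", "dvh", "synthetic", "report"}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown section(s): {', '.join(unknown)}")
    return RunConfig(
        radiobiology=_build(RadiobiologyConfig, data.get("radiobiology", {}), "radiobiology"),
        dvh=_build(DVHConfig, data.get("dvh", {}), "dvh"),
        synthetic=_build_synthetic(data.get("synthetic", {})),
        report=_build(ReportConfig, data.get("report", {}), "report"),
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Read a TOML config file; ``None`` yields the shipped defaults."""
    if path is None:
        return RunConfig()
    with open(path, "rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return from_dict(data)
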