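"""Pipeline configuration: dataclass schema + YAML loading/validation.

A pipeline run is fully described by a :class:`PipelineConfig`: the culture
layout, the response model, the stimulus (dispensing conditions or a
uniform bath), spatial parameters, resampling settings and seeds.  YAML
configuration files mirror the dataclass blocks::

    mode: cluster            # single_cell | cluster | whole_culture
    t_stim_min: 5
    seed: 1
    culture:  {density: 400}
    dispense: {c0_nM: 318}
    response: {}
    spatial:  {}
    stats:    {n_boot: 5000}
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .diffusion import DispenseConditions
from .spatial import SpatialParams
from .synthetic import CultureConfig, ResponseModelParams

__all__ = ["PipelineConfig", "StatsConfig", "load_config"]

MODES = ("single_cell", "cluster", "whole_culture")


@dataclass(frozen=True)
class StatsConfig:
    n_boot: int = 5000
    n_resamples: int = 5000
    calibration_n: int = 1000

    def __post_init__(self) -> None:
        if self.n_boot < 100 or self.n_resamples < 100:
            raise ValueError("n_boot and n_resamples must be at least 100")
        if self.calibration_n < 20:
            raise ValueError("calibration_n must be at least 20")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce one virtual experiment."""

    mode: str
    culture: CultureConfig
    t_stim_min: float = 5.0
    dispense: DispenseConditions | None = None
    bath_conc_nM: float | None = None
    response: ResponseModelParams = field(default_factory=ResponseModelParams)
    spatial: SpatialParams = field(default_factory=SpatialParams)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    render: bool = False
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "whole_culture":
            if self.bath_conc_nM is None:
                raise ValueError("whole_culture mode requires bath_conc_nM")
            if self.bath_conc_nM < 0:
                raise ValueError("bath_conc_nM must be non-negative")
        else:
            if self.dispense is None:
                raise ValueError(f"{self.mode} mode requires dispense conditions")
            if self.dispense.mode != self.mode:
                raise ValueError(
                    f"dispense mode {self.dispense.mode!r} does not match pipeline mode {self.mode!r}"
                )
        if self.t_stim_min <= 0:
            raise ValueError("t_stim_min must be positive")


def _build(cls, block: dict, what: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {what} block: {sorted(unknown)}")
    return cls(**block)


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("configuration root must be a mapping")
    mode = raw.get("mode")
    if mode not in MODES:
        raise ValueError(f"config must set mode to one of {MODES}")

    culture_block = dict(raw.get("culture") or {})
    culture_block.setdefault("seed", raw.get("seed", 0))
    culture = _build(CultureConfig, culture_block, "culture")

    dispense = None
    bath = raw.get("bath_conc_nM")
    if mode != "whole_culture":
        dispense_block = dict(raw.get("dispense") or {})
        dispense_block.setdefault("mode", mode)
        dispense_block.setdefault("duration_s", 60.0 * float(raw.get("t_stim_min", 5.0)))
        dispense = _build(DispenseConditions, dispense_block, "dispense")

    response = _build(ResponseModelParams, dict(raw.get("response") or {}), "response")
    spatial = _build(SpatialParams, dict(raw.get("spatial") or {}), "spatial")
    stats = _build(StatsConfig, dict(raw.get("stats") or {}), "stats")

    return PipelineConfig(
        mode=mode,
        culture=culture,
        t_stim_min=float(raw.get("t_stim_min", 5.0)),
        dispense=dispense,
        bath_conc_nM=float(bath) if bath is not None else None,
        response=response,
        spatial=spatial,
        stats=stats,
        seed=int(raw.get("seed", 0)),
        render=bool(raw.get("render", False)),
        experiment_id=str(raw.get("experiment_id", "")),
    )
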