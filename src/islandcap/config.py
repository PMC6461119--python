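"""Declarative run configuration: one YAML file holding every stage's
parameter block. Unknown keys are rejected, and each run writes the resolved
configuration next to its outputs so artifacts are reproducible from
(config, seed) alone."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .design import CollapseParams, DesignParams
from .evaluate import SnpFilterParams
from .similarity import AlignParams, SimilarityThresholds
from .simulate import CaptureConfig, SimulationConfig, VariantConfig
from .tiling import TilingParams


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    thresholds: SimilarityThresholds = SimilarityThresholds()
    align: AlignParams = AlignParams()
    collapse: CollapseParams = CollapseParams()
    design: DesignParams = DesignParams()
    tiling: TilingParams = TilingParams()
    snp_filter: SnpFilterParams = SnpFilterParams()
    simulation: SimulationConfig = SimulationConfig()


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under {path or '<root>'}"
        )
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _NESTED.get((cls, name))
        if sub is not None:
            kwargs[name] = _build(sub, value, f"{path}.{name}" if path else name)
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "thresholds"): SimilarityThresholds,
    (RunConfig, "align"): AlignParams,
    (RunConfig, "collapse"): CollapseParams,
    (RunConfig, "design"): DesignParams,
    (RunConfig, "tiling"): TilingParams,
    (RunConfig, "snp_filter"): SnpFilterParams,
    (RunConfig, "simulation"): SimulationConfig,
    (DesignParams, "thresholds"): SimilarityThresholds,
    (DesignParams, "collapse"): CollapseParams,
    (SimulationConfig, "capture"): CaptureConfig,
    (SimulationConfig, "variants"): VariantConfig,
}


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data, "")


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration (defaults included)."""
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(cfg), fh, sort_keys=True)
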