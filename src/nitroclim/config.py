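"""YAML pipeline configuration with strict validation.

Unknown keys are rejected so typos surface immediately; every section has
working defaults, so an empty config file runs the whole pipeline on the
synthetic study population.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .climate import PeriodDefinition
from .synth import GeneratorConfig, ScenarioTrend

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    periods: PeriodDefinition = field(default_factory=PeriodDefinition)
    smooth_covariates: tuple[str, ...] = ("P_annual",)
    basis_size: int = 10
    n_draws: int = 1000
    n_members: int = 16

    def as_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section '{path}'; "
            f"allowed: {sorted(allowed)}"
        )
    return data


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    data = _build(PipelineConfig, dict(raw), "root")
    if "generator" in data:
        gen = _build(GeneratorConfig, dict(data["generator"]), "generator")
        if "scenarios" in gen:
            gen["scenarios"] = tuple(
                ScenarioTrend(**s) for s in gen["scenarios"]
            )
        data["generator"] = GeneratorConfig(**gen)
    if "periods" in data:
        per = _build(PeriodDefinition, dict(data["periods"]), "periods")
        data["periods"] = PeriodDefinition(
            **{k: tuple(v) for k, v in per.items()}
        )
    if "smooth_covariates" in data:
        data["smooth_covariates"] = tuple(data["smooth_covariates"])
    return PipelineConfig(**data)
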