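"""Structured configuration for the analysis pipeline.

All defaults are the package's study conditions; a YAML/JSON file can
override any subset. Changing the PD transform constants away from
their model-locked values is allowed but logged prominently, since every
published quantity depends on them.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .estimation import PopulationPrior
from .model import DEFAULT_PD_CONSTANTS, PDConstants
from .simulate import GeneratorConfig

logger = logging.getLogger(__name__)

__all__ = ["ModelConfig", "EstimationConfig", "MetricsConfig", "AnalysisConfig",
           "PipelineConfig", "load_config"]


@dataclass(frozen=True)
class ModelConfig:
    m: float = 1.0
    default_tau_h: float = 24.0
    pd_a: float = DEFAULT_PD_CONSTANTS.a
    pd_b: float = DEFAULT_PD_CONSTANTS.b
    pd_p: float = DEFAULT_PD_CONSTANTS.p

    @property
    def pd_constants(self) -> PDConstants:
        consts = PDConstants(self.pd_a, self.pd_b, self.pd_p)
        if consts != DEFAULT_PD_CONSTANTS:
            logger.warning(
                "PD constants overridden from model defaults: a=%s b=%s p=%s",
                self.pd_a, self.pd_b, self.pd_p,
            )
        return consts


@dataclass(frozen=True)
class EstimationConfig:
    sigma_res: float = 0.1
    multistart: bool = True
    last_n: int | None = None


@dataclass(frozen=True)
class MetricsConfig:
    range_low: float = 2.0
    range_high: float = 3.0
    max_gap_days: float | None = 56.0
    wcm_convention: str = "difference"


@dataclass(frozen=True)
class AnalysisConfig:
    z: float = 1.96
    sided: str = "two"


@dataclass(frozen=True)
class PipelineConfig:
    model: ModelConfig = field(default_factory=ModelConfig)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    estimation: EstimationConfig = field(default_factory=EstimationConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    prior_overrides: dict = field(default_factory=dict)

    @property
    def prior(self) -> PopulationPrior:
        """Population prior: the generator's PK distributions unless overridden."""
        base = {
            name: (self.generator.pk_means[name], self.generator.pk_sds[name])
            for name in ("c_max", "k", "cl", "v_d")
        }
        base.update(self.prior_overrides)
        return PopulationPrior(**base, sigma_res=self.estimation.sigma_res)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def with_seed(self, seed: int) -> "PipelineConfig":
        gen = dataclasses.replace(self.generator, seed=seed)
        return dataclasses.replace(self, generator=gen)


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML/JSON file.

    The file may contain top-level blocks ``model:``, ``generator:``,
    ``estimation:``, ``metrics:``, ``analysis:`` and
    ``prior_overrides:``; omitted keys keep package defaults. Keyword
    overrides (same block names mapped to dicts) are applied on top.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    for block, values in overrides.items():
        data.setdefault(block, {}).update(values)

    sections = {
        "model": ModelConfig,
        "generator": GeneratorConfig,
        "estimation": EstimationConfig,
        "metrics": MetricsConfig,
        "analysis": AnalysisConfig,
    }
    kwargs = {}
    for block, cls in sections.items():
        block_data = data.pop(block, {})
        kwargs[block] = _build(cls, block_data)
    kwargs["prior_overrides"] = {
        k: tuple(v) for k, v in data.pop("prior_overrides", {}).items()
    }
    if data:
        raise ValueError(f"unknown config blocks: {sorted(data)}")
    return PipelineConfig(**kwargs)
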