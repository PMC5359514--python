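"""Pipeline configuration: a validated, explicit record of every threshold.

Configs are YAML mappings validated before any computation; unknown keys are
rejected and every analysis threshold must be stated explicitly, so a config
file is a complete, self-contained description of a run.
:func:`default_config_dict` emits a fully populated template.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import consensus as cns
from . import factors as fct
from . import ordering as ordg
from . import segmentation as seg
from .pipeline import PipelineParams

__all__ = [
    "PipelineConfig",
    "ConfigError",
    "load_config",
    "default_config_dict",
    "config_hash",
]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class TrajectoryInput(_Strict):
    id: str
    topology: str
    trajectory: str


class CVDefinitionConfig(_Strict):
    id: str
    kind: str
    selections: list[str] = Field(default_factory=list)
    params: dict = Field(default_factory=dict)
    unit: str = ""


class InputConfig(_Strict):
    mode: Literal["synthetic", "cv_tables", "trajectories"]
    cv_tables: list[str] = Field(default_factory=list)
    trajectories: list[TrajectoryInput] = Field(default_factory=list)
    reference: str | None = None
    cv_definitions: Literal["default_pka"] | list[CVDefinitionConfig] = "default_pka"


class SyntheticConfig(_Strict):
    n_replicates: int = 13
    T: int = 3000
    noise_scale: float = 1.0


class SegmentationConfig(_Strict):
    window: int
    transition_z: float
    min_part_length: int | None = None


class FactorConfig(_Strict):
    n_factors: int | Literal["kaiser"]
    min_ratio: float
    min_rho: float
    varimax_tol: float = 1e-8
    varimax_max_iter: int = 1000


class OrderingConfig(_Strict):
    max_lag: int | None
    sig_k: float
    min_lag: int


class ConsensusConfig(_Strict):
    congruence_threshold: float
    salient_loading: float = cns.DEFAULT_SALIENT_LOADING
    event_quorum: float
    majority: float
    minority_max: float = cns.DEFAULT_MINORITY_MAX
    event_labels: dict[str, str] = Field(default_factory=dict)


class PipelineConfig(_Strict):
    seed: int
    outdir: str
    input: InputConfig
    synthetic: SyntheticConfig = Field(default_factory=SyntheticConfig)
    segmentation: SegmentationConfig
    factors: FactorConfig
    ordering: OrderingConfig
    consensus: ConsensusConfig

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be non-negative")
        return v

    def params(self) -> PipelineParams:
        return PipelineParams(
            window=self.segmentation.window,
            transition_z=self.segmentation.transition_z,
            min_part_length=self.segmentation.min_part_length,
            n_factors=self.factors.n_factors,
            varimax_tol=self.factors.varimax_tol,
            varimax_max_iter=self.factors.varimax_max_iter,
            min_ratio=self.factors.min_ratio,
            min_rho=self.factors.min_rho,
            max_lag=self.ordering.max_lag,
            sig_k=self.ordering.sig_k,
            min_lag=self.ordering.min_lag,
            congruence_threshold=self.consensus.congruence_threshold,
            salient_loading=self.consensus.salient_loading,
            event_quorum=self.consensus.event_quorum,
            majority=self.consensus.majority,
            minority_max=self.consensus.minority_max,
            event_labels=dict(self.consensus.event_labels),
        )


def default_config_dict(mode: str = "synthetic") -> dict:
    """A fully populated config template with the package defaults."""
    return {
        "seed": 1,
        "outdir": "results/run",
        "input": {"mode": mode},
        "synthetic": {"n_replicates": 13, "T": 3000, "noise_scale": 1.0},
        "segmentation": {
            "window": seg.DEFAULT_WINDOW,
            "transition_z": seg.DEFAULT_TRANSITION_Z,
            "min_part_length": None,
        },
        "factors": {
            "n_factors": "kaiser",
            "min_ratio": fct.DEFAULT_MIN_RATIO,
            "min_rho": fct.DEFAULT_MIN_RHO,
            "varimax_tol": 1e-8,
            "varimax_max_iter": 1000,
        },
        "ordering": {
            "max_lag": None,
            "sig_k": ordg.DEFAULT_SIG_K,
            "min_lag": ordg.DEFAULT_MIN_LAG,
        },
        "consensus": {
            "congruence_threshold": cns.DEFAULT_CONGRUENCE_THRESHOLD,
            "salient_loading": cns.DEFAULT_SALIENT_LOADING,
            "event_quorum": cns.DEFAULT_EVENT_QUORUM,
            "majority": cns.DEFAULT_MAJORITY,
            "minority_max": cns.DEFAULT_MINORITY_MAX,
            "event_labels": {},
        },
    }


def load_config(path: str | Path) -> PipelineConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    try:
        return PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{path}: invalid config:\n{exc}") from exc


def config_hash(config: PipelineConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
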