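"""Run configuration: a structured, validated description of a full
simulate-and-analyze run, loadable from YAML.

A single global seed is expanded into independent per-stage,
per-participant streams via ``numpy.random.SeedSequence`` so that any stage
can be re-run in isolation and reproduce its part of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .agents import AgentParams
from .epochs import GenParams

__all__ = ["RunConfig", "load_config", "config_hash", "stage_rng"]


@dataclass(frozen=True)
class DesignConfig:
    n_trials: int = 100
    n_blocks: int = 5
    ev_diff: float = 0.9


@dataclass(frozen=True)
class AnalysisConfig:
    rsa_window: tuple = (0.30, 0.60)
    cluster_threshold_p: float = 0.05
    n_permutations: int = 10000
    smoothing_hwhm_ms: float = 35.0
    min_samples_per_trial: int = 5


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    n_per_group: int = 10
    design: DesignConfig = field(default_factory=DesignConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    gen: GenParams = field(default_factory=GenParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    output_dir: str = "sampeeg_run"

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (group statistics need it)")
        t0, t1 = self.analysis.rsa_window
        if not (-0.2 <= t0 < t1 <= 0.8):
            raise ValueError("rsa_window must lie within the epoch (-0.2, 0.8)")


def _from_mapping(cls, mapping):
    return cls(**mapping) if isinstance(mapping, dict) else mapping


def load_config(path) -> RunConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    for key, cls in (
        ("design", DesignConfig),
        ("agent", AgentParams),
        ("gen", GenParams),
        ("analysis", AnalysisConfig),
    ):
        if key in raw:
            if key == "analysis" and isinstance(raw[key], dict) and "rsa_window" in raw[key]:
                raw[key]["rsa_window"] = tuple(raw[key]["rsa_window"])
            raw[key] = _from_mapping(cls, raw[key])
    return RunConfig(**raw)


def config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def stage_rng(seed: int, stage: str, participant: int = 0) -> np.random.Generator:
    """Independent stream for (seed, stage, participant)."""
    stage_key = int(hashlib.sha256(stage.encode()).hexdigest()[:8], 16)
    ss = np.random.SeedSequence([seed, stage_key, participant])
    return np.random.default_rng(ss)
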