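"""Pipeline configuration: one structured file mapping onto every stage spec.

A config is YAML or JSON with sections ``protocol``, ``activation``,
``frontend``, ``segmentation``, ``features``, ``classifier``,
``motion_test``, ``stats``, ``experiment``, and a global ``seed``. Missing
sections and fields fall back to the pipeline defaults (the published
protocol constants). A single global seed deterministically derives every
per-stage seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from emgpr.features import FeatureSpec
from emgpr.motiontest import MotionTestConfig
from emgpr.preprocess import SegmentationSpec
from emgpr.sessions import ProtocolSpec
from emgpr.synth import ActivationModel, FrontEndSpec, make_activation_matrix


@dataclass
class ExperimentSpec:
    n_subjects: int = 4
    # condition name -> channel subset (None = all channels)
    conditions: dict[str, list[int] | None] = field(
        default_factory=lambda: {"ch16": None, "ch8": list(range(0, 16, 2))}
    )
    paired: bool = True
    overlap: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("experiment.n_subjects must be >= 1")
        if len(self.conditions) < 1:
            raise ValueError("experiment.conditions must be non-empty")
        if not self.paired and self.n_subjects < 2 * len(self.conditions):
            raise ValueError(
                "independent design needs at least 2 subjects per condition"
            )
        if not (0.0 <= self.overlap <= 1.0):
            raise ValueError("experiment.overlap must lie in [0, 1]")


@dataclass
class StatsSpec:
    m: int = 5
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("stats.m must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("stats.alpha must lie in (0, 1)")


@dataclass
class PipelineConfig:
    seed: int = 0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    activation_params: dict = field(default_factory=dict)
    frontend: FrontEndSpec = field(default_factory=FrontEndSpec)
    segmentation: SegmentationSpec = field(default_factory=SegmentationSpec)
    features: FeatureSpec = field(default_factory=FeatureSpec)
    ridge_lambda: float | None = None
    motion_test: MotionTestConfig = field(default_factory=MotionTestConfig)
    stats: StatsSpec = field(default_factory=StatsSpec)
    experiment: ExperimentSpec = field(default_factory=ExperimentSpec)
    raw: dict = field(default_factory=dict, repr=False)

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Derive a per-stage seed from the global seed, deterministically."""
        digest = hashlib.sha256(f"{self.seed}:{stage}:{index}".encode()).digest()
        return int.from_bytes(digest[:4], "little")

    def make_activation(self, overlap: float | None = None, seed: int | None = None) -> ActivationModel:
        params = dict(self.activation_params)
        if overlap is not None:
            params["overlap"] = overlap
        params.setdefault("overlap", self.experiment.overlap)
        return make_activation_matrix(
            n_movements=len(self.protocol.movements),
            n_channels=self.protocol.n_channels,
            rng_seed=self.stage_seed("activation") if seed is None else seed,
            **params,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTION_BUILDERS = {
    "protocol": lambda d: ProtocolSpec(**{**d, "movements": tuple(d["movements"])} if "movements" in d else d),
    "frontend": lambda d: FrontEndSpec(**d),
    "segmentation": lambda d: SegmentationSpec(**d),
    "features": lambda d: FeatureSpec(**{**d, "features": tuple(d["features"])} if "features" in d else d),
    "motion_test": lambda d: MotionTestConfig(**d),
    "stats": lambda d: StatsSpec(**d),
    "experiment": lambda d: ExperimentSpec(**d),
}


def load_config_dict(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return data


def build_config(data: dict) -> PipelineConfig:
    """Construct a PipelineConfig from a parsed mapping, applying defaults."""
    errors = validate_config_dict(data)
    if errors:
        raise ValueError("invalid config:\n" + "\n".join(errors))
    kwargs: dict[str, Any] = {"seed": int(data.get("seed", 0)), "raw": data}
    for section, builder in _SECTION_BUILDERS.items():
        if section in data:
            kwargs[section if section != "motion_test" else "motion_test"] = builder(data[section])
    if "activation" in data:
        kwargs["activation_params"] = dict(data["activation"])
    if "classifier" in data:
        kwargs["ridge_lambda"] = data["classifier"].get("ridge_lambda")
    cfg = PipelineConfig(**kwargs)
    cfg.frontend.validate_against(cfg.protocol.sampling_rate)
    return cfg


def validate_config_dict(data: dict) -> list[str]:
    """Every violated invariant, as 'section.field: message' strings."""
    errors: list[str] = []
    sections: dict[str, Any] = {}
    for section, builder in _SECTION_BUILDERS.items():
        payload = data.get(section, {})
        if not isinstance(payload, dict):
            errors.append(f"{section}: must be a mapping")
            continue
        try:
            sections[section] = builder(payload)
        except (TypeError, ValueError) as exc:
            errors.append(f"{section}: {exc}")
    act = data.get("activation", {})
    if isinstance(act, dict):
        for key in ("overlap", "ramp_fraction"):
            if key in act and not (0.0 <= act[key] <= (0.5 if key == "ramp_fraction" else 1.0)):
                errors.append(f"activation.{key}: outside valid range")
        if act.get("baseline_noise_rms", 0) < 0:
            errors.append("activation.baseline_noise_rms: must be >= 0")
    else:
        errors.append("activation: must be a mapping")
    if "protocol" in sections and "frontend" in sections:
        try:
            sections["frontend"].validate_against(sections["protocol"].sampling_rate)
        except ValueError as exc:
            errors.append(f"frontend: {exc}")
    return errors


def load_config(path: str | Path) -> PipelineConfig:
    return build_config(load_config_dict(path))
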