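"""Run configuration: documented defaults, YAML round-trip, semantic hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ringdose.phantom import PhantomParams
from ringdose.network import TrainingConfig
from ringdose.rings import DEFAULT_RING_WIDTH_MM, MAX_RINGS
from ringdose.dvh import DEFAULT_ALPHA_BETA, DEFAULT_CONSTRAINTS
from ringdose.evaluate import DEFAULT_QA_THRESHOLD


@dataclass
class RunConfig:
    """Everything a pipeline run needs; every field has a default."""

    phantom: PhantomParams = field(default_factory=PhantomParams)
    ring_width_mm: float = DEFAULT_RING_WIDTH_MM
    n_rings: int = MAX_RINGS
    alpha_beta: dict = field(default_factory=lambda: dict(DEFAULT_ALPHA_BETA))
    constraints: dict = field(default_factory=lambda: dict(DEFAULT_CONSTRAINTS))
    training: TrainingConfig = field(default_factory=TrainingConfig)
    qa_threshold: float = DEFAULT_QA_THRESHOLD
    n_plans: int = 218
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    group_split_by_patient: bool = False
    seed: int = 42
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        return d

    def semantic_hash(self) -> str:
        """Stable hash over every semantic field (paths/log level excluded)."""
        d = self.to_dict()
        d.pop("log_level", None)
        blob = json.dumps(d, sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _apply(dc, data: dict, ctx: str):
    known = set(dc.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s) under {ctx}: {sorted(unknown)}")
    return data


def load_config(path) -> RunConfig:
    """Load a YAML config; unknown keys are rejected, absent keys default."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    cfg = RunConfig()
    top = {f for f in cfg.__dataclass_fields__}
    unknown = set(data) - top
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    kwargs = {}
    if "phantom" in data:
        sub = _apply(PhantomParams, data.pop("phantom"), "phantom")
        sub = {k: tuple(v) if isinstance(v, list) else v for k, v in sub.items()}
        kwargs["phantom"] = PhantomParams(**sub)
    if "training" in data:
        kwargs["training"] = TrainingConfig(**_apply(TrainingConfig, data.pop("training"), "training"))
    if "split_fractions" in data:
        kwargs["split_fractions"] = tuple(data.pop("split_fractions"))
    kwargs.update(data)
    return RunConfig(**kwargs)


def save_config(path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
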