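"""Structured run configuration: one YAML file drives a whole experiment.

Unknown keys are rejected so a typo in a config never silently falls back to
a default.  The file round-trips losslessly through :func:`load_config` /
:func:`save_config`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .detect import DetectorConfig
from .postprocess import PostprocessConfig
from .segment import SegConfig
from .synth import SceneSpec

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/default"
    n_images: int = 50
    train_fraction: float = 0.8
    fov_mm2: Optional[float] = None
    verbosity: int = 1
    generator: SceneSpec = field(default_factory=SceneSpec)
    detector: DetectorConfig = field(default_factory=DetectorConfig.small)
    segmenter: SegConfig = field(default_factory=SegConfig.small)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)


_SUBCONFIGS = {
    "generator": SceneSpec,
    "detector": DetectorConfig,
    "segmenter": SegConfig,
    "postprocess": PostprocessConfig,
}

_TUPLE_FIELDS = {"input_size", "anchor_scales", "anchor_ratios"}


def _build(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and isinstance(v, list) else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    top_names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - top_names
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for key, val in raw.items():
        if key in _SUBCONFIGS:
            kwargs[key] = _build(_SUBCONFIGS[key], val or {})
        else:
            kwargs[key] = val
    return RunConfig(**kwargs)


def save_config(cfg: RunConfig, path) -> None:
    data = dataclasses.asdict(cfg)
    for key in _SUBCONFIGS:
        sub = data[key]
        for k, v in list(sub.items()):
            if isinstance(v, tuple):
                sub[k] = list(v)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of a config, for run logs."""
    data = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=list)
    return hashlib.sha256(data.encode()).hexdigest()[:12]
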