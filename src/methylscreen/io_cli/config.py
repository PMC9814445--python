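"""Structured pipeline configuration with lossless YAML round-tripping.

Unknown keys are rejected rather than ignored, so a typo in a config file
fails loudly instead of silently running with defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, get_args, get_origin, get_type_hints

import yaml

from ..cohort_sim import CohortParams
from ..context_qc import FilterConfig
from ..conversion_sim import ConversionParams, FragmentParams
from ..methylquant import SiteClassConfig
from ..panel_design import SelectionThresholds
from ..screen_model import TrainConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "out"
    filter: FilterConfig = field(default_factory=FilterConfig)
    sites: SiteClassConfig = field(default_factory=SiteClassConfig)
    selection: SelectionThresholds = field(default_factory=SelectionThresholds)
    fragments: FragmentParams = field(default_factory=FragmentParams)
    conversion: ConversionParams = field(default_factory=ConversionParams)
    cohort: CohortParams = field(default_factory=CohortParams)
    training: TrainConfig = field(default_factory=TrainConfig)


def _coerce(value: Any, annotation: Any) -> Any:
    """Rebuild nested dataclasses and tuple-typed fields from plain YAML data."""
    if value is None:
        return None
    if is_dataclass(annotation) and isinstance(value, dict):
        return from_dict(annotation, value)
    origin = get_origin(annotation)
    if (origin is tuple or annotation is tuple) and isinstance(value, (list, tuple)):
        args = get_args(annotation)
        if args and args[-1] is Ellipsis:
            return tuple(_coerce(v, args[0]) for v in value)
        if args and len(args) == len(value):
            return tuple(_coerce(v, a) for v, a in zip(value, args))
        return tuple(value)
    if (origin is dict or annotation is dict) and isinstance(value, dict):
        args = get_args(annotation)
        val_t = args[1] if len(args) == 2 else Any
        return {k: _coerce(v, val_t) for k, v in value.items()}
    return value


def from_dict(cls: type, data: dict) -> Any:
    """Instantiate a (possibly nested) config dataclass, rejecting unknown keys."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    hints = get_type_hints(cls)
    kwargs = {name: _coerce(value, hints.get(name, Any)) for name, value in data.items()}
    return cls(**kwargs)


def _plain(value: Any) -> Any:
    if is_dataclass(value) and not isinstance(value, type):
        return {f.name: _plain(getattr(value, f.name)) for f in fields(value)}
    if isinstance(value, tuple):
        return [_plain(v) for v in value]
    if isinstance(value, dict):
        return {k: _plain(v) for k, v in value.items()}
    if isinstance(value, list):
        return [_plain(v) for v in value]
    return value


def to_dict(config: Any) -> dict:
    return _plain(config)


def load_config(path: str | Path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return from_dict(PipelineConfig, data)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(config), sort_keys=True))


def config_hash(config: PipelineConfig) -> str:
    """Stable content hash used for run logging."""
    canonical = yaml.safe_dump(to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def replace(config: Any, **changes: Any) -> Any:
    return dataclasses.replace(config, **changes)
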