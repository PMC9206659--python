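"""Typed run configuration with strict (unknown-key rejecting) validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict, is_dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config", "config_hash"]


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys, recursing."""
    known = {f.name: f for f in fields(cls)}
    unknown = set(data) - set(known)
    if unknown:
        raise ValueError(f"{cls.__name__}: unknown config keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = known[name].type
        target = _SECTION_TYPES.get((cls.__name__, name))
        if target is not None and isinstance(value, dict):
            kwargs[name] = _from_dict(target, value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


@dataclass
class PolarimetryOptions:
    sign_s1: int = 1
    sign_s3: int = 1
    snr_threshold: float = 3.0
    snr_threshold_display: float = 1.0
    r_branch: str = "auto"  # plus | minus | auto
    r_probe: float = 2.0

    def __post_init__(self) -> None:
        if self.r_branch not in ("plus", "minus", "auto"):
            raise ValueError("r_branch must be plus, minus or auto")
        if self.snr_threshold < 0:
            raise ValueError("snr_threshold must be >= 0")


@dataclass
class TextureOptions:
    tiles_per_side: int = 8
    n_g: int = 64
    d: int = 1
    min_density_frac: float = 0.01
    printed_correlation_sign: bool = False

    def __post_init__(self) -> None:
        if self.tiles_per_side < 1 or self.n_g < 2 or self.d < 1:
            raise ValueError("invalid texture options")
        if not 0 <= self.min_density_frac <= 1:
            raise ValueError("min_density_frac must be in [0, 1]")


@dataclass
class StatsOptions:
    trim_lo: float = 1.0
    trim_hi: float = 99.0
    trim_for_classification: bool = False  # default: trimming for stats only
    reference_group: str = "normal"

    def __post_init__(self) -> None:
        if self.trim_lo >= self.trim_hi:
            raise ValueError("trim_lo must be < trim_hi")


@dataclass
class ClassifyOptions:
    k_folds: int = 5
    repeats: int = 1000
    threshold: float = 0.5
    ridge_alpha: float = 0.0
    positive_label: str = "tumor"
    held_out_cores: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must be in (0, 1)")


@dataclass
class SimulateOptions:
    n_cores_per_group: int = 8
    core_size: int = 512
    presets_file: str | None = None  # None -> packaged defaults


@dataclass
class RunConfig:
    """Flat, typed pipeline configuration; unknown keys are rejected."""

    out_dir: str = "pshg_out"
    input_stacks: list = field(default_factory=list)  # (core_id, path, label)
    seed: int = 0
    polarimetry: PolarimetryOptions = field(default_factory=PolarimetryOptions)
    texture: TextureOptions = field(default_factory=TextureOptions)
    stats: StatsOptions = field(default_factory=StatsOptions)
    classify: ClassifyOptions = field(default_factory=ClassifyOptions)
    simulate: SimulateOptions = field(default_factory=SimulateOptions)


_SECTION_TYPES = {
    ("RunConfig", "polarimetry"): PolarimetryOptions,
    ("RunConfig", "texture"): TextureOptions,
    ("RunConfig", "stats"): StatsOptions,
    ("RunConfig", "classify"): ClassifyOptions,
    ("RunConfig", "simulate"): SimulateOptions,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config file (or defaults) with optional flat overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    cfg = _from_dict(RunConfig, data)
    if overrides:
        for key, value in overrides.items():
            if value is None:
                continue
            if "." in key:
                section, name = key.split(".", 1)
                setattr(getattr(cfg, section), name, value)
            else:
                setattr(cfg, key, value)
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Deterministic hash of the analytic configuration.

    The output location is excluded so identical analyses written to
    different directories share a hash (and hence byte-identical
    CSV/JSON artifacts).
    """
    payload = asdict(cfg)
    payload.pop("out_dir", None)
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
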