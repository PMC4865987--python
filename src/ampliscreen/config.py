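"""Run configuration: serializable parameters for the end-to-end pipeline."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from ampliscreen.genotype import CallThresholds
from ampliscreen.pooling import PoolingParams
from ampliscreen.simulate import DepthModel, ReadSimParams


def _construct_unchecked(klass, values: dict):
    """Build a params dataclass without running invariant checks.

    Loading a config must not fail fast: validate_config reports every
    violated constraint instead of stopping at the first constructor error.
    """
    obj = object.__new__(klass)
    defaults = {f.name: f.default for f in dataclasses.fields(klass)}
    unknown = set(values) - set(defaults)
    if unknown:
        raise ValueError(f"{klass.__name__}: unknown fields {sorted(unknown)}")
    for name, default in defaults.items():
        object.__setattr__(obj, name, values.get(name, default))
    return obj


@dataclass
class RunConfig:
    """Full configuration of an end-to-end run; a copy is written into the
    output directory so every run is reproducible from its artifacts."""

    outdir: str = "run_output"
    seed: int = 0
    preset: str = "paper-scale"
    paralog_mode: str = "dilute"
    # user-supplied inputs; when unset the simulator generates the universe
    reference: Optional[str] = None
    panel: Optional[str] = None
    amplicons: Optional[str] = None
    fastq_dir: Optional[str] = None
    known_list: Optional[str] = None
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    pooling: PoolingParams = field(default_factory=PoolingParams)
    depth_model: DepthModel = field(default_factory=DepthModel)
    read_params: ReadSimParams = field(default_factory=ReadSimParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        doc = dict(doc)
        for key, klass in (
            ("thresholds", CallThresholds),
            ("pooling", PoolingParams),
            ("depth_model", DepthModel),
            ("read_params", ReadSimParams),
        ):
            if key in doc and isinstance(doc[key], dict):
                doc[key] = _construct_unchecked(klass, doc[key])
        return cls(**doc)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "RunConfig":
        """Load YAML (or JSON — valid YAML) configuration."""
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_dict(doc)

    def save(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def validate_config(config: RunConfig) -> list[str]:
    """Return every violated constraint (empty list means valid)."""
    v: list[str] = []
    if config.seed < 0:
        v.append("seed must be non-negative")
    if config.preset not in ("paper-scale", "tiny"):
        v.append(f"unknown preset {config.preset!r}")
    if config.paralog_mode not in ("dilute", "enrich"):
        v.append(f"unknown paralog_mode {config.paralog_mode!r}")
    t = config.thresholds
    try:
        CallThresholds(**dataclasses.asdict(t))
    except ValueError as exc:
        v.append(f"thresholds: {exc}")
    try:
        PoolingParams(**dataclasses.asdict(config.pooling))
    except ValueError as exc:
        v.append(f"pooling: {exc}")
    try:
        DepthModel(**dataclasses.asdict(config.depth_model))
    except ValueError as exc:
        v.append(f"depth_model: {exc}")
    if config.read_params.read_length < 50:
        v.append("read_length must be >= 50")
    if not (0 <= config.read_params.per_base_error < 0.5):
        v.append("per_base_error out of range")
    for name in ("reference", "panel", "amplicons", "fastq_dir", "known_list"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            v.append(f"{name} path does not exist: {path}")
    return v
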