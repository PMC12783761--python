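"""Run configuration: one flat JSON/YAML file drives the whole chain.

The schema is explicit — unknown keys are rejected — and every block maps
onto the dataclasses of the corresponding module.  A stable hash of the
validated configuration is stamped into every output file so reruns are
attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from .hfl_core import FederationConfig

__all__ = ["RunConfig", "CohortBlock", "SelectionBlock", "EvaluationBlock",
           "load_config", "config_hash"]

METHODS = ("hflm", "fedavg", "fedprox", "moon", "fedproto", "kd", "cdtm",
           "clinical")


@dataclass
class CohortBlock:
    scale: str = "tiny"            # 'tiny' or 'full'
    image_size: int = 64
    channels: int = 1
    base_seed: int = 0
    image_format: str = "png"


@dataclass
class SelectionBlock:
    alpha: float = 0.05
    k: int = 15
    hidden_n: int = 50
    extractor: str = "local"       # 'local' or 'global' feature pathway


@dataclass
class EvaluationBlock:
    calibration_bins: int = 10
    crossval: bool = False
    stratified: bool = False


@dataclass
class RunConfig:
    output_dir: str = "runs/default"
    seed: int = 0
    method: str = "hflm"
    server_index: int = 0
    global_arch: str = "tiny_global"
    local_arch: str = "tiny_local"
    cohort: CohortBlock = field(default_factory=CohortBlock)
    federation: FederationConfig = field(default_factory=FederationConfig)
    selection: SelectionBlock = field(default_factory=SelectionBlock)
    evaluation: EvaluationBlock = field(default_factory=EvaluationBlock)

    def validate(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.cohort.scale not in ("tiny", "full"):
            raise ValueError("cohort.scale must be 'tiny' or 'full'")
        if self.cohort.channels not in (1, 3):
            raise ValueError("cohort.channels must be 1 or 3")
        if self.selection.extractor not in ("local", "global"):
            raise ValueError("selection.extractor must be 'local' or 'global'")
        self.federation.validate()


def _from_mapping(cls, data: dict, path: str):
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        f = names[key]
        if dataclasses.is_dataclass(f.type) or f.name in (
                "cohort", "federation", "selection", "evaluation"):
            sub = {"cohort": CohortBlock, "federation": FederationConfig,
                   "selection": SelectionBlock,
                   "evaluation": EvaluationBlock}[f.name]
            kwargs[key] = _from_mapping(sub, val, f"{path}.{key}")
        else:
            kwargs[key] = val
    return cls(**kwargs)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Read a JSON or YAML config file; flat CLI overrides win."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        node = data
        *parents, leaf = key.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[leaf] = val
    cfg = _from_mapping(RunConfig, data, "config")
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
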