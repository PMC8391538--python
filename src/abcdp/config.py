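"""Run configuration: YAML/JSON loading, validation, serialization."""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["RunConfig", "ConfigError", "load_config"]

_MODELS = ("mixture", "polynomial", "external-csv")
_KINDS = ("mmd", "weighted_l2")


class ConfigError(ValueError):
    """Invalid run configuration; the message carries the offending field path."""


@dataclass
class RunConfig:
    model: str = "mixture"
    # distance
    kind: str = "mmd"
    bandwidth: float | str = "median"  # "median" or a positive number
    clip: float | None = None
    weights: list | None = None
    delta_rho: float | str = "auto"
    # privacy / ABC
    epsilon_total: float = math.inf
    epsilon_abc: float = 0.05
    c: int = 10
    resample: bool = False
    # stream sizes
    T: int = 2000
    n_observed: int = 1000
    n_per_dataset: int = 1000
    # external data / misc
    observed_csv: str | None = None
    seed: int = 0

    def validate(self) -> "RunConfig":
        def bad(path, msg):
            raise ConfigError(f"{path}: {msg}")

        if self.model not in _MODELS:
            bad("model", f"must be one of {_MODELS}, got {self.model!r}")
        if self.kind not in _KINDS:
            bad("kind", f"must be one of {_KINDS}, got {self.kind!r}")
        if self.bandwidth != "median" and not (
            isinstance(self.bandwidth, (int, float)) and self.bandwidth > 0
        ):
            bad("bandwidth", 'must be "median" or a positive number')
        if self.clip is not None and not self.clip > 0:
            bad("clip", "must be positive when set")
        if not (self.epsilon_total > 0):
            bad("epsilon_total", "must be positive (use 'inf' for non-private)")
        if self.delta_rho != "auto" and not (
            isinstance(self.delta_rho, (int, float)) and self.delta_rho > 0
        ):
            bad("delta_rho", 'must be "auto" or a positive number')
        if self.kind == "weighted_l2" and self.delta_rho == "auto" and math.isfinite(self.epsilon_total):
            bad(
                "delta_rho",
                "weighted_l2 has no derivable sensitivity; supply delta_rho explicitly",
            )
        for name in ("c", "T", "n_observed", "n_per_dataset"):
            if not (isinstance(getattr(self, name), (int, np.integer)) and getattr(self, name) >= 1):
                bad(name, "must be a positive integer")
        if self.model == "external-csv" and not self.observed_csv:
            bad("observed_csv", "required when model is 'external-csv'")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(self.epsilon_total):
            d["epsilon_total"] = "inf"
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{sorted(unknown)[0]}: unknown configuration key")
        if raw.get("epsilon_total") in ("inf", "Infinity", None):
            raw["epsilon_total"] = math.inf
        return cls(**raw).validate()


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (or JSON) run configuration from disk."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigError("<root>: configuration must be a mapping")
    return RunConfig.from_dict(raw)


def dump_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
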