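"""Run configuration: every tunable default, YAML round trip, schema check."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml

SCHEMA_VERSION = "1"


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline defaults in one validated, echoable record."""

    # grid / tensorization
    p1: int = 33
    p2: int = 32
    # covariate selection
    k_select: int = 30
    nested: bool = True           # False = one global covariate selection
    pseudo_count: float = 1.0
    # discriminant model
    lambda_rule: str = "cv"       # cv | sparsity | fixed
    s_target: int = 10
    n_lambdas: int = 50
    lambda_min_ratio: float = 0.01
    cv_folds: int = 5
    fixed_lambda: float | None = None
    ridge_eps: float = 1e-4
    cd_tol: float = 1e-8
    flipflop_tol: float = 1e-6
    # evaluation
    train_frac: float = 0.67
    iterations: int = 100
    scheme: str = "split"         # split (67/33 x N) | cv3
    methods: tuple = ("catch", "dlda", "rf")
    # downstream
    top_features: int = 10
    correlation_method: str = "pearson"
    # io
    delimiter: str = ","
    impute_missing: bool = False
    # simulation
    simulate: bool = False
    sim_preset: str = "moderate"  # moderate | null | strong
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_rule not in ("cv", "sparsity", "fixed"):
            raise ConfigError(f"unknown lambda_rule {self.lambda_rule!r}")
        if self.scheme not in ("split", "cv3"):
            raise ConfigError(f"unknown scheme {self.scheme!r}")
        if self.sim_preset not in ("moderate", "null", "strong"):
            raise ConfigError(f"unknown sim_preset {self.sim_preset!r}")
        if self.correlation_method not in ("pearson", "spearman"):
            raise ConfigError(f"unknown correlation_method {self.correlation_method!r}")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigError("train_frac must be in (0, 1)")
        if isinstance(self.methods, list):
            self.methods = tuple(self.methods)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must hold a key-value mapping")
        raw.pop("schema_version", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]
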