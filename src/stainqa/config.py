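"""Run configuration, validation, seeding and reproducibility manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Configuration validation failure naming the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"config field '{field_name}': {message}")


@dataclass
class RunConfig:
    """Paths, pipeline sizes, thresholds and seeds for a pipeline run.

    ``alpha``/``beta`` may be numbers or the string ``"fit"`` to fit them
    from data during the run.  Every stochastic stage derives its stream from
    ``seed``.
    """

    data_dir: str = "data"
    checkpoint_dir: str = "checkpoints"
    output_dir: str = "outputs"
    T: int = 5
    C: int = 3
    alpha: float | str = "fit"
    beta: float | str = "fit"
    seed: int = 0
    preset: str = "desk"             # "desk" or "full"
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.T < 1:
            raise ConfigError("T", f"must be >= 1, got {self.T}")
        if self.C < 1:
            raise ConfigError("C", f"must be >= 1, got {self.C}")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "fit":
                    raise ConfigError(name, f"must be a number or 'fit', got {v!r}")
            elif not (0.0 <= float(v) <= 1.0):
                raise ConfigError(name, f"must lie in [0, 1], got {v}")
        if self.preset not in ("desk", "full"):
            raise ConfigError("preset", f"must be 'desk' or 'full', got {self.preset!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed", "must be an integer")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra).validate()

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def derive_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the base seed."""
    h = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def rng_for(base_seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(base_seed, stage))


def write_manifest(out_dir: str | Path, config: RunConfig,
                   stage_seeds: dict[str, int] | None = None) -> Path:
    """Write the reproducibility manifest (seeds, config hash, versions)."""
    import numpy
    import scipy

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "stage_seeds": stage_seeds or {},
        "versions": {
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
        },
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
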