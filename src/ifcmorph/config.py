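"""Run configuration: one serializable object per end-to-end run.

A run is reproducible from its config plus the root seed alone; every CLI
invocation writes a provenance record (config hash, seed, package
versions) next to its outputs. The YAML round trip is bit-exact for the
documented key set.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .preprocess import MIN_SHORT_EDGE
from .sampling import QuotaSpec, SplitSpec
from .synth import HierarchySpec
from .training import TrainConfig


@dataclass(frozen=True)
class RunConfig:
    """Stage parameters for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/out"
    # generator
    hierarchy: dict = field(
        default_factory=lambda: {
            "n_bulls": 6,
            "ejaculates_per_bull": {"fresh": 2, "frozen": 1},
            "files_per_ejaculate": 2,
            "events_per_file": 50_000,
            "bull_effect_sd": 0.05,
            "ejaculate_effect_sd": 0.03,
        }
    )
    domain_shift_scale: float = 1.0
    canvas_px: int = 96
    # preprocess
    min_short_edge: int = MIN_SHORT_EDGE
    # sampling
    quota: int = 200
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    lobo_fractions: tuple[float, ...] = (0.1, 0.2, 0.5, 1.0)
    # training
    train: dict = field(default_factory=lambda: asdict(TrainConfig()))
    n_seeds: int = 3
    # evaluation
    bootstrap_B: int = 5000
    ci_level: float = 0.95

    # -- factories -------------------------------------------------------
    def hierarchy_spec(self) -> HierarchySpec:
        return HierarchySpec(seed=self.seed, **self.hierarchy)

    def quota_spec(self, allow_short: bool = False) -> QuotaSpec:
        return QuotaSpec(per_stratum_quota=self.quota, allow_short=allow_short)

    def split_spec(self) -> SplitSpec:
        return SplitSpec(fractions=tuple(self.split_fractions), seed=self.seed)

    def train_config(self, **overrides) -> TrainConfig:
        kw = dict(self.train)
        kw.setdefault("seed", self.seed)
        kw.update(overrides)
        return TrainConfig(**kw)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["split_fractions"] = list(self.split_fractions)
        d["lobo_fractions"] = list(self.lobo_fractions)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)
        )

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "split_fractions" in d:
            d["split_fractions"] = tuple(d["split_fractions"])
        if "lobo_fractions" in d:
            d["lobo_fractions"] = tuple(d["lobo_fractions"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} does not hold a mapping")
        return cls.from_dict(raw)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def provenance_record(cfg: RunConfig) -> dict:
    import numpy
    import pandas

    from . import __version__

    return {
        "config_hash": cfg.digest(),
        "seed": cfg.seed,
        "versions": {
            "ifcmorph": __version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
        },
    }


def write_provenance(cfg: RunConfig, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "provenance.json").write_text(
        json.dumps(provenance_record(cfg), indent=2, sort_keys=True)
    )
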