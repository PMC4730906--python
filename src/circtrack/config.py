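"""Run configuration: a validated bundle of grid, prior, and run settings.

Configs load from YAML or JSON; every field has the harness default, so an
empty config is valid.  Commands write a JSON provenance sidecar (package
version, config hash, seed) sufficient to re-run bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .grid import StateGrid, TransitionPrior, build_grid
from .synth import HARNESS_K, HARNESS_SIGMA2

__all__ = ["RunConfig", "write_sidecar"]


@dataclass
class RunConfig:
    m: int = 20
    ell: float = 19.0
    kappa_spacing: str = "linear"
    K: float = HARNESS_K
    sigma2: float = HARNESS_SIGMA2
    tail_length: int = 50
    window_sizes: list[int] = field(default_factory=lambda: [50, 100, 200, 400])
    overlap: float = 0.98
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.ell <= 0:
            raise ValueError("ell must be positive")
        if self.K < 0 or self.sigma2 <= 0:
            raise ValueError("K must be >= 0 and sigma2 > 0")
        if self.tail_length < 1:
            raise ValueError("tail_length must be >= 1")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def grid(self) -> StateGrid:
        return build_grid(self.m, self.ell, kappa_spacing=self.kappa_spacing)

    def prior(self, grid: StateGrid | None = None) -> TransitionPrior:
        return TransitionPrior.from_grid(
            grid or self.grid(), K=self.K, sigma2=self.sigma2
        )

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_sidecar(out_path: str | Path, config: RunConfig, **extra) -> Path:
    """Write the JSON provenance sidecar next to an output file."""
    side = Path(str(out_path) + ".meta.json")
    side.write_text(
        json.dumps(
            {
                "version": __version__,
                "config": asdict(config),
                "config_hash": config.digest(),
                "seed": config.seed,
                **extra,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return side
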