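"""Run configuration for the end-to-end benchmark pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Sequence

from .mock_community import (
    DEFAULT_LOAD_MEDIANS_PG,
    DILUTION_SERIES_PG,
    KITS,
    InvalidConfigError,
    default_bias,
)

__all__ = ["RunConfig", "config_hash"]

_DEFAULT_METHODS = ("fold5", "fold10", "frequency", "prevalence", "either")


def _default_bias_dict() -> dict:
    return asdict(default_bias())


@dataclass
class RunConfig:
    """All knobs of one benchmark run; serializable round-trip is lossless."""

    seed: int
    n_components: int = 83
    n_tiers: int = 8
    kits: tuple[str, ...] = KITS
    dilution_series_pg: tuple[float, ...] = DILUTION_SERIES_PG
    replicates: int = 2
    n_nc: int = 2
    depth: int = 100_000
    load_medians_pg: dict = field(
        default_factory=lambda: dict(DEFAULT_LOAD_MEDIANS_PG))
    load_dispersion: float = 1.0
    genus_sigma: float = 0.6
    profile_sigma: float = 1.5
    bias: dict = field(default_factory=_default_bias_dict)
    endo_mass_fraction: float = 0.001
    wga: bool = False
    methods: tuple[str, ...] = _DEFAULT_METHODS
    grid_n: int = 40
    grid_lo: float = 0.1
    grid_hi: float = 0.5
    permanova_permutations: int = 199

    def validate(self) -> None:
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")
        if not self.kits:
            raise InvalidConfigError("kit list is empty")
        missing = [k for k in self.kits if k not in self.load_medians_pg]
        if missing:
            raise InvalidConfigError(
                f"kits without contaminant pool medians: {missing}")
        if self.replicates < 1 or self.n_nc < 2:
            raise InvalidConfigError(
                "need >=1 replicate and >=2 negative controls")
        if self.depth < 1:
            raise InvalidConfigError("depth must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["kits"] = list(self.kits)
        d["dilution_series_pg"] = list(self.dilution_series_pg)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("kits", "dilution_series_pg", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        cfg = cls(**d)
        cfg.validate()
        return cfg


def config_hash(config: RunConfig) -> str:
    """Stable hash of the canonical JSON form, for provenance fields."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
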