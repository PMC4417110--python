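"""Run configuration: every tunable threshold in one serializable record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path


@dataclass(frozen=True)
class RunConfig:
    """All pipeline thresholds with their documented defaults.

    Outputs embed ``config_hash`` so any result can be traced to the exact
    configuration that produced it.
    """

    # alignment / QC
    min_read_length: int = 30
    identity_floor: float = 0.80
    min_efficiency: float = 0.95
    min_called_fraction: float = 0.5
    strand_mode: str = "top"
    # DMR classification
    dmr_hi: float = 0.75
    dmr_lo: float = 0.25
    dmr_min_clones: int = 3
    # gamete state
    gamete_hi: float = 0.80
    gamete_lo: float = 0.20
    gamete_min_clones: int = 5
    partial_lo: float = 0.10
    partial_hi: float = 0.90
    # expression tiers
    t_complete: float = 0.10
    t_biallelic: float = 0.35
    # trajectory
    trajectory_tolerance: float = 0.05
    # simulation
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        payload = {"config": self.to_dict(), "config_hash": self.config_hash}
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        payload = json.loads(Path(path).read_text())
        return cls(**payload.get("config", payload))

    def override(self, **kwargs) -> "RunConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
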