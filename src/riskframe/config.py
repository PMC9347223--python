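"""Run configuration for the end-to-end pipeline (YAML-serialisable)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .sampling import SamplerConfig

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with an explicit seed.

    ``t_change_definition`` selects the hormone covariate: ``relative`` is
    (T1 - T0)/T0, ``absolute`` is T1 - T0.
    """

    seed: int
    out_dir: str = "results"
    # sampler
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    target_accept: float = 0.9
    # analysis settings
    hdi_mass_choice: float = 0.94
    hdi_mass_items: float = 0.95
    t_change_definition: str = "relative"
    zero_bid_threshold: float = 0.3
    framing_variant: str = "hierarchical+T+covariance"
    # inputs: None means simulate
    games_path: str | None = None
    choices_path: str | None = None
    hormones_path: str | None = None
    endowment_path: str | None = None
    n_items_per_type: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.t_change_definition not in ("relative", "absolute"):
            raise ValueError("t_change_definition must be relative|absolute")

    def sampler_config(self) -> SamplerConfig:
        return SamplerConfig(
            chains=self.chains, draws=self.draws, warmup=self.warmup,
            target_accept=self.target_accept,
        )

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)
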