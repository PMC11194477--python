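"""Run configuration: one flat mapping of every tunable, YAML-loadable,
with CLI flags overriding file values.  Each run report echoes the full
configuration and its digest so equal digests + seeds imply equal outputs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .interfaces import (
    DEFAULT_CLASH_CUTOFF,
    DEFAULT_CLASH_TOLERANCE,
    DEFAULT_CONTACT_CUTOFF,
)
from .mcts import MCTSConfig
from .processing import (
    DEFAULT_DEDUP_THRESHOLD,
    DEFAULT_MIN_PAIR_CONTACTS,
    DEFAULT_PAIR_RMSD_TOLERANCE,
)


@dataclass
class RunConfig:
    """Every tunable of the pipeline with its documented default."""

    subcomponent_mode: str = "4mer"      # "3mer": sizes 2-3; "4mer": 2-4
    use_all_models: bool = True          # pool pairs from all 5 predictor models
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF
    min_pair_contacts: int = DEFAULT_MIN_PAIR_CONTACTS
    dedup_threshold: float = DEFAULT_DEDUP_THRESHOLD
    pair_rmsd_tolerance: float = DEFAULT_PAIR_RMSD_TOLERANCE
    clash_cutoff: float = DEFAULT_CLASH_CUTOFF
    clash_tolerance: float = DEFAULT_CLASH_TOLERANCE
    mcts_iterations: int = 100
    c_explore: float = math.sqrt(2.0)
    max_chains: int = 30
    rollout_depth: int = 6
    heuristic_on: bool = True
    n_restarts: int = 1
    time_limit: Optional[float] = None
    success_threshold: float = 0.8
    seed: int = 0

    @property
    def composition_sizes(self) -> tuple[int, int]:
        if self.subcomponent_mode == "3mer":
            return (2, 3)
        if self.subcomponent_mode == "4mer":
            return (2, 4)
        raise ValueError(
            f"subcomponent_mode must be '3mer' or '4mer', "
            f"got {self.subcomponent_mode!r}"
        )

    def mcts(self) -> MCTSConfig:
        return MCTSConfig(
            iterations=self.mcts_iterations,
            c_explore=self.c_explore,
            max_chains=self.max_chains,
            rollout_depth=self.rollout_depth,
            heuristic_on=self.heuristic_on,
            contact_cutoff=self.contact_cutoff,
            clash_cutoff=self.clash_cutoff,
            clash_tolerance=self.clash_tolerance,
            time_limit=self.time_limit,
            n_restarts=self.n_restarts,
        )

    def as_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **kwargs) -> "RunConfig":
        data = self.as_dict()
        data.update({k: v for k, v in kwargs.items() if v is not None})
        return RunConfig(**data)
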