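"""Pipeline configuration: a flat, typo-safe key/value file."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .types import DomainError


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, in one flat mapping.

    Paths may be left empty when a stage is not run (e.g. no profiles means
    no diversity stage). Numeric parameters mirror the domains of the
    functions they feed and are validated here so a bad config fails before
    any computation starts.
    """

    # inputs
    screens: list[str] | None = None       # RNK paths
    gmt: str | None = None                 # pathway database
    profiles: str | None = None            # signature matrix TSV
    profiles_metadata: str | None = None   # sidecar
    synergy_sets: str | None = None        # curated synergy TSV
    # enrichment
    n_perm: int = 1000
    weight: float = 1.0
    p_max: float = 0.05
    q_max: float = 0.25
    relaxed_q_max: float = 0.40
    relax_below: int = 300
    # integration
    min_screens: int = 2
    recurrence_k: int = 3
    jaccard_threshold: float = 0.5
    # diversity
    n_dims: int = 2
    normalize_profiles: bool = False
    distance_space: str = "full"
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_perm < 100:
            raise DomainError("n_perm must be >= 100")
        if self.weight < 0:
            raise DomainError("weight must be non-negative")
        for name in ("p_max", "q_max", "relaxed_q_max"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0, 1], got {v}")
        if self.min_screens < 2:
            raise DomainError("min_screens must be >= 2")
        if self.recurrence_k < 1:
            raise DomainError("recurrence_k must be >= 1")
        if not 0.0 < self.jaccard_threshold <= 1.0:
            raise DomainError("jaccard_threshold must be in (0, 1]")
        if self.n_dims < 1:
            raise DomainError("n_dims must be >= 1")
        if self.distance_space not in ("full", "mds"):
            raise DomainError("distance_space must be 'full' or 'mds'")

    @classmethod
    def from_mapping(cls, data: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise DomainError(f"unknown config key(s): {unknown}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise DomainError(f"{path}: config must be a flat mapping")
        return cls.from_mapping(data)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)
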