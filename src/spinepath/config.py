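"""Analysis configuration shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["CohortConfig"]


@dataclass
class CohortConfig:
    """Knobs governing clustering, fusion grouping and significance testing.

    Defaults: the number of clusters is searched over 2..6 with 100
    restarts of k-means++-seeded Lloyd iterations; fusion groups smaller
    than 3 patients are excluded; all hypothesis tests use alpha = 0.05.
    """

    k_min: int = 2
    k_max: int = 6
    restarts: int = 100
    seed: int = 20181102
    min_fusion_group_size: int = 3
    label_order: str = "size"  # canonical cluster numbering convention
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError(f"invalid k range [{self.k_min}, {self.k_max}]")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.min_fusion_group_size < 1:
            raise ValueError("min_fusion_group_size must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.label_order != "size":
            raise ValueError("only the 'size' labelling convention is supported")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
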