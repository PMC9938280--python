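"""Run configuration: CV geometry, grids, seeds.

The master seed is mandatory; every stage derives its own stream from
it, so a full run is reproducible bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json

from .svm import DEFAULT_C_GRID

__all__ = ["PipelineConfig"]


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the nested-CV pipeline.

    Defaults mirror the canonical design: 10-fold cross-validation
    with 5 repetitions at both levels (an ensemble of 50 base models
    per outer partition), k = 7 imputation neighbours, an 11-point
    power-of-two C grid, and 1000 label permutations at alpha = 0.05.
    """

    outer_folds: int = 10
    outer_repetitions: int = 5
    inner_folds: int = 10
    inner_repetitions: int = 5
    k_neighbours: int = 7
    c_grid: tuple[float, ...] = DEFAULT_C_GRID
    max_features: int | None = None
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("outer_folds", "outer_repetitions", "inner_folds", "inner_repetitions", "k_neighbours"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not self.c_grid:
            raise ValueError("c_grid must be nonempty")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be positive")
        if self.seed is None:
            raise ValueError("a master seed is mandatory")

    def seed_for(self, stage: str, *parts: int) -> int:
        """Derived deterministic seed for a named stage (< 2**31)."""
        key = json.dumps([self.seed, stage, *map(int, parts)]).encode()
        return int.from_bytes(hashlib.sha256(key).digest()[:4], "big") % (2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["c_grid"] = list(self.c_grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "c_grid" in d:
            d["c_grid"] = tuple(float(c) for c in d["c_grid"])
        return cls(**d)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]
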