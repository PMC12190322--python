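"""Pipeline configuration: analysis windows, permutation counts, seeds."""

from __future__ import annotations

import dataclasses
from os import PathLike
from typing import Any

import yaml


@dataclasses.dataclass
class PipelineConfig:
    """Constants shared across pipeline stages.

    Windows are in seconds: a 0.5 s response window ending at odor un-poke,
    a 1.0 s baseline window ending at trial initiation, 50 ms count bins.
    """

    response_window: float = 0.5
    baseline_window: float = 1.0
    bin_width: float = 0.05
    align_window: tuple[float, float] = (-1.5, 0.0)
    alpha: float = 0.05
    n_permutations: int = 1000
    seed: int = 0
    embedding_method: str = "linear-fallback"
    embedding_dims: int = 3
    n_per_type: int = 10
    svm_c: float = 1.0
    scenario: str | None = None
    data_dir: str | None = None
    out_dir: str = "schema_mux_results"
    n_sessions: int = 3
    n_trials_per_session: int = 300
    n_units: int = 40

    def __post_init__(self) -> None:
        for name in ("response_window", "baseline_window", "bin_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")
        self.align_window = tuple(self.align_window)  # type: ignore[assignment]

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "PipelineConfig":
        with open(path) as fh:
            raw: dict[str, Any] = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["align_window"] = list(self.align_window)
        return d
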