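"""Pipeline configuration.

One flat document with per-stage sections; defaults equal the published
protocol thresholds (cap 100, LT 10, PL-root 70, minimum cluster size 5,
specificity 0.2, TS strata 2 / 3-9 / >=10, TB extremes 10 and 0.1).
Command-line flags override file values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .annotation import DEFAULT_BLACKLIST
from .synthetic_data import SyntheticSpec


@dataclass
class PipelineConfig:
    # similarity
    cap: float = 100.0
    k: int = 3
    s: float = 40.0
    # clustering / stability
    lt_min: int = 10
    pl_root: float = 70.0
    merge_cutoff: float = 100.0
    # mapping
    tau_map: float = 1.0
    prefer: str = "size"
    # annotation
    min_size: int = 5
    min_spec: float = 0.2
    blacklist: tuple = DEFAULT_BLACKLIST
    # paralog statistics
    ts_strata: tuple = ((2, 2), (3, 9), (10, None))
    ts_bin_width: float = 0.1
    ts_divergence_cutoff: float = 0.2
    tb_high: float = 10.0
    tb_low: float = 0.1
    min_paralogs: int = 2
    # orchestration
    species_of_interest: str = "daphnia"
    reference_species: str = "fly"
    seed: int = 0
    log_level: str = "INFO"
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self) -> None:
        if not (0 < self.pl_root <= 100):
            raise ValueError("pl_root must be in (0, 100]")
        if self.lt_min < 0:
            raise ValueError("lt_min must be >= 0")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if not (0 <= self.min_spec <= 1):
            raise ValueError("min_spec must be in [0, 1]")
        if self.tau_map <= 0:
            raise ValueError("tau_map must be positive")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["synthetic"] = dataclasses.asdict(self.synthetic)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "synthetic" in data and not isinstance(data["synthetic"], SyntheticSpec):
            syn = dict(data["synthetic"] or {})
            for key in (
                "family_size_range", "species", "species_mix",
                "within_log10_range", "seq_length_range",
            ):
                if key in syn and isinstance(syn[key], list):
                    syn[key] = tuple(syn[key])
            data["synthetic"] = SyntheticSpec(**syn)
        for key in ("blacklist",):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        if "ts_strata" in data:
            data["ts_strata"] = tuple(
                tuple(pair) for pair in data["ts_strata"]
            )
        return cls(**data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def save(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(_listify(self.to_dict()), sort_keys=True)
        )


def _listify(obj):
    """YAML-friendly view: tuples become lists recursively."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj
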