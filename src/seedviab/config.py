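"""Pipeline configuration: a single YAML-mappable record with validation."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from os import PathLike
from typing import Any

import yaml

from .errors import ConfigError
from .seedcore import SPECIES
from .synthetic import DEFAULT_ADAPTER


@dataclass
class PipelineConfig:
    """Everything a full run needs: thresholds, group map and file paths.

    ``groups`` maps group names to sample identifiers; every sample must
    appear in exactly one group.  All randomness downstream flows from
    ``rng_seed``.
    """

    species: str = "mouse"
    groups: dict[str, list[str]] = field(default_factory=dict)
    control_group: str = "control"
    perturbed_group: str = "perturbed"
    adapter: str = DEFAULT_ADAPTER
    min_overlap: int = 4
    min_total: int = 6
    alpha: float = 0.05
    test: str = "student"
    divisor: int = 1000
    bin_width: float = 1.0
    rng_seed: int = 0
    viability_csv: str | None = None
    counts_table: str | None = None
    fastq: dict[str, str] = field(default_factory=dict)
    references: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.species not in SPECIES:
            raise ConfigError(f"species must be one of {SPECIES}, got {self.species!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.divisor < 1:
            raise ConfigError("divisor must be >= 1")
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        if self.min_total < 0:
            raise ConfigError("min_total must be >= 0")
        if self.min_overlap < 1:
            raise ConfigError("min_overlap must be >= 1")
        if self.test not in ("student", "welch"):
            raise ConfigError("test must be 'student' or 'welch'")
        seen: dict[str, str] = {}
        for group, samples in self.groups.items():
            for sample in samples:
                if sample in seen:
                    raise ConfigError(
                        f"sample {sample!r} appears in groups {seen[sample]!r}"
                        f" and {group!r}; each sample belongs to exactly one group"
                    )
                seen[sample] = group
        for role, group in (
            ("control_group", self.control_group),
            ("perturbed_group", self.perturbed_group),
        ):
            if self.groups and group not in self.groups:
                raise ConfigError(f"{role} {group!r} not defined in groups")
        if self.fastq:
            unknown = [s for s in self.fastq if s not in seen]
            if unknown:
                raise ConfigError(f"fastq samples not assigned to any group: {unknown}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | PathLike) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | PathLike) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)
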