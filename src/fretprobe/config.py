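"""Run configuration: buffer, grid, design and primer constraints from YAML."""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .design import DesignConstraints
from .errors import ValidationError
from .melt import DEFAULT_STEP, DEFAULT_T_MAX, DEFAULT_T_MIN
from .primers import PrimerConstraints
from .thermo import BufferConditions


@dataclass(frozen=True)
class GridConfig:
    t_min: float = DEFAULT_T_MIN
    t_max: float = DEFAULT_T_MAX
    step: float = DEFAULT_STEP

    def __post_init__(self):
        if self.t_min >= self.t_max or self.step <= 0:
            raise ValidationError(f"invalid temperature grid {self}")


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for CLI runs; unknown keys are rejected."""

    buffer: BufferConditions = field(default_factory=BufferConditions)
    grid: GridConfig = field(default_factory=GridConfig)
    design: DesignConstraints = field(default_factory=DesignConstraints)
    primers: PrimerConstraints = field(default_factory=PrimerConstraints)
    seed: int = 1
    output_dir: str = "."
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known_sections = {
            "buffer": BufferConditions,
            "grid": GridConfig,
            "design": DesignConstraints,
            "primers": PrimerConstraints,
        }
        scalars = {"seed", "output_dir", "log_level"}
        kwargs: dict = {}
        for key, value in data.items():
            if key in known_sections:
                section_cls = known_sections[key]
                valid = {f.name for f in fields(section_cls)}
                unknown = set(value) - valid
                if unknown:
                    raise ValidationError(f"unknown keys in section {key!r}: {sorted(unknown)}")
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
                }
                kwargs[key] = section_cls(**coerced)
            elif key in scalars:
                kwargs[key] = value
            else:
                raise ValidationError(f"unknown configuration key {key!r}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"{path}: configuration root must be a mapping")
        return cls.from_dict(data)
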