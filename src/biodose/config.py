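"""Run configuration: every model parameter block with its defaults, YAML I/O.

The config deserializes strictly — unknown keys are rejected so a typo in a
parameter name cannot silently fall back to a default — and serializes
losslessly, which lets every report embed the full effective configuration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cellkill import FractionationParams, RadiobioParams
from .density import CellDensityParams
from .errors import ConfigError
from .grid import ImageGrid
from .oxygen import OxyConversionParams
from .phantom import PhantomSpec, PlanEmulatorSpec
from .prescription import PrescriptionParams


def _build(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{section}' must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) in '{section}': {sorted(unknown)}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid value in '{section}': {e}") from e


def _phantom_from_dict(data: dict) -> PhantomSpec:
    data = dict(data)
    grid_kwargs = {"shape": (64, 64, 64)}
    for key in ("shape", "spacing", "origin"):
        if key in data:
            grid_kwargs[key] = tuple(data.pop(key))
    return _build(PhantomSpec, dict(data, grid=ImageGrid(**grid_kwargs)), "phantom")


@dataclass
class RunConfig:
    """Aggregated parameters for the end-to-end pipeline."""

    seed: int = 0
    use_fdg: bool = True
    oxygen: OxyConversionParams = field(default_factory=OxyConversionParams)
    density: CellDensityParams = field(default_factory=CellDensityParams)
    radiobiology: RadiobioParams = field(default_factory=RadiobioParams)
    fractionation: FractionationParams = field(default_factory=FractionationParams)
    prescription: PrescriptionParams = field(default_factory=PrescriptionParams)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    emulator: PlanEmulatorSpec = field(default_factory=PlanEmulatorSpec)

    _SECTIONS = {
        "oxygen": OxyConversionParams,
        "density": CellDensityParams,
        "radiobiology": RadiobioParams,
        "fractionation": FractionationParams,
        "prescription": PrescriptionParams,
        "emulator": PlanEmulatorSpec,
    }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("config root must be a mapping")
        known = {"seed", "use_fdg", "phantom", *cls._SECTIONS}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        kwargs = {}
        if "seed" in data:
            kwargs["seed"] = int(data["seed"])
        if "use_fdg" in data:
            kwargs["use_fdg"] = bool(data["use_fdg"])
        for name, klass in cls._SECTIONS.items():
            if name in data:
                kwargs[name] = _build(klass, data[name], name)
        if "phantom" in data:
            kwargs["phantom"] = _phantom_from_dict(data["phantom"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        return cls.from_dict(yaml.safe_load(text) or {})

    def to_dict(self) -> dict:
        out = {"seed": self.seed, "use_fdg": self.use_fdg}
        for name in self._SECTIONS:
            out[name] = dataclasses.asdict(getattr(self, name))
        ph = dataclasses.asdict(self.phantom)
        grid = ph.pop("grid")
        ph.update(shape=list(grid["shape"]), spacing=list(grid["spacing"]),
                  origin=list(grid["origin"]))
        out["phantom"] = ph
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
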