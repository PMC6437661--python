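"""Run configuration for the end-to-end demonstrations.

A :class:`RunConfig` captures every constant a run needs — simulator sizes,
basis shape, noise presets, transform specification, decoding grid — and
round-trips losslessly through YAML so runs are exactly reproducible from a
config file plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import InvalidParameterError
from .simulate import NOISE_PRESETS

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    voxel_count: int = 100
    unit_count: int = 180
    tuning_hwhh_deg: float = 40.0
    channel_count: int = 8
    basis_exponent: int = 7
    noise_presets: dict = field(default_factory=lambda: dict(NOISE_PRESETS))
    transform: dict = field(
        default_factory=lambda: {"kind": "bimodal", "lobe_shift": 3, "secondary_gain": 0.9}
    )
    n_orientations: int = 8
    repeats: int = 27
    grid_step_deg: float = 0.5
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        positives = {
            "voxel_count": self.voxel_count,
            "unit_count": self.unit_count,
            "tuning_hwhh_deg": self.tuning_hwhh_deg,
            "channel_count": self.channel_count,
            "basis_exponent": self.basis_exponent,
            "n_orientations": self.n_orientations,
            "repeats": self.repeats,
            "grid_step_deg": self.grid_step_deg,
        }
        for name, value in positives.items():
            if value <= 0:
                raise InvalidParameterError(f"{name} must be positive, got {value}")
        for name, sigma in self.noise_presets.items():
            if sigma < 0:
                raise InvalidParameterError(f"noise preset {name!r} has negative sd {sigma}")

    def fingerprint(self) -> dict:
        """Flat dict identifying the run (written into every output table)."""
        fp = asdict(self)
        fp["noise_presets"] = dict(self.noise_presets)
        return fp

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise InvalidParameterError("config file must contain a mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise InvalidParameterError(f"malformed config: {exc}") from exc


def load_config(path) -> RunConfig:
    try:
        text = Path(path).read_text()
    except OSError as exc:
        raise InvalidParameterError(f"cannot read config {path}: {exc}") from exc
    try:
        return RunConfig.from_yaml(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise InvalidParameterError(f"config parse error{where}: {exc}") from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(config.to_yaml())
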