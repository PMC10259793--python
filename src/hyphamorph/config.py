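"""Run configuration: one serializable object holding every pipeline knob.

A run's effective configuration (defaults resolved) is written beside its
outputs together with a version stamp, so any result can be replayed
exactly from the config file and seed alone.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .exceptions import ConfigurationError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # inputs
    input_dir: str = "."
    pixel_size_um: float = 0.065
    channels: tuple[str, ...] = ()
    # morphometry
    simplify_tol_um: float = 0.1
    min_kink_deg: float = 10.0
    include_junction: bool = True
    # tracing
    prune_len_um: float = 0.2
    min_area_px: int = 20
    body_width_ratio: float = 0.6
    bud_width_ratio: float = 0.5
    sample_step_um: float = 0.05
    # localization
    bin_step_um: float = 0.05
    smooth_window_um: float = 0.15
    include_bud_in_peak: bool = True
    # statistics: ordered [threshold, label] pairs
    significance_thresholds: tuple = (
        (0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.1, "*"))
    # reproducibility
    seed: int = 0
    output_dir: str = "out"
    version: str = __version__

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.simplify_tol_um < 0:
            raise ConfigurationError("simplify_tol_um must be >= 0")
        if not (0 <= self.min_kink_deg < 180):
            raise ConfigurationError("min_kink_deg must be in [0, 180)")
        self.significance_thresholds = tuple(
            (float(t), str(lab)) for t, lab in self.significance_thresholds)
        self.channels = tuple(self.channels)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        raw.pop("version", None)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["significance_thresholds"] = [
            [t, lab] for t, lab in self.significance_thresholds]
        data["channels"] = list(self.channels)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def with_overrides(self, **kwargs) -> "RunConfig":
        clean = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **clean)
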