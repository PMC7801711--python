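"""Run configuration: every analysis constant in one validated place.

Defaults are the field-calibrated values for pink bollworm: thresholds
13.0/34.0 degC, thermal constant 503.62 DD, acceptance band 500 +/- 10 DD,
emergence proxy >= 2 moths/trap/week, and the published LTT/UTT candidate
grids.  Loadable from a YAML mapping; the resolved configuration can be
dumped back out as a reproducibility manifest.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .degreedays import ThresholdPair
from .errors import ConfigurationError
from .phenology import GenerationConfig

__all__ = ["RunConfig", "DEFAULT_LTT_GRID", "DEFAULT_UTT_GRID"]

DEFAULT_LTT_GRID = (12.5, 13.0, 13.4, 13.9, 15.5)
DEFAULT_UTT_GRID = (32.5, 32.8, 34.0, 35.5, 37.5)


@dataclass
class RunConfig:
    ltt: float = 13.0
    utt: float = 34.0
    ltt_grid: tuple[float, ...] = DEFAULT_LTT_GRID
    utt_grid: tuple[float, ...] = DEFAULT_UTT_GRID
    generation_dd: float = 503.62
    acceptance_center: float = 500.0
    acceptance_band: float = 10.0
    emergence_min_catch: float = 2.0
    peak_min_prominence: float = 2.0
    peak_min_separation_days: int = 21
    peak_smooth_window: int = 3
    seed: int = 0
    method: str = "single_sine"

    def __post_init__(self) -> None:
        self.ltt_grid = tuple(float(v) for v in self.ltt_grid)
        self.utt_grid = tuple(float(v) for v in self.utt_grid)
        try:
            self.thresholds  # validates ltt < utt
        except Exception as exc:
            raise ConfigurationError(str(exc)) from exc
        if self.method not in ("single_sine", "simple_average"):
            raise ConfigurationError(f"unknown method {self.method!r}")

    @property
    def thresholds(self) -> ThresholdPair:
        return ThresholdPair(self.ltt, self.utt)

    @property
    def generation(self) -> GenerationConfig:
        return GenerationConfig(
            generation_dd=self.generation_dd,
            acceptance_center=self.acceptance_center,
            acceptance_band=self.acceptance_band,
            emergence_min_catch=self.emergence_min_catch,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc

    def to_yaml(self, path=None) -> str:
        data = dataclasses.asdict(self)
        data["ltt_grid"] = list(self.ltt_grid)
        data["utt_grid"] = list(self.utt_grid)
        text = yaml.safe_dump(data, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text
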