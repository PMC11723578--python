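"""Run configuration: YAML-serializable settings for a full pipeline run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError
from .session import AnalysisWindows
from .synth import PopulationSpec, TransientModel

METHODS = ("circular_shift", "sign_rank", "both")


@dataclass
class RunConfig:
    """Everything a pipeline run needs, with defaults mirroring the
    conditioning paradigm (B = 500 null draws, alpha = 0.05, standard
    analysis windows)."""

    mode: str = "simulate"                      # 'simulate' | 'load'
    population: PopulationSpec = field(default_factory=PopulationSpec)
    transient: TransientModel = field(default_factory=TransientModel)
    load_paths: dict = field(default_factory=dict)
    session_format: str = "hdf5"
    windows: dict = field(default_factory=dict)  # stimulus -> window overrides
    B: int = 500
    alpha: float = 0.05
    method: str = "circular_shift"
    seed: int = 0
    output_dir: Path = Path("calshift-out")

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ConfigError(f"mode must be 'simulate' or 'load', got {self.mode!r}")
        if self.mode == "load":
            missing = {"appetitive", "fear", "registration"} - set(self.load_paths)
            if missing:
                raise ConfigError(f"load mode needs paths for {sorted(missing)}")
        if self.B < 1:
            raise ConfigError("B must be >= 1")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if self.method not in METHODS:
            raise ConfigError(f"method must be one of {METHODS}")
        self.output_dir = Path(self.output_dir)

    def analysis_windows(self, stimulus: str) -> AnalysisWindows:
        """Windows for a stimulus, with any configured overrides applied."""
        if stimulus in self.windows:
            w = self.windows[stimulus]
            return AnalysisWindows(
                stimulus=stimulus,
                isolation_window_s=tuple(w["isolation_window_s"]),
                pre_window_s=tuple(w["pre_window_s"]),
                post_window_s=tuple(w["post_window_s"]),
            )
        return AnalysisWindows.for_stimulus(stimulus)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "population": self.population.to_dict(),
            "transient": self.transient.to_dict(),
            "load_paths": {k: str(v) for k, v in self.load_paths.items()},
            "session_format": self.session_format,
            "windows": self.windows,
            "B": self.B,
            "alpha": self.alpha,
            "method": self.method,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {
            "mode", "population", "transient", "load_paths", "session_format",
            "windows", "B", "alpha", "method", "seed", "output_dir",
        }
        if unknown:
            raise ConfigError(f"unknown config key(s) {sorted(unknown)}")
        try:
            if "population" in d:
                d["population"] = PopulationSpec.from_dict(d["population"])
            if "transient" in d:
                d["transient"] = TransientModel.from_dict(d["transient"])
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except (OSError, yaml.YAMLError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        if not isinstance(data, Mapping):
            raise ConfigError(f"config {path} must be a YAML mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
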