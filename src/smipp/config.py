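"""Pipeline configuration: a validated YAML-loadable settings object.

Defaults reproduce the analysis' canonical choices: degree-6 seasonal
polynomial for 8-day data, 4-component SSA with a 120-day window for daily
data, a 10 % threshold, a 30-day preseason window, and a 5-year minimum
record for the anomaly regression.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    mode: str = "grid"  # "grid" (8-day, polynomial) | "site" (daily, SSA)
    threshold_fraction: float = 0.10
    poly_degree: int = 6
    ssa_window: int = 120
    ssa_components: int = 4
    min_years: int = 5
    preseason_window: int = 30
    summer_precip_mode: str = "monthly_total"  # mean monthly JJA precipitation
    crossing_rule: str = "peak_run"  # "peak_run" | "whole_year"
    iav_reference: str = "reconstructed"  # "reconstructed" | "observed"
    seed: int = 0
    n_years: int = 15
    grid_shape: tuple[int, int] = (4, 4)
    gpp_path: str | None = None  # when set, read instead of simulating
    climate_path: str | None = None
    out_dir: str = "smipp_out"
    overwrite: bool = False
    #: keyword overrides applied to the synthetic TruthParams when simulating
    truth_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.mode not in ("grid", "site"):
            raise ConfigError(f"mode must be 'grid' or 'site', got {self.mode!r}")
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ConfigError(
                f"threshold_fraction must be in (0, 1), got {self.threshold_fraction}"
            )
        if self.poly_degree < 1:
            raise ConfigError("poly_degree must be ≥ 1")
        if not 2 <= self.ssa_window:
            raise ConfigError("ssa_window must be ≥ 2")
        if not 1 <= self.ssa_components <= self.ssa_window:
            raise ConfigError("ssa_components must be in [1, ssa_window]")
        if self.min_years < 5:
            raise ConfigError("min_years must be ≥ 5 (4 parameters need a residual dof)")
        if self.preseason_window < 1:
            raise ConfigError("preseason_window must be ≥ 1")
        if self.summer_precip_mode not in ("mean", "monthly_total"):
            raise ConfigError(f"unknown summer_precip_mode {self.summer_precip_mode!r}")
        if self.crossing_rule not in ("peak_run", "whole_year"):
            raise ConfigError(f"unknown crossing_rule {self.crossing_rule!r}")
        if self.iav_reference not in ("reconstructed", "observed"):
            raise ConfigError(f"unknown iav_reference {self.iav_reference!r}")
        if self.n_years < 3:
            raise ConfigError("n_years must be ≥ 3")
        shape = tuple(self.grid_shape)
        if len(shape) != 2 or any(int(s) < 1 for s in shape):
            raise ConfigError(f"grid_shape must be (ny, nx) ≥ 1, got {self.grid_shape}")
        self.grid_shape = (int(shape[0]), int(shape[1]))

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        """Load from a YAML mapping; keyword overrides (e.g. CLI flags) win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path!r}: top level must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path!r}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grid_shape"] = list(self.grid_shape)
        return out
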