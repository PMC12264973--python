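"""Structured simulation configuration, named conditions, and YAML I/O."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError

__all__ = ["SimConfig", "CONDITIONS", "load_config", "save_config"]


@dataclass
class SimConfig:
    """Everything needed to reproduce a simulation run.

    Named conditions (see :data:`CONDITIONS`): ``no_raster`` (all electrodes
    on every frame, temporal model on), ``main`` (5 groups, 44.4 ms group
    interval → 4.5 Hz cycle; the headline configuration, also labelled
    "5 Hz"), ``fast`` (5 groups at the 11.1 ms render-period interval → 18
    full cycles per second), ``four_group`` (4 groups, 55.6 ms interval,
    keeping the 4.5 Hz-class cycle rate).
    """

    # electrode array
    rows: int = 10
    cols: int = 10
    pitch_um: float = 400.0
    center_um: tuple = (0.0, 0.0)
    # retina / percept grid
    um_per_degree: float = 280.0
    percept_grid_extent_deg: float = 12.0
    percept_grid_step_deg: float = 0.25
    # axon map
    n_axons: int = 500
    axon_step_um: float = 50.0
    rho_um: float = 300.0
    lam_um: float = 1000.0
    # raster
    raster_pattern: str = "checkerboard"  # horizontal|vertical|checkerboard|random|none
    n_groups: int = 5
    group_interval_ms: float = 44.4
    reshuffle_every: int = 5
    # temporal model
    temporal_enabled: bool = True
    temporal_preset: str = "5Hz"
    # rendering
    render_rate_hz: float = 90.0
    frame_fov_deg: float = 60.0
    display_gain: float = 2.0  # fixed brightness→[0,1] display mapping
    # stimulus defaults
    letter_size_deg: float = 41.1
    stimulus_duration_s: float = 5.0
    bar_width_frac: float = 0.1
    # gaze
    gaze_mode: str = "fixation"
    gaze_noise_deg: float = 1.9
    # reproducibility
    seed: int = 0
    condition_name: str = ""

    def validate(self) -> "SimConfig":
        from .raster import PATTERN_NAMES

        if self.raster_pattern not in PATTERN_NAMES:
            raise ConfigurationError(
                f"unknown raster pattern {self.raster_pattern!r}; choose from {PATTERN_NAMES}"
            )
        if self.n_groups < 1:
            raise ConfigurationError("n_groups must be >= 1")
        if self.display_gain <= 0:
            raise ConfigurationError("display_gain must be positive")
        return self

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def condition(cls, name: str, pattern: str | None = None, **kw) -> "SimConfig":
        """Build a named condition, optionally overriding the raster pattern
        (the fast/four_group follow-ups used checkerboard and random only)."""
        if name not in CONDITIONS:
            raise ConfigurationError(
                f"unknown condition {name!r}; choose from {tuple(CONDITIONS)}"
            )
        base = dict(CONDITIONS[name])
        if pattern is not None:
            base["raster_pattern"] = pattern
        base.update(kw)
        return cls(condition_name=name, **base).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["center_um"] = list(d["center_um"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "center_um" in d:
            d = dict(d, center_um=tuple(d["center_um"]))
        return cls(**d).validate()


CONDITIONS = {
    "no_raster": {"raster_pattern": "none", "temporal_enabled": True},
    # 44.4 ms × 5 groups = 222 ms cycle (4.5 Hz); labelled "5 Hz" in the
    # rate follow-up
    "main": {"n_groups": 5, "group_interval_ms": 44.4, "temporal_preset": "5Hz"},
    # one group per render frame: 5 × 11.1 ms = 55.6 ms cycle, 18 cycles/s
    "fast": {"n_groups": 5, "group_interval_ms": 1000.0 / 90.0, "temporal_preset": "20Hz"},
    # four groups at the 4.5 Hz-class cycle: 55.6 ms group interval
    "four_group": {"n_groups": 4, "group_interval_ms": 5000.0 / 90.0, "temporal_preset": "5Hz"},
}


def load_config(path) -> SimConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig.from_dict(data)


def save_config(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
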