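"""Run configuration: defaults, YAML round-trip and hashing.

One flat, explicit configuration object covers every stage (sampling ranges,
candidate grids, tolerance model, device, schedule, classifier settings).
All stochastic stages derive their seeds from the single master seed, so a
run is reproducible from its config file alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import yaml

from .dielectrics import DielectricMaterial, Medium
from .errors import ConfigurationError
from .optimizer import NARROW_RANGE, WIDE_RANGE, ToleranceModel
from .sampling import ParameterRanges
from .spring import DeviceState, ExponentialForceProfile
from .trajectories import DEFAULT_SCHEDULE, FrequencySchedule

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """Master configuration for simulation and end-to-end runs."""

    seed: int = 0
    # Monte Carlo frequency study
    n_runs: int = 100
    n_cells: int = 1000
    max_steps: int = 4
    grid_points: int = 100
    wide_range: tuple[float, float] = WIDE_RANGE
    narrow_range: tuple[float, float] = NARROW_RANGE
    # sampling
    cytoplasm_conductivity: tuple[float, float] = (0.2, 1.2)
    cytoplasm_permittivity: tuple[float, float] = (20.0, 80.0)
    membrane_conductivity: tuple[float, float] = (10e-9, 1e-6)
    membrane_permittivity: tuple[float, float] = (2.0, 20.0)
    outer_radius: tuple[float, float] = (2.0e-6, 8.0e-6)
    log_membrane_conductivity: bool = False
    medium_conductivity: float = 1.5
    medium_permittivity: float = 78.5
    # tolerance model
    tolerance_mode: str = "absolute"
    cm_tolerance: float = 0.026
    position_uncertainty: float = 0.5e-6
    # device
    channel_width: float = 1.0e-3
    channel_height: float = 50e-6
    electrode_angle_deg: float = 15.0
    flow_rate: float = 0.6e-9 / 60.0
    rms_voltage: float = 5.0
    viscosity: float = 1.0e-3
    geometry_factor: float = 3.0e12
    decay_length: float = 25e-6
    # trajectory synthesis
    schedule: tuple[tuple[float, float], ...] = DEFAULT_SCHEDULE.entries
    settle_time: float = 0.2
    trajectory_noise_sd: float = 0.25e-6
    frame_rate: float = 20.0
    # end-to-end experiment
    n_cells_per_class: int = 40
    class_separation: float = 0.06
    #: per-schedule-entry Re[CM] baselines of the control class; the high/low
    #: frequency contrast mirrors the large 25 MHz vs 1.2/2 MHz balance jump
    baseline_re_cm: tuple[float, ...] = (-0.15, -0.36, -0.32)
    classifier_resolution_deg: float = 1.0
    n_permutations: int = 999

    def validate(self) -> None:
        if self.n_runs < 1 or self.n_cells < 2 or self.max_steps < 1:
            raise ConfigurationError("invalid Monte Carlo sizes")
        if self.tolerance_mode not in ("absolute", "relative"):
            raise ConfigurationError("tolerance_mode must be 'absolute' or 'relative'")

    # ---- derived objects -------------------------------------------------
    @property
    def medium(self) -> Medium:
        return Medium(DielectricMaterial(self.medium_permittivity, self.medium_conductivity))

    @property
    def parameter_ranges(self) -> ParameterRanges:
        return ParameterRanges(
            cytoplasm_conductivity=tuple(self.cytoplasm_conductivity),
            cytoplasm_permittivity=tuple(self.cytoplasm_permittivity),
            membrane_conductivity=tuple(self.membrane_conductivity),
            membrane_permittivity=tuple(self.membrane_permittivity),
            outer_radius=tuple(self.outer_radius),
            medium=self.medium,
            log_membrane_conductivity=self.log_membrane_conductivity,
        )

    @property
    def tolerance_model(self) -> ToleranceModel:
        return ToleranceModel(
            position_uncertainty=self.position_uncertainty,
            decay_length=self.decay_length,
            mode=self.tolerance_mode,
            absolute_tolerance=self.cm_tolerance,
        )

    @property
    def device(self) -> DeviceState:
        return DeviceState(
            channel_width=self.channel_width,
            channel_height=self.channel_height,
            electrode_angle=np.deg2rad(self.electrode_angle_deg),
            flow_rate=self.flow_rate,
            rms_voltage=self.rms_voltage,
            viscosity=self.viscosity,
            geometry_factor=self.geometry_factor,
            medium=self.medium,
            force_profile=ExponentialForceProfile(self.decay_length),
        )

    @property
    def frequency_schedule(self) -> FrequencySchedule:
        return FrequencySchedule(tuple(tuple(e) for e in self.schedule))

    # ---- serialization ---------------------------------------------------
    def to_yaml(self, path=None) -> str:
        payload = {}
        for k, v in asdict(self).items():
            if isinstance(v, tuple):
                v = [list(e) if isinstance(e, tuple) else e for e in v]
            payload[k] = v
        text = yaml.safe_dump(payload, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        if hasattr(source, "read"):
            payload = yaml.safe_load(source.read())
        else:
            try:
                with open(source) as fh:
                    payload = yaml.safe_load(fh)
            except (OSError, ValueError):
                payload = yaml.safe_load(source)
        def detuple(v):
            if isinstance(v, list):
                return tuple(detuple(e) for e in v)
            return v
        cfg = cls(**{k: detuple(v) for k, v in payload.items()})
        cfg.validate()
        return cfg

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]
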