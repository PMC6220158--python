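"""Forward and inverse DEP-spring balance-position model.

A cell flowing over a pair of slanted coplanar electrodes experiences a
negative-DEP force pushing it away from the electrode pair and a drag force
pushing it along; their balance defines a stable *balance position* delta,
measured from the electrode-pair center along the flow-transverse y axis.
The force balance reads

    delta = q_R^{-1}( 3 eta sin(theta) [6Q/(w h^3) (h - R)]
                      / ( R eps_m |Re[CM]| V_RMS^2 p(f, sigma_m) ) )

where q_R is the dimensionless decay of the DEP force with distance from the
electrodes, eta the medium viscosity, theta the electrode angle to the flow,
Q the volumetric flow rate, w and h the channel width and height, R the cell
radius, eps_m the medium (absolute) permittivity, V_RMS the applied RMS
voltage and p(f, sigma_m) a frequency-dependent field-normalization factor
calibrated with beads of known CM factor.

q_R is modelled as exponential decay, q_R(delta) = exp(-delta/lambda) with a
configurable decay length lambda, giving the closed-form inverse
q_R^{-1}(u) = -lambda ln(u).  The model is a plug-in interface
(:class:`SpringForceProfile`) so an alternative profile can be substituted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dielectrics import DielectricMaterial, Medium, cm_factor
from .errors import CalibrationError, GeometryError, NoBalanceError
from .sampling import DEFAULT_MEDIUM

__all__ = [
    "SpringForceProfile",
    "ExponentialForceProfile",
    "NormalizationTable",
    "DeviceState",
    "BalancePrediction",
    "spring_argument",
    "balance_position",
    "invert_cm",
    "calibrate_p",
    "size_correct",
    "DEFAULT_DEVICE",
]


class SpringForceProfile:
    """Plug-in interface for the DEP-force position dependence q_R."""

    def q(self, delta):  # pragma: no cover - interface
        raise NotImplementedError

    def inverse(self, u):  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ExponentialForceProfile(SpringForceProfile):
    """q_R(delta) = exp(-delta/lambda): quasi-exponential force decay away
    from coplanar electrodes, with closed-form inverse -lambda ln(u)."""

    decay_length: float = 25e-6

    def __post_init__(self) -> None:
        if self.decay_length <= 0:
            raise ValueError("decay_length must be > 0")

    def q(self, delta):
        return np.exp(-np.asarray(delta, dtype=float) / self.decay_length)

    def inverse(self, u):
        return -self.decay_length * np.log(np.asarray(u, dtype=float))


@dataclass(frozen=True)
class NormalizationTable:
    """p(f): field-normalization factors at calibrated frequencies,
    interpolated log-linearly in frequency and held constant outside the
    calibrated band."""

    frequencies: np.ndarray
    factors: np.ndarray

    def __post_init__(self) -> None:
        f = np.atleast_1d(np.asarray(self.frequencies, dtype=float))
        p = np.atleast_1d(np.asarray(self.factors, dtype=float))
        if f.shape != p.shape or f.size == 0:
            raise ValueError("frequencies and factors must be equal-length, non-empty")
        order = np.argsort(f)
        f, p = f[order], p[order]
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and distinct")
        if np.any(p <= 0):
            raise ValueError("normalization factors must be > 0")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "factors", p)

    def __call__(self, f):
        f = np.asarray(f, dtype=float)
        out = np.interp(np.log(f), np.log(self.frequencies), self.factors)
        return out if out.ndim else float(out)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"frequency_hz": self.frequencies, "p": self.factors})


@dataclass(frozen=True)
class DeviceState:
    """Geometry, flow and drive parameters of the DEP-spring device.

    Defaults describe a representative coplanar-electrode microchannel:
    1 mm wide, 50 um tall, electrodes at 15 degrees to the flow, 0.6 uL/min
    total flow of an aqueous 1.5 S/m buffer driven at 5 V RMS.

    ``geometry_factor`` (m^-3) converts the squared drive voltage into the
    DEP force scale at the electrode center — it collects the electric-field
    geometry (electrode gap and width) that the force balance needs to make
    its argument dimensionless.  The default puts typical cells
    (R ~ 5 um, Re[CM] in -0.5..-0.1) at balance positions of roughly
    10-50 um, the working range of this device class.
    """

    channel_width: float = 1.0e-3
    channel_height: float = 50e-6
    electrode_angle: float = np.deg2rad(15.0)
    flow_rate: float = 0.6e-9 / 60.0  # 0.6 uL/min in m^3/s
    rms_voltage: float = 5.0
    viscosity: float = 1.0e-3
    geometry_factor: float = 3.0e12
    medium: Medium = DEFAULT_MEDIUM
    force_profile: SpringForceProfile = field(default_factory=ExponentialForceProfile)
    normalization: NormalizationTable | None = None

    def __post_init__(self) -> None:
        for name in (
            "channel_width",
            "channel_height",
            "flow_rate",
            "rms_voltage",
            "viscosity",
            "geometry_factor",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.electrode_angle < np.pi / 2:
            raise ValueError("electrode_angle must lie in (0, pi/2)")

    @property
    def decay_length(self) -> float:
        return self.force_profile.decay_length

    def p(self, f):
        return 1.0 if self.normalization is None else self.normalization(f)

    def drag_prefactor(self, cell_radius: float) -> float:
        """3 eta sin(theta) 6Q/(w h^3) (h - R): the drag side of the balance."""
        w, h = self.channel_width, self.channel_height
        return (
            3.0
            * self.viscosity
            * np.sin(self.electrode_angle)
            * (6.0 * self.flow_rate / (w * h**3))
            * (h - cell_radius)
        )


DEFAULT_DEVICE = DeviceState()


@dataclass(frozen=True)
class BalancePrediction:
    """A predicted balance position (m, >= 0, from the electrode-pair center
    along y) for one cell radius at one frequency."""

    delta: float
    frequency: float
    cell_radius: float


def spring_argument(cell_radius: float, re_cm: float, device: DeviceState, f: float) -> float:
    """The dimensionless argument u of q_R^{-1} in the force balance.

    Requires negative DEP (``re_cm < 0``) and a cell smaller than the channel.
    u scales as 1/(R |Re[CM]| V^2 p) and linearly with Q.
    """
    if cell_radius >= device.channel_height:
        raise GeometryError("cell radius must be smaller than the channel height")
    if cell_radius <= 0:
        raise GeometryError("cell radius must be positive")
    if re_cm >= 0:
        raise NoBalanceError("no nDEP equilibrium: Re[CM] must be negative")
    num = device.drag_prefactor(cell_radius)
    den = (
        cell_radius
        * device.medium.absolute_permittivity
        * abs(re_cm)
        * device.rms_voltage**2
        * device.geometry_factor
        * device.p(f)
    )
    return float(num / den)


def balance_position(
    cell_radius: float, re_cm: float, device: DeviceState, f: float
) -> BalancePrediction:
    """Balance position delta = q_R^{-1}(u).

    For u > 1 the nDEP force cannot push the cell away from the electrode
    center even at delta = 0; the position is clamped to 0 with a warning.
    """
    u = spring_argument(cell_radius, re_cm, device, f)
    if u > 1.0:
        warnings.warn(
            "force-balance argument u > 1: cell balances at the electrode center (delta=0)",
            stacklevel=2,
        )
        delta = 0.0
    else:
        delta = float(device.force_profile.inverse(u))
    return BalancePrediction(delta=delta, frequency=f, cell_radius=cell_radius)


def invert_cm(delta: float, cell_radius: float, device: DeviceState, f: float) -> float:
    """Re[CM] (negative) implied by a measured balance position.

    Exact inverse of :func:`balance_position` on its valid domain.  Values
    below the physical floor of -0.5 are returned as-is with a warning (they
    indicate a mis-specified device or radius rather than a math error).
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    u = float(device.force_profile.q(delta))
    num = device.drag_prefactor(cell_radius)
    den = (
        cell_radius
        * device.medium.absolute_permittivity
        * device.rms_voltage**2
        * device.geometry_factor
        * device.p(f)
    )
    re_cm = -num / (den * u)
    if re_cm < -0.5:
        warnings.warn(
            f"inverted Re[CM]={re_cm:.4g} lies outside the physical range [-0.5, 0)",
            stacklevel=2,
        )
    return float(re_cm)


def calibrate_p(
    bead_positions: pd.DataFrame,
    bead_radius: float,
    bead_material: DielectricMaterial,
    device: DeviceState,
) -> NormalizationTable:
    """Solve the field-normalization factors p(f) from bead balance positions.

    ``bead_positions`` needs columns ``frequency_hz`` and ``delta_m``.  The
    bead CM factor is computed from ``bead_material`` (homogeneous sphere);
    p(f) is solved so the forward model reproduces each bead position, then
    normalized to 1 at the lowest calibrated frequency.
    """
    freqs = np.asarray(bead_positions["frequency_hz"], dtype=float)
    deltas = np.asarray(bead_positions["delta_m"], dtype=float)
    if freqs.size == 0:
        raise CalibrationError("at least one calibration frequency is required")
    if np.any(deltas < 0):
        raise CalibrationError("bead balance positions must be >= 0")
    base = replace(device, normalization=None)
    p = np.empty_like(freqs)
    for i, (f, d) in enumerate(zip(freqs, deltas)):
        re_cm = cm_factor(bead_material, device.medium, f).real
        if re_cm >= 0:
            raise CalibrationError("calibration bead must show negative DEP")
        u_target = float(device.force_profile.q(d))
        p[i] = spring_argument(bead_radius, re_cm, base, f) / u_target
    if np.any(p <= 0) or not np.all(np.isfinite(p)):
        raise CalibrationError("solved normalization factors are non-physical")
    order = np.argsort(freqs)
    freqs, p = freqs[order], p[order]
    return NormalizationTable(frequencies=freqs, factors=p / p[0])


def size_correct(
    delta_measured: float,
    radius_measured: float,
    radius_reference: float,
    device: DeviceState,
    f: float,
) -> float:
    """Map a measured balance position to the one a reference-radius cell with
    the same Re[CM] would show: invert at the measured radius, re-apply the
    forward model at the reference radius."""
    re_cm = invert_cm(delta_measured, radius_measured, device, f)
    return balance_position(radius_reference, re_cm, device, f).delta
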