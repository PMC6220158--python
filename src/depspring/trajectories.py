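"""Trajectory segmentation, balance-position validation and synthesis.

In a multi-frequency measurement the drive frequency follows a repeating
schedule (default 25 MHz for 1.3 s, 1.2 MHz for 1.8 s, 2 MHz for 0.7 s); a
cell's y trajectory relaxes toward a new balance position after each
transition.  A segment yields a *valid* balance position when the cell has
settled: every sample in the segment's final 250 ms must lie within 10% of
the cell's average frequency-to-frequency balance-position jump of the
segment's final position.  The balance position itself is the final y sample
of the segment.

The truncation analysis shortens every segment by a common factor and
re-applies the criterion, quantifying how much schedule time settling
actually needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .spring import DeviceState, balance_position

__all__ = [
    "FrequencySchedule",
    "DEFAULT_SCHEDULE",
    "Trajectory",
    "Segment",
    "BalanceRecord",
    "moving_average",
    "segment_by_schedule",
    "validate_balance",
    "truncation_analysis",
    "simulate_trajectory",
]


@dataclass(frozen=True)
class FrequencySchedule:
    """Ordered (frequency Hz, duration s) entries, cyclically repeated."""

    entries: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ConfigurationError("schedule must have at least one entry")
        for f, d in self.entries:
            if f <= 0 or d <= 0:
                raise ConfigurationError("schedule frequencies and durations must be > 0")

    @property
    def cycle_duration(self) -> float:
        return float(sum(d for _, d in self.entries))

    @property
    def frequencies(self) -> tuple[float, ...]:
        return tuple(f for f, _ in self.entries)

    def scaled(self, factor: float) -> "FrequencySchedule":
        """Schedule with every duration multiplied by ``factor``."""
        if not 0 < factor:
            raise ConfigurationError("factor must be positive")
        return FrequencySchedule(tuple((f, d * factor) for f, d in self.entries))

    def boundaries(self) -> np.ndarray:
        """Cumulative within-cycle boundary times, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([d for _, d in self.entries])])


#: 25 MHz / 1.2 MHz / 2 MHz repeating sequence (1.3 / 1.8 / 0.7 s).
DEFAULT_SCHEDULE = FrequencySchedule(((25e6, 1.3), (1.2e6, 1.8), (2e6, 0.7)))


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled y positions (m) of one tracked cell; y is measured
    from the electrode-pair center."""

    t: np.ndarray
    y: np.ndarray
    x: np.ndarray | None = None
    frame_interval: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if t.ndim != 1 or t.shape != y.shape or t.size == 0:
            raise ValidationError("t and y must be equal-length 1-D arrays")
        if t.size > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValidationError("timestamps must be strictly increasing")
            if (dt.max() - dt.min()) > 0.01 * dt.mean():
                raise ValidationError("sampling must be uniform to within 1%")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if self.x is not None:
            x = np.asarray(self.x, dtype=float)
            if x.shape != t.shape:
                raise ValidationError("x must match t")
            object.__setattr__(self, "x", x)
        if self.frame_interval is None and t.size > 1:
            object.__setattr__(self, "frame_interval", float(np.mean(np.diff(t))))

    def __len__(self) -> int:
        return len(self.t)

    def to_dataframe(self) -> pd.DataFrame:
        data = {"t_s": self.t}
        if self.x is not None:
            data["x_m"] = self.x
        data["y_m"] = self.y
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Trajectory":
        return cls(
            t=df["t_s"].to_numpy(),
            y=df["y_m"].to_numpy(),
            x=df["x_m"].to_numpy() if "x_m" in df else None,
        )


@dataclass(frozen=True)
class Segment:
    """Samples of one trajectory during one schedule entry."""

    index: int
    frequency: float
    t: np.ndarray
    y: np.ndarray
    start_time: float
    nominal_duration: float

    def __len__(self) -> int:
        return len(self.t)

    @property
    def final_y(self) -> float:
        return float(self.y[-1])


@dataclass(frozen=True)
class BalanceRecord:
    """Validated (or not) balance position of one segment."""

    segment_index: int
    frequency: float
    balance_position: float
    valid: bool
    reason: str = ""


def moving_average(traj: Trajectory, window: int = 4) -> Trajectory:
    """Trailing ``window``-point moving average of the positions.

    Length and timestamps are preserved; the first ``window - 1`` points
    average the shorter prefix that exists (shrinking-window edge policy).
    """
    if window < 1:
        raise ConfigurationError("window must be >= 1")
    if len(traj) < window:
        raise ValidationError(f"trajectory needs at least {window} samples")

    def smooth(v: np.ndarray) -> np.ndarray:
        c = np.concatenate([[0.0], np.cumsum(v)])
        out = np.empty_like(v)
        out[: window - 1] = c[1:window] / np.arange(1, window)
        out[window - 1 :] = (c[window:] - c[:-window]) / window
        return out

    return replace(
        traj,
        y=smooth(traj.y),
        x=smooth(traj.x) if traj.x is not None else None,
    )


def segment_by_schedule(
    traj: Trajectory, schedule: FrequencySchedule = DEFAULT_SCHEDULE, t0: float = 0.0
) -> list[Segment]:
    """Assign every sample to the schedule entry active at its timestamp.

    ``t0`` is the schedule start time relative to the trajectory clock
    (offsetting by a whole number of cycles changes nothing).  Segments are
    returned in time order; only segments containing samples are returned.
    """
    cycle = schedule.cycle_duration
    bounds = schedule.boundaries()
    rel = traj.t - t0
    cycle_idx = np.floor(rel / cycle).astype(int)
    phase = rel - cycle_idx * cycle
    entry_idx = np.clip(np.searchsorted(bounds, phase, side="right") - 1, 0, len(schedule.entries) - 1)
    absolute = cycle_idx * len(schedule.entries) + entry_idx
    segments = []
    for seg_id in np.unique(absolute):
        sel = absolute == seg_id
        k = int(seg_id % len(schedule.entries))
        f, dur = schedule.entries[k]
        start = t0 + (seg_id // len(schedule.entries)) * cycle + bounds[k]
        segments.append(
            Segment(
                index=int(seg_id),
                frequency=f,
                t=traj.t[sel],
                y=traj.y[sel],
                start_time=float(start),
                nominal_duration=float(dur),
            )
        )
    return segments


def _mean_balance_jump(segments: list[Segment]) -> float:
    finals = np.array([s.final_y for s in segments])
    return float(np.mean(np.abs(np.diff(finals))))


def validate_balance(
    segments: list[Segment],
    settle_window: float = 0.25,
    fraction: float = 0.1,
    reference_scale: float | None = None,
) -> list[BalanceRecord]:
    """Apply the settling criterion to each segment of one cell.

    The reference scale D defaults to the cell's own mean absolute difference
    between consecutive segment balance positions (``reference_scale``
    overrides it, e.g. with a population-wide value).  A segment is valid iff
    every sample in its final ``settle_window`` seconds lies within
    ``fraction * D`` of the segment's final y; the balance position is that
    final y.
    """
    if len(segments) < 2 and reference_scale is None:
        raise ValidationError("need at least two segments to form a balance-position difference")
    d = _mean_balance_jump(segments) if reference_scale is None else float(reference_scale)
    records = []
    for seg in segments:
        final_t, final_y = seg.t[-1], seg.final_y
        window = seg.t >= final_t - settle_window
        if int(window.sum()) < 2:
            records.append(
                BalanceRecord(seg.index, seg.frequency, final_y, False, "insufficient samples")
            )
            continue
        settled = bool(np.all(np.abs(seg.y[window] - final_y) <= fraction * d))
        records.append(
            BalanceRecord(
                seg.index,
                seg.frequency,
                final_y,
                settled,
                "" if settled else "motion in settle window exceeds criterion",
            )
        )
    return records


def truncation_analysis(
    trajectories: list[Trajectory],
    schedule: FrequencySchedule = DEFAULT_SCHEDULE,
    factors=(1.0, 0.9, 0.8),
    t0: float = 0.0,
    settle_window: float = 0.25,
    fraction: float = 0.1,
) -> pd.DataFrame:
    """Fraction of valid balance positions as the schedule is shortened.

    For each duration scale factor in (0, 1], each segment is truncated to
    ``factor * duration`` (samples beyond it dropped) and the validation
    criterion re-applied.  Factor 1 reproduces the untruncated analysis.
    Returns a table with columns ``factor``, ``total_duration_s``,
    ``n_valid``, ``n_records`` and ``valid_fraction``.
    """
    factors = np.asarray(factors, dtype=float)
    if np.any(factors <= 0) or np.any(factors > 1):
        raise ConfigurationError("factors must lie in (0, 1]")
    rows = []
    for factor in factors:
        n_valid = n_records = 0
        for traj in trajectories:
            segments = segment_by_schedule(traj, schedule, t0=t0)
            truncated = []
            for seg in segments:
                keep = seg.t - seg.start_time <= factor * seg.nominal_duration
                if not np.any(keep):
                    continue
                truncated.append(replace(seg, t=seg.t[keep], y=seg.y[keep]))
            if len(truncated) < 2:
                continue
            for rec in validate_balance(
                truncated, settle_window=settle_window, fraction=fraction
            ):
                n_records += 1
                n_valid += int(rec.valid)
        rows.append(
            {
                "factor": float(factor),
                "total_duration_s": factor * schedule.cycle_duration,
                "n_valid": n_valid,
                "n_records": n_records,
                "valid_fraction": n_valid / n_records if n_records else 0.0,
            }
        )
    return pd.DataFrame(rows)


def simulate_trajectory(
    re_cm_by_frequency: dict[float, float],
    cell_radius: float,
    device: DeviceState,
    schedule: FrequencySchedule = DEFAULT_SCHEDULE,
    settle_time: float = 0.2,
    noise_sd: float = 0.0,
    frame_rate: float = 20.0,
    n_cycles: int = 1,
    y0: float | None = None,
    seed: int | None = None,
) -> Trajectory:
    """Synthesize a cell trajectory under a frequency schedule.

    The underlying position relaxes first-order (time constant
    ``settle_time``) toward the balance position of the active frequency;
    i.i.d. Gaussian position noise of ``noise_sd`` is added to the *recorded*
    samples, emulating centroid-localization error.
    """
    if settle_time <= 0:
        raise ConfigurationError("settle_time must be > 0")
    if frame_rate <= 0:
        raise ConfigurationError("frame_rate must be > 0")
    rng = np.random.default_rng(seed)
    dt = 1.0 / frame_rate
    total = schedule.cycle_duration * n_cycles
    # frame-midpoint timestamps: no sample coincides with a schedule boundary
    t = (np.arange(int(round(total * frame_rate))) + 0.5) * dt
    targets = {
        f: balance_position(cell_radius, re_cm_by_frequency[f], device, f).delta
        for f in schedule.frequencies
    }
    bounds = schedule.boundaries()
    decay = np.exp(-dt / settle_time)
    y = np.empty_like(t)
    # steady-cycle initial condition: arrive settled at the previous (last) entry
    state = targets[schedule.entries[-1][0]] if y0 is None else float(y0)
    for i, ti in enumerate(t):
        phase = ti % schedule.cycle_duration
        k = min(int(np.searchsorted(bounds, phase, side="right")) - 1, len(schedule.entries) - 1)
        target = targets[schedule.entries[k][0]]
        state = target + (state - target) * decay
        y[i] = state
    y = y + rng.normal(0.0, noise_sd, size=y.shape) if noise_sd > 0 else y
    return Trajectory(t=t, y=y, frame_interval=dt)
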