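"""Trajectory filtering, segmentation, balance validation, synthesis."""

import dataclasses

import numpy as np
import pytest
from scipy import optimize

from depspring.errors import ConfigurationError, ValidationError
from depspring.spring import balance_position, invert_cm
from depspring.trajectories import (
    DEFAULT_SCHEDULE,
    FrequencySchedule,
    Trajectory,
    moving_average,
    segment_by_schedule,
    simulate_trajectory,
    truncation_analysis,
    validate_balance,
)


def make_traj(y, dt=0.05):
    # frame-midpoint timestamps: no sample sits exactly on a schedule boundary
    y = np.asarray(y, dtype=float)
    return Trajectory(t=(np.arange(len(y)) + 0.5) * dt, y=y)


class TestMovingAverage:
    def test_constant_unchanged(self):
        traj = make_traj(np.full(20, 3.0))
        assert np.allclose(moving_average(traj).y, 3.0)

    def test_unit_impulse_spreads_to_quarter(self):
        y = np.zeros(20)
        y[10] = 1.0
        out = moving_average(make_traj(y)).y
        assert np.allclose(out[10:14], 0.25)
        assert np.allclose(np.delete(out, range(10, 14)), 0.0)

    def test_white_noise_variance_reduced_fourfold(self, rng):
        y = rng.normal(0.0, 1.0, size=10_000)
        out = moving_average(make_traj(y)).y
        assert np.var(out[3:]) == pytest.approx(0.25, rel=0.1)

    def test_shrinking_start_window(self):
        out = moving_average(make_traj([4.0, 8.0, 12.0, 16.0, 20.0])).y
        assert out[0] == 4.0
        assert out[1] == 6.0
        assert out[2] == 8.0
        assert out[3] == 10.0  # full 4-point window from here on

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            moving_average(make_traj([1.0, 2.0]))


class TestSegmentation:
    def test_default_schedule_durations(self):
        """One 3.8 s cycle at 20 fps splits 26/36/14 samples (1.3/1.8/0.7 s)."""
        traj = make_traj(np.zeros(76))
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        assert [len(s) for s in segs] == [26, 36, 14]
        assert [s.frequency for s in segs] == [25e6, 1.2e6, 2e6]

    def test_short_trajectory_single_partial_segment(self):
        traj = make_traj(np.zeros(5))
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        assert len(segs) == 1
        assert len(segs[0]) == 5

    def test_every_sample_assigned_once(self):
        traj = make_traj(np.zeros(200))
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        assert sum(len(s) for s in segs) == 200

    def test_full_cycle_offset_is_identity(self):
        traj = make_traj(np.arange(76.0))
        a = segment_by_schedule(traj, DEFAULT_SCHEDULE, t0=0.0)
        b = segment_by_schedule(traj, DEFAULT_SCHEDULE, t0=-DEFAULT_SCHEDULE.cycle_duration)
        assert [len(s) for s in a] == [len(s) for s in b]
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.y, sb.y)
            assert sa.frequency == sb.frequency

    def test_schedule_validation(self):
        with pytest.raises(ConfigurationError):
            FrequencySchedule(())
        with pytest.raises(ConfigurationError):
            FrequencySchedule(((1e6, -1.0),))


class TestValidation:
    def two_level_segments(self, tail_dev=0.0, dt=0.05):
        """Two settled segments at 0 and 10 um, optionally perturbing the
        penultimate samples of the second segment's settle window."""
        y1 = np.zeros(26)
        y2 = np.full(36, 10e-6)
        y2[-5:-1] += tail_dev
        traj = make_traj(np.concatenate([y1, y2]), dt=dt)
        return segment_by_schedule(traj, DEFAULT_SCHEDULE)

    def test_settled_segments_valid(self):
        records = validate_balance(self.two_level_segments())
        assert all(r.valid for r in records)
        assert records[1].balance_position == pytest.approx(10e-6)

    def test_ramping_tail_invalid(self):
        # D = 10 um, criterion 1 um; 2 um residual motion violates it
        records = validate_balance(self.two_level_segments(tail_dev=2e-6))
        assert records[0].valid and not records[1].valid

    def test_sub_criterion_motion_still_valid(self):
        records = validate_balance(self.two_level_segments(tail_dev=0.5e-6))
        assert all(r.valid for r in records)

    def test_insufficient_samples_flagged(self):
        traj = make_traj(np.concatenate([np.zeros(26), np.full(36, 10e-6)]), dt=0.05)
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        short = dataclasses.replace(segs[0], t=segs[0].t[-1:], y=segs[0].y[-1:])
        records = validate_balance([short, segs[1]])
        assert not records[0].valid
        assert records[0].reason == "insufficient samples"

    def test_scale_equivariance(self, rng):
        """Scaling all positions by k scales D and the windows identically,
        so validity flags are unchanged."""
        y = np.concatenate(
            [rng.normal(0, 0.2e-6, 26), 10e-6 + rng.normal(0, 0.2e-6, 36),
             3e-6 + rng.normal(0, 0.2e-6, 14)]
        )
        base = validate_balance(segment_by_schedule(make_traj(y), DEFAULT_SCHEDULE))
        scaled = validate_balance(
            segment_by_schedule(make_traj(123.0 * y), DEFAULT_SCHEDULE)
        )
        assert [r.valid for r in base] == [r.valid for r in scaled]

    def test_population_scale_override(self):
        segs = self.two_level_segments(tail_dev=2e-6)
        loose = validate_balance(segs, reference_scale=100e-6)
        assert all(r.valid for r in loose)

    def test_exponential_settling_threshold(self):
        """For a pure first-order relaxation in the short (0.7 s) segment the
        criterion flips at an analytically locatable time constant tau*."""
        dt = 0.05
        jump = 10e-6  # reference scale D

        def worst_residual(tau):
            # largest |y(t) - y(T)| among settle-window samples of the final
            # 0.7 s segment, relaxation amplitude `jump` from segment start
            seg_t = (np.arange(14) + 0.5) * dt
            y = jump * np.exp(-seg_t / tau)
            window = seg_t >= seg_t[-1] - 0.25
            return np.max(np.abs(y[window] - y[-1])) - 0.1 * jump

        assert worst_residual(0.05) < 0 < worst_residual(0.3)
        tau_star = optimize.brentq(worst_residual, 0.05, 0.3)

        def run(tau):
            seg1 = np.zeros(26)
            seg2 = np.full(36, jump)
            t3 = (np.arange(14) + 0.5) * dt
            seg3 = jump * np.exp(-t3 / tau)
            traj = make_traj(np.concatenate([seg1, seg2, seg3]), dt=dt)
            segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
            recs = validate_balance(segs, reference_scale=jump)
            return recs[2].valid

        assert run(tau_star * 0.9)
        assert not run(tau_star * 1.1)


class TestTruncation:
    def cohort(self, rng, n=60):
        trajs = []
        for _ in range(n):
            tau = rng.uniform(0.05, 1.2)
            t = (np.arange(76) + 0.5) * 0.05
            y = np.where(
                t <= 1.3,
                5e-6 * np.exp(-t / tau),
                np.where(
                    t <= 3.1,
                    10e-6 - 10e-6 * np.exp(-(t - 1.3) / tau),
                    4e-6 + 6e-6 * np.exp(-(t - 3.1) / tau),
                ),
            )
            trajs.append(make_traj(y))
        return trajs

    def test_factor_one_reproduces_validate_balance(self, rng):
        trajs = self.cohort(rng)
        table = truncation_analysis(trajs, DEFAULT_SCHEDULE, factors=[1.0])
        n_valid = sum(
            rec.valid
            for traj in trajs
            for rec in validate_balance(segment_by_schedule(traj, DEFAULT_SCHEDULE))
        )
        assert table.loc[0, "n_valid"] == n_valid
        assert table.loc[0, "total_duration_s"] == pytest.approx(3.8)

    def test_fraction_non_decreasing_with_duration(self, rng):
        trajs = self.cohort(rng)
        table = truncation_analysis(
            trajs, DEFAULT_SCHEDULE, factors=np.linspace(0.4, 1.0, 7)
        )
        fracs = table.sort_values("factor")["valid_fraction"].to_numpy()
        assert np.all(np.diff(fracs) >= -1e-12)

    def test_tiny_factor_leaves_no_valid_windows(self, rng):
        trajs = self.cohort(rng, n=10)
        table = truncation_analysis(trajs, DEFAULT_SCHEDULE, factors=[0.02])
        assert table.loc[0, "valid_fraction"] == 0.0

    def test_invalid_factor_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            truncation_analysis(self.cohort(rng, n=2), DEFAULT_SCHEDULE, factors=[1.5])


class TestSimulateTrajectory:
    RE_CM = {25e6: -0.18, 1.2e6: -0.38, 2e6: -0.33}

    def test_settled_limit_matches_forward_model(self, device):
        traj = simulate_trajectory(
            self.RE_CM, 5e-6, device, settle_time=0.02, noise_sd=0.0, seed=0
        )
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        for seg in segs:
            expected = balance_position(5e-6, self.RE_CM[seg.frequency], device, seg.frequency).delta
            assert seg.final_y == pytest.approx(expected, rel=1e-3)

    def test_infinite_settling_freezes_at_start(self, device):
        traj = simulate_trajectory(
            self.RE_CM, 5e-6, device, settle_time=1e6, noise_sd=0.0, y0=12e-6, seed=0
        )
        assert np.allclose(traj.y, 12e-6, rtol=1e-3)

    def test_noise_level_in_settled_tail(self, device):
        traj = simulate_trajectory(
            self.RE_CM, 5e-6, device, settle_time=0.01, noise_sd=0.25e-6,
            frame_rate=20.0, n_cycles=14, seed=1,
        )
        segs = segment_by_schedule(traj, DEFAULT_SCHEDULE)
        tail = np.concatenate([s.y[5:] for s in segs if len(s) > 10])
        resid = tail - np.concatenate(
            [np.full(len(s.y[5:]), np.median(s.y[5:])) for s in segs if len(s) > 10]
        )
        assert np.std(resid) == pytest.approx(0.25e-6, rel=0.1)

    def test_seed_determinism(self, device):
        a = simulate_trajectory(self.RE_CM, 5e-6, device, noise_sd=0.3e-6, seed=5)
        b = simulate_trajectory(self.RE_CM, 5e-6, device, noise_sd=0.3e-6, seed=5)
        assert np.array_equal(a.y, b.y)

    def test_round_trip_recovers_cm(self, device):
        """Fast-settling noiseless trajectories validate everywhere and invert
        back to the input Re[CM] to 1e-3 relative."""
        traj = simulate_trajectory(
            self.RE_CM, 5e-6, device, settle_time=0.02, noise_sd=0.0, seed=0
        )
        records = validate_balance(segment_by_schedule(traj, DEFAULT_SCHEDULE))
        assert all(r.valid for r in records)
        for rec in records:
            got = invert_cm(rec.balance_position, 5e-6, device, rec.frequency)
            assert got == pytest.approx(self.RE_CM[rec.frequency], rel=1e-3)


class TestTrajectoryContainer:
    def test_nonuniform_sampling_rejected(self):
        with pytest.raises(ValidationError):
            Trajectory(t=np.array([0.1, 0.2, 0.4]), y=np.zeros(3))

    def test_dataframe_round_trip(self):
        traj = make_traj([1.0, 2.0, 3.0])
        back = Trajectory.from_dataframe(traj.to_dataframe())
        assert np.array_equal(back.y, traj.y)
        assert np.array_equal(back.t, traj.t)
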