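"""Forward/inverse balance-position model, bead calibration, size correction."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from depspring.dielectrics import DielectricMaterial, cm_factor
from depspring.errors import GeometryError, NoBalanceError
from depspring.spring import (
    DeviceState,
    ExponentialForceProfile,
    NormalizationTable,
    balance_position,
    calibrate_p,
    invert_cm,
    size_correct,
    spring_argument,
)

import dataclasses


def manual_spring_argument(radius, re_cm, dev, f=1e6):
    """Term-by-term arithmetic oracle for the force-balance argument."""
    drag = (
        3.0
        * dev.viscosity
        * np.sin(dev.electrode_angle)
        * (6.0 * dev.flow_rate / (dev.channel_width * dev.channel_height**3))
        * (dev.channel_height - radius)
    )
    dep = (
        radius
        * dev.medium.absolute_permittivity
        * abs(re_cm)
        * dev.rms_voltage**2
        * dev.geometry_factor
        * dev.p(f)
    )
    return drag / dep


class TestSpringArgument:
    def test_term_by_term_oracle(self, device):
        u = spring_argument(5e-6, -0.2, device, 1e6)
        assert u == pytest.approx(manual_spring_argument(5e-6, -0.2, device), rel=1e-12)
        assert u > 0

    def test_voltage_squared_scaling(self, device):
        doubled = dataclasses.replace(device, rms_voltage=2 * device.rms_voltage)
        assert spring_argument(5e-6, -0.2, doubled, 1e6) == pytest.approx(
            spring_argument(5e-6, -0.2, device, 1e6) / 4.0, rel=1e-12
        )

    def test_inverse_linearity_in_cm(self, device):
        assert spring_argument(5e-6, -0.1, device, 1e6) == pytest.approx(
            2.0 * spring_argument(5e-6, -0.2, device, 1e6), rel=1e-12
        )

    def test_flow_rate_monotonicity(self, device):
        faster = dataclasses.replace(device, flow_rate=2 * device.flow_rate)
        assert spring_argument(5e-6, -0.2, faster, 1e6) > spring_argument(
            5e-6, -0.2, device, 1e6
        )

    def test_positive_cm_has_no_balance(self, device):
        with pytest.raises(NoBalanceError):
            spring_argument(5e-6, 0.3, device, 1e6)

    def test_oversized_cell_rejected(self, device):
        with pytest.raises(GeometryError):
            spring_argument(device.channel_height, -0.2, device, 1e6)


class TestBalancePosition:
    def test_unit_argument_gives_zero_position(self, device):
        # craft re_cm so that u = 1 exactly
        u_ref = spring_argument(5e-6, -1.0, device, 1e6)
        re_cm = -u_ref
        assert spring_argument(5e-6, re_cm, device, 1e6) == pytest.approx(1.0, rel=1e-12)
        assert balance_position(5e-6, re_cm, device, 1e6).delta == pytest.approx(0.0, abs=1e-15)

    def test_voltage_doubling_shifts_by_lambda_ln4(self, device):
        lam = device.decay_length
        d1 = balance_position(5e-6, -0.3, device, 1e6).delta
        doubled = dataclasses.replace(device, rms_voltage=2 * device.rms_voltage)
        d2 = balance_position(5e-6, -0.3, doubled, 1e6).delta
        assert d2 - d1 == pytest.approx(lam * np.log(4.0), rel=1e-9)

    def test_monotone_in_cm_magnitude(self, device):
        deltas = [
            balance_position(5e-6, c, device, 1e6).delta
            for c in np.linspace(-0.05, -0.5, 20)
        ]
        assert np.all(np.diff(deltas) > 0)

    def test_overdamped_cell_clamps_to_center_with_warning(self, device):
        with pytest.warns(UserWarning, match="electrode center"):
            pred = balance_position(5e-6, -1e-4, device, 1e6)
        assert pred.delta == 0.0

    def test_cm_voltage_scaling_invariance(self, device):
        """delta is unchanged under Re[CM] -> k Re[CM], V^2 -> V^2 / k."""
        k = 3.7
        base = balance_position(5e-6, -0.1, device, 1e6).delta
        scaled_dev = dataclasses.replace(device, rms_voltage=device.rms_voltage / np.sqrt(k))
        assert balance_position(5e-6, -0.1 * k, scaled_dev, 1e6).delta == pytest.approx(
            base, rel=1e-12
        )


class TestInversion:
    def test_round_trip_identity(self, device, rng):
        """invert(forward(c)) = c to 1e-9 relative on 1000 random valid inputs."""
        for _ in range(1000):
            radius = rng.uniform(2e-6, 8e-6)
            re_cm = -rng.uniform(0.02, 0.5)
            f = 10 ** rng.uniform(5, 8)
            pred = balance_position(radius, re_cm, device, f)
            if pred.delta == 0.0:
                continue
            assert invert_cm(pred.delta, radius, device, f) == pytest.approx(re_cm, rel=1e-9)

    def test_zero_position_recovers_unit_argument_cm(self, device):
        re_cm = invert_cm(0.0, 5e-6, device, 1e6)
        assert spring_argument(5e-6, re_cm, device, 1e6) == pytest.approx(1.0, rel=1e-12)

    def test_against_bisection_oracle(self, device):
        delta = 30e-6
        oracle = optimize.brentq(
            lambda c: balance_position(5e-6, c, device, 1e6).delta - delta,
            -0.5,
            -1e-3,
            xtol=1e-15,
        )
        assert invert_cm(delta, 5e-6, device, 1e6) == pytest.approx(oracle, rel=1e-9)

    def test_unphysical_inversion_warns(self, device):
        weak = dataclasses.replace(device, rms_voltage=0.1)
        with pytest.warns(UserWarning, match="physical range"):
            invert_cm(1e-6, 5e-6, weak, 1e6)


class TestCalibration:
    BEAD = DielectricMaterial(2.5, 1e-12)
    RADIUS = 5.13e-6

    def _bead_positions(self, device, freqs, p_true):
        dev = dataclasses.replace(
            device, normalization=NormalizationTable(freqs, p_true)
        )
        rows = []
        for f in freqs:
            re_cm = cm_factor(self.BEAD, device.medium, f).real
            rows.append(
                {"frequency_hz": f, "delta_m": balance_position(self.RADIUS, re_cm, dev, f).delta}
            )
        return pd.DataFrame(rows)

    def test_known_normalization_recovered(self, device):
        freqs = np.array([5e5, 2e6, 1e7, 2.5e7])
        p_true = np.array([1.0, 0.9, 0.75, 0.6])  # normalized at the lowest frequency
        table = calibrate_p(
            self._bead_positions(device, freqs, p_true), self.RADIUS, self.BEAD, device
        )
        assert np.allclose(table.factors, p_true, rtol=1e-9)

    def test_single_frequency_normalizes_to_one(self, device):
        table = calibrate_p(
            self._bead_positions(device, np.array([1e6]), np.array([0.8])),
            self.RADIUS,
            self.BEAD,
            device,
        )
        assert table.factors == pytest.approx([1.0])

    def test_log_linear_interpolation(self, device):
        freqs = np.array([1e6, 1e8])
        table = calibrate_p(
            self._bead_positions(device, freqs, np.array([1.0, 0.5])),
            self.RADIUS,
            self.BEAD,
            device,
        )
        assert table(1e7) == pytest.approx(0.75, rel=1e-9)  # midpoint in log f

    def test_noise_propagation_bounded(self, device, rng):
        """0.5 um position noise perturbs recovered p by at most a few
        percent (Monte Carlo over 300 noisy calibrations)."""
        freqs = np.array([5e5, 2.5e7])
        p_true = np.array([1.0, 0.7])
        clean = self._bead_positions(device, freqs, p_true)
        lam = device.decay_length
        errors = []
        for _ in range(300):
            noisy = clean.copy()
            noisy["delta_m"] += rng.normal(0.0, 0.5e-6, size=len(noisy))
            table = calibrate_p(noisy, self.RADIUS, self.BEAD, device)
            errors.append(abs(table.factors[1] - p_true[1]) / p_true[1])
        # each position error dd perturbs p by ~ exp(dd/lambda) - 1 ~ 2%
        predicted = np.sqrt(2.0) * 0.5e-6 / lam
        assert np.mean(errors) == pytest.approx(np.sqrt(2 / np.pi) * predicted, rel=0.5)
        assert np.max(errors) < 6 * predicted


class TestSizeCorrection:
    def test_identity_at_reference_radius(self, device):
        d = balance_position(5e-6, -0.25, device, 1e6).delta
        assert size_correct(d, 5e-6, 5e-6, device, 1e6) == pytest.approx(d, rel=1e-12)

    def test_removes_radius_dependence(self, device):
        d_small = balance_position(3e-6, -0.25, device, 1e6).delta
        d_large = balance_position(7e-6, -0.25, device, 1e6).delta
        assert d_small != pytest.approx(d_large, rel=1e-3)
        c_small = size_correct(d_small, 3e-6, 5e-6, device, 1e6)
        c_large = size_correct(d_large, 7e-6, 5e-6, device, 1e6)
        assert c_small == pytest.approx(c_large, rel=1e-9)

    def test_preserves_cm_ordering(self, device, rng):
        # stay inside the unclamped domain (u < 1) so positions are informative
        cells = [(rng.uniform(3e-6, 7e-6), -rng.uniform(0.16, 0.5)) for _ in range(100)]
        corrected = []
        for radius, re_cm in cells:
            d = balance_position(radius, re_cm, device, 1e6).delta
            corrected.append((abs(re_cm), size_correct(d, radius, 5e-6, device, 1e6)))
        corrected.sort()
        deltas = [d for _, d in corrected]
        assert np.all(np.diff(deltas) > 0)
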