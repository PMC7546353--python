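import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from impactkin import biphasic
from impactkin.errors import ConfigError, NoPulseError

FS = 1000.0
T = np.arange(100) / FS


def _triangle_trace(t0_ms=20, tm_ms=25, t1_ms=35, amp=200.0):
    """Triangle pulse embedded in zeros, vertices on the sample grid."""
    trace = np.zeros(100)
    up = slice(t0_ms, tm_ms + 1)
    trace[up] = amp * (np.arange(t0_ms, tm_ms + 1) - t0_ms) / (tm_ms - t0_ms)
    down = slice(tm_ms, t1_ms + 1)
    trace[down] = amp * (t1_ms - np.arange(tm_ms, t1_ms + 1)) / (t1_ms - tm_ms)
    return trace


class TestDetectPulse:
    def test_planted_triangle_window_recovery(self):
        trace = _triangle_trace()
        w = biphasic.detect_pulse(trace, FS)
        assert abs(w.i0 - 20) <= 1
        assert abs(w.i1 - 35) <= 1
        assert w.i_M == 25
        # analytic area 0.5 * 200 * 15 ms = 1.5
        assert w.delta_omega == pytest.approx(1.5, rel=0.01)

    def test_detection_idempotent_on_synthesized_triangle(self):
        w0 = biphasic.detect_pulse(_triangle_trace(), FS)
        pulse = biphasic.fit_biphasic(w0, "triangle")
        w1 = biphasic.detect_pulse(biphasic.synthesize(pulse, T), FS)
        assert abs(w1.i0 - w0.i0) <= 1
        assert abs(w1.i1 - w0.i1) <= 1

    def test_full_sine_period_boundaries_at_zero_crossings(self):
        # one 20 ms period starting at 30 ms; peak at the first crest
        trace = np.zeros(100)
        k = np.arange(30, 50)
        trace[k] = np.sin(2 * np.pi * (k - 30) / 20.0)
        w = biphasic.detect_pulse(trace, FS)
        assert w.i_M == 35
        assert abs(w.i0 - 30) <= 1
        assert abs(w.i1 - 40) <= 1

    def test_peak_at_first_sample_gives_right_half_pulse(self):
        trace = np.exp(-np.arange(100) / 10.0)
        w = biphasic.detect_pulse(trace, FS)
        assert w.half_pulse == "right_only"
        assert w.t0 == w.t_M == 0.0

    def test_peak_at_last_sample_gives_left_half_pulse(self):
        trace = np.exp((np.arange(100) - 99) / 10.0)
        w = biphasic.detect_pulse(trace, FS)
        assert w.half_pulse == "left_only"
        assert w.t1 == w.t_M

    def test_no_boundary_before_edge_is_clamped_and_flagged(self):
        # concave-up monotone rise: no sign or convexity change on the left
        trace = np.exp(np.linspace(0, 3, 100))
        w = biphasic.detect_pulse(trace, FS)
        assert w.clamped

    def test_zero_trace_raises(self):
        with pytest.raises(NoPulseError):
            biphasic.detect_pulse(np.zeros(50), FS)

    def test_short_trace_raises(self):
        with pytest.raises(ConfigError):
            biphasic.detect_pulse(np.array([1.0, 2.0]), FS)


class TestFitBiphasic:
    @pytest.mark.parametrize(
        "shape, expected",
        [("triangle", 200.0), ("half_sine", np.pi / 2 * 100.0)],
    )
    def test_amplitude_formulas(self, shape, expected):
        w = biphasic.PulseWindow(
            t_M=0.025, alpha_M=150.0, t0=0.02, t1=0.03, dt=0.01,
            delta_omega=1.0, i0=20, i_M=25, i1=30,
        )
        pulse = biphasic.fit_biphasic(w, shape)
        assert pulse.amplitude == pytest.approx(expected)

    @settings(deadline=None, max_examples=50)
    @given(
        dw=st.floats(min_value=0.01, max_value=50.0),
        dt_ms=st.integers(min_value=2, max_value=50),
        sign=st.sampled_from([-1.0, 1.0]),
    )
    def test_triangle_to_halfsine_amplitude_ratio_is_4_over_pi(
        self, dw, dt_ms, sign
    ):
        dt = dt_ms / 1000.0
        w = biphasic.PulseWindow(
            t_M=dt / 2, alpha_M=sign * 100.0, t0=0.0,
            t1=dt, dt=dt,
            delta_omega=sign * dw, i0=0, i_M=dt_ms // 2, i1=dt_ms,
        )
        tri = biphasic.fit_biphasic(w, "triangle")
        hs = biphasic.fit_biphasic(w, "half_sine")
        assert tri.amplitude / hs.amplitude == pytest.approx(4 / np.pi)
        assert np.sign(tri.amplitude) == np.sign(w.alpha_M)

    def test_zero_velocity_change_rejected(self):
        w = biphasic.PulseWindow(
            t_M=0.01, alpha_M=1.0, t0=0.005, t1=0.015, dt=0.01,
            delta_omega=0.0, i0=5, i_M=10, i1=15,
        )
        with pytest.raises(ConfigError):
            biphasic.fit_biphasic(w, "triangle")


class TestSynthesize:
    @pytest.mark.parametrize("shape", ["triangle", "half_sine"])
    @pytest.mark.parametrize("half", ["none", "left_only", "right_only"])
    def test_area_conservation(self, shape, half):
        if half == "none":
            w = biphasic.PulseWindow(
                t_M=0.025, alpha_M=100.0, t0=0.02, t1=0.035, dt=0.015,
                delta_omega=2.0, i0=20, i_M=25, i1=35,
            )
        elif half == "right_only":
            w = biphasic.PulseWindow(
                t_M=0.0, alpha_M=100.0, t0=0.0, t1=0.012, dt=0.012,
                delta_omega=2.0, half_pulse=half, i0=0, i_M=0, i1=12,
            )
        else:
            w = biphasic.PulseWindow(
                t_M=0.099, alpha_M=100.0, t0=0.087, t1=0.099, dt=0.012,
                delta_omega=2.0, half_pulse=half, i0=87, i_M=99, i1=99,
            )
        pulse = biphasic.fit_biphasic(w, shape)
        trace = biphasic.synthesize(pulse, T)
        area = np.trapezoid(trace, dx=1 / FS)
        assert area == pytest.approx(w.delta_omega, rel=0.005)

    def test_peak_values_match_shape_definition(self):
        w = biphasic.PulseWindow(
            t_M=0.025, alpha_M=100.0, t0=0.02, t1=0.03, dt=0.01,
            delta_omega=1.0, i0=20, i_M=25, i1=30,
        )
        tri = biphasic.synthesize(biphasic.fit_biphasic(w, "triangle"), T)
        assert tri[25] == pytest.approx(200.0)
        hs = biphasic.synthesize(biphasic.fit_biphasic(w, "half_sine"), T)
        assert hs[25] == pytest.approx(np.pi / 2 * 100.0)  # midpoint of window

    def test_support_is_exactly_zero_outside_window(self):
        w = biphasic.PulseWindow(
            t_M=0.025, alpha_M=100.0, t0=0.02, t1=0.03, dt=0.01,
            delta_omega=1.0, i0=20, i_M=25, i1=30,
        )
        trace = biphasic.synthesize(biphasic.fit_biphasic(w, "triangle"), T)
        assert np.all(trace[:20] == 0.0)
        assert np.all(trace[31:] == 0.0)

    def test_grid_coarser_than_pulse_rejected(self):
        w = biphasic.PulseWindow(
            t_M=0.025, alpha_M=100.0, t0=0.024, t1=0.026, dt=0.002,
            delta_omega=0.5, i0=24, i_M=25, i1=26,
        )
        pulse = biphasic.fit_biphasic(w, "triangle")
        with pytest.raises(ConfigError, match="coarser"):
            biphasic.synthesize(pulse, np.arange(0, 0.1, 0.004))


class TestIntegrateToVelocity:
    def test_constant_acceleration(self):
        omega = biphasic.integrate_to_velocity(np.full(101, 3.0), FS)
        assert omega[-1] == pytest.approx(3.0 * 0.1)

    def test_zero_acceleration_keeps_initial_velocity(self):
        omega = biphasic.integrate_to_velocity(np.zeros(50), FS, omega0=2.5)
        np.testing.assert_allclose(omega, 2.5)

    def test_velocity_plateaus_after_pulse(self):
        w = biphasic.PulseWindow(
            t_M=0.025, alpha_M=100.0, t0=0.02, t1=0.035, dt=0.015,
            delta_omega=2.0, i0=20, i_M=25, i1=35,
        )
        pulse = biphasic.fit_biphasic(w, "half_sine")
        trace = biphasic.synthesize(pulse, T)
        omega = biphasic.integrate_to_velocity(trace, FS)
        plateau = omega[40:]
        np.testing.assert_allclose(plateau, plateau[0], atol=1e-12)
        assert plateau[0] == pytest.approx(2.0, rel=0.005)


def test_fit_dataset_table_schema(small_dataset):
    table = biphasic.fit_dataset(small_dataset, "triangle")
    assert set(table.columns) >= {
        "record_id", "direction", "t0", "tM", "t1", "dt",
        "delta_omega", "amplitude", "half_pulse",
    }
    assert len(table) == 3 * len(small_dataset)
    assert (table["dt"] > 0).all()


def test_biphasic_dataset_velocities_plateau(small_dataset):
    ds = biphasic.build_biphasic_dataset(small_dataset, "triangle")
    rec = ds[0]
    # after the fitted pulse the angular velocity stays constant
    for d in range(3):
        tail = rec.ang_vel[d, -5:]
        np.testing.assert_allclose(tail, tail[0], atol=1e-12)
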