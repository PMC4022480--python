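"""Unit tests for the single-cell gene models and their integrators."""

import math

import numpy as np
import pytest

from cyberloop.gene_models import (
    BinaryInputSignal,
    Gal1Parameters,
    IrmaParameters,
    Trajectory,
    constant_history,
    irma_vector_field,
    simulate_gal1,
    simulate_irma,
    steady_state,
    step_response,
)


def reference_field(x, xd, u, p):
    """Independent transcription of the network equations (plain numpy,
    written without reference to the implementation)."""
    hill = lambda s, k, h: s ** h / (k ** h + s ** h)
    dx = np.empty(5)
    dx[0] = (p.alpha1 + p.v1 * hill(xd[2], p.k1, p.h1)
             / (1 + (xd[3] / p.k2) ** p.h2) - p.d1 * x[0])
    dx[1] = p.alpha2 + p.v2 * hill(x[0], p.k3, p.h3) - p.d2 * x[1]
    dx[2] = (p.alpha3 + u * p.v3 * hill(x[1], p.k4, p.h4)
             / (1 + x[4] / p.gamma) - p.d3 * x[2])
    dx[3] = p.alpha4 + p.v4 * hill(x[2], p.k5, p.h1) - p.d4 * x[3]
    dx[4] = p.alpha5 + p.v5 * hill(x[2], p.k6, p.h1) - p.d5 * x[4]
    return dx


class TestVectorField:
    def test_zero_state_gives_basal_production(self, irma_params):
        z = np.zeros(5)
        dx = irma_vector_field(z, z, 0, irma_params)
        assert np.all(dx >= 0)
        # degradation vanishes at zero: derivative is pure basal input
        assert dx[0] == pytest.approx(irma_params.alpha1)

    def test_steady_state_is_fixed_point(self, irma_params):
        for u in (0, 1):
            ss = steady_state(irma_params, u)
            dx = irma_vector_field(ss, ss, u, irma_params)
            assert np.linalg.norm(dx) < 1e-8

    def test_matches_independent_transcription(self, irma_nodelay, rng):
        p = irma_nodelay
        for _ in range(50):
            x = rng.uniform(0, 3, size=5)
            for u in (0, 1):
                got = irma_vector_field(x, x, u, p)
                want = reference_field(x, x, u, p)
                np.testing.assert_allclose(got, want, rtol=0, atol=1e-12)

    def test_galactose_enables_swi5_production(self, irma_params):
        x = np.full(5, 0.5)
        d0 = irma_vector_field(x, x, 0, irma_params)
        d1 = irma_vector_field(x, x, 1, irma_params)
        assert d1[2] > d0[2]
        np.testing.assert_allclose(np.delete(d1, 2), np.delete(d0, 2))

    def test_rejects_negative_state(self, irma_params):
        x = np.zeros(5)
        bad = x.copy()
        bad[1] = -0.1
        with pytest.raises(ValueError):
            irma_vector_field(bad, x, 0, irma_params)
        with pytest.raises(ValueError):
            irma_vector_field(x, x, 2, irma_params)


class TestParameters:
    def test_positivity_enforced(self, irma_params):
        fields = {k: getattr(irma_params, k)
                  for k in irma_params.__dataclass_fields__}
        fields["v1"] = -1.0
        with pytest.raises(ValueError):
            IrmaParameters(**fields)
        with pytest.raises(ValueError):
            Gal1Parameters(vmax=0.0, d=0.01)

    def test_negative_tau_rejected(self, irma_params):
        with pytest.raises(ValueError):
            irma_params.with_tau(-1.0)


class TestBinaryInputSignal:
    def test_right_continuous_piecewise_constant(self):
        sig = BinaryInputSignal([0.0, 10.0, 25.0], [1, 0, 1])
        assert sig.level_at(9.999) == 1
        assert sig.level_at(10.0) == 0       # right-continuous
        assert sig.level_at(24.0) == 0
        assert sig.level_at(25.0) == 1
        assert sig.level_at(-5.0) == 1       # before the record

    def test_validation(self):
        with pytest.raises(ValueError):
            BinaryInputSignal([0.0, 0.0], [0, 1])     # not increasing
        with pytest.raises(ValueError):
            BinaryInputSignal([0.0], [2])             # not binary

    def test_from_segments_merges_repeats(self):
        sig = BinaryInputSignal.from_segments(
            [(0.0, 1), (5.0, 1), (10.0, 0)])
        assert sig.times.tolist() == [0.0, 10.0]


class TestSimulateIrma:
    def test_agrees_with_fine_euler_without_delay(self, irma_nodelay):
        """RK4 path against a brute-force small-step Euler oracle."""
        p = irma_nodelay
        sig = BinaryInputSignal([0.0, 150.0], [1, 0])
        x0 = steady_state(p, 0)
        dt = 0.5
        traj = simulate_irma(p, sig, 0.0, 300.0, initial_state=x0, dt=dt)
        # Euler at dt/100
        h = dt / 100
        x = x0.copy()
        t = 0.0
        euler = [x0.copy()]
        for i in range(int(300.0 / h)):
            x = np.maximum(x + h * reference_field(x, x, sig.level_at(t), p),
                           0.0)
            t += h
            if (i + 1) % 100 == 0:
                euler.append(x.copy())
        euler = np.asarray(euler)
        scale = np.max(euler, axis=0)
        rel = np.max(np.abs(traj.states - euler) / scale)
        assert rel < 1e-3

    def test_equilibrium_invariance(self, irma_params):
        ss = steady_state(irma_params, 0)
        sig = BinaryInputSignal.constant(0)
        traj = simulate_irma(irma_params, sig, 0.0, 500.0,
                             history=constant_history(ss), dt=0.5)
        assert np.max(np.abs(traj.states - ss)) < 1e-6

    def test_switch_off_protocol(self, irma_params):
        """Galactose for 180 min then glucose: Cbf1 rises, then decays
        monotonically toward the glucose steady state."""
        ss0 = steady_state(irma_params, 0)
        sig = BinaryInputSignal([0.0, 180.0], [1, 0])
        traj = simulate_irma(irma_params, sig, 0.0, 600.0,
                             history=constant_history(ss0), dt=0.5)
        cbf1 = traj.output
        assert cbf1[np.searchsorted(traj.time, 180.0)] > 3 * ss0[0]
        peak = int(np.argmax(cbf1))
        assert np.all(np.diff(cbf1[peak:]) <= 1e-9)
        assert cbf1[-1] == pytest.approx(ss0[0], rel=1e-2)

    def test_non_negative_trajectories(self, irma_params, rng):
        times = np.sort(rng.uniform(0, 400, size=8))
        levels = rng.integers(0, 2, size=8)
        sig = BinaryInputSignal(times - times[0], levels)
        traj = simulate_irma(irma_params, sig, 0.0, 500.0,
                             initial_state=rng.uniform(0, 2, 5), dt=0.5)
        assert np.all(traj.states >= 0)

    def test_input_validation(self, irma_params):
        with pytest.raises(ValueError):
            simulate_irma(irma_params, BinaryInputSignal.constant(0),
                          10.0, 5.0, initial_state=np.zeros(5))
        with pytest.raises(ValueError):
            # 0 < tau < dt is not representable on the grid
            simulate_irma(irma_params.with_tau(0.1),
                          BinaryInputSignal.constant(0),
                          0.0, 10.0, initial_state=np.zeros(5), dt=0.5)


class TestSteadyState:
    def test_hybrid_ordering(self, irma_params):
        """Galactose switches the network on: higher Cbf1."""
        assert steady_state(irma_params, 1)[0] > steady_state(irma_params, 0)[0]

    def test_matches_long_simulation(self, irma_params):
        for u in (0, 1):
            ss = steady_state(irma_params, u)
            traj = simulate_irma(irma_params, BinaryInputSignal.constant(u),
                                 0.0, 4000.0,
                                 initial_state=np.full(5, 0.3), dt=0.5)
            np.testing.assert_allclose(traj.states[-1], ss, atol=1e-4)


class TestStepResponse:
    def test_same_level_is_constant(self, irma_params):
        traj = step_response(irma_params, 0, 0, horizon=200.0, dt=0.5)
        assert np.max(np.abs(traj.output - traj.output[0])) < 1e-9

    def test_initial_value_and_rise(self, irma_params):
        traj = step_response(irma_params, 0, 1, horizon=1200.0, dt=0.5)
        assert traj.output[0] == pytest.approx(
            steady_state(irma_params, 0)[0], abs=1e-8)
        after = traj.output[np.searchsorted(traj.time, irma_params.tau):]
        # rising to the peak after the delay; the delayed ASH1 repression
        # wave may carve a small shoulder, so allow a ripple of < 1% of
        # the total excursion per step
        peak = int(np.argmax(after))
        rise = after[peak] - traj.output[0]
        assert np.all(np.diff(after[:peak + 1]) > -0.01 * rise)
        assert after[peak] > traj.output[0] + 0.5

    def test_delay_shifts_response_onset(self, irma_nodelay):
        """Shifting tau by delta shifts the Cbf1 rise onset by delta."""
        dt = 0.5

        def onset(tau):
            traj = step_response(irma_nodelay.with_tau(tau), 0, 1,
                                 horizon=600.0, dt=dt)
            y = traj.output
            lift = y[0] + 0.02 * (y[-1] - y[0])
            return traj.time[np.argmax(y > lift)]

        delta = onset(150.0) - onset(50.0)
        assert delta == pytest.approx(100.0, abs=2 * dt)


class TestGal1:
    def test_rise_closed_form(self, gal1_params):
        p = Gal1Parameters(vmax=gal1_params.vmax, d=gal1_params.d, lag=0.0)
        traj = simulate_gal1(p, BinaryInputSignal.constant(1), 0.0, 400.0,
                             dt=0.5)
        expect = (p.vmax / p.d) * (1 - np.exp(-p.d * traj.time))
        np.testing.assert_allclose(traj.output, expect, rtol=1e-10)

    def test_decay_closed_form(self, gal1_params):
        p = Gal1Parameters(vmax=gal1_params.vmax, d=gal1_params.d, lag=0.0)
        traj = simulate_gal1(p, BinaryInputSignal.constant(0), 0.0, 400.0,
                             dt=0.5, y0=80.0)
        np.testing.assert_allclose(traj.output,
                                   80.0 * np.exp(-p.d * traj.time),
                                   rtol=1e-10)

    def test_pulse_train_cycle_average(self):
        """50% duty pulsing settles into an oscillation whose cycle
        average matches the closed-form periodic solution."""
        p = Gal1Parameters(vmax=1.0, d=0.01, lag=0.0)
        period, high = 10.0, 5.0
        n_cycles = 400
        times = np.arange(0, n_cycles * period, high)
        levels = np.tile([1, 0], n_cycles)
        sig = BinaryInputSignal(times, levels)
        traj = simulate_gal1(p, sig, 0.0, n_cycles * period, dt=0.25)

        # closed-form periodic fixed point: y_lo at cycle start
        a_on = math.exp(-p.d * high)
        a_off = math.exp(-p.d * (period - high))
        ymax = p.vmax / p.d
        y_lo = ymax * (1 - a_on) * a_off / (1 - a_on * a_off)
        y_hi = ymax + (y_lo - ymax) * a_on
        # analytic integral of the exact solution over one cycle
        int_on = ymax * high + (y_lo - ymax) * (1 - a_on) / p.d
        int_off = y_hi * (1 - a_off) / p.d
        avg_expect = (int_on + int_off) / period

        i0 = np.searchsorted(traj.time, (n_cycles - 1) * period)
        i1 = np.searchsorted(traj.time, n_cycles * period)
        avg_sim = np.trapezoid(traj.output[i0:i1 + 1],
                               traj.time[i0:i1 + 1]) / period
        assert avg_sim == pytest.approx(avg_expect, abs=1e-6 * ymax)

    def test_lag_delays_production(self):
        p = Gal1Parameters(vmax=1.0, d=0.01, lag=15.0)
        sig = BinaryInputSignal([-1000.0, 0.0], [0, 1])
        traj = simulate_gal1(p, sig, 0.0, 100.0, dt=0.5)
        before = traj.output[traj.time < 15.0]
        assert np.all(before == 0.0)
        assert traj.output[-1] > 0


class TestTrajectory:
    def test_uniform_grid_enforced(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 3.0]), np.zeros((3, 1)),
                       np.zeros(3))

    def test_csv_round_trip(self, irma_params, tmp_path):
        ss = steady_state(irma_params, 0)
        traj = simulate_irma(irma_params, BinaryInputSignal.constant(1),
                             0.0, 50.0, history=constant_history(ss), dt=0.5)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "time_min,u,cbf1,gal4,swi5,ash1,gal80"
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        np.testing.assert_allclose(data[:, 2:], traj.states, rtol=1e-9)
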