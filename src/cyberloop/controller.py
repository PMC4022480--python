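"""Discrete-time PI regulation, PWM encoding of the binary sugar input,
measurement low-pass filtering, and Cohen-Coon tuning.

The control level computed by the PI block lives on the PWM sawtooth
scale (default [0, 1]); the PWM comparator turns it into a train of
galactose/glucose pulses whose high-time fraction per sawtooth period
equals the (clamped, normalized) level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from cyberloop.gene_models import BinaryInputSignal, Trajectory


# --------------------------------------------------------------------------
# PI regulator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PIConfig:
    """Proportional-integral controller settings.

    ``Ts`` is the loop sampling interval in minutes (one microscopy
    frame every 5 min).  Output saturates on ``[u_min, u_max]`` — the
    sawtooth scale — and with ``anti_windup`` the integral freezes while
    the output is saturated (conditional integration).
    """

    Kp: float
    Ki: float
    Ts: float = 5.0
    u_min: float = 0.0
    u_max: float = 1.0
    anti_windup: bool = True

    def __post_init__(self) -> None:
        if not (self.Ts > 0):
            raise ValueError("Ts must be positive")
        if not (self.u_min < self.u_max):
            raise ValueError("u_min must be below u_max")


@dataclass(frozen=True)
class PIState:
    integral: float = 0.0    # accumulated error integral, error*min
    last_error: float = 0.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.integral) and math.isfinite(self.last_error)):
            raise ValueError("PI state must be finite")


def pi_step(cfg: PIConfig, st: PIState, error: float) -> tuple[float, PIState]:
    """One PI update (backward-Euler integral).

    Returns the saturated control level and the new state; the integral
    update is discarded when it would deepen saturation and anti-windup
    is enabled.
    """
    if not math.isfinite(error):
        raise ValueError("error must be finite")
    integral_new = st.integral + error * cfg.Ts
    raw = cfg.Kp * error + cfg.Ki * integral_new
    level = min(max(raw, cfg.u_min), cfg.u_max)
    if raw != level and cfg.anti_windup:
        integral_new = st.integral  # freeze while saturated
    return level, PIState(integral=integral_new, last_error=error)


# --------------------------------------------------------------------------
# PWM encoder
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PWMConfig:
    """Sawtooth-comparator pulse width modulation.

    A rising sawtooth of period ``T_pwm`` (reset each period, running on
    absolute time so its phase is shared across sampling windows) is
    compared with the control level: galactose (1) while the level is at
    or above the ramp, glucose (0) otherwise.  Pulses are realized on a
    ``quantum``-minute grid, with the comparator evaluated at quantum
    midpoints, so the duty per period matches the normalized level to
    within half a quantum.
    """

    T_pwm: float = 10.0
    saw_min: float = 0.0
    saw_max: float = 1.0
    quantum: float = 1.0

    def __post_init__(self) -> None:
        if not (self.T_pwm > 0):
            raise ValueError("T_pwm must be positive")
        if not (self.saw_min < self.saw_max):
            raise ValueError("saw_min must be below saw_max")
        if not (self.quantum > 0):
            raise ValueError("quantum must be positive")
        ratio = self.T_pwm / self.quantum
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("quantum must divide T_pwm")

    def sawtooth(self, t: float | np.ndarray) -> float | np.ndarray:
        """Rising ramp from ``saw_min`` to ``saw_max``, reset each period."""
        phase = np.mod(t, self.T_pwm) / self.T_pwm
        return self.saw_min + (self.saw_max - self.saw_min) * phase

    def duty(self, level: float) -> float:
        """Clamped normalized level = ideal high-fraction per period."""
        x = (level - self.saw_min) / (self.saw_max - self.saw_min)
        return min(max(x, 0.0), 1.0)


def pwm_encode(control_level: float, cfg: PWMConfig, window_start: float,
               window_length: float | None = None) -> BinaryInputSignal:
    """Encode a control level as binary pulses over one sampling window.

    The window defaults to one sawtooth period.  The comparator is
    sampled at the midpoint of each quantum (tie counts as high, so a
    saturated level gives duty exactly 1 and a level at or below the
    ramp minimum gives duty 0).
    """
    if not math.isfinite(control_level):
        raise ValueError("control level must be finite")
    if window_length is None:
        window_length = cfg.T_pwm
    n = int(round(window_length / cfg.quantum))
    if abs(n * cfg.quantum - window_length) > 1e-9 * max(1.0, window_length):
        raise ValueError("quantum must divide the window length")
    starts = window_start + cfg.quantum * np.arange(n)
    saw = cfg.sawtooth(starts + 0.5 * cfg.quantum)
    levels = (control_level >= saw).astype(int)
    return BinaryInputSignal(starts, levels) if n else BinaryInputSignal(
        [window_start], [0])


# --------------------------------------------------------------------------
# measurement low-pass filter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LowPassFilterState:
    """First-order low-pass: dy_f/dt = (y - y_f) / time_constant."""

    time_constant: float
    value: float = 0.0
    initialized: bool = False

    def __post_init__(self) -> None:
        if not (self.time_constant >= 0):
            raise ValueError("time constant must be >= 0")


def lowpass_step(fst: LowPassFilterState, y_raw: float,
                 dt: float) -> tuple[float, LowPassFilterState]:
    """Advance the filter by ``dt`` with the input held at ``y_raw``
    (exact exponential discretization).  The first sample initializes
    the state; a zero time constant passes the input through."""
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if not fst.initialized:
        return y_raw, replace(fst, value=y_raw, initialized=True)
    if fst.time_constant == 0.0:
        return y_raw, replace(fst, value=y_raw)
    a = math.exp(-dt / fst.time_constant)
    y_f = y_raw + (fst.value - y_raw) * a
    return y_f, replace(fst, value=y_f)


# --------------------------------------------------------------------------
# FOPDT identification and Cohen-Coon tuning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FOPDTEstimate:
    """First-order-plus-dead-time fit: K e^{-d s} / (T s + 1)."""

    K: float
    T: float              # time constant, min
    d: float              # dead time, min

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ValueError("time constant must be positive")
        if not (self.d >= 0):
            raise ValueError("dead time must be >= 0")


def fopdt_response(est: FOPDTEstimate, t: np.ndarray, y0: float = 0.0,
                   du: float = 1.0) -> np.ndarray:
    """Closed-form step response of an FOPDT system (for tests and
    round-trip checks)."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, y0)
    active = t > est.d
    y[active] = y0 + est.K * du * (1.0 - np.exp(-(t[active] - est.d) / est.T))
    return y


def _crossing_time(t: np.ndarray, y: np.ndarray, target: float) -> float:
    """First time ``y`` reaches ``target``, linearly interpolated."""
    above = np.nonzero(y >= target)[0]
    if above.size == 0:
        raise ValueError("response never reaches the requested fraction")
    i = above[0]
    if i == 0:
        return float(t[0])
    y0, y1 = y[i - 1], y[i]
    w = (target - y0) / (y1 - y0) if y1 != y0 else 0.0
    return float(t[i - 1] + w * (t[i] - t[i - 1]))


def estimate_fopdt(step: Trajectory, du: float = 1.0,
                   settle_tol: float = 0.02) -> FOPDTEstimate:
    """Fit an FOPDT model to a settling step response by the two-point
    (28.3% / 63.2%) construction.

    ``K = (y_final - y_initial) / du``; the time constant is
    ``1.5 (t_63.2 - t_28.3)`` and the dead time ``t_63.2 - T`` (clamped
    at zero).  The last 10% of the horizon must be flat to
    ``settle_tol`` of the total excursion, otherwise the response is
    rejected as non-settling.
    """
    t = step.time
    y = step.output
    n_tail = max(2, int(0.1 * y.size))
    tail = y[-n_tail:]
    y_final = float(np.mean(tail))
    y_initial = float(y[0])
    span = y_final - y_initial
    if span == 0.0:
        raise ValueError("flat response: no step to identify")
    if np.max(np.abs(tail - y_final)) > settle_tol * abs(span):
        raise ValueError("response has not settled within the horizon")
    sign = 1.0 if span > 0 else -1.0
    yn = sign * (y - y_initial)   # normalized to a rising response
    t28 = _crossing_time(t - t[0], yn, 0.283 * abs(span))
    t63 = _crossing_time(t - t[0], yn, 0.632 * abs(span))
    T = 1.5 * (t63 - t28)
    d = max(t63 - T, 0.0)
    return FOPDTEstimate(K=span / du, T=T, d=d)


def cohen_coon_gains(est: FOPDTEstimate, Ts: float = 5.0,
                     **pi_kwargs) -> PIConfig:
    """Cohen-Coon PI tuning from an FOPDT fit.

    Kp = (1/K)(T/d)(0.9 + d/(12T)),  Ti = d(30 + 3d/T)/(9 + 20d/T),
    Ki = Kp/Ti.  Singular at zero dead time: callers must then supply
    gains manually.
    """
    if est.d <= 0:
        raise ValueError("Cohen-Coon PI formulas are singular at zero dead "
                         "time; supply gains manually")
    r = est.d / est.T
    Kp = (1.0 / est.K) * (est.T / est.d) * (0.9 + r / 12.0)
    Ti = est.d * (30.0 + 3.0 * r) / (9.0 + 20.0 * r)
    return PIConfig(Kp=Kp, Ki=Kp / Ti, Ts=Ts, **pi_kwargs)
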