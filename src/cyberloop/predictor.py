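"""Smith-type predictor compensating the transcriptional delay.

The predictor runs a delay-free copy of the plant model in parallel with
the real (delayed) plant, both driven by the applied binary input.  The
plant measurement is compared with a delayed replica of the model output
(a stored ring buffer shifted by ``tau_m``); the mismatch is low-pass
filtered and added to the undelayed model output, and the result is fed
back to the comparator in place of the raw measurement:

    y_fb(t) = y_model(t) + LP[ y_meas(t) - y_model(t - tau_m) ]

With a perfect model the mismatch vanishes and the PI effectively
controls the delay-free system; model error enters only through the
filtered correction.  An affine calibration maps model units to
fluorescence units so both signals live on the measurement scale.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

from cyberloop.controller import LowPassFilterState, lowpass_step
from cyberloop.gene_models import (
    BinaryInputSignal,
    Gal1Parameters,
    IrmaParameters,
    simulate_gal1,
    simulate_irma,
    steady_state,
)


# --------------------------------------------------------------------------
# unit calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class AffineCalibration:
    """Affine map between model units and fluorescence units:
    ``fluo = offset + scale * model``."""

    offset: float
    scale: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.scale) and self.scale > 0):
            raise ValueError("calibration scale must be positive")
        if not math.isfinite(self.offset):
            raise ValueError("calibration offset must be finite")

    def to_fluo(self, model_value: float) -> float:
        return self.offset + self.scale * model_value

    def to_model(self, fluo_value: float) -> float:
        return (fluo_value - self.offset) / self.scale


IDENTITY_CALIBRATION = AffineCalibration(offset=0.0, scale=1.0)


def calibrate_units(min_fluo: float, max_fluo: float,
                    model_min: float, model_max: float) -> AffineCalibration:
    """Affine map sending [model_min, model_max] -> [min_fluo, max_fluo]
    (``to_model`` provides the inverse direction)."""
    if not (max_fluo > min_fluo):
        raise ValueError("max_fluo must exceed min_fluo")
    if not (model_max > model_min):
        raise ValueError("model_max must exceed model_min")
    scale = (max_fluo - min_fluo) / (model_max - model_min)
    offset = min_fluo - scale * model_min
    return AffineCalibration(offset=offset, scale=scale)


# --------------------------------------------------------------------------
# internal delay-free models
# --------------------------------------------------------------------------

class InternalModel(Protocol):
    """Delay-free model advanced open-loop under the applied input."""

    def advance(self, signal: BinaryInputSignal, t0: float, t1: float) -> float:
        """Integrate over [t0, t1] and return the output at t1
        (model units)."""
        ...


class IrmaInternalModel:
    """Delay-free IRMA copy stepped with the shared RK4 integrator."""

    def __init__(self, params: IrmaParameters, initial_state=None,
                 dt: float = 0.5):
        self.params = params.with_tau(0.0)
        self.dt = dt
        if initial_state is None:
            initial_state = steady_state(self.params, 0)
        self.state = np.asarray(initial_state, dtype=float)

    def advance(self, signal: BinaryInputSignal, t0: float, t1: float) -> float:
        traj = simulate_irma(self.params, signal, t0, t1,
                             initial_state=self.state, dt=self.dt)
        self.state = traj.states[-1]
        return float(traj.output[-1])

    @property
    def output(self) -> float:
        return float(self.state[0])


class Gal1InternalModel:
    """Delay-free GAL1 copy (exact piecewise-exponential update)."""

    def __init__(self, params: Gal1Parameters, y0: float = 0.0,
                 dt: float = 0.5):
        self.params = Gal1Parameters(vmax=params.vmax, d=params.d, lag=0.0)
        self.dt = dt
        self.y = float(y0)

    def advance(self, signal: BinaryInputSignal, t0: float, t1: float) -> float:
        traj = simulate_gal1(self.params, signal, t0, t1, dt=self.dt, y0=self.y)
        self.y = float(traj.output[-1])
        return self.y

    @property
    def output(self) -> float:
        return self.y


# --------------------------------------------------------------------------
# predictor block
# --------------------------------------------------------------------------

@dataclass
class PredictorConfig:
    """Settings for the Smith-predictor block.

    ``model`` is the delay-free internal model; ``tau_m`` the modelled
    delay used to produce the delayed replica of the model output;
    ``filter_time_constant`` the first-order mismatch filter (default
    3x the 5-min sampling interval); ``calibration`` the model-to-
    fluorescence affine map.
    """

    model: InternalModel
    tau_m: float
    filter_time_constant: float = 15.0
    calibration: AffineCalibration | None = None

    def __post_init__(self) -> None:
        if not (self.tau_m >= 0):
            raise ValueError("tau_m must be >= 0")
        if not (self.filter_time_constant >= 0):
            raise ValueError("filter time constant must be >= 0")


@dataclass
class PredictorState:
    """Stored model-output history (for the delayed replica) and the
    mismatch filter state."""

    history_t: deque = field(default_factory=deque)
    history_y: deque = field(default_factory=deque)
    filter_state: LowPassFilterState | None = None
    t: float = 0.0


def init_predictor(cfg: PredictorConfig, t0: float = 0.0) -> PredictorState:
    if cfg.calibration is None:
        raise ValueError("predictor calibration map is uninitialized; run "
                         "the calibration phase or set it explicitly")
    st = PredictorState(filter_state=LowPassFilterState(
        time_constant=cfg.filter_time_constant), t=t0)
    y0 = cfg.calibration.to_fluo(cfg.model.output)
    st.history_t.append(t0)
    st.history_y.append(y0)
    return st


def _delayed_output(st: PredictorState, t_query: float) -> float:
    """Model output at ``t_query`` from the stored ring buffer (linear
    interpolation; clamped at the ends)."""
    ts, ys = st.history_t, st.history_y
    if t_query <= ts[0]:
        return ys[0]
    if t_query >= ts[-1]:
        return ys[-1]
    arr_t = np.asarray(ts)
    i = int(np.searchsorted(arr_t, t_query, side="right")) - 1
    t_lo, t_hi = ts[i], ts[i + 1]
    w = (t_query - t_lo) / (t_hi - t_lo)
    return (1.0 - w) * ys[i] + w * ys[i + 1]


def predictor_step(cfg: PredictorConfig, st: PredictorState,
                   u_applied: BinaryInputSignal, y_measured: float,
                   dt: float) -> tuple[float, PredictorState]:
    """Advance the predictor one sampling interval.

    Runs the delay-free model forward under the realized input window,
    forms the delayed replica from the stored output history, filters
    the plant/model mismatch and returns the corrected feedback signal
    (fluorescence units) together with the updated state.
    """
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if not math.isfinite(y_measured):
        raise ValueError("y_measured must be finite")
    if cfg.calibration is None:
        raise ValueError("predictor calibration map is uninitialized")

    t_new = st.t + dt
    y_model = cfg.calibration.to_fluo(
        cfg.model.advance(u_applied, st.t, t_new))
    st.history_t.append(t_new)
    st.history_y.append(y_model)
    # ring buffer needs to span tau_m plus one interpolation bracket
    horizon = t_new - (cfg.tau_m + 2 * dt)
    while len(st.history_t) > 2 and st.history_t[1] <= horizon:
        st.history_t.popleft()
        st.history_y.popleft()

    y_delayed = _delayed_output(st, t_new - cfg.tau_m)
    mismatch = y_measured - y_delayed
    correction, fstate = lowpass_step(st.filter_state, mismatch, dt)
    st.filter_state = fstate
    st.t = t_new
    return y_model + correction, st


def predictor_internals(cfg: PredictorConfig, st: PredictorState
                        ) -> tuple[float, float, float]:
    """(undelayed model output, delayed replica, current correction) in
    fluorescence units, for per-step trace logging."""
    y_model = st.history_y[-1]
    y_delayed = _delayed_output(st, st.t - cfg.tau_m)
    corr = st.filter_state.value if st.filter_state.initialized else 0.0
    return y_model, y_delayed, corr
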