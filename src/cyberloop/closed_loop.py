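"""Experiment driver: the finite-state control cycle, reference
generation, calibration, and post-hoc tracking metrics.

Each experiment mirrors the automaton running on the control computer:
an initial calibration phase establishes the minimal (glucose) and
maximal (galactose) fluorescence of the population, then the loop cycles
every sampling interval Ts (5 min, one microscopy frame): compute the
PI-PWM input from the current error, update the model prediction, apply
the sugar pulse train to the plant, form the delayed predicted output,
ingest the new measurement and recompute the error.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from cyberloop.controller import (
    LowPassFilterState,
    PIConfig,
    PIState,
    PWMConfig,
    lowpass_step,
    pi_step,
    pwm_encode,
)
from cyberloop.gene_models import (
    BinaryInputSignal,
    Gal1Parameters,
    IrmaIntegrator,
    IrmaParameters,
    constant_history,
    simulate_gal1,
    steady_state,
)
from cyberloop.predictor import (
    PredictorConfig,
    calibrate_units,
    init_predictor,
    predictor_internals,
    predictor_step,
)

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# plants
# --------------------------------------------------------------------------

class Plant(Protocol):
    """Anything the loop can actuate and measure."""

    t: float

    def apply(self, signal: BinaryInputSignal, t1: float) -> None:
        """Advance the plant to ``t1`` under the realized input."""
        ...

    def measure(self) -> float:
        """Current measured output (fluorescence units)."""
        ...


class Gal1Plant:
    """Deterministic GAL1-promoter plant.

    ``output_delay`` models a pure transport delay on the measurement
    (the sensor sees ``y(t - delay)``), the setting in which the
    classical Smith-predictor equivalence is exact.
    """

    def __init__(self, params: Gal1Parameters, y0: float = 0.0,
                 output_delay: float = 0.0, dt: float = 0.5,
                 measurement_noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None):
        if output_delay < 0:
            raise ValueError("output_delay must be >= 0")
        self.params = params
        self.dt = dt
        self.t = 0.0
        self.output_delay = output_delay
        self.noise_sd = measurement_noise_sd
        self.rng = rng or np.random.default_rng(0)
        self._hist_t = [0.0]
        self._hist_y = [float(y0)]
        # rolling input record so the activation lag can look across
        # sampling-window boundaries (glucose assumed before t = 0)
        self._segments: list[tuple[float, int]] = [(-max(self.params.lag, 1.0)
                                                    - 1.0, 0)]

    @property
    def y(self) -> float:
        return self._hist_y[-1]

    def apply(self, signal: BinaryInputSignal, t1: float) -> None:
        self._segments.extend(
            (float(ts), int(lv))
            for ts, lv in zip(np.atleast_1d(signal.times),
                              np.atleast_1d(signal.levels))
            if self.t - 1e-9 <= ts < t1)
        keep_from = self.t - self.params.lag - 1.0
        while len(self._segments) > 1 and self._segments[1][0] <= keep_from:
            self._segments.pop(0)
        full = BinaryInputSignal.from_segments(self._segments)
        traj = simulate_gal1(self.params, full, self.t, t1, dt=self.dt,
                             y0=self.y)
        self._hist_t.extend(traj.time[1:].tolist())
        self._hist_y.extend(traj.output[1:].tolist())
        self.t = t1
        # keep just enough history to serve the delayed measurement
        keep_from = self.t - (self.output_delay + 2 * self.dt)
        while len(self._hist_t) > 2 and self._hist_t[1] <= keep_from:
            self._hist_t.pop(0)
            self._hist_y.pop(0)

    def measure(self) -> float:
        tq = self.t - self.output_delay
        y = float(np.interp(tq, self._hist_t, self._hist_y))
        if self.noise_sd > 0:
            y += float(self.rng.normal(0.0, self.noise_sd))
        return y


class IrmaPlant:
    """Deterministic IRMA plant (single-cell DDE, Cbf1-Gfp output)."""

    def __init__(self, params: IrmaParameters, initial_state=None,
                 dt: float = 0.5, measurement_noise_sd: float = 0.0,
                 rng: np.random.Generator | None = None):
        if initial_state is None:
            initial_state = steady_state(params, 0)
        self.params = params
        self._stepper = IrmaIntegrator(params, t0=0.0,
                                       history=constant_history(initial_state),
                                       dt=dt)
        self.noise_sd = measurement_noise_sd
        self.rng = rng or np.random.default_rng(0)

    @property
    def t(self) -> float:
        return self._stepper.t

    @property
    def state(self) -> np.ndarray:
        return self._stepper.state

    def apply(self, signal: BinaryInputSignal, t1: float) -> None:
        self._stepper.advance(signal, t1)

    def measure(self) -> float:
        y = self._stepper.output
        if self.noise_sd > 0:
            y += float(self.rng.normal(0.0, self.noise_sd))
        return y


# --------------------------------------------------------------------------
# reference signals
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReferenceSpec:
    """Desired-output specification, as a fraction of the calibrated
    fluorescence range.

    * ``constant`` — hold ``f_low`` of the range;
    * ``triangular`` — oscillate between ``f_low`` and ``f_high`` with
      the given ``period`` (peak at half a period after control start);
    * ``ramp_down`` — rise linearly to ``f_high`` over ``rise_duration``
      then decrease with ``slope`` (fractions of range per min), floored
      at ``f_low``.
    """

    kind: str = "constant"
    f_low: float = 0.5
    f_high: float = 0.8
    period: float = 800.0
    rise_duration: float = 200.0
    slope: float = 5e-4
    t_start: float = 0.0     # control-action start time, min

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "triangular", "ramp_down"):
            raise ValueError(f"unknown reference kind {self.kind!r}")
        for name in ("f_low", "f_high"):
            f = getattr(self, name)
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.kind != "constant" and not (self.period > 0):
            raise ValueError("period must be positive")


def generate_reference(spec: ReferenceSpec, y_max: float, y_min: float,
                       t: float | np.ndarray) -> float | np.ndarray:
    """Reference value r(t) in fluorescence units.

    ``t`` is absolute experiment time; querying before the control start
    (the calibration regime) is an error.
    """
    if not (y_max > y_min):
        raise ValueError("y_max must exceed y_min")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < spec.t_start):
        raise ValueError("reference is undefined before the control start "
                         "(calibration regime)")
    rng_ = y_max - y_min
    rel = t_arr - spec.t_start
    if spec.kind == "constant":
        r = np.full_like(rel, y_min + spec.f_low * rng_)
    elif spec.kind == "triangular":
        phase = np.mod(rel, spec.period) / spec.period
        tri = np.where(phase <= 0.5, 2.0 * phase, 2.0 * (1.0 - phase))
        frac = spec.f_low + (spec.f_high - spec.f_low) * tri
        r = y_min + frac * rng_
    else:  # ramp_down
        peak = y_min + spec.f_high * rng_
        floor = y_min + spec.f_low * rng_
        rise = y_min + (peak - y_min) * np.clip(rel / spec.rise_duration, 0, 1)
        down = peak - spec.slope * rng_ * (rel - spec.rise_duration)
        r = np.where(rel <= spec.rise_duration, rise, np.maximum(down, floor))
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(r)
    return r


# --------------------------------------------------------------------------
# calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationProtocol:
    """Open-loop phases establishing the fluorescence range.

    ``phases`` is a list of (input level, duration in min); the max/min
    estimates are the means of the last ``last_k`` samples of the
    galactose / glucose phases respectively (30 min at 5-min sampling).
    """

    phases: tuple[tuple[int, float], ...] = ((1, 240.0), (0, 240.0))
    last_k: int = 6

    def __post_init__(self) -> None:
        for level, dur in self.phases:
            if level not in (0, 1):
                raise ValueError("phase level must be 0 or 1")
            if not (dur > 0):
                raise ValueError("phase durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.phases))


# --------------------------------------------------------------------------
# records and metrics
# --------------------------------------------------------------------------

@dataclass
class ControlRecord:
    """Synchronized per-sample series of one control experiment."""

    time: np.ndarray          # sampling instants (window starts), min
    r: np.ndarray             # reference
    y: np.ndarray             # measured output
    y_fb: np.ndarray          # feedback signal seen by the comparator
    e: np.ndarray             # error used by the PI at that instant
    pi_level: np.ndarray      # PI output on the sawtooth scale
    duty: np.ndarray          # realized galactose fraction of each window
    input_signal: BinaryInputSignal | None   # realized u on the quantum grid
    y_min_cal: float
    y_max_cal: float
    calibration_time: np.ndarray = field(default_factory=lambda: np.empty(0))
    calibration_y: np.ndarray = field(default_factory=lambda: np.empty(0))
    predictor_trace: dict[str, np.ndarray] | None = None
    snapshots: list | None = None      # PopulationSnapshot list, if any
    truncated: bool = False
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.time.size
        for name in ("r", "y", "y_fb", "e", "pi_level", "duty"):
            if getattr(self, name).size != n:
                raise ValueError(f"series {name!r} length mismatch")

    def to_csv(self, path: str | Path) -> None:
        """CSV with header ``time_min,r,y,y_fb,e,pi_level,u`` (u is the
        realized galactose fraction of the sampling window)."""
        data = np.column_stack([self.time, self.r, self.y, self.y_fb,
                                self.e, self.pi_level, self.duty])
        np.savetxt(path, data, delimiter=",",
                   header="time_min,r,y,y_fb,e,pi_level,u", comments="",
                   fmt="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, y_min_cal: float = 0.0,
                 y_max_cal: float = 1.0) -> "ControlRecord":
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(time=data[:, 0], r=data[:, 1], y=data[:, 2],
                   y_fb=data[:, 3], e=data[:, 4], pi_level=data[:, 5],
                   duty=data[:, 6], input_signal=None,
                   y_min_cal=y_min_cal, y_max_cal=y_max_cal)


@dataclass(frozen=True)
class Metrics:
    """Tracking-quality summary over the control-active interval."""

    nrmse: float
    error_mean: float
    error_var: float
    error_cv: float
    max_abs_error_settled: float
    mean_abs_error_settled: float
    settling_time: float | None
    n_samples: int

    def to_json(self, path: str | Path) -> None:
        payload = {k: (None if (isinstance(v, float) and not math.isfinite(v))
                       else v)
                   for k, v in self.__dict__.items()}
        Path(path).write_text(json.dumps(payload, indent=2))


def compute_metrics(rec: ControlRecord, settle_fraction: float = 0.1,
                    ) -> Metrics:
    """Summarize tracking quality.

    NRMSE is the RMS of ``y - r`` normalized by the calibrated range.
    "Settled" statistics start at the first sample whose deviation drops
    below ``settle_fraction`` of the range (the whole record if that
    never happens).
    """
    if rec.time.size == 0:
        raise ValueError("empty control record")
    dev = rec.y - rec.r
    rng_ = rec.y_max_cal - rec.y_min_cal
    if not (rng_ > 0):
        raise ValueError("calibration range must be positive")
    nrmse = float(np.sqrt(np.mean(dev ** 2)) / rng_)
    mean = float(np.mean(dev))
    var = float(np.var(dev))
    cv = float(np.sqrt(var) / abs(mean)) if mean != 0 else math.inf
    inside = np.nonzero(np.abs(dev) <= settle_fraction * rng_)[0]
    if inside.size:
        i0 = int(inside[0])
        settling_time = float(rec.time[i0] - rec.time[0])
    else:
        i0 = 0
        settling_time = None
    tail = np.abs(dev[i0:])
    return Metrics(nrmse=nrmse, error_mean=mean, error_var=var, error_cv=cv,
                   max_abs_error_settled=float(np.max(tail)),
                   mean_abs_error_settled=float(np.mean(tail)),
                   settling_time=settling_time, n_samples=int(rec.time.size))


# --------------------------------------------------------------------------
# the control cycle
# --------------------------------------------------------------------------

def _run_calibration(plant: Plant, calib: CalibrationProtocol, Ts: float,
                     ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Apply the open-loop calibration phases, sampling every Ts.

    Returns (times, measurements, y_min, y_max)."""
    times, ys = [], []
    y_by_level: dict[int, list[float]] = {0: [], 1: []}
    t = plant.t
    for level, duration in calib.phases:
        n = int(round(duration / Ts))
        signal = BinaryInputSignal.constant(level, t)
        for _ in range(n):
            plant.apply(signal, t + Ts)
            t = t + Ts
            y = plant.measure()
            times.append(t)
            ys.append(y)
            y_by_level[level].append(y)
    k = calib.last_k
    if not y_by_level[1] or not y_by_level[0]:
        raise ValueError("calibration needs at least one galactose and one "
                         "glucose phase")
    y_max = float(np.mean(y_by_level[1][-k:]))
    y_min = float(np.mean(y_by_level[0][-k:]))
    if not (y_max > y_min):
        raise ValueError("calibration found y_max <= y_min; check phases")
    return np.asarray(times), np.asarray(ys), y_min, y_max


def run_fsa_loop(plant: Plant, pi_cfg: PIConfig, pwm_cfg: PWMConfig,
                 refspec: ReferenceSpec, duration: float,
                 predictor_cfg: PredictorConfig | None = None,
                 calib: CalibrationProtocol | None = CalibrationProtocol(),
                 y_range: tuple[float, float] | None = None,
                 Ts: float = 5.0,
                 feedback_filter_tc: float = 0.0,
                 model_range: tuple[float, float] | None = None,
                 ) -> ControlRecord:
    """Run one closed-loop experiment and return its ControlRecord.

    ``duration`` is the length of the control-active interval (min);
    the calibration protocol runs before it (pass ``calib=None`` with an
    explicit ``y_range=(y_min, y_max)`` to skip calibration).  Without a
    predictor the feedback is the (optionally low-pass filtered, time
    constant ``feedback_filter_tc``) measurement.  With a predictor
    whose calibration map is unset, the map is fitted from the
    calibrated fluorescence range and ``model_range`` (defaults to the
    internal model's glucose/galactose steady-state outputs).

    A plant failure mid-run truncates the record and flags it rather
    than discarding it.
    """
    n_windows = int(round(duration / Ts))
    if n_windows <= 0:
        raise ValueError("duration must cover at least one sampling window")

    if calib is not None:
        logger.info("state 0: calibration (%s)", calib.phases)
        cal_t, cal_y, y_min, y_max = _run_calibration(plant, calib, Ts)
    else:
        if y_range is None:
            raise ValueError("either a calibration protocol or an explicit "
                             "y_range is required")
        y_min, y_max = y_range
        cal_t = np.empty(0)
        cal_y = np.empty(0)
    t_start = plant.t
    logger.info("calibration done: y_min=%.4g y_max=%.4g; control starts "
                "at t=%.1f min for %.0f min", y_min, y_max, t_start, duration)
    refspec = ReferenceSpec(**{**refspec.__dict__, "t_start": t_start})

    pred_state = None
    if predictor_cfg is not None:
        if predictor_cfg.calibration is None:
            if model_range is None:
                model = predictor_cfg.model
                if hasattr(model, "params") and isinstance(
                        model.params, IrmaParameters):
                    lo = steady_state(model.params, 0)[0]
                    hi = steady_state(model.params, 1)[0]
                elif hasattr(model, "params"):
                    lo, hi = 0.0, model.params.y_max
                else:
                    raise ValueError("cannot infer model range; pass "
                                     "model_range=(lo, hi)")
            else:
                lo, hi = model_range
            predictor_cfg.calibration = calibrate_units(y_min, y_max, lo, hi)
        pred_state = init_predictor(predictor_cfg, t0=t_start)

    filt = LowPassFilterState(time_constant=feedback_filter_tc)
    pist = PIState()
    y0 = plant.measure() if calib is None else float(cal_y[-1])
    y_fb, filt = lowpass_step(filt, y0, Ts) if predictor_cfg is None \
        else (float(predictor_cfg.calibration.to_fluo(
            predictor_cfg.model.output)), filt)

    cols: dict[str, list[float]] = {k: [] for k in
                                    ("t", "r", "y", "y_fb", "e", "lvl", "duty")}
    trace: dict[str, list[float]] = {"y_model": [], "y_model_delayed": [],
                                     "correction": []}
    seg: list[tuple[float, int]] = []
    truncated = False
    snapshots = []
    for k in range(n_windows):
        t = t_start + k * Ts
        r_k = generate_reference(refspec, y_max, y_min, t)
        e_k = r_k - y_fb
        level, pist = pi_step(pi_cfg, pist, e_k)
        window = pwm_encode(level, pwm_cfg, t, Ts)
        seg.extend(zip(window.times.tolist(), window.levels.tolist()))
        try:
            plant.apply(window, t + Ts)
            y_meas = plant.measure()
        except Exception:   # plant failure: truncate, keep the record
            truncated = True
            break
        if predictor_cfg is not None:
            y_fb, pred_state = predictor_step(predictor_cfg, pred_state,
                                              window, y_meas, Ts)
            ym, yd, corr = predictor_internals(predictor_cfg, pred_state)
            trace["y_model"].append(ym)
            trace["y_model_delayed"].append(yd)
            trace["correction"].append(corr)
        else:
            y_fb, filt = lowpass_step(filt, y_meas, Ts)
        if hasattr(plant, "snapshot"):
            snapshots.append(plant.snapshot())
        cols["t"].append(t)
        cols["r"].append(r_k)
        cols["y"].append(y_meas)
        cols["y_fb"].append(y_fb)
        cols["e"].append(e_k)
        cols["lvl"].append(level)
        cols["duty"].append(float(np.mean(window.levels)))
        logger.debug("cycle t=%.0f: states 1-5 done (r=%.4g y=%.4g e=%.4g "
                     "pi=%.3f duty=%.2f)", t, r_k, y_meas, e_k, level,
                     cols["duty"][-1])

    logger.info("run complete: %d cycles%s", len(cols["t"]),
                " (truncated)" if truncated else "")
    realized = BinaryInputSignal.from_segments(seg) if seg else None
    return ControlRecord(
        time=np.asarray(cols["t"]), r=np.asarray(cols["r"]),
        y=np.asarray(cols["y"]), y_fb=np.asarray(cols["y_fb"]),
        e=np.asarray(cols["e"]), pi_level=np.asarray(cols["lvl"]),
        duty=np.asarray(cols["duty"]), input_signal=realized,
        y_min_cal=y_min, y_max_cal=y_max,
        calibration_time=cal_t, calibration_y=cal_y,
        predictor_trace={k: np.asarray(v) for k, v in trace.items()}
        if predictor_cfg is not None else None,
        snapshots=snapshots or None,
        truncated=truncated,
        metadata={"Ts": Ts, "duration": duration, "kind": refspec.kind},
    )


# --------------------------------------------------------------------------
# negative controls
# --------------------------------------------------------------------------

def random_input_control(plant: Plant, pi_cfg: PIConfig, pwm_cfg: PWMConfig,
                         refspec: ReferenceSpec, duration: float, seed: int,
                         calib: CalibrationProtocol | None = CalibrationProtocol(),
                         y_range: tuple[float, float] | None = None,
                         Ts: float = 5.0,
                         reach_fraction: float = 0.05) -> ControlRecord:
    """Negative-control run: closed-loop until the output first comes
    within ``reach_fraction`` of the set-point, then the input switches
    randomly (Bernoulli(0.5) per sampling window) for the remainder.
    """
    n_windows = int(round(duration / Ts))
    if n_windows <= 0:
        raise ValueError("zero-duration negative control")
    rng = np.random.default_rng(seed)
    if calib is not None:
        cal_t, cal_y, y_min, y_max = _run_calibration(plant, calib, Ts)
    else:
        if y_range is None:
            raise ValueError("need calibration or an explicit y_range")
        y_min, y_max = y_range
        cal_t = np.empty(0)
        cal_y = np.empty(0)
    t_start = plant.t
    refspec = ReferenceSpec(**{**refspec.__dict__, "t_start": t_start})
    rng_range = y_max - y_min

    pist = PIState()
    y_fb = float(cal_y[-1]) if calib is not None else plant.measure()
    reached = False
    cols: dict[str, list[float]] = {k: [] for k in
                                    ("t", "r", "y", "y_fb", "e", "lvl", "duty")}
    seg: list[tuple[float, int]] = []
    for k in range(n_windows):
        t = t_start + k * Ts
        r_k = generate_reference(refspec, y_max, y_min, t)
        e_k = r_k - y_fb
        if not reached and abs(e_k) <= reach_fraction * rng_range:
            reached = True
        if reached:
            level = float(rng.integers(0, 2))
            window = BinaryInputSignal.constant(int(level), t)
        else:
            level, pist = pi_step(pi_cfg, pist, e_k)
            window = pwm_encode(level, pwm_cfg, t, Ts)
        seg.extend(zip(np.atleast_1d(window.times).tolist(),
                       np.atleast_1d(window.levels).tolist()))
        plant.apply(window, t + Ts)
        y_meas = plant.measure()
        y_fb = y_meas
        cols["t"].append(t)
        cols["r"].append(r_k)
        cols["y"].append(y_meas)
        cols["y_fb"].append(y_fb)
        cols["e"].append(e_k)
        cols["lvl"].append(level)
        cols["duty"].append(float(np.mean(window.levels)))
    return ControlRecord(
        time=np.asarray(cols["t"]), r=np.asarray(cols["r"]),
        y=np.asarray(cols["y"]), y_fb=np.asarray(cols["y_fb"]),
        e=np.asarray(cols["e"]), pi_level=np.asarray(cols["lvl"]),
        duty=np.asarray(cols["duty"]),
        input_signal=BinaryInputSignal.from_segments(seg),
        y_min_cal=y_min, y_max_cal=y_max,
        calibration_time=cal_t, calibration_y=cal_y,
        metadata={"Ts": Ts, "duration": duration, "seed": seed,
                  "negative_control": "random_input"},
    )


def constant_input_control(plant: Plant, level: int,
                           refspec: ReferenceSpec, duration: float,
                           calib: CalibrationProtocol | None = CalibrationProtocol(),
                           y_range: tuple[float, float] | None = None,
                           Ts: float = 5.0) -> ControlRecord:
    """Negative-control run with a sustained input (e.g. constant
    galactose), measured against the same reference."""
    n_windows = int(round(duration / Ts))
    if n_windows <= 0:
        raise ValueError("zero-duration negative control")
    if calib is not None:
        cal_t, cal_y, y_min, y_max = _run_calibration(plant, calib, Ts)
    else:
        if y_range is None:
            raise ValueError("need calibration or an explicit y_range")
        y_min, y_max = y_range
        cal_t = np.empty(0)
        cal_y = np.empty(0)
    t_start = plant.t
    refspec = ReferenceSpec(**{**refspec.__dict__, "t_start": t_start})
    signal = BinaryInputSignal.constant(level, t_start)
    cols: dict[str, list[float]] = {k: [] for k in ("t", "r", "y")}
    for k in range(n_windows):
        t = t_start + k * Ts
        plant.apply(signal, t + Ts)
        cols["t"].append(t)
        cols["r"].append(generate_reference(refspec, y_max, y_min, t))
        cols["y"].append(plant.measure())
    t_arr = np.asarray(cols["t"])
    y_arr = np.asarray(cols["y"])
    r_arr = np.asarray(cols["r"])
    zeros = np.zeros_like(t_arr)
    return ControlRecord(
        time=t_arr, r=r_arr, y=y_arr, y_fb=y_arr, e=r_arr - y_arr,
        pi_level=zeros + level, duty=zeros + level, input_signal=signal,
        y_min_cal=y_min, y_max_cal=y_max,
        calibration_time=cal_t, calibration_y=cal_y,
        metadata={"Ts": Ts, "duration": duration,
                  "negative_control": f"constant_u{level}"},
    )
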