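"""Deterministic single-cell models of the controlled gene systems.

Two plants are modelled:

* the endogenous *GAL1* promoter — a one-state linear production/decay
  model whose production is gated by the sugar input (galactose on,
  glucose off);
* IRMA, a five-gene synthetic yeast network (CBF1, GAL4, SWI5, ASH1,
  GAL80) with a transcriptional positive feedback loop
  (CBF1 -> GAL4 -> SWI5 -> CBF1), a negative loop via ASH1, and a
  protein–protein inhibition of Gal4p by Gal80p.  Galactose enables
  GAL10-promoter-driven SWI5 transcription; glucose disables it, so the
  network is a hybrid system switching between two vector fields.
  HO-promoter-driven CBF1 production lags the rest of the network by a
  transcriptional delay ``tau`` (sequential recruitment of
  chromatin-modifying complexes), which makes the model a delay
  differential equation (DDE).

The integrator is a fixed-step RK4 with a ring buffer of past states for
the delayed term (method of steps with linear interpolation inside the
buffer).  Fixed step keeps trajectories bit-reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

#: order of the IRMA state vector
IRMA_SPECIES = ("cbf1", "gal4", "swi5", "ash1", "gal80")

#: index of the measured output (Cbf1-Gfp) in the state vector
OUTPUT_INDEX = 0


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IrmaParameters:
    """Kinetic parameters of the five-gene network.

    Rates are in concentration/min (model units), thresholds in
    concentration, Hill coefficients dimensionless, degradation/dilution
    rates in 1/min, and ``tau`` (min) is the transcriptional delay on
    HO-promoter-driven CBF1 production.
    """

    # basal transcription rates
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    alpha5: float
    # maximal promoter-driven production rates
    v1: float
    v2: float
    v3: float
    v4: float
    v5: float
    # activation/repression thresholds
    k1: float   # Swi5 -> HO (CBF1) activation
    k2: float   # Ash1 -| HO (CBF1) repression
    k3: float   # Cbf1 -> GAL4 activation
    k4: float   # Gal4 -> GAL10 (SWI5) activation
    k5: float   # Swi5 -> ASH1 activation
    k6: float   # Swi5 -> GAL80 activation
    # Hill coefficients
    h1: float   # Swi5 activation terms
    h2: float   # Ash1 repression
    h3: float   # Cbf1 activation of GAL4
    h4: float   # Gal4 activation of GAL10
    # degradation + dilution
    d1: float
    d2: float
    d3: float
    d4: float
    d5: float
    # Gal80p–Gal4p protein–protein inhibition constant
    gamma: float
    # transcriptional delay on CBF1 production (min)
    tau: float = 0.0

    def __post_init__(self) -> None:
        for name in ("alpha1", "alpha2", "alpha3", "alpha4", "alpha5",
                     "v1", "v2", "v3", "v4", "v5",
                     "k1", "k2", "k3", "k4", "k5", "k6",
                     "h1", "h2", "h3", "h4",
                     "d1", "d2", "d3", "d4", "d5", "gamma"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0.0:
                raise ValueError(f"IRMA parameter {name!r} must be strictly "
                                 f"positive and finite, got {value!r}")
        if not math.isfinite(self.tau) or self.tau < 0.0:
            raise ValueError(f"tau must be finite and >= 0, got {self.tau!r}")

    def with_tau(self, tau: float) -> "IrmaParameters":
        """Copy of the parameter set with a different delay."""
        fields = {k: getattr(self, k) for k in self.__dataclass_fields__}
        fields["tau"] = tau
        return IrmaParameters(**fields)


@dataclass(frozen=True)
class Gal1Parameters:
    """One-state GAL1-promoter model: dy/dt = u(t - lag) * vmax - d * y."""

    vmax: float          # maximal production rate, fluorescence-units/min
    d: float             # degradation + dilution, 1/min
    lag: float = 0.0     # optional activation lag, min

    def __post_init__(self) -> None:
        if not (math.isfinite(self.vmax) and self.vmax > 0):
            raise ValueError(f"vmax must be positive, got {self.vmax!r}")
        if not (math.isfinite(self.d) and self.d > 0):
            raise ValueError(f"d must be positive, got {self.d!r}")
        if not (math.isfinite(self.lag) and self.lag >= 0):
            raise ValueError(f"lag must be >= 0, got {self.lag!r}")

    @property
    def y_max(self) -> float:
        """Steady-state output under sustained galactose."""
        return self.vmax / self.d


def load_parameters(path: str | Path) -> dict[str, float]:
    """Read a flat ``key = value`` plain-text parameter file.

    Blank lines and lines starting with ``#`` are ignored.
    """
    values: dict[str, float] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed parameter line: {raw!r}")
        key, _, val = line.partition("=")
        values[key.strip()] = float(val.strip())
    return values


def _bundled(name: str) -> Path:
    return Path(str(resources.files("cyberloop").joinpath("data", name)))


def default_irma_parameters(tau: float | None = None) -> IrmaParameters:
    """IRMA parameter set shipped with the package (editable flat file)."""
    values = load_parameters(_bundled("irma.params"))
    if tau is not None:
        values["tau"] = tau
    return IrmaParameters(**values)


def default_gal1_parameters() -> Gal1Parameters:
    values = load_parameters(_bundled("gal1.params"))
    return Gal1Parameters(**values)


# --------------------------------------------------------------------------
# input signal and trajectory containers
# --------------------------------------------------------------------------

class BinaryInputSignal:
    """Piecewise-constant binary sugar signal u(t).

    ``levels[i]`` holds on ``[times[i], times[i+1])``; ``level_at`` is
    right-continuous, with 1 = galactose and 0 = glucose.  Times before
    ``times[0]`` evaluate to ``levels[0]``.
    """

    def __init__(self, times: Sequence[float], levels: Sequence[int]):
        times = np.asarray(times, dtype=float)
        levels = np.asarray(levels, dtype=int)
        if times.ndim != 1 or times.shape != levels.shape or times.size == 0:
            raise ValueError("times and levels must be equal-length 1-D "
                             "non-empty sequences")
        if np.any(np.diff(times) <= 0):
            raise ValueError("switch times must be strictly increasing")
        if not np.all(np.isin(levels, (0, 1))):
            raise ValueError("levels must be 0 (glucose) or 1 (galactose)")
        self.times = times
        self.levels = levels

    @classmethod
    def constant(cls, level: int, t_start: float = 0.0) -> "BinaryInputSignal":
        return cls([t_start], [level])

    @classmethod
    def from_segments(cls, segments: Sequence[tuple[float, int]]) -> "BinaryInputSignal":
        """Build from (start_time, level) pairs, merging repeated levels."""
        times, levels = [], []
        for t, lv in segments:
            if levels and levels[-1] == lv:
                continue
            times.append(t)
            levels.append(lv)
        return cls(times, levels)

    def level_at(self, t: float | np.ndarray) -> int | np.ndarray:
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, self.levels.size - 1)
        out = self.levels[idx]
        if np.isscalar(t) or np.ndim(t) == 0:
            return int(out)
        return out

    def shifted(self, lag: float) -> "BinaryInputSignal":
        """The signal delayed by ``lag`` minutes (u'(t) = u(t - lag))."""
        return BinaryInputSignal(self.times + lag, self.levels)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"BinaryInputSignal(times={self.times!r}, levels={self.levels!r})"


@dataclass
class Trajectory:
    """Simulated states on a uniform time grid, with the applied input."""

    time: np.ndarray      # (n,), min, uniform step
    states: np.ndarray    # (n, m)
    u: np.ndarray         # (n,), input level at each grid point

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        self.u = np.asarray(self.u)
        n = self.time.size
        if self.states.shape[0] != n or self.u.size != n:
            raise ValueError("time, states and u must have the same length")
        steps = np.diff(self.time)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("time grid must be uniform")
        if np.any(self.states < 0):
            raise ValueError("state rows must be non-negative")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if self.time.size > 1 else 0.0

    @property
    def output(self) -> np.ndarray:
        """Measured species (Cbf1-Gfp for IRMA, Gal1-Gfp for GAL1)."""
        return self.states[:, OUTPUT_INDEX]

    def to_csv(self, path: str | Path) -> None:
        """CSV with header ``time_min,u,cbf1,gal4,swi5,ash1,gal80`` (IRMA)
        or ``time_min,u,y`` (one-state models)."""
        if self.states.shape[1] == len(IRMA_SPECIES):
            names = ",".join(IRMA_SPECIES)
        else:
            names = ",".join(f"y{i}" for i in range(self.states.shape[1]))
            if self.states.shape[1] == 1:
                names = "y"
        data = np.column_stack([self.time, self.u, self.states])
        np.savetxt(path, data, delimiter=",", header=f"time_min,u,{names}",
                   comments="", fmt="%.10g")


#: history function type: maps t <= t0 to a non-negative state vector
HistoryFunction = Callable[[float], np.ndarray]


def constant_history(state: Sequence[float]) -> HistoryFunction:
    """History equal to a fixed state for all t <= t0 (the default:
    cells are assumed at steady growth before the experiment)."""
    arr = np.asarray(state, dtype=float)

    def history(_t: float) -> np.ndarray:
        return arr

    return history


# --------------------------------------------------------------------------
# IRMA vector field
# --------------------------------------------------------------------------

def _hill_act(x: float, k: float, h: float) -> float:
    xh = x ** h
    return xh / (k ** h + xh)


def irma_vector_field(state: np.ndarray, delayed_state: np.ndarray,
                      u: int, p: IrmaParameters) -> np.ndarray:
    """Right-hand side of the hybrid IRMA model.

    The ``u = 1`` (galactose) field enables GAL10-promoter-driven SWI5
    production; the ``u = 0`` (glucose) field disables it.  CBF1
    production reads Swi5 and Ash1 from ``delayed_state`` (state at
    ``t - tau``).
    """
    state = np.asarray(state, dtype=float)
    delayed_state = np.asarray(delayed_state, dtype=float)
    if state.shape != (5,) or delayed_state.shape != (5,):
        raise ValueError("IRMA state vectors have 5 components")
    if np.any(state < 0) or np.any(delayed_state < 0):
        raise ValueError("negative concentrations are not meaningful")
    if u not in (0, 1):
        raise ValueError(f"u must be 0 or 1, got {u!r}")
    x1, x2, x3, x5 = state[0], state[1], state[2], state[4]
    x3d, x4d = delayed_state[2], delayed_state[3]

    # HO promoter: activated by (delayed) Swi5, repressed by (delayed) Ash1
    ho = _hill_act(x3d, p.k1, p.h1) / (1.0 + (x4d / p.k2) ** p.h2)
    # GAL10 promoter: activated by Gal4, Gal4 sequestered by Gal80;
    # transcription only proceeds in galactose (u = 1)
    gal10 = _hill_act(x2, p.k4, p.h4) / (1.0 + x5 / p.gamma)

    return np.array([
        p.alpha1 + p.v1 * ho - p.d1 * x1,
        p.alpha2 + p.v2 * _hill_act(x1, p.k3, p.h3) - p.d2 * x2,
        p.alpha3 + u * p.v3 * gal10 - p.d3 * x3,
        p.alpha4 + p.v4 * _hill_act(x3, p.k5, p.h1) - p.d4 * state[3],
        p.alpha5 + p.v5 * _hill_act(x3, p.k6, p.h1) - p.d5 * x5,
    ])


def _vector_field_clipped(state, delayed_state, u, p):
    # RK4 stage states may transiently undershoot zero; Hill terms have no
    # semantics for negative concentrations, so stages are evaluated at
    # the clipped state.
    return irma_vector_field(np.maximum(state, 0.0),
                             np.maximum(delayed_state, 0.0), u, p)


# --------------------------------------------------------------------------
# integrators
# --------------------------------------------------------------------------

class DelayBuffer:
    """Past-state lookup for the delayed term (linear interpolation on
    the integration grid; history function before t0)."""

    def __init__(self, t0: float, dt: float, history: HistoryFunction,
                 capacity_time: float):
        self.t0 = t0
        self.dt = dt
        self.history = history
        n = max(2, int(round(capacity_time / dt)) + 2)
        self._times: list[float] = [t0]
        self._states: list[np.ndarray] = [np.asarray(history(t0), dtype=float)]
        self._max_len = n

    def push(self, t: float, state: np.ndarray) -> None:
        self._times.append(t)
        self._states.append(np.asarray(state, dtype=float))
        if len(self._times) > self._max_len:
            self._times.pop(0)
            self._states.pop(0)

    def state_at(self, t: float) -> np.ndarray:
        if t <= self.t0:
            return np.maximum(np.asarray(self.history(t), dtype=float), 0.0)
        times = self._times
        if t >= times[-1]:
            return self._states[-1]
        # grid is uniform past t0; locate bracketing samples
        i = int((t - times[0]) / self.dt)
        i = min(max(i, 0), len(times) - 2)
        while times[i + 1] < t:
            i += 1
        while times[i] > t:
            i -= 1
        t_lo, t_hi = times[i], times[i + 1]
        w = 0.0 if t_hi == t_lo else (t - t_lo) / (t_hi - t_lo)
        return (1.0 - w) * self._states[i] + w * self._states[i + 1]


class IrmaIntegrator:
    """Persistent fixed-step RK4 integrator for the IRMA DDE.

    Keeps the current state and the delayed-state ring buffer across
    calls, so a closed-loop driver can advance the plant one sampling
    window at a time with bit-identical results to a single
    :func:`simulate_irma` run over the concatenated input.
    """

    def __init__(self, p: IrmaParameters, t0: float = 0.0,
                 history: HistoryFunction | None = None,
                 initial_state: Sequence[float] | None = None,
                 dt: float = 0.5, record: bool = False):
        if not (dt > 0):
            raise ValueError("dt must be positive")
        if 0.0 < p.tau < dt:
            raise ValueError("delay tau must be 0 or >= dt")
        if initial_state is None and history is None:
            raise ValueError("provide an initial_state or a history function")
        if history is None:
            history = constant_history(initial_state)
        x0 = np.asarray(history(t0) if initial_state is None else initial_state,
                        dtype=float)
        if x0.shape != (5,) or np.any(x0 < 0) or not np.all(np.isfinite(x0)):
            raise ValueError("initial state must be a non-negative 5-vector")
        self.p = p
        self.dt = dt
        self.t = float(t0)
        self.state = x0.copy()
        self._buffer = DelayBuffer(t0, dt, history,
                                   capacity_time=p.tau + 4 * dt)
        self._clipped = False
        self._record = record
        if record:
            self._times = [self.t]
            self._states = [self.state.copy()]
            self._inputs: list[int] = []

    def advance(self, input_signal: BinaryInputSignal, t1: float) -> np.ndarray:
        """Integrate up to ``t1`` (which must land on the step grid)."""
        n_steps = int(round((t1 - self.t) / self.dt))
        if n_steps <= 0 or abs(self.t + n_steps * self.dt - t1) > 1e-9 * max(1.0, abs(t1)):
            raise ValueError("t1 must exceed t and lie on the dt grid")
        p, dt = self.p, self.dt
        x = self.state
        for _ in range(n_steps):
            t = self.t
            # input constant over [t, t+dt): switches are grid-aligned
            u = int(input_signal.level_at(t))
            if p.tau == 0.0:
                k1 = _vector_field_clipped(x, x, u, p)
                s2 = x + 0.5 * dt * k1
                k2 = _vector_field_clipped(s2, s2, u, p)
                s3 = x + 0.5 * dt * k2
                k3 = _vector_field_clipped(s3, s3, u, p)
                s4 = x + dt * k3
                k4 = _vector_field_clipped(s4, s4, u, p)
            else:
                d0 = self._buffer.state_at(t - p.tau)
                dh = self._buffer.state_at(t + 0.5 * dt - p.tau)
                d1_ = self._buffer.state_at(t + dt - p.tau)
                k1 = _vector_field_clipped(x, d0, u, p)
                k2 = _vector_field_clipped(x + 0.5 * dt * k1, dh, u, p)
                k3 = _vector_field_clipped(x + 0.5 * dt * k2, dh, u, p)
                k4 = _vector_field_clipped(x + dt * k3, d1_, u, p)
            x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            if np.any(x < 0):
                self._clipped = True
                x = np.maximum(x, 0.0)
            self.t = t + dt
            self._buffer.push(self.t, x)
            if self._record:
                self._times.append(self.t)
                self._states.append(x.copy())
                self._inputs.append(u)
        self.state = x
        if self._clipped:
            logger.warning("IRMA integration clipped a negative undershoot to 0")
            self._clipped = False
        return x

    @property
    def output(self) -> float:
        """Cbf1-Gfp, the measured species."""
        return float(self.state[OUTPUT_INDEX])

    def trajectory(self, input_signal: BinaryInputSignal) -> Trajectory:
        if not self._record:
            raise RuntimeError("integrator was created with record=False")
        time = np.asarray(self._times)
        return Trajectory(time, np.asarray(self._states),
                          np.asarray(input_signal.level_at(time)))


def simulate_irma(p: IrmaParameters, input_signal: BinaryInputSignal,
                  t0: float, t1: float, history: HistoryFunction | None = None,
                  dt: float = 0.5, initial_state: Sequence[float] | None = None,
                  ) -> Trajectory:
    """Integrate the IRMA DDE with fixed-step RK4 and a delayed-state
    ring buffer (method of steps, linear interpolation in the buffer).

    ``history`` seeds the delayed term on ``[t0 - tau, t0]``; by default
    it is constant and equal to the initial state.  ``initial_state``
    defaults to ``history(t0)``.  Undershoots below zero are clipped with
    a logged warning.
    """
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    stepper = IrmaIntegrator(p, t0=t0, history=history,
                             initial_state=initial_state, dt=dt, record=True)
    stepper.advance(input_signal, t1)
    return stepper.trajectory(input_signal)


def simulate_gal1(p: Gal1Parameters, input_signal: BinaryInputSignal,
                  t0: float, t1: float, dt: float = 0.5,
                  y0: float = 0.0) -> Trajectory:
    """Simulate the one-state GAL1 model with its exact piecewise-
    exponential solution, sampled on a uniform grid.

    Production is active iff the (lag-shifted) input is galactose:
    within a constant-input segment, ``y(t) = y* + (y0 - y*) exp(-d t)``
    with ``y* = u vmax / d``.
    """
    if not (dt > 0):
        raise ValueError("dt must be positive")
    if t1 <= t0:
        raise ValueError("t1 must exceed t0")
    if y0 < 0:
        raise ValueError("y0 must be non-negative")
    effective = input_signal.shifted(p.lag) if p.lag > 0 else input_signal

    n = int(round((t1 - t0) / dt)) + 1
    time = t0 + dt * np.arange(n)
    y = np.empty(n)
    y[0] = y0

    # breakpoints: grid points plus input switch times inside each step
    switches = effective.times
    current = y0
    for i in range(n - 1):
        a, b = time[i], time[i + 1]
        inner = switches[(switches > a) & (switches < b)]
        pts = np.concatenate([[a], inner, [b]])
        for s, e in zip(pts[:-1], pts[1:]):
            u = effective.level_at(s)
            target = u * p.vmax / p.d
            current = target + (current - target) * math.exp(-p.d * (e - s))
        y[i + 1] = current
    u_grid = np.asarray(input_signal.level_at(time))
    return Trajectory(time, y[:, None], u_grid)


# --------------------------------------------------------------------------
# steady states and step responses
# --------------------------------------------------------------------------

def steady_state(p: IrmaParameters, u: int, x0: Sequence[float] | None = None,
                 tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Equilibrium of the u-field with ``delayed_state = state``.

    A short damped fixed-point run from a non-negative start conditions
    the problem, then a Newton-type root solve polishes it; the residual
    is verified below ``tol``.
    """
    if u not in (0, 1):
        raise ValueError("u must be 0 or 1")
    if x0 is None:
        alphas = np.array([p.alpha1, p.alpha2, p.alpha3, p.alpha4, p.alpha5])
        vs = np.array([p.v1, p.v2, p.v3, p.v4, p.v5])
        ds = np.array([p.d1, p.d2, p.d3, p.d4, p.d5])
        x = (alphas + 0.5 * u * vs) / ds
    else:
        x = np.asarray(x0, dtype=float)

    ds = np.array([p.d1, p.d2, p.d3, p.d4, p.d5])
    for _ in range(max_iter):
        f = irma_vector_field(x, x, u, p)
        x_new = np.maximum(x + f / ds * 0.5, 0.0)   # damped fixed point
        if np.max(np.abs(x_new - x)) < 1e-12:
            break
        x = x_new

    def resid(z: np.ndarray) -> np.ndarray:
        return irma_vector_field(np.maximum(z, 0.0), np.maximum(z, 0.0), u, p)

    sol = optimize.root(resid, x, method="hybr", tol=1e-12)
    x = np.maximum(sol.x, 0.0)
    residual = float(np.linalg.norm(irma_vector_field(x, x, u, p)))
    if residual >= tol:
        raise RuntimeError(f"steady-state search did not converge "
                           f"(residual {residual:.3e} >= {tol:.1e})")
    return x


def step_response(p: IrmaParameters, u_from: int, u_to: int,
                  horizon: float, dt: float = 0.5) -> Trajectory:
    """Trajectory after stepping the input at t = 0 from the ``u_from``
    steady state (the Cbf1 column is the output used for tuning)."""
    x_ss = steady_state(p, u_from)
    signal = BinaryInputSignal([0.0], [u_to])
    return simulate_irma(p, signal, 0.0, horizon,
                         history=constant_history(x_ss), dt=dt)
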