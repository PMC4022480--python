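"""Virtual cell population: the synthetic-data plant.

Emulates the microfluidic cell trap: a monolayer of yeast cells growing
exponentially (roughly 100 to 1200 cells over an experiment), each cell
an instance of the single-cell model with extrinsic variability (a
per-cell log-normal multiplier on production rates), dividing on an
age-based schedule with jittered inheritance, with the oldest cells
washed out once the trap capacity is reached.  The measured signal is
the population-average fluorescence plus measurement noise, sampled at
the 5-min imaging interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

from cyberloop.gene_models import (
    BinaryInputSignal,
    Gal1Parameters,
    IrmaParameters,
    steady_state,
)


@dataclass(frozen=True)
class EnsembleConfig:
    """Population settings.

    ``extrinsic_sd`` is the SD of the per-cell log-multiplier applied to
    production rates (0.3 gives a cell-to-cell CV of roughly 30%, the
    expected range for protein-level variability in yeast);
    ``division_jitter_sd`` the log-scale jitter a daughter's multiplier
    inherits; ``measurement_noise_sd`` additive noise on the population
    mean (fluorescence units).  Capacity defaults to the 1200-cell trap.
    """

    n_initial: int = 100
    doubling_time: float = 180.0
    extrinsic_sd: float = 0.3
    measurement_noise_sd: float = 0.0
    division_jitter_sd: float = 0.05
    capacity: int = 1200
    seed: int = 0
    stochastic_division: bool = False

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise ValueError("need at least one initial cell")
        if not (self.doubling_time > 0):
            raise ValueError("doubling time must be positive")
        for name in ("extrinsic_sd", "measurement_noise_sd",
                     "division_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.capacity < 1:
            raise ValueError("capacity must be >= 1")


@dataclass(frozen=True)
class PopulationSnapshot:
    """Per-frame population statistics (population-SD convention,
    divide by N)."""

    time: float
    count: int
    mean: float
    sd: float
    cv: float

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("snapshot requires at least one cell")
        if self.cv < 0:
            raise ValueError("CV must be >= 0")


def snapshots_to_csv(snapshots: list[PopulationSnapshot],
                     path: str | Path) -> None:
    data = np.array([[s.time, s.count, s.mean, s.sd, s.cv]
                     for s in snapshots])
    np.savetxt(path, data, delimiter=",", header="time_min,count,mean,sd,cv",
               comments="", fmt="%.10g")


class CellEnsemble:
    """Growing population of single-cell models.

    ``kind`` selects the per-cell model: the one-state GAL1 promoter
    (advanced with its exact piecewise-exponential update) or the IRMA
    DDE (vectorized RK4 over cells with a shared delayed-state buffer).
    """

    def __init__(self, cfg: EnsembleConfig,
                 base_params: Gal1Parameters | IrmaParameters,
                 u0: int = 0, dt: float = 0.5):
        self.cfg = cfg
        self.params = base_params
        self.kind: Literal["gal1", "irma"] = (
            "gal1" if isinstance(base_params, Gal1Parameters) else "irma")
        self.dt = dt
        self.t = 0.0
        self.rng = np.random.default_rng(cfg.seed)
        n = cfg.n_initial
        self.multipliers = np.exp(
            self.rng.normal(0.0, cfg.extrinsic_sd, size=n)) \
            if cfg.extrinsic_sd > 0 else np.ones(n)
        self.birth_times = np.zeros(n)
        if cfg.stochastic_division:
            # desynchronized ages: cells are part-way through their cycle
            self.birth_times = -self.rng.uniform(0, cfg.doubling_time, size=n)
        self.next_division = self.birth_times + cfg.doubling_time

        if self.kind == "gal1":
            if base_params.lag > 0:
                raise ValueError("ensemble GAL1 cells do not model the "
                                 "activation lag; use lag = 0")
            # per-cell steady state under u0
            self.states = (u0 * base_params.vmax / base_params.d
                           * self.multipliers)[:, None]
        else:
            if 0.0 < base_params.tau < dt:
                raise ValueError("tau must be 0 or >= dt")
            base_ss = steady_state(base_params, u0)
            # per-cell equilibrium: damped fixed-point iteration from the
            # production-scaled base state (vectorized over cells)
            self.states = base_ss[None, :] * self.multipliers[:, None]
            ds = np.array([base_params.d1, base_params.d2, base_params.d3,
                           base_params.d4, base_params.d5])
            for _ in range(400):
                f = self._irma_field(self.states, self.states, u0)
                self.states = np.maximum(self.states + 0.5 * f / ds, 0.0)
            depth = int(round(base_params.tau / dt)) + 2
            self._history: list[np.ndarray] = [self.states.copy()
                                               for _ in range(depth)]

    # -- population bookkeeping ------------------------------------------

    @property
    def count(self) -> int:
        return self.states.shape[0]

    def outputs(self) -> np.ndarray:
        """Per-cell measured species (first state column)."""
        return self.states[:, 0]

    def _divide_and_evict(self) -> None:
        cfg = self.cfg
        due = np.nonzero(self.next_division <= self.t)[0]
        if due.size:
            jitter = np.exp(self.rng.normal(0.0, cfg.division_jitter_sd,
                                            size=due.size)) \
                if cfg.division_jitter_sd > 0 else np.ones(due.size)
            self.multipliers = np.concatenate(
                [self.multipliers, self.multipliers[due] * jitter])
            self.states = np.vstack([self.states, self.states[due]])
            self.birth_times = np.concatenate(
                [self.birth_times, np.full(due.size, self.t)])
            if cfg.stochastic_division:
                next_mother = self.t + self.rng.exponential(
                    cfg.doubling_time, size=due.size)
                next_daughter = self.t + self.rng.exponential(
                    cfg.doubling_time, size=due.size)
            else:
                next_mother = self.next_division[due] + cfg.doubling_time
                next_daughter = np.full(due.size, self.t + cfg.doubling_time)
            self.next_division[due] = next_mother
            self.next_division = np.concatenate(
                [self.next_division, next_daughter])
            if self.kind == "irma":
                for i, past in enumerate(self._history):
                    self._history[i] = np.vstack([past, past[due]])
        excess = self.count - cfg.capacity
        if excess > 0:
            # wash out the oldest cells (stable order on ties)
            order = np.argsort(self.birth_times, kind="stable")
            keep = np.sort(order[excess:])
            self._select(keep)

    def _select(self, idx: np.ndarray) -> None:
        self.multipliers = self.multipliers[idx]
        self.states = self.states[idx]
        self.birth_times = self.birth_times[idx]
        self.next_division = self.next_division[idx]
        if self.kind == "irma":
            self._history = [past[idx] for past in self._history]

    # -- dynamics ---------------------------------------------------------

    def _irma_field(self, states: np.ndarray, delayed: np.ndarray,
                    u: int) -> np.ndarray:
        p = self.params
        m = self.multipliers
        x1, x2, x3, x4, x5 = states.T
        x3d, x4d = delayed[:, 2], delayed[:, 3]
        states = np.maximum(states, 0.0)

        def act(x, k, h):
            xh = np.maximum(x, 0.0) ** h
            return xh / (k ** h + xh)

        ho = act(x3d, p.k1, p.h1) / (1.0 + (np.maximum(x4d, 0) / p.k2) ** p.h2)
        gal10 = act(x2, p.k4, p.h4) / (1.0 + np.maximum(x5, 0) / p.gamma)
        return np.stack([
            m * (p.alpha1 + p.v1 * ho) - p.d1 * x1,
            m * (p.alpha2 + p.v2 * act(x1, p.k3, p.h3)) - p.d2 * x2,
            m * (p.alpha3 + u * p.v3 * gal10) - p.d3 * x3,
            m * (p.alpha4 + p.v4 * act(x3, p.k5, p.h1)) - p.d4 * x4,
            m * (p.alpha5 + p.v5 * act(x3, p.k6, p.h1)) - p.d5 * x5,
        ], axis=1)

    def advance(self, signal: BinaryInputSignal, t1: float) -> None:
        """Advance every cell to ``t1``, dividing/evicting at each
        internal step boundary."""
        n_steps = int(round((t1 - self.t) / self.dt))
        if n_steps <= 0 or abs(self.t + n_steps * self.dt - t1) > 1e-9 * max(1.0, abs(t1)):
            raise ValueError("t1 must exceed t and lie on the dt grid")
        p, dt = self.params, self.dt
        for _ in range(n_steps):
            u = int(signal.level_at(self.t))
            if self.kind == "gal1":
                target = (u * p.vmax / p.d) * self.multipliers
                y = self.states[:, 0]
                self.states = (target + (y - target)
                               * math.exp(-p.d * dt))[:, None]
            else:
                if p.tau == 0.0:
                    d0 = dh = d1_ = None
                else:
                    lag = int(round(p.tau / dt))
                    d0 = self._history[-1 - lag] if lag < len(self._history) \
                        else self._history[0]
                    d_half = self._history[-lag] if lag >= 1 else d0
                    dh = 0.5 * (d0 + d_half)
                    d1_ = d_half
                x = self.states
                k1 = self._irma_field(x, x if d0 is None else d0, u)
                s2 = x + 0.5 * dt * k1
                k2 = self._irma_field(s2, s2 if dh is None else dh, u)
                s3 = x + 0.5 * dt * k2
                k3 = self._irma_field(s3, s3 if dh is None else dh, u)
                s4 = x + dt * k3
                k4 = self._irma_field(s4, s4 if d1_ is None else d1_, u)
                x = x + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                self.states = np.maximum(x, 0.0)
                self._history.append(self.states.copy())
                self._history.pop(0)
            self.t += dt
            self._divide_and_evict()


def init_ensemble(cfg: EnsembleConfig,
                  base_params: Gal1Parameters | IrmaParameters,
                  u0: int = 0, dt: float = 0.5) -> CellEnsemble:
    """Population of ``n_initial`` cells at the ``u0`` steady state of
    their per-cell parameters, with i.i.d. log-normal multipliers."""
    return CellEnsemble(cfg, base_params, u0=u0, dt=dt)


def ensemble_step(ens: CellEnsemble, u: BinaryInputSignal | int,
                  dt: float) -> CellEnsemble:
    """Advance the ensemble by ``dt`` minutes under input ``u``."""
    signal = u if isinstance(u, BinaryInputSignal) \
        else BinaryInputSignal.constant(int(u), ens.t)
    ens.advance(signal, ens.t + dt)
    return ens


def population_readout(ens: CellEnsemble,
                       rng: np.random.Generator | None = None
                       ) -> PopulationSnapshot:
    """Mean/SD/CV of the per-cell output, with additive measurement
    noise on the mean (population-SD convention, divide by N)."""
    if ens.count == 0:
        raise ValueError("empty ensemble")
    y = ens.outputs()
    mean = float(np.mean(y))
    sd = float(np.std(y))          # population convention (ddof = 0)
    if rng is not None and ens.cfg.measurement_noise_sd > 0:
        mean += float(rng.normal(0.0, ens.cfg.measurement_noise_sd))
    cv = sd / mean if mean > 0 else 0.0
    return PopulationSnapshot(time=ens.t, count=ens.count, mean=mean,
                              sd=sd, cv=max(cv, 0.0))


def save_checkpoint(ens: CellEnsemble, path: str | Path) -> None:
    """Portable CSV checkpoint of the per-cell state (multipliers,
    birth/division times, model states).

    Resuming an IRMA ensemble re-seeds the delay buffer as constant at
    the checkpointed states, so the first ``tau`` minutes after a resume
    approximate the delayed terms.
    """
    data = np.column_stack([ens.multipliers, ens.birth_times,
                            ens.next_division, ens.states])
    state_cols = ",".join(f"x{i}" for i in range(ens.states.shape[1]))
    header = f"# t={ens.t} kind={ens.kind}\n" \
             f"multiplier,birth_time,next_division,{state_cols}"
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")


def load_checkpoint(cfg: EnsembleConfig,
                    base_params: Gal1Parameters | IrmaParameters,
                    path: str | Path, dt: float = 0.5) -> CellEnsemble:
    """Rebuild an ensemble from :func:`save_checkpoint` output."""
    lines = Path(path).read_text().splitlines()
    t = float(lines[0].split("t=")[1].split()[0])
    data = np.loadtxt(path, delimiter=",", skiprows=2, ndmin=2)
    ens = CellEnsemble(cfg, base_params, u0=0, dt=dt)
    ens.t = t
    ens.multipliers = data[:, 0]
    ens.birth_times = data[:, 1]
    ens.next_division = data[:, 2]
    ens.states = data[:, 3:]
    if ens.kind == "irma":
        depth = int(round(base_params.tau / dt)) + 2
        ens._history = [ens.states.copy() for _ in range(depth)]
    return ens


class EnsemblePlant:
    """Loop adapter: the growing population as the controlled plant."""

    def __init__(self, cfg: EnsembleConfig,
                 base_params: Gal1Parameters | IrmaParameters,
                 u0: int = 0, dt: float = 0.5):
        self.ensemble = init_ensemble(cfg, base_params, u0=u0, dt=dt)
        # separate named stream so measurement noise does not perturb
        # the division/extrinsic draws
        self.measure_rng = np.random.default_rng(cfg.seed + 1)
        self._last: PopulationSnapshot | None = None

    @property
    def t(self) -> float:
        return self.ensemble.t

    def apply(self, signal: BinaryInputSignal, t1: float) -> None:
        self.ensemble.advance(signal, t1)
        self._last = None

    def measure(self) -> float:
        return self.snapshot().mean

    def snapshot(self) -> PopulationSnapshot:
        if self._last is None:
            self._last = population_readout(self.ensemble, self.measure_rng)
        return self._last
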