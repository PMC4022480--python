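"""Experiment configuration: validated YAML/JSON files, seeded
reproducible runs, and the manifest that makes a run repeatable.

One experiment = one file.  Unknown keys are rejected with a
field-precise message; every stochastic component draws from a named
seed stream derived from the experiment seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from cyberloop.closed_loop import CalibrationProtocol, ReferenceSpec
from cyberloop.controller import PIConfig, PWMConfig
from cyberloop.gene_models import (
    Gal1Parameters,
    IrmaParameters,
    default_gal1_parameters,
    default_irma_parameters,
    load_parameters,
)
from cyberloop.virtual_cells import EnsembleConfig

_PLANTS = ("gal1", "irma", "ensemble", "ensemble_imaging")


@dataclass
class ExperimentConfig:
    """Complete description of one closed-loop experiment."""

    plant: str = "irma"
    params_file: str | None = None       # flat key/value file; bundled default
    tau: float | None = None             # delay override, min
    # controller ("auto" gains = Cohen-Coon from the model step response)
    Kp: float | str = "auto"
    Ki: float | str = "auto"
    Ts: float = 5.0
    T_pwm: float = 10.0
    quantum: float = 1.0
    # predictor
    use_predictor: bool = True
    tau_m: float | None = None           # defaults to the model delay
    mismatch_filter_tc: float | None = None   # defaults to 3 * Ts
    feedback_filter_tc: float = 0.0      # plain-loop measurement filter
    # reference
    reference: str = "constant"
    f_low: float = 0.5
    f_high: float = 0.8
    period: float = 2400.0
    rise_duration: float = 200.0
    slope: float = 5e-4
    # calibration phases: list of [level, duration]
    calibration: list = field(
        default_factory=lambda: [[1, 480.0], [0, 300.0]])
    # run
    duration: float = 2400.0
    dt: float = 0.5
    seed: int = 0
    # population plant settings (plant = ensemble / ensemble_imaging)
    n_initial: int = 100
    doubling_time: float = 180.0
    extrinsic_sd: float = 0.3
    measurement_noise_sd: float = 0.0
    division_jitter_sd: float = 0.05
    capacity: int = 1200

    def __post_init__(self) -> None:
        if self.plant not in _PLANTS:
            raise ValueError(f"plant must be one of {_PLANTS}, "
                             f"got {self.plant!r}")
        if not (self.Ts > 0):
            raise ValueError("Ts must be positive")
        if not (self.duration > 0):
            raise ValueError("duration must be positive")
        if not (self.dt > 0):
            raise ValueError("dt must be positive")
        for name in ("Kp", "Ki"):
            v = getattr(self, name)
            if isinstance(v, str) and v != "auto":
                raise ValueError(f"{name} must be a number or 'auto'")
        self.calibration = [(int(lv), float(d)) for lv, d in self.calibration]
        # constructing these validates the remaining fields
        self.reference_spec()
        self.calibration_protocol()

    # -- derived objects --------------------------------------------------

    def model_parameters(self) -> Gal1Parameters | IrmaParameters:
        if self.plant in ("irma",):
            p = (IrmaParameters(**load_parameters(self.params_file))
                 if self.params_file else default_irma_parameters())
            return p.with_tau(self.tau) if self.tau is not None else p
        if self.params_file:
            return Gal1Parameters(**load_parameters(self.params_file))
        return default_gal1_parameters()

    def pwm_config(self) -> PWMConfig:
        return PWMConfig(T_pwm=self.T_pwm, quantum=self.quantum)

    def pi_config(self, Kp: float | None = None,
                  Ki: float | None = None) -> PIConfig:
        """PI settings; pass tuned gains when the file says 'auto'."""
        kp = self.Kp if isinstance(self.Kp, float | int) else Kp
        ki = self.Ki if isinstance(self.Ki, float | int) else Ki
        if kp is None or ki is None:
            raise ValueError("gains are 'auto' but no tuned values supplied")
        return PIConfig(Kp=float(kp), Ki=float(ki), Ts=self.Ts)

    def reference_spec(self) -> ReferenceSpec:
        return ReferenceSpec(kind=self.reference, f_low=self.f_low,
                             f_high=self.f_high, period=self.period,
                             rise_duration=self.rise_duration,
                             slope=self.slope)

    def calibration_protocol(self) -> CalibrationProtocol:
        return CalibrationProtocol(phases=tuple(self.calibration))

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            n_initial=self.n_initial, doubling_time=self.doubling_time,
            extrinsic_sd=self.extrinsic_sd,
            measurement_noise_sd=self.measurement_noise_sd,
            division_jitter_sd=self.division_jitter_sd,
            capacity=self.capacity, seed=self.seed)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration"] = [list(pair) for pair in d["calibration"]]
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    def manifest(self) -> dict:
        """Config hash + seed + version: enough to reproduce the run."""
        from cyberloop import __version__
        blob = json.dumps(self.to_dict(), sort_keys=True)
        return {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
                "seed": self.seed, "cyberloop_version": __version__}


def load_config(path: str | Path) -> ExperimentConfig:
    """Read and validate a YAML (or JSON — a YAML subset) experiment
    file; unknown keys are rejected by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("experiment file must contain a mapping")
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    try:
        return ExperimentConfig(**raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid configuration: {exc}") from exc
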