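"""Canned in-silico experiments.

Each recipe assembles a plant, tunes the PI by Cohen-Coon from the
model's galactose step response, runs the closed loop (or the open-loop
protocol) and writes its artifacts — record/trajectory CSVs, a metrics
JSON, a tuning CSV, a config/manifest sidecar and a summary plot — into
the output directory.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from cyberloop.closed_loop import (
    CalibrationProtocol,
    ControlRecord,
    Gal1Plant,
    IrmaPlant,
    ReferenceSpec,
    compute_metrics,
    constant_input_control,
    random_input_control,
    run_fsa_loop,
)
from cyberloop.controller import (
    PIConfig,
    PWMConfig,
    cohen_coon_gains,
    estimate_fopdt,
)
from cyberloop.gene_models import (
    BinaryInputSignal,
    Gal1Parameters,
    constant_history,
    default_gal1_parameters,
    default_irma_parameters,
    simulate_gal1,
    simulate_irma,
    steady_state,
    step_response,
)
from cyberloop.predictor import (
    IrmaInternalModel,
    PredictorConfig,
)
from cyberloop.virtual_cells import EnsembleConfig, EnsemblePlant, snapshots_to_csv

logger = logging.getLogger(__name__)

RECIPES = ("fig4_tracking", "s5_s6_predictor", "s7_s8_pipwm",
           "s25_switchoff", "gal1_setpoint", "negative_controls")

#: canonical tracking task: one triangular cycle over the experiment
TRACKING_REF = ReferenceSpec(kind="triangular", f_low=0.2, f_high=0.8,
                             period=2400.0)
SETPOINT_REF = ReferenceSpec(kind="constant", f_low=0.5)
IRMA_CALIB = CalibrationProtocol(phases=((1, 480.0), (0, 300.0)))
GAL1_CALIB = CalibrationProtocol(phases=((1, 300.0), (0, 300.0)))


def tune_irma(tau: float | None = None, Ts: float = 5.0,
              horizon: float = 1500.0, dt: float = 0.5):
    """Cohen-Coon PI gains from the IRMA galactose step response."""
    p = default_irma_parameters(tau=tau)
    step = step_response(p, 0, 1, horizon=horizon, dt=dt)
    est = estimate_fopdt(step)
    return cohen_coon_gains(est, Ts=Ts), est, p


def tune_gal1(Ts: float = 5.0, dt: float = 0.5):
    """Cohen-Coon PI gains from the (lagged) GAL1 step response."""
    p = default_gal1_parameters()
    sig = BinaryInputSignal([-10 * p.lag - 1000.0, 0.0], [0, 1])
    horizon = max(900.0, 8.0 / p.d)
    step = simulate_gal1(p, sig, 0.0, horizon, dt=dt)
    est = estimate_fopdt(step)
    return cohen_coon_gains(est, Ts=Ts), est, p


def write_tuning_csv(path: Path, est, pi: PIConfig) -> None:
    path.write_text("K,T,d,Kp,Ki\n"
                    f"{est.K:.10g},{est.T:.10g},{est.d:.10g},"
                    f"{pi.Kp:.10g},{pi.Ki:.10g}\n")


def _plot_record(rec: ControlRecord, path: Path, title: str) -> None:
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5),
                                   height_ratios=[3, 1])
    if rec.calibration_time.size:
        ax1.plot(rec.calibration_time, rec.calibration_y, color="0.7",
                 label="calibration")
    ax1.plot(rec.time, rec.r, "b-", label="reference r")
    ax1.plot(rec.time, rec.y, "g-", label="measured y")
    ax1.set_ylabel("fluorescence (model units)")
    ax1.legend(loc="best", fontsize=8)
    ax1.set_title(title)
    ax2.step(rec.time, rec.duty, "r-", where="post")
    ax2.set_ylabel("galactose\nfraction")
    ax2.set_xlabel("time (min)")
    ax2.set_ylim(-0.05, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)


def _write_run(out: Path, stem: str, rec: ControlRecord, title: str) -> dict:
    rec.to_csv(out / f"{stem}.csv")
    metrics = compute_metrics(rec)
    metrics.to_json(out / f"{stem}_metrics.json")
    _plot_record(rec, out / f"{stem}.png", title)
    if rec.predictor_trace is not None:
        data = np.column_stack([rec.time,
                                rec.predictor_trace["y_model"],
                                rec.predictor_trace["y_model_delayed"],
                                rec.predictor_trace["correction"]])
        np.savetxt(out / f"{stem}_predictor_trace.csv", data, delimiter=",",
                   header="time_min,y_model,y_model_delayed,correction",
                   comments="", fmt="%.10g")
    if rec.snapshots:
        snapshots_to_csv(rec.snapshots, out / f"{stem}_population.csv")
    return {"nrmse": metrics.nrmse, "error_mean": metrics.error_mean,
            "error_var": metrics.error_var}


def _irma_loop(use_predictor: bool, tau: float | None, refspec: ReferenceSpec,
               duration: float, dt: float = 0.5) -> ControlRecord:
    pi, est, p = tune_irma(tau=tau)
    plant = IrmaPlant(p, dt=dt)
    pred = None
    if use_predictor:
        pred = PredictorConfig(model=IrmaInternalModel(p, dt=dt), tau_m=p.tau)
    return run_fsa_loop(plant, pi, PWMConfig(), refspec, duration=duration,
                        predictor_cfg=pred, calib=IRMA_CALIB, Ts=pi.Ts)


def run_recipe(name: str, out_dir: str | Path, seed: int = 0) -> dict:
    """Run one named experiment; returns a summary dict (also written to
    ``summary.json`` in the output directory)."""
    if name not in RECIPES:
        raise ValueError(f"unknown recipe {name!r}; choose from {RECIPES}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"recipe": name, "seed": seed}

    if name in ("fig4_tracking", "s5_s6_predictor", "s7_s8_pipwm"):
        use_pred = name != "s7_s8_pipwm"
        pi, est, p = tune_irma()
        write_tuning_csv(out / "tuning.csv", est, pi)
        variants = [("tracking_delay", TRACKING_REF, None)]
        if name != "fig4_tracking":
            variants = [("tracking_nodelay", TRACKING_REF, 0.0),
                        ("tracking_delay", TRACKING_REF, None),
                        ("setpoint_nodelay", SETPOINT_REF, 0.0),
                        ("setpoint_delay", SETPOINT_REF, None)]
        for stem, ref, tau in variants:
            rec = _irma_loop(use_pred, tau, ref, duration=2400.0)
            label = "PI-PWM + predictor" if use_pred else "plain PI-PWM"
            summary[stem] = _write_run(out, stem, rec,
                                       f"IRMA {stem} ({label})")

    elif name == "s25_switchoff":
        p = default_irma_parameters()
        ss0 = steady_state(p, 0)
        signal = BinaryInputSignal([0.0, 180.0], [1, 0])
        traj = simulate_irma(p, signal, 0.0, 600.0,
                             history=constant_history(ss0), dt=0.5)
        traj.to_csv(out / "switchoff.csv")
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.plot(traj.time, traj.output, "g-", label="Cbf1 (model)")
        ax.step(traj.time, traj.u * traj.output.max(), "r-", where="post",
                alpha=0.4, label="input (scaled)")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("Cbf1 (model units)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out / "switchoff.png", dpi=110)
        plt.close(fig)
        i_switch = int(np.argmax(traj.time >= 180.0))
        post = traj.output[i_switch:]
        summary["cbf1_peak"] = float(traj.output.max())
        summary["cbf1_final"] = float(traj.output[-1])
        summary["glucose_steady_state"] = float(ss0[0])
        summary["monotone_decay_after_peak"] = bool(
            np.all(np.diff(post[np.argmax(post):]) <= 1e-9))

    elif name == "gal1_setpoint":
        pi, est, p = tune_gal1()
        write_tuning_csv(out / "tuning.csv", est, pi)
        cells = Gal1Parameters(vmax=p.vmax, d=p.d, lag=0.0)
        cfg = EnsembleConfig(n_initial=100, doubling_time=180.0,
                             extrinsic_sd=0.3, measurement_noise_sd=0.5,
                             division_jitter_sd=0.05, capacity=1200,
                             seed=seed)
        plant = EnsemblePlant(cfg, cells, u0=0)
        rec = run_fsa_loop(plant, pi, PWMConfig(), SETPOINT_REF,
                           duration=2000.0, calib=GAL1_CALIB, Ts=pi.Ts)
        summary["setpoint"] = _write_run(out, "setpoint", rec,
                                         "GAL1 population set-point control")

    elif name == "negative_controls":
        pi, est, p = tune_gal1()
        write_tuning_csv(out / "tuning.csv", est, pi)
        runs = {}
        closed = run_fsa_loop(Gal1Plant(p, dt=0.5), pi, PWMConfig(),
                              SETPOINT_REF, duration=1500.0,
                              calib=GAL1_CALIB, Ts=pi.Ts)
        runs["closed_loop"] = closed
        runs["random_input"] = random_input_control(
            Gal1Plant(p, dt=0.5), pi, PWMConfig(), SETPOINT_REF,
            duration=1500.0, seed=seed, calib=GAL1_CALIB, Ts=pi.Ts)
        runs["constant_galactose"] = constant_input_control(
            Gal1Plant(p, dt=0.5), 1, SETPOINT_REF, duration=1500.0,
            calib=GAL1_CALIB, Ts=pi.Ts)
        for stem, rec in runs.items():
            summary[stem] = _write_run(out, stem, rec,
                                       f"GAL1 negative control: {stem}")

    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2))
    logger.info("recipe %s written to %s", name, out)
    return summary
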