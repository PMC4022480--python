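# Methods

This note documents the models, numerical choices and design decisions
behind `cyberloop`, and what the synthetic experiments do and do not
show about real cells.

## Gene models

### GAL1 promoter

A single fluorescence state y with gated production,
dy/dt = u(t − lag)·v_max − d·y. Defaults (`data/gal1.params`):
v_max = 1 fluorescence-unit/min, d = 0.01 /min (a ~70-min half-life
combining protein turnover and dilution by growth, giving a steady-state
range of 0–100 units), lag = 15 min (induction machinery turn-on; it
also gives the step response a nonzero dead time so Cohen-Coon tuning is
well-posed). Because the model is piecewise linear, it is advanced with
its exact piecewise-exponential solution — no integration error, and a
convenient independent oracle for the loop code.

### IRMA network

Five concentrations x = (CBF1, GAL4, SWI5, ASH1, GAL80) in model units,
with Hill-type promoter activities, a Gal80p–Gal4p sequestration factor
1/(1 + x₅/γ), and a binary galactose gate u multiplying GAL10-driven
SWI5 production — two vector fields switched by the sugar. CBF1
production reads SWI5 and ASH1 at t − τ: the transcriptional delay of
the HO promoter (chromatin-remodeling recruitment) makes the model a
DDE. The delay dominates every control question in this package.

**Parameter provenance.** The network topology (which species activates
or represses which promoter, the galactose gate, the delayed HO arm) is
fixed by the biology of the construct. The numeric rates shipped in
`data/irma.params` are this package's own calibration, chosen once so
the model reproduces the qualitative behaviour reported for the real
network: switch-on within ~3 h of galactose with a ~20-fold CBF1
dynamic range, switch-off decay within ~7 h of glucose, protein
half-lives of tens of minutes, and τ = 100 min, large against the 5-min
sampling interval. The file is flat `key = value` text precisely so a
user with better estimates can drop them in; nothing in the code
hard-codes the values.

### Integration

Fixed-step RK4 (default dt = 0.5 min) with a ring buffer of past states
for the delayed term; delayed lookups interpolate linearly inside the
buffer and fall back to the (constant, by default) history function for
t ≤ t₀. Fixed step was chosen over adaptive integration because the
closed loop replays the plant in 5-min windows and trajectories must be
bit-reproducible regardless of how the horizon is partitioned (this is
asserted in tests). All RK4 stages use the input level that governs
[t, t+dt) — switches are grid-aligned by construction (the PWM quantum
is a multiple of dt) — otherwise a step straddling a sugar switch
blends the two vector fields and costs an O(dt) error at every edge.
Stage states that undershoot zero are clipped before evaluating Hill
terms (negative concentrations have no semantics); a completed step
that lands negative is clipped to zero with a logged warning.
Requirements: dt > 0, and τ = 0 or τ ≥ dt. Steady states are found by a
damped fixed-point sweep (step x ← x + F(x)/(2d)) followed by a Newton
polish, and verified to residual < 1e-8.

At τ = 0 the integrator agrees with a 100×-finer-step Euler oracle to a
relative error of ~2e-4 over 1000 min; equilibria are preserved to
< 1e-6 over 500 min.

## Controller

* **PI block**: backward-Euler (rectangular) integral, output clamped to
  the sawtooth range [0, 1]; anti-windup by conditional integration
  (the integral update is discarded whenever it would deepen
  saturation). The PI output lives directly on the PWM scale, so one
  normalization point serves the whole loop.
* **PWM**: rising sawtooth with period 10 min running on absolute time
  (its phase is shared across the 5-min sampling windows, two windows
  per period). Pulses are realized on a 1-min quantum; the comparator
  is evaluated at quantum midpoints with ties counting high, which
  makes the duty of a saturated level exactly 1, the duty of a level at
  or below the ramp minimum exactly 0, and bounds the duty error by
  half a quantum per period. Galactose pulses sit at the start of each
  period (contiguous duty).
* **Measurement filter**: first-order exponential smoothing with the
  exact discretization y_f ← y + (y_f − y)e^(−dt/T_f); T_f = 0 is a
  pass-through, which is also the plain-loop default for deterministic
  plants (the ensemble's frame-to-frame noise is already tamed by
  population averaging).
* **FOPDT identification**: two-point method — t₂₈.₃ and t₆₃.₂ of the
  normalized settling step give T = 1.5(t₆₃ − t₂₈), d = t₆₃ − T,
  K = Δy/Δu. Chosen over tangent-through-inflection because it needs no
  derivative estimate and is deterministic on sampled data. The final
  10% of the horizon must be flat to 2% of the excursion or the
  response is rejected as non-settling.
* **Cohen-Coon PI**: Kp = (1/K)(T/d)(0.9 + d/(12T)),
  Ti = d(30 + 3d/T)/(9 + 20d/T). Singular at d = 0, in which case the
  caller must supply gains. For the shipped IRMA model the fit is
  K = 1.20, T = 46 min, d = 107 min — a dead-time-dominated plant, the
  regime where plain PI control degrades and delay compensation pays.

## Smith-type predictor

The delay-free internal model (the same integrator, τ = 0) is advanced
open-loop under the realized sugar windows. Its output history is kept
in a ring buffer; the feedback signal is
ŷ(t) + LP[y_meas(t) − ŷ(t − τ_m)], with a first-order mismatch filter
(default time constant 3·Ts = 15 min) suppressing measurement noise in
the correction path. The filter sits on the mismatch, not on the raw
measurement, and an affine calibration map (fitted from the calibrated
fluorescence range against the model's glucose/galactose steady-state
outputs) reconciles model units with fluorescence units.

For a plant whose delay is a pure input/output transport delay and a
perfect model, this scheme is *exactly* equivalent to the delay-free
loop — the package verifies the classical equivalence on a
delayed-output GAL1 plant, where the error sequences of the two loops
agree to machine precision. For the IRMA DDE the delay is internal to
the state dynamics, so the equivalence is not a theorem; there the
predictor's value is measured empirically: on the triangular tracking
task with τ = 100 min, removing the predictor raises the NRMSE by a
factor of ~2.3 (0.11 → 0.26), while at τ = 0 the two loops produce
bit-identical records. The residual predictor-loop error is mostly the
unavoidable lag of the physical output behind a moving reference —
no feedback law can make a plant with a 100-min dead time track a ramp
without ~slope·τ of error.

## Experiment driver

Each run mirrors the control automaton: a calibration phase (default
480 min galactose then 300 min glucose; max/min estimated as the mean
of the last 6 samples ≈ 30 min of each phase) establishes the
fluorescence range, then the loop cycles every Ts = 5 min — error → PI
→ PWM window → model prediction → actuate → delayed replica → new
measurement → next error. References are fractions of the calibrated
range: constant (default 50%), triangular (default 20%–80%, one cycle
per experiment, peak at half a period), or rise-then-ramp-down. The
canonical tracking task spans 2400 min — matching the duration scale of
the real multi-day experiments — because a triangle much faster than
that is unreachable for any controller facing a 100-min delay.

Metrics are computed over the control-active interval only:
NRMSE = RMS(y − r)/(y_max − y_min) with the calibration range as the
normalizer; error mean/variance/CV; and "settled" statistics starting
at the first sample whose deviation drops below 10% of the range.
A plant failure mid-run truncates and flags the record instead of
discarding it.

Negative controls: (a) closed loop until the set-point is first
reached, then Bernoulli(0.5) sugar per window (the in-vivo
randomization scheme is unspecified; a fair coin is the natural null);
(b) sustained galactose. Both are scored against the same reference and
produce strictly larger NRMSE than the closed loop.

## Virtual population

Each cell is a model instance whose production rates (basal and
promoter-driven) are scaled by a log-normal multiplier, exp N(0, σ)
with σ = 0.3 — extrinsic variability in expression capacity, the
dominant noise source at the protein level; the resulting cell-to-cell
CV of ~0.3 sits in the range reported for yeast. Division is
deterministic and age-based (default doubling time 180 min, plausible
for stressed cells in a trap) with daughters inheriting the mother's
state and a jittered multiplier (log-SD 0.05); a stochastic-division
mode (exponential inter-division times) exists behind a flag but the
deterministic schedule is the default for reproducibility. Beyond the
1200-cell capacity the oldest cells are washed out. Snapshots report
the population mean, SD and CV with the population convention (divide
by N — these are per-frame descriptive statistics, not estimators of a
larger population). Measurement noise is additive on the mean, from a
seed stream separate from the biology so that enabling it does not
perturb the division/variability draws.

GAL1 ensembles advance with the exact per-cell exponential update; IRMA
ensembles use the RK4 stepper vectorized over cells with a shared
delayed-state buffer. A degenerate ensemble (σ = 0, no jitter)
reproduces the single-cell integrator to 1e-9, which ties the two code
paths together.

What this generator does *not* emulate: intrinsic (birth–death)
transcriptional noise, spatial crowding or nutrient gradients in the
trap, cell-cycle-dependent expression, and correlations between
mother/daughter beyond the inherited multiplier. Passing tests
therefore demonstrate robustness to extrinsic heterogeneity, growth and
measurement noise — not to every noise source a microfluidic experiment
sees.

## Imaging chain

Rendered frames: dark circular cell bodies (radius 5–8 px, the yeast
scale at the usual magnification) with a 1-px bright halo on a gray
background plus Gaussian optics noise; the fluorescence channel holds
each cell's expression level on its disk. The pipeline is Otsu →
connected components → convex hulls → circular Hough (radius range
4–12 px) → quantification:

* **Otsu** is computed on the exact value histogram (no fixed-bin
  quantization), so the threshold shifts by exactly c when all pixels
  shift by c; `skimage.filters.threshold_otsu` is the independent
  cross-check in tests.
* **Hulls** (scipy Qhull on component pixels; bounding-box fallback for
  degenerate components) limit where the Hough transform runs. Canny
  edges (σ = 1.5) are taken inside each padded hull bounding box;
  accumulator peaks need ≥ 35% of a full circle's evidence, candidate
  centers must lie in the originating hull (padding can clip a
  neighbouring cell into a spurious arc), and detections are
  non-maximum-suppressed globally by a 7-px center distance.
* **Mask semantics**: the final mask is the union of detected circle
  disks *intersected with the Otsu foreground*. The Hough output
  localizes cells; the intersection keeps only cell-body pixels. A
  plain disk union admits halo and background pixels through 1–2 px
  center/radius errors and biased the quantified mean several percent
  low; the intersection brings the population mean within 1% of ground
  truth while remaining Hough-localized.
* A frame with zero detections is flagged and its measurement set to
  NaN; the loop holds the previous value rather than crashing.

On 20 seeded ~100-cell frames the chain achieves recall ≈ 0.99,
precision ≈ 0.98, center errors ≤ 1.9 px and quantification within 1%.

## Switch-off protocol

180 min of galactose followed by 420 min of glucose, starting from the
glucose steady state. Because CBF1 production reads SWI5 at t − τ, the
output keeps rising for up to τ after the sugar switch (the delayed
production wave) and only then decays — monotonically, to within 2% of
the glucose steady state by 600 min. The acceptance check is therefore
phrased as: rise during galactose; peak within τ of the switch;
strictly monotone decay from the peak; convergence to the glucose
state. A check demanding decay from the instant of the switch would
contradict the delay the model is built around.

## Determinism and seeds

Every stochastic component (ensemble initialization, division jitter,
measurement noise, scene generation, random-input control) draws from a
named `numpy` Generator seeded from the experiment seed; identical
configs and seeds give byte-identical CSVs (asserted in tests). Each
run writes a manifest with the config hash, seed and package version.

## Known limitations

* IRMA rate constants are a calibration reproducing qualitative
  behaviour, not fitted to measurements; quantitative predictions in
  model units carry no error bars.
* The actuator is ideal: sugar switches take effect instantly and
  uniformly (no mixing dynamics, no Dial-a-Wave transients).
* The Smith equivalence is exact only for transport delays; for the
  state-delayed network the predictor is a (well-performing) heuristic.
* Cell segmentation is tuned for the synthetic renderer's contrast
  geometry; real phase-contrast images would need the documented knobs
  (radius range, Canny σ, peak threshold) re-tuned.
* Metrics treat the calibration range as exact; drift in the true
  dynamic range over a long experiment is not re-estimated.
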