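# Methods

This note documents the models, the synthetic data they are exercised on, and
the numerical choices behind the `softsensor` package.

## The measurement problem

An in-line capacitance probe measures the permittivity increment of a cell
suspension at radio frequencies. Intact cell membranes charge in the applied
field (the β-dispersion), so the low-frequency capacitance increment scales
with *viable biovolume* — the product of viable cell concentration (VCC),
viability and per-cell volume — not with cell count directly. A single-
frequency reading calibrated against VCC is therefore confounded by any
change in cell diameter: when cells swell, the signal rises although the
count does not. Scanning 25 frequencies between 50 and 20,000 kHz captures
the *shape* of the dispersion, which shifts with cell radius, and a
multivariate calibration can separate the count from the size effect.

## β-dispersion forward model (simulate)

For a dilute suspension of membrane-bounded spheres of radius `r` (m) at
number density `N` (cells/m³), with membrane capacitance `Cm` (F/m²),
cytoplasm conductivity `σi` and medium conductivity `σm` (S/m):

- biovolume fraction `P = N · (4/3)πr³` (the simulator rejects `P ≥ 1`),
- dispersion amplitude `Δε = 9 r P Cm / 4`,
- characteristic frequency `fc = 1 / (2π r Cm (1/σi + 1/(2σm)))`,
- measured capacitance at frequency `f`:
  `C(f) = C∞ + k · Δε · Re[1 / (1 + (j f/fc)^(1−α))]`,

a Cole–Cole relaxation with broadening exponent `α ∈ [0, 1)` (`α = 0` is the
Debye case, asserted in the tests to 1e-12 against the closed form).
`k` (`cell_constant`) is a single lumped scalar converting the permittivity
increment into pF/cm; it absorbs probe geometry, electrode polarization and
the vacuum permittivity, none of which the package resolves individually.
Defaults (`Cm = 0.01 F/m²`, `σi = 0.5 S/m`, `σm = 1.5 S/m`, `α = 0.1`,
`C∞ = 2 pF/cm`, `k = 1.8e9`) put `fc` near 900 kHz for 15 µm cells and keep
spectra in a realistic 0–100 pF/cm span. The absolute capacitance scale is
self-consistent only; no instrument is being matched.

Dead cells have leaky membranes and contribute no dispersion, so the
generator drives the signal with `VCC × viability`.

## Perfusion process model (simulate)

One run integrates a viable-cell balance over 26 days at a 0.005-day step
with exact exponential stepping (`V ← V·exp((µ − kd − b)·dt)`):

- 3-day batch phase, then perfusion; growth `µ = 0.60/day`, death
  `kd = 0.02/day`, inoculation at 0.5e6 cells/mL;
- once VCC first reaches the setpoint, a positional discrete-time PID on the
  normalized error `(V − S)/S` sets the bleed rate `b ≥ 0` (clamped, with
  conditional-integration anti-windup). Default gains `Kp = 6/day`,
  `Ki = 9/day²`, `Kd = 0` give a critically-damped-ish response that holds
  `|V − S|/S < 10%` from two days after bleed onset (asserted in tests, and
  in practice < 0.3%);
- viable cell diameter: base 15 µm with a linear ramp of +20% over days
  7–10, constant thereafter — the drift that confounds the single-frequency
  sensor. The ramp magnitude is a configuration choice consistent with the
  ">16%" swelling the sensor must tolerate;
- viability: mild logistic decline 0.98 → 0.90 centred on day 16 (a typical
  healthy perfusion profile; no reference values exist to match);
- capacitance scans every 30 s (74,881 scans over 26 days) with i.i.d.
  Gaussian noise (sd 0.2 pF/cm) per frequency; daily offline reference
  samples (27 per run) with 5% multiplicative counting noise — a realistic
  cell-counter CV.

One seed per run; spectra noise and offline-count noise draw from
independent named substreams, so enabling one never shifts the other.

## Calibration contract (preprocess)

Spectra are smoothed with a 5-minute *trailing* rolling mean — the causal
form a streaming consumer can compute, which is what makes batch calibration
and online prediction identical — then merged with offline references by
nearest timestamp within 150 s (half the smoothing window); unmatched
references are dropped with a warning, never interpolated. Predictors are
mean-centered only (high-capacitance frequencies legitimately dominate);
the response is autoscaled with the n−1 sample standard deviation.

## O-PLS (opls)

Single-response NIPALS O-PLS. On centered X and scaled y:
`w ∝ Xᵀy` (computed once — it is invariant under the y-orthogonal deflation
that follows); then for each of K orthogonal rounds `t = Xw`,
`p = Xᵀt/(tᵀt)`, `w_o = p − (wᵀp)w` normalized, `t_o = Xw_o`,
`p_o = Xᵀt_o/(t_oᵀt_o)`, `X ← X − t_o p_oᵀ`; finally `q = yᵀt/(tᵀt)`.
The deployed configuration is one predictive + two orthogonal components.
Degeneracies fail loudly: uncorrelated predictors (`‖Xᵀy‖ = 0`) and
exhausted orthogonal variation (`‖w_o‖ < 1e-12`, the exactly-rank-1 case)
raise instead of fitting noise directions.

Because centering, deflation, projection and unscaling are all affine, the
model collapses exactly to `ŷ = intercept + coefficients·x` with
`coefficients = y_sd·q·Dw`, `D = ∏(I − w_o p_oᵀ)` in fitting order — the
flat-equation export the streaming engine executes. The collapse is asserted
to 1e-10·y_sd against stepwise prediction.

Model files carry their frequency grid and refuse prediction on mismatched
grids; there is no silent interpolation.

## Single-frequency baseline (baseline)

Ordinary least squares of VCC on the capacitance column nearest the nominal
580 kHz (607 kHz on the default log grid; the snap is logged). An
intercept-free variant is available by flag. This is the comparison arm: it
tracks viable biovolume, so after the diameter ramp it overpredicts VCC.

## Evaluation (evaluate)

`rmse = sqrt(Σ(ŷᵢ − yᵢ)²/n)`; reported as RMSEP on external pairs and as
RMSEcv over pooled held-out cross-validation predictions. The two are
labelled distinctly and never ranked against each other. Cross-validation
partitions rows into contiguous time blocks within batch (7 folds by
default) to avoid temporal leakage, and refits the scaling inside every
training fold. Relative error uses observed y in the denominator, over
pairs with y > 0, within a stated day window.

## Virtual campaigns (scenarios)

The canonical study design: three calibration runs at setpoints 30/50/70e6
cells/mL (decorrelating VCC from batch maturity) and one validation run at
40e6, all under the drift conditions above. Under these conditions, across
ten seeded replicates, the O-PLS sensor beats the single-frequency sensor in
every replicate (median RMSEP ratio ≈ 0.5) and the single-frequency sensor's
post-day-10 residuals are positive-biased (pooled sign test p ≈ 3e-17).

The *parameter-recovery* campaign is noise-free with time-constant diameter
and viability. A subtlety: with everything constant, all 25 capacitance
columns are exactly proportional to viable biovolume — the data are exactly
rank-1, there is no y-orthogonal variation, and the orthogonal-component
extraction (correctly) refuses to run. The recovery campaign therefore gives
each batch a slightly different base diameter (14.4/15.0/15.6 µm, validation
at 15.0 µm), emulating ordinary inter-batch variability. That supplies
genuine y-orthogonal spectral-shape variation for the two orthogonal
components to absorb, and the 1+2 model recovers held-out VCC to ~0.02% of
its mean.

## Streaming (stream)

The online loop maintains a trailing buffer, evicts scans older than the
window, averages, and evaluates every registered model per scan. It is
purely causal and pacing-independent; replaying a file reproduces the batch
pipeline record for record (asserted over a full 74,881-scan run).
Malformed rows are skipped, counted and logged; negative predictions are
emitted and flagged rather than clamped, since clamping would mask a failing
calibration. Real OPC UA/SCADA transport is out of scope; the source/sink
interfaces are the seam where such adapters would attach.

## What the synthetic data does not capture

The generator omits electrode polarization drift, temperature effects,
medium-conductivity changes, aggregation/ATF shear effects, metabolite
dynamics, and non-spherical or size-distributed cells; its capacitance scale
is arbitrary. Passing tests therefore demonstrate correctness of the
algorithms and the qualitative drift-robustness mechanism, not instrument-
level accuracy on real cultivations. Problem sizes used in the tests — 26-day
runs, 30-s scans, 27 offline samples/run, ten replicate campaigns — were
chosen as the package's standard desk-scale study conditions.
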