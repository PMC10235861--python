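"""Synthetic perfusion process and dielectric (capacitance) spectrum generator.

This module stands in for real cultivation campaigns: it integrates a simple
viable-cell balance for a perfusion run with PID-actuated cell bleed, imposes
the cell-diameter drift that confounds single-frequency capacitance readings,
and renders multifrequency capacitance scans from a Cole-Cole beta-dispersion
model of the cell suspension.

The physical picture: intact cell membranes charge up in a radio-frequency
field, producing a permittivity increment (the beta dispersion) whose
low-frequency amplitude scales with viable biovolume and whose characteristic
frequency decreases with cell radius.  Dead cells have leaky membranes and do
not contribute, so the dispersion tracks ``VCC x viability``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DielectricParams",
    "ProcessConfig",
    "ProcessTrajectory",
    "SpectrumRecord",
    "OfflineSample",
    "SimulationError",
    "default_frequency_grid",
    "simulate_process",
    "beta_dispersion_capacitance",
    "generate_spectra",
    "sample_offline",
]


class SimulationError(RuntimeError):
    """Raised when a simulated process reaches a non-physical state."""


def default_frequency_grid(n: int = 25, lo_kHz: float = 50.0, hi_kHz: float = 20000.0) -> tuple[float, ...]:
    """Log-spaced scan grid, rounded to integer kHz (unique after rounding)."""
    grid = np.geomspace(lo_kHz, hi_kHz, n)
    grid = np.round(grid).astype(float)
    if len(np.unique(grid)) != n:
        raise ValueError("frequency grid not unique after rounding to integer kHz")
    return tuple(float(f) for f in grid)


@dataclass
class DielectricParams:
    """Suspension dielectric parameters for the beta-dispersion model.

    Units follow the Schwan description of a dilute suspension of membrane-
    bounded spheres: membrane capacitance in F/m^2, conductivities in S/m.
    ``cell_constant`` is a single lumped scalar converting the suspension
    permittivity increment into the measured capacitance increment (pF/cm per
    unit of permittivity increment); it absorbs probe geometry, electrode
    polarization and the vacuum permittivity, none of which are resolved
    individually here.
    """

    membrane_capacitance_Cm: float = 1.0e-2      # F/m^2 (~1 uF/cm^2, typical mammalian)
    cytoplasm_conductivity_sigma_i: float = 0.5  # S/m
    medium_conductivity_sigma_m: float = 1.5     # S/m
    cole_cole_alpha: float = 0.1                 # broadening exponent, 0 = Debye
    baseline_capacitance_Cinf: float = 2.0       # pF/cm, fully relaxed background
    cell_constant: float = 1.8e9                 # pF/cm per unit permittivity increment
    spectrum_noise_sd: float = 0.2               # pF/cm, i.i.d. per frequency per scan

    def __post_init__(self) -> None:
        if self.membrane_capacitance_Cm <= 0:
            raise ValueError("membrane capacitance must be > 0")
        if self.cytoplasm_conductivity_sigma_i <= 0 or self.medium_conductivity_sigma_m <= 0:
            raise ValueError("conductivities must be > 0")
        if not 0.0 <= self.cole_cole_alpha < 1.0:
            raise ValueError("Cole-Cole alpha must lie in [0, 1)")
        if self.spectrum_noise_sd < 0:
            raise ValueError("spectrum noise sd must be >= 0")


@dataclass
class ProcessConfig:
    """Configuration of one simulated perfusion run.

    Defaults emulate a 26-day run with a 3-day batch phase, exponential growth
    and a PID-controlled cell bleed that holds VCC at the setpoint, plus a
    linear viable-cell-diameter ramp (default +20% over days 7-10) and a mild
    logistic viability decline.
    """

    duration_days: float = 26.0
    batch_phase_days: float = 3.0
    specific_growth_rate_per_day: float = 0.60
    death_rate_per_day: float = 0.02
    initial_vcc_cells_per_mL: float = 0.5e6
    target_vcc_cells_per_mL: float = 50e6
    pid_gains: tuple[float, float, float] = (6.0, 9.0, 0.0)  # Kp [1/day], Ki [1/day^2], Kd [-]
    max_bleed_per_day: float = 2.0
    diameter_base_um: float = 15.0
    diameter_ramp: tuple[float, float, float] = (7.0, 10.0, 0.20)  # (start_day, end_day, fractional_increase)
    viability_start: float = 0.98
    viability_end: float = 0.90
    viability_midpoint_day: float = 16.0
    viability_steepness_per_day: float = 0.4
    offline_sampling_times: tuple[float, ...] | None = None  # days; None -> daily incl. both ends
    offline_vcc_cv: float = 0.05
    scan_interval_s: float = 30.0
    frequencies_kHz: tuple[float, ...] = field(default_factory=default_frequency_grid)
    time_step_days: float = 0.005
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_days < self.batch_phase_days:
            raise ValueError("duration must cover the batch phase")
        freqs = np.asarray(self.frequencies_kHz, dtype=float)
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if freqs[0] < 50.0 or freqs[-1] > 20000.0:
            raise ValueError("frequencies must lie within [50, 20000] kHz")
        if self.diameter_ramp[2] < 0:
            raise ValueError("diameter ramp fractional increase must be >= 0")
        if self.diameter_ramp[1] < self.diameter_ramp[0]:
            raise ValueError("diameter ramp end must not precede its start")
        if self.initial_vcc_cells_per_mL <= 0:
            raise ValueError("initial VCC must be > 0")
        if self.scan_interval_s <= 0 or self.time_step_days <= 0:
            raise ValueError("scan interval and time step must be > 0")
        if not 0 < self.viability_end <= 1 or not 0 < self.viability_start <= 1:
            raise ValueError("viabilities must lie in (0, 1]")
        if self.offline_vcc_cv < 0:
            raise ValueError("offline VCC CV must be >= 0")

    def sampling_times_days(self) -> np.ndarray:
        if self.offline_sampling_times is not None:
            return np.asarray(self.offline_sampling_times, dtype=float)
        return np.arange(0.0, math.floor(self.duration_days) + 1.0)


@dataclass
class ProcessTrajectory:
    """Ground-truth time course of one simulated run (dense grid, days)."""

    times_days: np.ndarray
    vcc_cells_per_mL: np.ndarray
    diameter_um: np.ndarray
    viability_fraction: np.ndarray
    bleed_rate: np.ndarray  # volume fraction per day

    def __post_init__(self) -> None:
        n = len(self.times_days)
        for name in ("vcc_cells_per_mL", "diameter_um", "viability_fraction", "bleed_rate"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")
        if np.any(self.vcc_cells_per_mL < 0):
            raise ValueError("VCC must be >= 0")
        if np.any(self.diameter_um <= 0):
            raise ValueError("diameter must be > 0")
        if np.any((self.viability_fraction < 0) | (self.viability_fraction > 1)):
            raise ValueError("viability must lie in [0, 1]")


@dataclass
class SpectrumRecord:
    """One timestamped capacitance scan (seconds since run start; pF/cm)."""

    timestamp: float
    capacitance_pF_per_cm: np.ndarray

    def __post_init__(self) -> None:
        self.capacitance_pF_per_cm = np.asarray(self.capacitance_pF_per_cm, dtype=float)
        if not np.all(np.isfinite(self.capacitance_pF_per_cm)):
            raise ValueError("capacitance values must be finite")


@dataclass
class OfflineSample:
    """One manual reference sample (cell-counter style)."""

    timestamp: float
    vcc_cells_per_mL: float
    viability_fraction: float
    diameter_um: float

    def __post_init__(self) -> None:
        if self.vcc_cells_per_mL < 0:
            raise ValueError("VCC must be >= 0")


def _diameter_at(t_days: np.ndarray, config: ProcessConfig) -> np.ndarray:
    start, end, frac = config.diameter_ramp
    base = config.diameter_base_um
    if end == start:
        ramp = np.where(t_days >= end, frac, 0.0)
    else:
        ramp = np.clip((t_days - start) / (end - start), 0.0, 1.0) * frac
    return base * (1.0 + ramp)


def _viability_at(t_days: np.ndarray, config: ProcessConfig) -> np.ndarray:
    lo, hi = config.viability_end, config.viability_start
    if hi == lo:
        return np.full_like(np.asarray(t_days, dtype=float), hi)
    z = config.viability_steepness_per_day * (np.asarray(t_days, dtype=float) - config.viability_midpoint_day)
    return lo + (hi - lo) / (1.0 + np.exp(z))


def simulate_process(config: ProcessConfig) -> ProcessTrajectory:
    """Integrate one perfusion run: batch growth, then PID-regulated cell bleed.

    Batch phase (and before the setpoint is first reached):
    ``dV/dt = (mu - kd) V`` with no bleed.  Once the VCC first reaches the
    setpoint, a positional discrete-time PID acting on the normalized error
    ``(V - setpoint)/setpoint`` sets the bleed rate, clamped to
    ``[0, max_bleed]`` with conditional-integration anti-windup, and
    ``dV/dt = (mu - kd - bleed) V``.  Deterministic given the config.
    """
    dt = config.time_step_days
    n_steps = int(round(config.duration_days / dt))
    times = np.arange(n_steps + 1) * dt
    mu = config.specific_growth_rate_per_day
    kd = config.death_rate_per_day
    kp, ki, kd_gain = config.pid_gains
    setpoint = config.target_vcc_cells_per_mL

    vcc = np.empty(n_steps + 1)
    bleed = np.zeros(n_steps + 1)
    vcc[0] = config.initial_vcc_cells_per_mL
    controlling = False
    integral = 0.0
    prev_err = 0.0

    for i in range(n_steps):
        t = times[i]
        v = float(vcc[i])
        if not math.isfinite(v):
            raise SimulationError(f"non-finite VCC reached on day {t:.2f}; reduce growth rate or time step")
        b = 0.0
        if t >= config.batch_phase_days:
            if not controlling and np.isfinite(setpoint) and v >= setpoint:
                controlling = True
                prev_err = (v - setpoint) / setpoint  # avoid derivative kick at onset
            if controlling:
                err = (v - setpoint) / setpoint
                derivative = (err - prev_err) / dt
                raw = kp * err + ki * integral + kd_gain * derivative
                b = min(max(raw, 0.0), config.max_bleed_per_day)
                if raw == b:  # integrate only while unclamped (anti-windup)
                    integral += err * dt
                prev_err = err
        bleed[i] = b
        vcc[i + 1] = v * math.exp((mu - kd - b) * dt)

    bleed[n_steps] = bleed[n_steps - 1] if controlling else 0.0
    if not np.all(np.isfinite(vcc)):
        raise SimulationError(f"non-finite VCC at end of run (day {times[-1]:.2f})")
    return ProcessTrajectory(
        times_days=times,
        vcc_cells_per_mL=vcc,
        diameter_um=_diameter_at(times, config),
        viability_fraction=_viability_at(times, config),
        bleed_rate=bleed,
    )


def _dispersion_terms(vcc, diameter_um, params: DielectricParams):
    """Return (delta_eps, fc_kHz, biovolume_fraction) for viable states."""
    vcc = np.asarray(vcc, dtype=float)
    diameter_um = np.asarray(diameter_um, dtype=float)
    r = diameter_um * 1e-6 / 2.0  # m
    n_per_m3 = vcc * 1e6          # cells/mL -> cells/m^3
    p = n_per_m3 * (4.0 / 3.0) * np.pi * r**3
    cm = params.membrane_capacitance_Cm
    delta_eps = 9.0 * r * p * cm / 4.0
    tau_like = r * cm * (1.0 / params.cytoplasm_conductivity_sigma_i
                         + 1.0 / (2.0 * params.medium_conductivity_sigma_m))
    fc_hz = 1.0 / (2.0 * np.pi * tau_like)
    return delta_eps, fc_hz / 1e3, p


def _cole_cole_real(f_over_fc, alpha: float):
    """Re[1 / (1 + (j x)^(1-alpha))] for x = f/fc, evaluated real-valued."""
    x = np.asarray(f_over_fc, dtype=float)
    b = 1.0 - alpha
    xb = np.power(x, b, where=x > 0, out=np.zeros_like(x))
    c = math.cos(math.pi * b / 2.0)
    s = math.sin(math.pi * b / 2.0)
    re = (1.0 + xb * c) / ((1.0 + xb * c) ** 2 + (xb * s) ** 2)
    return np.where(x > 0, re, 1.0)


def beta_dispersion_capacitance(vcc, diameter_um, frequency_kHz, params: DielectricParams):
    """Capacitance (pF/cm) of a viable-cell suspension at one frequency.

    Implements the dilute-suspension beta dispersion: the permittivity
    increment ``delta_eps = 9 r P Cm / 4`` (P the biovolume fraction) relaxes
    around the characteristic frequency
    ``fc = 1 / (2 pi r Cm (1/sigma_i + 1/(2 sigma_m)))`` following a
    Cole-Cole law with broadening exponent alpha; the measured capacitance is
    ``Cinf + cell_constant * delta_eps * Re[1/(1 + (j f/fc)^(1-alpha))]``.

    Broadcasts over numpy arrays; scalar inputs return a scalar.
    """
    vcc_a = np.asarray(vcc, dtype=float)
    d_a = np.asarray(diameter_um, dtype=float)
    f_a = np.asarray(frequency_kHz, dtype=float)
    if np.any(~np.isfinite(vcc_a)) or np.any(~np.isfinite(d_a)) or np.any(~np.isfinite(f_a)):
        raise ValueError("all inputs must be finite")
    if np.any(vcc_a < 0) or np.any(d_a <= 0) or np.any(f_a < 0):
        raise ValueError("VCC must be >= 0, diameter > 0, frequency >= 0")
    delta_eps, fc_kHz, p = _dispersion_terms(vcc_a, d_a, params)
    if np.any(p >= 1.0):
        raise ValueError(f"non-physical biovolume fraction >= 1 (max {np.max(p):.3f}); lower VCC or diameter")
    re = _cole_cole_real(f_a / fc_kHz, params.cole_cole_alpha)
    out = params.baseline_capacitance_Cinf + params.cell_constant * delta_eps * re
    return out if out.ndim else float(out)


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    """Independent named substreams so enabling one noise source never shifts another."""
    spectra_ss, offline_ss = np.random.SeedSequence(seed).spawn(2)
    return {"spectra": np.random.default_rng(spectra_ss), "offline": np.random.default_rng(offline_ss)}


def generate_spectra(traj: ProcessTrajectory, params: DielectricParams, config: ProcessConfig) -> list[SpectrumRecord]:
    """Render the capacitance scans a probe would log during ``traj``.

    One scan per ``scan_interval_s`` from t=0 to the end of the trajectory;
    the dispersion is driven by the viable biovolume state
    (``VCC x viability``, interpolated) and i.i.d. Gaussian noise of sd
    ``spectrum_noise_sd`` is added per frequency (seeded substream).
    """
    if len(traj.times_days) == 0:
        raise ValueError("empty trajectory")
    t_end_s = traj.times_days[-1] * 86400.0
    scan_t = np.arange(0.0, t_end_s + 1e-9, config.scan_interval_s)
    t_days = scan_t / 86400.0
    viable = np.interp(t_days, traj.times_days, traj.vcc_cells_per_mL * traj.viability_fraction)
    diam = np.interp(t_days, traj.times_days, traj.diameter_um)
    freqs = np.asarray(config.frequencies_kHz, dtype=float)

    delta_eps, fc_kHz, p = _dispersion_terms(viable, diam, params)
    if np.any(p >= 1.0):
        raise ValueError("non-physical biovolume fraction >= 1 during run")
    re = _cole_cole_real(freqs[None, :] / fc_kHz[:, None], params.cole_cole_alpha)
    cap = params.baseline_capacitance_Cinf + params.cell_constant * delta_eps[:, None] * re
    if params.spectrum_noise_sd > 0:
        rng = _rngs(config.rng_seed)["spectra"]
        cap = cap + rng.normal(0.0, params.spectrum_noise_sd, size=cap.shape)
    return [SpectrumRecord(timestamp=float(t), capacitance_pF_per_cm=row) for t, row in zip(scan_t, cap)]


def sample_offline(traj: ProcessTrajectory, config: ProcessConfig) -> list[OfflineSample]:
    """Draw the manual reference samples: VCC with multiplicative counting noise.

    VCC is perturbed by a Gaussian factor with CV ``offline_vcc_cv`` (seeded
    substream); diameter and viability are reported at trajectory values.
    """
    t_days = config.sampling_times_days()
    t0, t1 = traj.times_days[0], traj.times_days[-1]
    bad = t_days[(t_days < t0) | (t_days > t1)]
    if bad.size:
        raise ValueError(f"sampling times outside trajectory span [{t0}, {t1}] days: {bad.tolist()}")
    vcc = np.interp(t_days, traj.times_days, traj.vcc_cells_per_mL)
    viab = np.interp(t_days, traj.times_days, traj.viability_fraction)
    diam = np.interp(t_days, traj.times_days, traj.diameter_um)
    if config.offline_vcc_cv > 0:
        rng = _rngs(config.rng_seed)["offline"]
        vcc = vcc * (1.0 + rng.normal(0.0, config.offline_vcc_cv, size=vcc.shape))
        vcc = np.maximum(vcc, 0.0)
    return [
        OfflineSample(timestamp=float(t * 86400.0), vcc_cells_per_mL=float(v),
                      viability_fraction=float(w), diameter_um=float(d))
        for t, v, w, d in zip(t_days, vcc, viab, diam)
    ]
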