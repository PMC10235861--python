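"""Canonical virtual-campaign conditions used for calibration and validation.

A campaign mirrors the study design the sensor is meant for: three
calibration perfusion runs at different VCC setpoints (so cell concentration
decorrelates from batch maturity) plus one validation run never seen during
calibration.  The default "drift" conditions include the +20% viable-cell
diameter ramp over days 7-10, a mild viability decline, and measurement noise
on both spectra and offline counts; the "constant-diameter" conditions switch
off drift and noise for parameter-recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .preprocess import CalibrationDataset, concat_datasets, merge_with_reference, rolling_mean
from .simulate import (
    DielectricParams,
    ProcessConfig,
    generate_spectra,
    sample_offline,
    simulate_process,
)

__all__ = [
    "CALIBRATION_TARGETS",
    "VALIDATION_TARGET",
    "drift_config",
    "constant_diameter_config",
    "run_to_dataset",
    "build_campaign",
    "Campaign",
]

CALIBRATION_TARGETS = (30e6, 50e6, 70e6)  # cells/mL; distinct setpoints per run
VALIDATION_TARGET = 40e6

# Inter-batch base-diameter variation for the constant-diameter (parameter-
# recovery) campaign.  Each run's diameter is constant in time but differs
# slightly between batches, as real inocula do; this is the y-orthogonal
# spectral-shape variation the orthogonal components absorb.  The validation
# batch lies at the centre of the calibrated range.
CONSTANT_DIAMETER_BASES_UM = (14.4, 15.0, 15.6)
CONSTANT_DIAMETER_VALIDATION_UM = 15.0


def drift_config(seed: int, target_vcc: float = VALIDATION_TARGET, **overrides) -> ProcessConfig:
    """Default study conditions: diameter ramp, viability decline, noise on."""
    return ProcessConfig(target_vcc_cells_per_mL=target_vcc, rng_seed=seed, **overrides)


def constant_diameter_config(seed: int, target_vcc: float = VALIDATION_TARGET, **overrides) -> ProcessConfig:
    """Noise-free, drift-free conditions: constant diameter and viability."""
    cfg = ProcessConfig(
        target_vcc_cells_per_mL=target_vcc,
        diameter_ramp=(7.0, 10.0, 0.0),
        viability_end=0.98,
        viability_start=0.98,
        offline_vcc_cv=0.0,
        rng_seed=seed,
        **overrides,
    )
    return cfg


def noise_free(params: DielectricParams) -> DielectricParams:
    return replace(params, spectrum_noise_sd=0.0)


def run_to_dataset(
    config: ProcessConfig,
    params: DielectricParams,
    batch_id: str,
    window_s: float = 300.0,
    tolerance_s: float = 150.0,
) -> CalibrationDataset:
    """Simulate one run and assemble its calibration rows.

    Pipeline: integrate the process, render scans, 5-min trailing rolling
    mean, merge with the offline references.
    """
    traj = simulate_process(config)
    spectra = generate_spectra(traj, params, config)
    offline = sample_offline(traj, config)
    smoothed = rolling_mean(spectra, window_s=window_s)
    return merge_with_reference(
        smoothed, offline, tolerance_s=tolerance_s, batch_id=batch_id,
        frequencies_kHz=np.asarray(config.frequencies_kHz),
    )


@dataclass
class Campaign:
    calibration: CalibrationDataset
    validation: CalibrationDataset
    validation_config: ProcessConfig


def build_campaign(
    seed: int,
    params: DielectricParams | None = None,
    drift: bool = True,
    calibration_targets=CALIBRATION_TARGETS,
    validation_target: float = VALIDATION_TARGET,
    **config_overrides,
) -> Campaign:
    """Three calibration runs + one validation run under shared conditions.

    Per-run RNG seeds are derived deterministically from ``seed`` so separate
    runs never share noise realizations.
    """
    params = params or DielectricParams()
    maker = drift_config if drift else constant_diameter_config
    cal_sets = []
    for i, target in enumerate(calibration_targets):
        overrides = dict(config_overrides)
        if not drift:
            overrides.setdefault("diameter_base_um", CONSTANT_DIAMETER_BASES_UM[i % len(CONSTANT_DIAMETER_BASES_UM)])
        cfg = maker(seed=(seed * 8 + i) % (2**31), target_vcc=target, **overrides)
        cal_sets.append(run_to_dataset(cfg, params, batch_id=f"cal{i + 1}"))
    val_overrides = dict(config_overrides)
    if not drift:
        val_overrides.setdefault("diameter_base_um", CONSTANT_DIAMETER_VALIDATION_UM)
    val_cfg = maker(seed=(seed * 8 + len(calibration_targets)) % (2**31),
                    target_vcc=validation_target, **val_overrides)
    validation = run_to_dataset(val_cfg, params, batch_id="val")
    return Campaign(calibration=concat_datasets(cal_sets), validation=validation, validation_config=val_cfg)
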