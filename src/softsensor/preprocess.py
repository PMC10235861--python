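"""Calibration-dataset assembly: rolling-mean smoothing, reference merge, scaling.

The calibration contract used throughout the package: capacitance predictors
are mean-centered only (no variance scaling, so high-capacitance frequencies
legitimately dominate), the VCC response is autoscaled (centered and scaled to
unit variance, sample sd with n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .simulate import OfflineSample, SpectrumRecord

__all__ = [
    "CalibrationDataset",
    "ScalingParams",
    "rolling_mean",
    "merge_with_reference",
    "concat_datasets",
    "fit_scaling",
    "apply_x_scaling",
    "apply_y_scaling",
    "invert_y_scaling",
]

logger = logging.getLogger(__name__)


@dataclass
class CalibrationDataset:
    """Paired spectra/reference rows ready for model fitting.

    X: (n_samples, n_frequencies) capacitance in pF/cm; y: VCC in cells/mL.
    """

    X: np.ndarray
    y: np.ndarray
    sample_timestamps: np.ndarray  # seconds
    batch_ids: np.ndarray          # run label per row
    frequencies_kHz: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float)
        self.sample_timestamps = np.asarray(self.sample_timestamps, dtype=float)
        self.batch_ids = np.asarray(self.batch_ids)
        self.frequencies_kHz = np.asarray(self.frequencies_kHz, dtype=float)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.sample_timestamps) == len(self.batch_ids) == n):
            raise ValueError("X rows, y, timestamps and batch ids must have equal length")
        if self.X.shape[1] != len(self.frequencies_kHz):
            raise ValueError("X columns must match frequency grid")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("dataset contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "CalibrationDataset":
        idx = np.asarray(idx)
        return CalibrationDataset(
            X=self.X[idx], y=self.y[idx], sample_timestamps=self.sample_timestamps[idx],
            batch_ids=self.batch_ids[idx], frequencies_kHz=self.frequencies_kHz,
        )


@dataclass
class ScalingParams:
    """Centering/scaling constants fitted on a calibration set."""

    x_mean: np.ndarray
    y_mean: float
    y_sd: float

    def __post_init__(self) -> None:
        self.x_mean = np.asarray(self.x_mean, dtype=float)
        if self.y_sd <= 0:
            raise ValueError("y_sd must be > 0")


def _timestamps(spectra: list[SpectrumRecord]) -> np.ndarray:
    return np.asarray([rec.timestamp for rec in spectra], dtype=float)


def rolling_mean(spectra: list[SpectrumRecord], window_s: float = 300.0) -> list[SpectrumRecord]:
    """Causal (trailing) rolling mean over a time window.

    The record at time t becomes the unweighted mean of all records with
    timestamp in (t - window_s, t]; early records average over fewer points,
    so output length equals input length.  The trailing form matches what a
    streaming consumer can compute, keeping batch calibration and online
    prediction identical.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if not spectra:
        return []
    times = _timestamps(spectra)
    if np.any(np.diff(times) < 0):
        raise ValueError("spectra must be time-sorted (refusing to sort silently)")
    X = np.stack([rec.capacitance_pF_per_cm for rec in spectra])
    # left[i] = first index with time > t_i - window (window open on the left)
    left = np.searchsorted(times, times - window_s, side="right")
    out = []
    for i, rec in enumerate(spectra):
        avg = np.mean(X[left[i]: i + 1], axis=0)
        out.append(SpectrumRecord(timestamp=rec.timestamp, capacitance_pF_per_cm=avg))
    return out


def merge_with_reference(
    spectra: list[SpectrumRecord],
    offline: list[OfflineSample],
    tolerance_s: float = 150.0,
    batch_id: str = "run",
    frequencies_kHz=None,
) -> CalibrationDataset:
    """Pair each offline reference with the nearest-in-time spectrum.

    References farther than ``tolerance_s`` from any spectrum are dropped with
    a logged warning.  Duplicate reference timestamps and an empty match set
    are errors.
    """
    if not spectra or not offline:
        raise ValueError("both spectra and offline references must be non-empty")
    times = _timestamps(spectra)
    if np.any(np.diff(times) < 0):
        raise ValueError("spectra must be time-sorted")
    off_t = np.asarray([s.timestamp for s in offline], dtype=float)
    if np.any(np.diff(off_t) < 0):
        raise ValueError("offline references must be time-sorted")
    if len(np.unique(off_t)) != len(off_t):
        raise ValueError("duplicate offline reference timestamps")

    rows, ys, ts = [], [], []
    n_dropped = 0
    for sample in offline:
        i = int(np.searchsorted(times, sample.timestamp))
        candidates = [j for j in (i - 1, i) if 0 <= j < len(times)]
        j_best = min(candidates, key=lambda j: abs(times[j] - sample.timestamp))
        if abs(times[j_best] - sample.timestamp) > tolerance_s:
            logger.warning(
                "offline reference at t=%.0f s is %.0f s from the nearest spectrum; dropped",
                sample.timestamp, abs(times[j_best] - sample.timestamp),
            )
            n_dropped += 1
            continue
        rows.append(spectra[j_best].capacitance_pF_per_cm)
        ys.append(sample.vcc_cells_per_mL)
        ts.append(sample.timestamp)
    if not rows:
        raise ValueError("no offline reference matched any spectrum within tolerance")
    if n_dropped:
        logger.warning("%d offline reference(s) dropped during merge", n_dropped)
    n_freq = len(rows[0])
    freqs = np.arange(n_freq, dtype=float) if frequencies_kHz is None else np.asarray(frequencies_kHz, dtype=float)
    return CalibrationDataset(
        X=np.stack(rows), y=np.asarray(ys), sample_timestamps=np.asarray(ts),
        batch_ids=np.asarray([batch_id] * len(ys)), frequencies_kHz=freqs,
    )


def concat_datasets(datasets: list[CalibrationDataset]) -> CalibrationDataset:
    """Stack several runs into one calibration set (grids must match)."""
    if not datasets:
        raise ValueError("nothing to concatenate")
    f0 = datasets[0].frequencies_kHz
    for d in datasets[1:]:
        if not np.array_equal(d.frequencies_kHz, f0):
            raise ValueError("frequency grids differ between datasets")
    return CalibrationDataset(
        X=np.vstack([d.X for d in datasets]),
        y=np.concatenate([d.y for d in datasets]),
        sample_timestamps=np.concatenate([d.sample_timestamps for d in datasets]),
        batch_ids=np.concatenate([d.batch_ids for d in datasets]),
        frequencies_kHz=f0,
    )


def fit_scaling(dataset: CalibrationDataset) -> ScalingParams:
    """Fit centering for X and autoscaling for y (sample sd, n-1)."""
    y_sd = float(np.std(dataset.y, ddof=1)) if dataset.n_samples > 1 else 0.0
    if y_sd == 0.0:
        raise ValueError("response is constant; cannot scale y to unit variance")
    return ScalingParams(
        x_mean=dataset.X.mean(axis=0),
        y_mean=float(dataset.y.mean()),
        y_sd=y_sd,
    )


def apply_x_scaling(X, params: ScalingParams) -> np.ndarray:
    return np.asarray(X, dtype=float) - params.x_mean


def apply_y_scaling(y, params: ScalingParams) -> np.ndarray:
    return (np.asarray(y, dtype=float) - params.y_mean) / params.y_sd


def invert_y_scaling(y_scaled, params: ScalingParams) -> np.ndarray:
    return np.asarray(y_scaled, dtype=float) * params.y_sd + params.y_mean
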