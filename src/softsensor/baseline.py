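"""Single-frequency linear VCC model — the conventional comparison arm.

Capacitance probes are routinely run at one frequency (nominally 580 kHz for
CHO) with a linear correlation to VCC.  That calibration is blind to changes
in cell diameter, which inflate the capacitance at fixed cell count; the
model here exists to quantify exactly that failure mode against the
multifrequency O-PLS sensor.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .preprocess import CalibrationDataset

__all__ = ["SingleFreqModel", "fit_single_frequency", "predict_single_frequency"]

logger = logging.getLogger(__name__)


@dataclass
class SingleFreqModel:
    """Affine map ``VCC = slope * C(grid_frequency) + intercept``."""

    frequency_kHz: float        # requested (nominal) frequency
    grid_frequency_kHz: float   # nearest column actually used
    slope: float                # cells/mL per pF/cm
    intercept: float            # cells/mL

    def predict(self, x, frequencies_kHz):
        return predict_single_frequency(self, x, frequencies_kHz)

    def to_dict(self) -> dict:
        return {
            "type": "single_frequency",
            "frequency_kHz": self.frequency_kHz,
            "grid_frequency_kHz": self.grid_frequency_kHz,
            "slope": self.slope,
            "intercept": self.intercept,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SingleFreqModel":
        if d.get("type") != "single_frequency":
            raise ValueError(f"not a single-frequency model file (type={d.get('type')!r})")
        return cls(frequency_kHz=float(d["frequency_kHz"]), grid_frequency_kHz=float(d["grid_frequency_kHz"]),
                   slope=float(d["slope"]), intercept=float(d["intercept"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SingleFreqModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_single_frequency(dataset: CalibrationDataset, frequency_kHz: float = 580.0,
                         with_intercept: bool = True) -> SingleFreqModel:
    """Ordinary least squares of VCC on the capacitance column nearest in
    frequency to the requested one (snapping is logged, never interpolated)."""
    if dataset.n_samples < 2:
        raise ValueError("need at least 2 samples")
    col = int(np.argmin(np.abs(dataset.frequencies_kHz - frequency_kHz)))
    grid_f = float(dataset.frequencies_kHz[col])
    if grid_f != frequency_kHz:
        logger.info("requested %.0f kHz snapped to nearest grid column %.0f kHz", frequency_kHz, grid_f)
    c = dataset.X[:, col]
    if np.ptp(c) == 0:
        raise ValueError(f"capacitance at {grid_f:g} kHz has zero variance; cannot fit")
    if with_intercept:
        slope, intercept = np.polyfit(c, dataset.y, 1)
    else:
        slope = float(c @ dataset.y / (c @ c))
        intercept = 0.0
    return SingleFreqModel(frequency_kHz=float(frequency_kHz), grid_frequency_kHz=grid_f,
                           slope=float(slope), intercept=float(intercept))


def predict_single_frequency(model: SingleFreqModel, x, frequencies_kHz):
    """Evaluate the affine model on the stored grid column of a spectrum."""
    freqs = np.asarray(frequencies_kHz, dtype=float)
    match = np.flatnonzero(np.isclose(freqs, model.grid_frequency_kHz, rtol=0, atol=1e-9))
    if match.size != 1:
        raise ValueError(
            f"model frequency {model.grid_frequency_kHz:g} kHz not present exactly once in grid"
        )
    x = np.asarray(x, dtype=float)
    c = x[..., match[0]]
    out = model.slope * c + model.intercept
    return float(out) if np.ndim(out) == 0 else out
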