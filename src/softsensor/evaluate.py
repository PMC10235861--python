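"""Model performance metrics: RMSEP, cross-validated RMSE, model comparison.

RMSE here is the root-mean-square error over prediction/reference pairs,
``sqrt(sum_i (yhat_i - y_i)^2 / n)``.  Applied to an external validation set
it is reported as RMSEP; applied to pooled held-out cross-validation
predictions it is reported as RMSEcv.  The two are kept distinct in every
report because they are not like-for-like quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .opls import fit_opls, predict_opls
from .preprocess import CalibrationDataset

__all__ = ["EvaluationReport", "rmse", "cross_validate", "compare_models"]


def rmse(predicted, observed) -> float:
    """Root-mean-square error over prediction/reference pairs."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError(f"length mismatch: {predicted.shape} vs {observed.shape}")
    if predicted.size == 0:
        raise ValueError("no prediction/reference pairs")
    return float(np.sqrt(np.mean((predicted - observed) ** 2)))


def _fold_indices(dataset: CalibrationDataset, n_folds: int) -> list[np.ndarray]:
    """Contiguous time blocks, rows ordered by (batch, time), to avoid
    temporal leakage between neighbouring scans."""
    batch_codes = np.unique(dataset.batch_ids, return_inverse=True)[1]
    order = np.lexsort((dataset.sample_timestamps, batch_codes))
    return [f for f in np.array_split(order, n_folds) if f.size]


def cross_validate(
    dataset: CalibrationDataset,
    n_ortho: int = 2,
    n_folds: int = 7,
    return_predictions: bool = False,
):
    """Leave-group-out cross-validation of the O-PLS model.

    Rows are partitioned into ``n_folds`` contiguous blocks (time-ordered
    within batch); each block is held out once, the model — including its
    scaling — is refit on the remainder, and the held-out rows are predicted.
    Returns RMSEcv over the pooled held-out predictions (and optionally the
    predictions themselves, aligned to dataset rows).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > dataset.n_samples:
        raise ValueError("more folds than samples")
    preds = np.full(dataset.n_samples, np.nan)
    for k, test_idx in enumerate(_fold_indices(dataset, n_folds)):
        train_idx = np.setdiff1d(np.arange(dataset.n_samples), test_idx)
        train = dataset.subset(train_idx)
        if np.ptp(train.y) == 0:
            raise ValueError(f"fold {k}: training response is constant; choose fewer folds")
        model = fit_opls(train, n_ortho=n_ortho)
        preds[test_idx] = predict_opls(model, dataset.X[test_idx])
    value = rmse(preds, dataset.y)
    return (value, preds) if return_predictions else value


@dataclass
class EvaluationReport:
    """Prediction-error summary of one model on one set of reference pairs."""

    model_id: str
    n_pairs: int
    rmsep: float                      # cells/mL
    mean_relative_error_pct: float    # mean |yhat - y| / y * 100 over y > 0
    residuals: np.ndarray             # yhat - y, aligned to input pairs
    windowed_rmsep: dict[str, float] = field(default_factory=dict)
    windowed_relative_error_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.n_pairs < 1:
            raise ValueError("need at least one prediction/reference pair")
        if self.rmsep < 0:
            raise ValueError("rmsep must be >= 0")


def _window_mask(t_days: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (t_days >= lo) & (t_days <= hi)


def compare_models(
    dataset: CalibrationDataset,
    models: dict[str, object],
    window_days: dict[str, tuple[float, float]] | None = None,
) -> dict[str, EvaluationReport]:
    """Evaluate several models on identical reference pairs.

    Every model is applied to the same rows of ``dataset`` (a validation set
    built like a calibration set: merged spectra + offline references), so
    RMSEP values are directly comparable.  ``window_days`` maps labels to
    (start, end) day ranges relative to the first sample; each yields a
    windowed RMSEP.  Relative error uses the observed VCC in the denominator
    and is computed over pairs with y > 0.
    """
    if not models:
        raise ValueError("no models to evaluate")
    if dataset.n_samples < 1:
        raise ValueError("no reference pairs")
    t_days = (dataset.sample_timestamps - dataset.sample_timestamps.min()) / 86400.0
    reports: dict[str, EvaluationReport] = {}
    for model_id, model in models.items():
        yhat = np.asarray(model.predict(dataset.X, dataset.frequencies_kHz), dtype=float)
        resid = yhat - dataset.y
        pos = dataset.y > 0
        rel = float(np.mean(np.abs(resid[pos]) / dataset.y[pos]) * 100.0) if pos.any() else float("nan")
        windows, win_rel = {}, {}
        for label, win in (window_days or {}).items():
            mask = _window_mask(t_days, win)
            if mask.any():
                windows[label] = rmse(yhat[mask], dataset.y[mask])
                wpos = mask & pos
                if wpos.any():
                    win_rel[label] = float(np.mean(np.abs(resid[wpos]) / dataset.y[wpos]) * 100.0)
        reports[model_id] = EvaluationReport(
            model_id=model_id, n_pairs=dataset.n_samples, rmsep=rmse(yhat, dataset.y),
            mean_relative_error_pct=rel, residuals=resid, windowed_rmsep=windows,
            windowed_relative_error_pct=win_rel,
        )
    return reports
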