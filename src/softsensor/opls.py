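"""O-PLS regression for a single response (NIPALS-based).

Orthogonal projections to latent structures split predictor variation into a
single y-predictive component and K y-orthogonal components.  The orthogonal
components absorb structured interference that is uncorrelated with the
response — here, the capacitance-spectrum shape change caused by cell-diameter
drift — before the predictive projection is made.

All fitting happens on scaled data (X centered, y autoscaled; see
``preprocess``).  Because centering, orthogonal deflation, projection and
unscaling are all affine, a fitted model collapses exactly to a flat linear
equation ``y = intercept + coefficients . x`` suitable for execution inside
dumb middleware; ``linearize`` performs that collapse symbolically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .preprocess import (
    CalibrationDataset,
    ScalingParams,
    apply_x_scaling,
    apply_y_scaling,
    fit_scaling,
    invert_y_scaling,
)

__all__ = ["OPLSModel", "LinearizedModel", "fit_opls", "predict_opls", "linearize"]

_WO_NORM_TOL = 1e-12


@dataclass
class OPLSModel:
    """Fitted O-PLS model: one predictive + ``n_ortho`` orthogonal components.

    Vectors live in the centered predictor space.  ``w`` (unit norm) is the
    predictive weight, ``p`` its loading, ``q`` the scalar response loading;
    ``W_ortho``/``P_ortho`` hold the orthogonal weights (unit norm, each
    orthogonal to ``w``) and loadings in fitting order.
    """

    scaling: ScalingParams
    w: np.ndarray
    p: np.ndarray
    q: float
    W_ortho: list[np.ndarray]
    P_ortho: list[np.ndarray]
    frequencies_kHz: np.ndarray
    r2_train: float = float("nan")
    x_variance_removed: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        self.W_ortho = [np.asarray(v, dtype=float) for v in self.W_ortho]
        self.P_ortho = [np.asarray(v, dtype=float) for v in self.P_ortho]
        self.frequencies_kHz = np.asarray(self.frequencies_kHz, dtype=float)

    @property
    def n_ortho(self) -> int:
        return len(self.W_ortho)

    def predict(self, x, frequencies_kHz=None):
        if frequencies_kHz is not None:
            _check_grid(frequencies_kHz, self.frequencies_kHz)
        return predict_opls(self, x)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "opls",
            "n_ortho": self.n_ortho,
            "frequencies_kHz": self.frequencies_kHz.tolist(),
            "x_mean": self.scaling.x_mean.tolist(),
            "y_mean": self.scaling.y_mean,
            "y_sd": self.scaling.y_sd,
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "q": self.q,
            "W_ortho": [v.tolist() for v in self.W_ortho],
            "P_ortho": [v.tolist() for v in self.P_ortho],
            "diagnostics": {"r2_train": self.r2_train, "x_variance_removed": self.x_variance_removed},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OPLSModel":
        if d.get("type") != "opls":
            raise ValueError(f"not an O-PLS model file (type={d.get('type')!r})")
        diag = d.get("diagnostics", {})
        return cls(
            scaling=ScalingParams(x_mean=np.asarray(d["x_mean"]), y_mean=d["y_mean"], y_sd=d["y_sd"]),
            w=np.asarray(d["w"]), p=np.asarray(d["p"]), q=float(d["q"]),
            W_ortho=[np.asarray(v) for v in d["W_ortho"]],
            P_ortho=[np.asarray(v) for v in d["P_ortho"]],
            frequencies_kHz=np.asarray(d["frequencies_kHz"]),
            r2_train=diag.get("r2_train", float("nan")),
            x_variance_removed=list(diag.get("x_variance_removed", [])),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "OPLSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class LinearizedModel:
    """Flat-equation export of an O-PLS model: ``y = intercept + coef . x``."""

    intercept: float
    coefficients: np.ndarray
    frequencies_kHz: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.frequencies_kHz = np.asarray(self.frequencies_kHz, dtype=float)
        if len(self.coefficients) != len(self.frequencies_kHz):
            raise ValueError("coefficient length must match frequency grid")

    def predict(self, x, frequencies_kHz=None):
        if frequencies_kHz is not None:
            _check_grid(frequencies_kHz, self.frequencies_kHz)
        x = np.asarray(x, dtype=float)
        if x.shape[-1] != len(self.coefficients):
            raise ValueError(
                f"spectrum has {x.shape[-1]} channels, model expects {len(self.coefficients)} "
                f"(grid {self.frequencies_kHz[0]:g}-{self.frequencies_kHz[-1]:g} kHz)"
            )
        out = self.intercept + x @ self.coefficients
        return float(out) if np.ndim(out) == 0 else out

    def to_dict(self) -> dict:
        return {
            "type": "linear_equation",
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "frequencies_kHz": self.frequencies_kHz.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LinearizedModel":
        if d.get("type") != "linear_equation":
            raise ValueError(f"not a linear-equation model file (type={d.get('type')!r})")
        return cls(intercept=float(d["intercept"]), coefficients=np.asarray(d["coefficients"]),
                   frequencies_kHz=np.asarray(d["frequencies_kHz"]))

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "LinearizedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_grid(given, expected) -> None:
    given = np.asarray(given, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if given.shape != expected.shape or not np.allclose(given, expected, rtol=0, atol=1e-9):
        raise ValueError(
            f"frequency grid mismatch: model expects {expected.tolist()} kHz"
        )


def fit_opls(dataset: CalibrationDataset, n_ortho: int = 2) -> OPLSModel:
    """Fit the single-response NIPALS O-PLS recursion.

    On centered X and autoscaled y: ``w = X'y / ||X'y||`` (invariant under the
    orthogonal deflation that follows, so computed once); then for each of the
    ``n_ortho`` rounds: ``t = Xw``, ``p = X't/(t't)``,
    ``w_o = p - (w'p)w`` normalized, ``t_o = Xw_o``,
    ``p_o = X't_o/(t_o't_o)``, ``X <- X - t_o p_o'``; finally ``t = Xw`` and
    ``q = y't/(t't)``.
    """
    if n_ortho < 0:
        raise ValueError("n_ortho must be >= 0")
    if dataset.n_samples <= n_ortho + 1:
        raise ValueError(f"need more than {n_ortho + 1} samples to fit 1 predictive + {n_ortho} orthogonal components")
    scaling = fit_scaling(dataset)
    X = apply_x_scaling(dataset.X, scaling)
    y = apply_y_scaling(dataset.y, scaling)
    total_xvar = float(np.sum(X**2))

    cov = X.T @ y
    cov_norm = float(np.linalg.norm(cov))
    if cov_norm < 1e-14:
        raise ValueError("predictors are uncorrelated with the response (||X'y|| = 0)")
    w = cov / cov_norm

    W_ortho: list[np.ndarray] = []
    P_ortho: list[np.ndarray] = []
    x_removed: list[float] = []
    for k in range(n_ortho):
        t = X @ w
        p = X.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = float(np.linalg.norm(w_o))
        if norm < _WO_NORM_TOL:
            raise ValueError(
                f"no y-orthogonal predictor variation left at component {k + 1}; refit with n_ortho={k}"
            )
        w_o = w_o / norm
        t_o = X @ w_o
        p_o = X.T @ t_o / (t_o @ t_o)
        X = X - np.outer(t_o, p_o)
        W_ortho.append(w_o)
        P_ortho.append(p_o)
        x_removed.append(float(np.sum(np.outer(t_o, p_o) ** 2)) / total_xvar if total_xvar > 0 else 0.0)

    t = X @ w
    q = float(y @ t / (t @ t))
    p = X.T @ t / (t @ t)

    resid = y - q * t
    ss_tot = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else float("nan")
    return OPLSModel(
        scaling=scaling, w=w, p=p, q=q, W_ortho=W_ortho, P_ortho=P_ortho,
        frequencies_kHz=dataset.frequencies_kHz, r2_train=r2, x_variance_removed=x_removed,
    )


def predict_opls(model: OPLSModel, x):
    """Predict VCC from one spectrum (1-D) or a stack of spectra (2-D).

    Centers the input, strips each orthogonal component in fitting order
    (``t_o = x'w_o``, ``x <- x - t_o p_o``), projects on the predictive
    weight and unscales: ``y = y_mean + y_sd * q * (x'w)``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    n_freq = len(model.w)
    if X.shape[1] != n_freq:
        raise ValueError(
            f"spectrum has {X.shape[1]} channels, model expects {n_freq} "
            f"(grid {model.frequencies_kHz[0]:g}-{model.frequencies_kHz[-1]:g} kHz)"
        )
    Xc = apply_x_scaling(X, model.scaling)
    for w_o, p_o in zip(model.W_ortho, model.P_ortho):
        t_o = Xc @ w_o
        Xc = Xc - np.outer(t_o, p_o)
    t = Xc @ model.w
    y = invert_y_scaling(model.q * t, model.scaling)
    return float(y[0]) if single else y


def linearize(model: OPLSModel) -> LinearizedModel:
    """Collapse the affine prediction chain to ``y = intercept + coef . x``.

    With D the ordered deflation product ``prod_k (I - w_ok p_ok')`` applied
    to row vectors, ``coefficients = y_sd * q * (D w)`` and
    ``intercept = y_mean - coefficients . x_mean``.
    """
    n = len(model.w)
    D = np.eye(n)
    for w_o, p_o in zip(model.W_ortho, model.P_ortho):
        D = D @ (np.eye(n) - np.outer(w_o, p_o))
    coef = model.scaling.y_sd * model.q * (D @ model.w)
    intercept = model.scaling.y_mean - float(coef @ model.scaling.x_mean)
    return LinearizedModel(intercept=intercept, coefficients=coef, frequencies_kHz=model.frequencies_kHz)
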