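"""T-wave drift-time -> collisional-cross-section calibration.

Traveling-wave ion mobility has no closed-form relation between drift time
and collisional cross-section, so the instrument is calibrated with species
of known Omega via the empirical power law

    Omega = c * q * t_D**X

with q the charge, c an instrument-scale parameter constant within one
experiment, and X an empirically fitted exponent. The calibrator fits
(c, X) to calibrant triples (q, t_D, Omega_ref) by nonlinear least squares,
initialized from the log-log line fit of ln(Omega/q) against ln(t_D);
conversions outside the calibrated drift-time range are flagged as
extrapolations rather than refused.

The estimator follows the scikit-learn protocol (``fit(X, y)`` /
``predict(X)`` with ``X = [[q, t_D], ...]``); :func:`fit_calibration` and
:func:`ccs_from_drift` are the corresponding functional surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "Calibrant",
    "CalibrationModel",
    "CCSResult",
    "PowerLawCCSCalibrator",
    "fit_calibration",
    "ccs_from_drift",
    "synthetic_calibrants",
    "read_calibrants",
    "write_model",
    "read_model",
]


@dataclass(frozen=True)
class Calibrant:
    """A species of known collisional cross-section."""

    label: str
    q: int
    t_d: float  # ms
    omega_ref: float  # A^2

    def __post_init__(self) -> None:
        if self.q < 1 or self.t_d <= 0 or self.omega_ref <= 0:
            raise ValueError("need q >= 1, t_d > 0, omega_ref > 0")


@dataclass(frozen=True)
class CalibrationModel:
    """Fitted (c, X) pair of the power law with its validity range."""

    c: float
    x: float
    t_min: float
    t_max: float
    rmse: float = 0.0

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be positive")
        if not 0 < self.x < 2:
            raise ValueError("exponent X must lie in (0, 2)")
        if not self.t_min < self.t_max:
            raise ValueError("need t_min < t_max")

    def omega(self, t_d: float, q: int) -> float:
        return self.c * q * t_d ** self.x

    def in_range(self, t_d: float) -> bool:
        return self.t_min <= t_d <= self.t_max


@dataclass(frozen=True)
class CCSResult:
    omega: float  # A^2
    in_range: bool  # False marks an extrapolation beyond the calibrated range


class PowerLawCCSCalibrator(RegressorMixin, BaseEstimator):
    """Fit Omega = c * q * t_D**X to calibrants and predict cross-sections.

    Parameters
    ----------
    c0, x0 : float or None
        Optional starting values; by default the start comes from the
        ordinary least-squares line fit of ln(Omega/q) vs ln(t_D), which is
        exact for noise-free power-law data.

    Attributes
    ----------
    c_, x_ : float
        Fitted scale and exponent.
    valid_range_ : tuple of float
        [min, max] calibrant drift time; predictions outside are extrapolations.
    rmse_ : float
        Root-mean-square residual of the fit, A^2.
    model_ : CalibrationModel
        The fitted parameters as an immutable record.
    """

    def __init__(self, c0: float | None = None, x0: float | None = None):
        self.c0 = c0
        self.x0 = x0

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [q, t_D]")
        if len(X) != len(y):
            raise ValueError("X and y length mismatch")
        q, t = X[:, 0], X[:, 1]
        if len(X) < 2 or len(np.unique(t)) < 2:
            raise ValueError("need >= 2 calibrants with >= 2 distinct drift times")
        if np.any(q < 1) or np.any(t <= 0) or np.any(y <= 0):
            raise ValueError("need q >= 1, t_D > 0, Omega > 0")

        # log-log line fit: ln(Omega/q) = ln c + X ln t
        slope, intercept = np.polyfit(np.log(t), np.log(y / q), 1)
        x0 = self.x0 if self.x0 is not None else float(slope)
        c0 = self.c0 if self.c0 is not None else float(np.exp(intercept))

        # relative residuals: calibrant uncertainty is multiplicative, and the
        # standard T-wave protocol fits the power law in log-log space — a
        # relative-error objective is its nonlinear counterpart and keeps the
        # exponent variance at the log-line level under multiplicative noise
        def resid(p):
            return (p[0] * q * t ** p[1] - y) / y

        sol = least_squares(
            resid, x0=[c0, x0], bounds=([1e-12, 1e-6], [np.inf, 2.0]), xtol=1e-14,
            ftol=1e-14, gtol=1e-14,
        )
        if not sol.success:
            raise RuntimeError(f"calibration fit did not converge: {sol.message}")
        self.c_, self.x_ = float(sol.x[0]), float(sol.x[1])
        self.valid_range_ = (float(t.min()), float(t.max()))
        self.rmse_ = float(np.sqrt(np.mean((self.c_ * q * t**self.x_ - y) ** 2)))
        self.model_ = CalibrationModel(
            c=self.c_, x=self.x_, t_min=self.valid_range_[0],
            t_max=self.valid_range_[1], rmse=self.rmse_,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "c_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): columns [q, t_D]")
        return self.c_ * X[:, 0] * X[:, 1] ** self.x_


def fit_calibration(calibrants) -> CalibrationModel:
    """Fit the power law to a list of :class:`Calibrant` (or a DataFrame)."""
    if isinstance(calibrants, pd.DataFrame):
        q = calibrants["q"].to_numpy(dtype=float)
        t = calibrants["t_d"].to_numpy(dtype=float)
        omega = calibrants["omega_ref"].to_numpy(dtype=float)
    else:
        q = np.array([c.q for c in calibrants], dtype=float)
        t = np.array([c.t_d for c in calibrants], dtype=float)
        omega = np.array([c.omega_ref for c in calibrants], dtype=float)
    est = PowerLawCCSCalibrator().fit(np.column_stack([q, t]), omega)
    return est.model_


def ccs_from_drift(t_d: float, q: int, model: CalibrationModel) -> CCSResult:
    """Convert one drift time to a cross-section; flags extrapolation."""
    if q < 1:
        raise ValueError(f"charge must be >= 1, got {q}")
    if t_d <= 0:
        raise ValueError("drift time must be positive")
    return CCSResult(omega=model.omega(t_d, q), in_range=model.in_range(t_d))


def synthetic_calibrants(
    n: int = 15,
    c: float = 53.1,
    x: float = 0.652,
    t_range: tuple[float, float] = (6.0, 17.0),
    charges: tuple[int, ...] = (6, 7, 8, 9, 10, 11, 12),
    noise: float = 0.0,
    seed: int | None = None,
) -> list[Calibrant]:
    """Synthetic calibrant set drawn exactly from a known power law.

    Stands in for a real calibrant table (the reference cross-sections of
    the usual protein standards — ubiquitin, cytochrome c, myoglobin — are
    instrument-protocol data, not shipped here). ``noise`` applies
    multiplicative Gaussian perturbation of that relative size to omega_ref.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(*t_range, n)
    q = np.array([charges[i % len(charges)] for i in range(n)])
    omega = c * q * t ** x
    if noise > 0:
        omega = omega * (1.0 + noise * rng.standard_normal(n))
    return [
        Calibrant(label=f"cal{i:02d}", q=int(q[i]), t_d=float(t[i]), omega_ref=float(omega[i]))
        for i in range(n)
    ]


def read_calibrants(path) -> list[Calibrant]:
    """Read a calibrant CSV with columns label, q, tD_ms, ccs_A2."""
    df = pd.read_csv(path)
    required = {"label", "q", "tD_ms", "ccs_A2"}
    if not required.issubset(df.columns):
        raise ValueError(f"calibrant CSV needs columns {sorted(required)}")
    return [
        Calibrant(label=str(r.label), q=int(r.q), t_d=float(r.tD_ms), omega_ref=float(r.ccs_A2))
        for r in df.itertuples()
    ]


def write_model(path, model: CalibrationModel) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {"c": model.c, "X": model.x, "t_min": model.t_min,
             "t_max": model.t_max, "rmse": model.rmse},
            fh, indent=2,
        )


def read_model(path) -> CalibrationModel:
    with open(path, encoding="utf-8") as fh:
        d = json.load(fh)
    return CalibrationModel(
        c=d["c"], x=d["X"], t_min=d["t_min"], t_max=d["t_max"], rmse=d.get("rmse", 0.0)
    )
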