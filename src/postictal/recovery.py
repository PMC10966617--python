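"""Sigmoidal model of postictal EEG restoration.

The per-minute ADR trajectory recovers from a suppressed level near -1 toward
an upper asymptote over the first postictal hour. We model it with a
lag-reparameterized Gompertz curve

    f(t) = (U - A) + A * exp(-exp(1 + (lam - t) / tau))

with A > 0 the distance from the upper level U to the lower asymptote
(extent of recovery, in ADR units), lam >= 0 the initial lag (minutes),
tau > 0 the time constant (minutes), and U the upper asymptote. f is bounded
in [U - A, U], non-decreasing, with a single inflection; the derivative

    df/dt = (A / tau) * exp(u - e^u),   u = 1 + (lam - t) / tau

is maximal at u = 0, i.e. analytically at T_max = lam + tau — the moment of
fastest EEG restoration. The functional form is pluggable via the
``model`` argument of :class:`SigmoidRecoveryModel`.

Fits are gated on goodness of fit: R^2 >= 0.7 (inclusive) counts as a
QC pass; sessions with fewer than 40 valid minute bins are excluded
(minimum postictal duration of 40 min).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

logger = logging.getLogger(__name__)

R2_GATE = 0.7
MIN_VALID_MINUTES = 40

__all__ = [
    "R2_GATE",
    "MIN_VALID_MINUTES",
    "sigmoid_eval",
    "sigmoid_deriv",
    "analytic_t_max",
    "SigmoidFit",
    "SigmoidRecoveryModel",
    "fit_sigmoid",
    "goodness_of_fit",
    "t_max",
    "extract_features",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Raised when a series has fewer valid minutes than the fit requires."""


def _check_params(A, lam, tau, U) -> None:
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if A <= 0:
        raise ValueError(f"A must be positive, got {A}")
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")


def sigmoid_eval(t, A: float, lam: float, tau: float, U: float):
    """Evaluate the recovery curve f(t) at minutes ``t``."""
    _check_params(A, lam, tau, U)
    t = np.asarray(t, dtype=float)
    out = (U - A) + A * np.exp(-np.exp(1.0 + (lam - t) / tau))
    return float(out) if out.ndim == 0 else out


def sigmoid_deriv(t, A: float, lam: float, tau: float, U: float):
    """Evaluate df/dt (ADR units per minute) at minutes ``t``."""
    _check_params(A, lam, tau, U)
    t = np.asarray(t, dtype=float)
    u = 1.0 + (lam - t) / tau
    out = (A / tau) * np.exp(u - np.exp(u))
    return float(out) if out.ndim == 0 else out


def analytic_t_max(lam: float, tau: float) -> float:
    """Timepoint of maximum recovery rate: T_max = lam + tau."""
    return lam + tau


# (function, derivative, analytic argmax) for the default model; a custom
# model plugs in as the same triple.
_DEFAULT_MODEL = (sigmoid_eval, sigmoid_deriv, analytic_t_max)


@dataclass
class SigmoidFit:
    """Fitted recovery-model parameters and derived quantities."""

    A: float
    lam: float
    tau: float
    U: float
    r_squared: float
    converged: bool
    t_max: float
    max_slope: float
    D: float  # fitted span in minutes (>= 40 when QC-passed)
    boundary_flag: bool = False

    @property
    def qc_pass(self) -> bool:
        return bool(self.converged and self.r_squared >= R2_GATE)


class SigmoidRecoveryModel(RegressorMixin, BaseEstimator):
    """Nonlinear least-squares fit of the sigmoidal ADR recovery curve.

    Parameters
    ----------
    bounds : dict, optional
        Per-parameter (lo, hi) bounds. Defaults: A in (0, 2.5], lam in [0, D],
        tau in [0.5, 60], U in [-1, 1.2].
    min_valid_minutes : int
        Minimum number of non-missing minute bins (default 40).
    model : tuple, optional
        (f, dfdt, argmax) triple replacing the default lag-Gompertz form.

    Attributes
    ----------
    A_, lam_, tau_, U_ : float
        Estimated parameters.
    r_squared_ : float
        1 - SSE/SST on the non-missing minutes.
    t_max_ : float
        Timepoint of maximum df/dt, cross-checked numerically.
    max_slope_ : float
        df/dt at t_max_ (ADR units / min).
    converged_ : bool
    boundary_flag_ : bool
        True when the derivative argmax lies on the boundary of [0, D].
    D_ : float
        Span of the fitted series in minutes.
    """

    def __init__(self, bounds=None, min_valid_minutes: int = MIN_VALID_MINUTES,
                 model=None):
        self.bounds = bounds
        self.min_valid_minutes = min_valid_minutes
        self.model = model

    def _model(self):
        return self.model if self.model is not None else _DEFAULT_MODEL

    def fit(self, X, y=None):
        """Fit to minutes ``X`` (1-d, minutes since seizure offset) and ADR
        values ``y``; NaNs in y are dropped from the loss (no imputation)."""
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("X and y must have the same length")
        ok = ~np.isnan(y) & ~np.isnan(t)
        t, y = t[ok], y[ok]
        if len(t) < self.min_valid_minutes:
            raise InsufficientDataError(
                f"{len(t)} valid minutes < required {self.min_valid_minutes}"
            )
        D = float(t.max())
        self.D_ = D
        f, dfdt, argmax = self._model()

        b = {"A": (1e-6, 2.5), "lam": (0.0, D), "tau": (0.5, 60.0),
             "U": (-1.0, 1.2)}
        if self.bounds:
            b.update(self.bounds)
        lo = np.array([b["A"][0], b["lam"][0], b["tau"][0], b["U"][0]])
        hi = np.array([b["A"][1], b["lam"][1], b["tau"][1], b["U"][1]])

        def residuals(p):
            return f(t, *p) - y

        best = None
        for p0 in self._initializations(t, y, b):
            try:
                res = least_squares(residuals, p0, bounds=(lo, hi))
            except Exception:  # optimizer failure on one start
                continue
            if res.success and (best is None or res.cost < best.cost):
                best = res

        if best is None:
            self.converged_ = False
            self.A_ = self.lam_ = self.tau_ = self.U_ = np.nan
            self.r_squared_ = np.nan
            self.t_max_ = np.nan
            self.max_slope_ = np.nan
            self.boundary_flag_ = False
            return self

        self.converged_ = True
        self.A_, self.lam_, self.tau_, self.U_ = best.x
        pred = f(t, *best.x)
        sse = float(np.sum((y - pred) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        self.r_squared_ = np.nan if sst == 0 else 1.0 - sse / sst

        tm = float(argmax(self.lam_, self.tau_))
        # numeric cross-check of the analytic argmax on a fine grid
        grid = np.arange(0.0, D + 1e-9, 0.01)
        tm_num = float(grid[np.argmax(dfdt(grid, *best.x))])
        if abs(tm - tm_num) > 0.05 and 0.01 < tm_num < D - 0.01:
            logger.warning(
                "analytic t_max %.3f disagrees with numeric argmax %.3f",
                tm, tm_num,
            )
        self.boundary_flag_ = not (0.0 < tm < D)
        self.t_max_ = float(np.clip(tm, 0.0, D))
        self.max_slope_ = float(dfdt(self.t_max_, *best.x))
        return self

    def _initializations(self, t, y, b):
        """Five deterministic starts from order statistics of the series."""
        ymax, ymin = float(np.max(y)), float(np.min(y))
        U0 = float(np.clip(ymax, b["U"][0], b["U"][1]))
        A0 = float(np.clip(ymax - ymin, b["A"][0] + 1e-3, b["A"][1]))
        rise = t[y > ymin + 0.1 * A0]
        lam_data = float(rise.min()) if len(rise) else 2.0
        half = t[y > ymin + 0.5 * A0]
        t_half = float(half.min()) if len(half) else lam_data + 10.0
        starts = []
        for lam0 in (lam_data, 2.0, 5.0, 8.0, 12.0):
            lam0 = float(np.clip(lam0, b["lam"][0], b["lam"][1]))
            tau0 = float(np.clip(t_half - lam0, 1.0, 40.0))
            starts.append(np.array([A0, lam0, tau0, U0]))
        return starts

    def predict(self, X):
        f, _, _ = self._model()
        return f(np.asarray(X, dtype=float).ravel(),
                 self.A_, self.lam_, self.tau_, self.U_)

    def to_fit(self) -> SigmoidFit:
        """Snapshot the fitted state as a :class:`SigmoidFit` record."""
        return SigmoidFit(
            A=float(self.A_), lam=float(self.lam_), tau=float(self.tau_),
            U=float(self.U_), r_squared=float(self.r_squared_),
            converged=bool(self.converged_), t_max=float(self.t_max_),
            max_slope=float(self.max_slope_), D=float(self.D_),
            boundary_flag=bool(self.boundary_flag_),
        )


def fit_sigmoid(series: pd.DataFrame, **kwargs) -> SigmoidFit:
    """Fit the recovery model to an ADR minute series (columns minute, adr).

    Raises
    ------
    InsufficientDataError
        With fewer than 40 non-missing minute bins; such sessions are
        excluded rather than extrapolated.
    """
    m = SigmoidRecoveryModel(**kwargs).fit(series["minute"], series["adr"])
    return m.to_fit()


def goodness_of_fit(series: pd.DataFrame, fit: SigmoidFit,
                    gate: float = R2_GATE) -> tuple[float, bool]:
    """R^2 of the fit on the series' non-missing minutes and the QC verdict
    (R^2 >= gate, inclusive). Zero-variance series yield NaN and QC-fail."""
    ok = series["adr"].notna()
    t = series.loc[ok, "minute"].to_numpy(dtype=float)
    y = series.loc[ok, "adr"].to_numpy(dtype=float)
    pred = sigmoid_eval(t, fit.A, fit.lam, fit.tau, fit.U)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return np.nan, False
    r2 = 1.0 - float(np.sum((y - pred) ** 2)) / sst
    return r2, bool(fit.converged and r2 >= gate)


def t_max(fit: SigmoidFit) -> float:
    """Timepoint of maximum recovery rate for a converged fit."""
    if not fit.converged:
        raise ValueError("t_max requires a converged fit")
    return analytic_t_max(fit.lam, fit.tau)


def extract_features(fits: dict[str, SigmoidFit]) -> pd.DataFrame:
    """Forward the EEG features (t_max, A, tau) of QC-passed fits.

    QC-failed sessions are omitted (logged), one row per passing session.
    """
    rows = []
    for sid, f in fits.items():
        if not f.qc_pass:
            logger.info("session %s excluded by QC (R^2=%.3f)", sid, f.r_squared)
            continue
        rows.append({"session_id": sid, "t_max": f.t_max, "amplitude": f.A,
                     "tau": f.tau})
    return pd.DataFrame(rows, columns=["session_id", "t_max", "amplitude", "tau"])
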