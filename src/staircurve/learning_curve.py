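"""Exponential learning-curve fitting.

The per-subject learning trajectory is modelled as a single exponential
in the block index n:

    T(n) = alpha * exp(-n / beta) + gamma

with alpha the learning amount, beta the learning speed (blocks; larger
means slower), gamma the asymptotic threshold, and alpha + gamma the
initial performance.  Fitting is bounded nonlinear least squares.

:class:`LearningCurveRegressor` follows the scikit-learn estimator
protocol (``fit``/``predict``, ``get_params``/``set_params``, fitted
attributes with trailing underscores) so it composes with sklearn
pipelines; :func:`fit_learning_curve` is a thin convenience wrapper
returning a frozen result record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .staircase import BlockSeries

__all__ = [
    "LearningCurveRegressor",
    "LearningCurveFit",
    "FitConfig",
    "fit_learning_curve",
    "fits_frame",
    "summarize_fits",
]

logger = logging.getLogger(__name__)


def exp_curve(n, alpha, beta, gamma):
    """T(n) = alpha * exp(-n/beta) + gamma."""
    return alpha * np.exp(-np.asarray(n, dtype=float) / beta) + gamma


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings for the exponential fit."""

    alpha_bounds: tuple[float, float] = (0.0, 1e3)
    beta_bounds: tuple[float, float] = (1e-2, 1e3)
    gamma_bounds: tuple[float, float] = (0.0, 1e3)
    n_restarts: int = 3
    xtol: float = 1e-12
    ftol: float = 1e-12
    random_state: int = 0


class LearningCurveRegressor(RegressorMixin, BaseEstimator):
    """Bounded least-squares fit of T(n) = alpha*exp(-n/beta) + gamma.

    Parameters
    ----------
    alpha_bounds, beta_bounds, gamma_bounds
        Box constraints; positivity is implied by the parameters'
        meaning (threshold units / blocks).
    n_restarts
        Jittered restarts attempted when the first solve fails to
        converge; the best-cost iterate is kept either way.
    random_state
        Seed for the restart jitter only — the fit itself is
        deterministic given identical input and settings.

    Attributes
    ----------
    alpha_, beta_, gamma_ : float
        Fitted learning amount, speed and asymptote.
    initial_performance_ : float
        ``alpha_ + gamma_``, the fitted block-zero threshold.
    r_squared_ : float
        1 - SS_res/SS_tot on the fitted blocks.  For a zero-variance
        series the convention is 1.0 for an exact fit, else 0.0.
    residuals_ : ndarray
        Observed minus fitted threshold per block.
    converged_ : bool
        False when every solve failed; the best iterate is still
        reported.
    """

    def __init__(
        self,
        alpha_bounds=(0.0, 1e3),
        beta_bounds=(1e-2, 1e3),
        gamma_bounds=(0.0, 1e3),
        n_restarts=3,
        xtol=1e-12,
        ftol=1e-12,
        random_state=0,
    ):
        self.alpha_bounds = alpha_bounds
        self.beta_bounds = beta_bounds
        self.gamma_bounds = gamma_bounds
        self.n_restarts = n_restarts
        self.xtol = xtol
        self.ftol = ftol
        self.random_state = random_state

    def _initial_guess(self, n, y):
        g0 = float(np.min(y))
        a0 = max(float(y[np.argmin(n)]) - g0, 1e-6)
        b0 = max(float(np.max(n)) / 3.0, self.beta_bounds[0])
        lo = [self.alpha_bounds[0], self.beta_bounds[0], self.gamma_bounds[0]]
        hi = [self.alpha_bounds[1], self.beta_bounds[1], self.gamma_bounds[1]]
        x0 = np.clip([a0, b0, g0], lo, hi)
        return x0, (np.array(lo), np.array(hi))

    def fit(self, X, y):
        """Fit the curve; ``X`` holds block indices, ``y`` the thresholds."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of block indices")
        y = np.asarray(y, dtype=float).ravel()
        n = X.ravel()
        if len(n) != len(y):
            raise ValueError("X and y lengths differ")
        mask = np.isfinite(n) & np.isfinite(y)
        n, y = n[mask], y[mask]
        if len(y) < 4:
            raise ValueError(
                f"need >= 4 valid block thresholds to fit 3 parameters, got {len(y)}"
            )
        if np.any(n < 0):
            raise ValueError("block indices must be >= 0")

        x0, (lo, hi) = self._initial_guess(n, y)
        rng = np.random.default_rng(self.random_state)

        def solve(start):
            return least_squares(
                lambda p: exp_curve(n, *p) - y,
                start,
                bounds=(lo, hi),
                xtol=self.xtol,
                ftol=self.ftol,
                gtol=1e-12,
            )

        best = solve(x0)
        if not best.success:
            for _ in range(self.n_restarts):
                jitter = np.exp(rng.normal(0.0, 0.3, size=3))
                res = solve(np.clip(x0 * jitter, lo, hi))
                if res.cost < best.cost:
                    best = res
                if res.success:
                    break

        self.alpha_, self.beta_, self.gamma_ = (float(v) for v in best.x)
        self.initial_performance_ = self.alpha_ + self.gamma_
        self.converged_ = bool(best.success)
        self.residuals_ = y - exp_curve(n, *best.x)
        ss_res = float(np.sum(self.residuals_**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot == 0.0:
            self.r_squared_ = 1.0 if np.allclose(self.residuals_, 0.0) else 0.0
        else:
            self.r_squared_ = 1.0 - ss_res / ss_tot
        self.n_features_in_ = 1
        self.n_blocks_ = len(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        n = np.asarray(X, dtype=float).ravel()
        return exp_curve(n, self.alpha_, self.beta_, self.gamma_)


@dataclass(frozen=True)
class LearningCurveFit:
    """Fitted exponential learning curve for one subject."""

    subject_id: str
    alpha: float
    beta: float
    gamma: float
    r_squared: float
    converged: bool
    residuals: tuple[float, ...] = field(default_factory=tuple)

    @property
    def initial_performance(self) -> float:
        return self.alpha + self.gamma


def _series_points(series) -> tuple[str, np.ndarray, np.ndarray]:
    if isinstance(series, BlockSeries):
        idx, thr = series.valid_points
        return series.subject_id, idx, thr
    thr = np.asarray(list(series), dtype=float)
    idx = np.arange(1, len(thr) + 1, dtype=float)
    mask = np.isfinite(thr)
    return "", idx[mask], thr[mask]


def fit_learning_curve(series, config: FitConfig | None = None) -> LearningCurveFit:
    """Fit T(n) = alpha*exp(-n/beta) + gamma to a subject's block thresholds.

    ``series`` is a :class:`~staircurve.staircase.BlockSeries` (invalid
    blocks are skipped) or a plain sequence of thresholds assumed to sit
    at blocks 1..N (NaNs skipped).  Requires at least 4 valid points.
    """
    if config is None:
        config = FitConfig()
    subject_id, idx, thr = _series_points(series)
    reg = LearningCurveRegressor(
        alpha_bounds=config.alpha_bounds,
        beta_bounds=config.beta_bounds,
        gamma_bounds=config.gamma_bounds,
        n_restarts=config.n_restarts,
        xtol=config.xtol,
        ftol=config.ftol,
        random_state=config.random_state,
    ).fit(idx.reshape(-1, 1), thr)
    return LearningCurveFit(
        subject_id=subject_id,
        alpha=reg.alpha_,
        beta=reg.beta_,
        gamma=reg.gamma_,
        r_squared=reg.r_squared_,
        converged=reg.converged_,
        residuals=tuple(float(r) for r in reg.residuals_),
    )


_PARAM_COLS = ["alpha", "beta", "gamma", "initial", "r_squared"]


def fits_frame(fits, ages=None) -> pd.DataFrame:
    """One row per fit: subject, alpha, beta, gamma, initial, r2, converged."""
    df = pd.DataFrame(
        {
            "subject": [f.subject_id for f in fits],
            "alpha": [f.alpha for f in fits],
            "beta": [f.beta for f in fits],
            "gamma": [f.gamma for f in fits],
            "initial": [f.initial_performance for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    if ages is not None:
        df["age"] = list(ages)
    return df


def summarize_fits(fits, ages=None) -> pd.DataFrame:
    """Cohort mean and SD of (alpha, beta, gamma, alpha+gamma, r2).

    Non-converged fits are excluded with a logged count.  SDs use the
    n-1 (sample) denominator.  The returned table feeds the correlation
    stage.
    """
    if len(fits) < 2:
        raise ValueError("need >= 2 fits to summarize")
    df = fits_frame(fits, ages)
    n_bad = int((~df["converged"]).sum())
    if n_bad:
        logger.warning("excluding %d non-converged fit(s) from the summary", n_bad)
        df = df[df["converged"]]
    cols = _PARAM_COLS + (["age"] if ages is not None else [])
    return pd.DataFrame({"mean": df[cols].mean(), "sd": df[cols].std(ddof=1)})
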