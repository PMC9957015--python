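"""First-order dissipation kinetics for single residue time courses.

Residue decline in stored commodities is conventionally summarised by a
first-order model ``C(t) = C0 * exp(-k t)``: the rate constant ``k`` is the
negative slope of ``ln C`` versus time, and the half-life is ``ln 2 / k``.
This module provides that fit (as a scikit-learn style estimator plus a thin
functional wrapper), day-0 normalisation to residue ratios, percent decrease
over a storage horizon, and the trapezoidal area under the decline curve
(AUC) used as a condition-level summary for effect analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import FitError, HorizonError, KineticsWarning, NormalizationError, ValidationError

__all__ = [
    "AUCResult",
    "FirstOrderDecay",
    "FirstOrderFit",
    "ResidueTimeCourse",
    "auc_trapezoid",
    "fit_first_order",
    "percent_decrease",
    "to_ratios",
]


@dataclass(frozen=True)
class ResidueTimeCourse:
    """One pesticide x matrix x (T, RH) x replicate decay series.

    ``days`` must be strictly increasing; ``concentrations`` are in mg/kg and
    non-negative; ``censored`` flags values substituted below the assay's
    detection limit.
    """

    pesticide: str
    matrix: str
    temperature_C: float
    rh_pct: float
    days: np.ndarray
    concentrations: np.ndarray
    censored: np.ndarray
    replicate: int = 1

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        conc = np.asarray(self.concentrations, dtype=float)
        cens = np.asarray(self.censored, dtype=bool)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "censored", cens)
        if days.ndim != 1 or days.shape != conc.shape or days.shape != cens.shape:
            raise ValidationError("days, concentrations and censored must be 1-D and equal length")
        if days.size and days[0] < 0:
            raise ValidationError("days must be non-negative")
        if days.size > 1 and not np.all(np.diff(days) > 0):
            raise ValidationError(
                f"days must be strictly increasing for {self.key()}"
            )
        if np.any(conc < 0):
            raise ValidationError("concentrations must be non-negative")

    def key(self) -> tuple:
        return (self.pesticide, self.matrix, self.temperature_C, self.rh_pct, self.replicate)

    def __len__(self) -> int:
        return int(self.days.size)


def to_ratios(tc: ResidueTimeCourse) -> ResidueTimeCourse:
    """Divide all concentrations by the day-0 value.

    The returned time course has ratio 1 at day 0 and preserves every other
    field, including censoring flags.  Idempotent.  Raises
    :class:`NormalizationError` when day 0 is absent or its value is zero.
    """
    if tc.days.size == 0 or tc.days[0] != 0:
        raise NormalizationError(f"time course {tc.key()} has no day-0 observation")
    c0 = tc.concentrations[0]
    if c0 <= 0:
        raise NormalizationError(f"day-0 concentration is not positive for {tc.key()}")
    return replace(tc, concentrations=tc.concentrations / c0)


class FirstOrderDecay(RegressorMixin, BaseEstimator):
    """Log-linear least-squares fit of first-order decay.

    Fits ``ln C = ln c0 - k t`` by ordinary least squares on the
    log-transformed concentrations.  Censored or non-positive observations
    are excluded from the fit (with a warning for non-positive values).

    Parameters
    ----------
    drop_censored : bool, default True
        Exclude censored (below-detection, substituted) points from the fit.

    Attributes
    ----------
    k_ : float
        First-order rate constant, per day (negative slope of the log fit).
    c0_hat_ : float
        Back-transformed intercept, mg/kg.
    half_life_ : float
        ``ln 2 / k_`` for ``k_ > 0``; ``inf`` otherwise (with a warning).
    r2_ : float
        Coefficient of determination of the log-linear fit.
    n_used_ : int
        Number of observations entering the fit.
    """

    def __init__(self, drop_censored: bool = True):
        self.drop_censored = drop_censored

    def fit(self, X, y, censored=None) -> "FirstOrderDecay":
        t = np.asarray(X, dtype=float).reshape(-1)
        c = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != c.shape:
            raise ValidationError("time and concentration arrays differ in length")
        mask = np.ones(t.size, dtype=bool)
        if censored is not None and self.drop_censored:
            mask &= ~np.asarray(censored, dtype=bool)
        nonpos = c <= 0
        if np.any(nonpos & mask):
            warnings.warn(
                f"excluding {int(np.sum(nonpos & mask))} non-positive concentration(s) "
                "from the log-linear fit",
                KineticsWarning,
                stacklevel=2,
            )
            mask &= ~nonpos
        if int(mask.sum()) < 2:
            raise FitError(
                f"need at least 2 usable (positive, uncensored) points, have {int(mask.sum())}"
            )
        tu, logc = t[mask], np.log(c[mask])
        slope, intercept = np.polyfit(tu, logc, 1)
        fitted = intercept + slope * tu
        sse = float(np.sum((logc - fitted) ** 2))
        sst = float(np.sum((logc - logc.mean()) ** 2))
        self.k_ = float(-slope)
        self.c0_hat_ = float(np.exp(intercept))
        self.r2_ = 1.0 if sst == 0 else max(0.0, 1.0 - sse / sst)
        if self.k_ > 0:
            self.half_life_ = math.log(2) / self.k_
        else:
            warnings.warn(
                f"non-positive rate constant ({self.k_:g}/day): no measurable decay, "
                "half-life reported as infinite",
                KineticsWarning,
                stacklevel=2,
            )
            self.half_life_ = math.inf
        self.n_used_ = int(mask.sum())
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "k_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.c0_hat_ * np.exp(-self.k_ * t)


@dataclass(frozen=True)
class FirstOrderFit:
    """Summary of a first-order kinetic fit for one time course."""

    k: float
    c0_hat: float
    half_life_days: float
    r2_loglinear: float
    n_used: int


def fit_first_order(tc: ResidueTimeCourse) -> FirstOrderFit:
    """Fit first-order decay to a time course; see :class:`FirstOrderDecay`."""
    est = FirstOrderDecay().fit(tc.days, tc.concentrations, censored=tc.censored)
    return FirstOrderFit(
        k=est.k_,
        c0_hat=est.c0_hat_,
        half_life_days=est.half_life_,
        r2_loglinear=est.r2_,
        n_used=est.n_used_,
    )


def percent_decrease(tc: ResidueTimeCourse, horizon: float) -> float:
    """Percent loss of residue between day 0 and ``horizon``: 100*(1 - C(h)/C(0)).

    The horizon must lie inside the observed span; when it falls between
    sampling days the concentration is linearly interpolated.
    """
    if tc.days.size == 0 or tc.days[0] != 0:
        raise NormalizationError(f"time course {tc.key()} has no day-0 observation")
    c0 = tc.concentrations[0]
    if c0 <= 0:
        raise NormalizationError(f"day-0 concentration is not positive for {tc.key()}")
    if not (tc.days[0] <= horizon <= tc.days[-1]):
        raise HorizonError(
            f"horizon {horizon} outside observed span [{tc.days[0]}, {tc.days[-1]}]"
        )
    ch = float(np.interp(horizon, tc.days, tc.concentrations))
    return 100.0 * (1.0 - ch / c0)


@dataclass(frozen=True)
class AUCResult:
    """Trapezoidal area under a residue decline curve."""

    value: float
    n_points: int
    t_span: float


def auc_trapezoid(tc: ResidueTimeCourse) -> AUCResult:
    """Trapezoidal-rule area under the observed curve, no extrapolation.

    Censored points contribute at their substituted value.  Units are
    concentration-units times days (mg·day/kg for raw concentrations,
    days for ratio-normalised courses).
    """
    if len(tc) < 2:
        raise FitError("AUC needs at least 2 points")
    value = float(np.trapezoid(tc.concentrations, tc.days))
    return AUCResult(value=value, n_points=len(tc), t_span=float(tc.days[-1] - tc.days[0]))
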