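"""Response-surface fitting and factorial effect analysis.

Fits the full second-order polynomial in storage time, temperature and
relative humidity to residue-ratio data (response surface methodology), with
coefficient standard errors and t-based p-values, and tests temperature /
humidity / interaction effects on a condition-level summary (typically AUC)
by two-factor ANOVA.

Least squares is solved by orthogonal decomposition (SVD), never by
explicitly inverted normal equations: monomial design matrices over
day/degree/%RH ranges are badly scaled, and predictors are centred and
scaled internally with coefficients mapped back to the raw parameterization
for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DesignError, FitError, RankError, ValidationError
from .models import COEFFICIENT_NAMES, QuadraticSurfaceModel

__all__ = [
    "EffectTable",
    "QuadraticSurfaceRegressor",
    "SurfaceFitResult",
    "build_design_matrix",
    "effect_anova",
    "fit_quadratic_surface",
]

#: Human-readable names of the ten design-matrix columns, canonical order.
TERM_NAMES = ("1", "t", "T", "RH", "t^2", "T^2", "RH^2", "t*T", "t*RH", "T*RH")


def build_design_matrix(points) -> np.ndarray:
    """Ten-column second-order design matrix for points ``(t, T, RH)``.

    Columns, in canonical order: 1, t, T, RH, t^2, T^2, RH^2, t*T, t*RH, T*RH.
    """
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValidationError(f"expected an (n, 3) array of (t, T, RH) points, got shape {P.shape}")
    if not np.all(np.isfinite(P)):
        raise ValidationError("design points must be finite")
    t, T, RH = P[:, 0], P[:, 1], P[:, 2]
    return np.column_stack(
        [np.ones_like(t), t, T, RH, t * t, T * T, RH * RH, t * T, t * RH, T * RH]
    )


class QuadraticSurfaceRegressor(RegressorMixin, BaseEstimator):
    """OLS fit of the ten-term second-order surface in (t, T, RH).

    Parameters
    ----------
    scale : bool, default True
        Standardise the nine non-constant monomial columns before solving;
        coefficients (and their standard errors) are mapped back to the raw
        parameterization, so reported values are identical up to conditioning.

    Attributes
    ----------
    coef_ : ndarray of shape (10,)
        Raw-scale coefficients in canonical order (intercept first).
    se_ : ndarray of shape (10,)
        Standard errors of the coefficients.
    pvalues_ : ndarray of shape (10,)
        Two-sided p-values from the t distribution with ``residual_df_``.
    r2_, r2_adj_ : float
        Coefficient of determination and its adjusted form.
    n_obs_, residual_df_ : int
        Observation count and residual degrees of freedom (``n_obs_ - 10``).
    """

    N_TERMS = 10

    def __init__(self, scale: bool = True):
        self.scale = scale

    def fit(self, X, y) -> "QuadraticSurfaceRegressor":
        D = build_design_matrix(X)
        y = np.asarray(y, dtype=float).reshape(-1)
        if y.shape[0] != D.shape[0]:
            raise ValidationError("response length does not match number of points")
        if not np.all(np.isfinite(y)):
            raise ValidationError("responses must be finite")
        n = D.shape[0]
        if n <= self.N_TERMS:
            raise FitError(
                f"need more than {self.N_TERMS} observations to fit the "
                f"ten-term surface, have {n}"
            )
        # Column scaling keeps the SVD well conditioned for monomials over
        # wide day/degree ranges; the intercept column is left at 1.
        if self.scale:
            norms = np.linalg.norm(D, axis=0)
            norms[norms == 0] = 1.0
        else:
            norms = np.ones(self.N_TERMS)
        Ds = D / norms
        rank = np.linalg.matrix_rank(Ds)
        if rank < self.N_TERMS:
            aliased = self._aliased_columns(Ds)
            raise RankError(
                f"design matrix rank {rank} < {self.N_TERMS}; aliased columns: "
                + ", ".join(aliased)
            )
        coef_s, _, _, sv = np.linalg.lstsq(Ds, y, rcond=None)
        fitted = Ds @ coef_s
        resid = y - fitted
        sse = float(resid @ resid)
        sst = float(np.sum((y - y.mean()) ** 2))
        df = n - self.N_TERMS
        sigma2 = sse / df
        # (X'X)^-1 via the SVD of the scaled design.
        U, S, Vt = np.linalg.svd(Ds, full_matrices=False)
        xtx_inv_diag = np.einsum("ji,i,ji->j", Vt.T, 1.0 / S**2, Vt.T)
        se_s = np.sqrt(sigma2 * xtx_inv_diag)
        self.coef_ = coef_s / norms
        self.se_ = se_s / norms
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = np.where(self.se_ > 0, self.coef_ / self.se_, np.inf)
        self.pvalues_ = 2.0 * stats.t.sf(np.abs(tstat), df)
        self.r2_ = 1.0 if sst == 0 else 1.0 - sse / sst
        self.r2_adj_ = 1.0 - (1.0 - self.r2_) * (n - 1) / df
        self.n_obs_ = int(n)
        self.residual_df_ = int(df)
        self.sse_ = sse
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        return build_design_matrix(X) @ self.coef_

    def to_model(
        self, pesticide: str = "fitted", matrix: str = "wheat"
    ) -> QuadraticSurfaceModel:
        """Package the fitted coefficients as a :class:`QuadraticSurfaceModel`."""
        check_is_fitted(self, "coef_")
        return QuadraticSurfaceModel(
            pesticide=pesticide,
            matrix=matrix,
            **dict(zip(COEFFICIENT_NAMES, map(float, self.coef_))),
            r2_reported=None,
        )

    @staticmethod
    def _aliased_columns(D: np.ndarray) -> list[str]:
        # Greedy scan: a column not raising the rank of its predecessors is aliased.
        aliased = []
        kept = np.empty((D.shape[0], 0))
        for j in range(D.shape[1]):
            cand = np.column_stack([kept, D[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                aliased.append(TERM_NAMES[j])
            else:
                kept = cand
        return aliased


@dataclass(frozen=True)
class SurfaceFitResult:
    """A fitted surface with its inference summary."""

    model: QuadraticSurfaceModel
    r2: float
    r2_adj: float
    coef_se: np.ndarray
    coef_p: np.ndarray
    n_obs: int
    residual_df: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": TERM_NAMES,
                "coef": self.model.coefficients,
                "se": self.coef_se,
                "p_value": self.coef_p,
            }
        )


def fit_quadratic_surface(
    points, ratios, pesticide: str = "fitted", matrix: str = "wheat"
) -> SurfaceFitResult:
    """Fit the ten-term surface to ``(t, T, RH) -> ratio`` observations.

    Needs at least 11 observations spanning a full-rank second-order design
    (>= 3 distinct levels overall in each factor direction, with spread in
    the cross terms).
    """
    est = QuadraticSurfaceRegressor().fit(points, ratios)
    return SurfaceFitResult(
        model=est.to_model(pesticide=pesticide, matrix=matrix),
        r2=est.r2_,
        r2_adj=est.r2_adj_,
        coef_se=est.se_,
        coef_p=est.pvalues_,
        n_obs=est.n_obs_,
        residual_df=est.residual_df_,
    )


@dataclass(frozen=True)
class EffectTable:
    """Two-factor effect test on a condition-level response (typically AUC)."""

    response: str
    p_T: float
    p_RH: float
    p_TxRH: float
    table: pd.DataFrame
    method: str

    def to_frame(self) -> pd.DataFrame:
        return self.table


def _anova_replicated(y: np.ndarray) -> list[tuple[str, float, int]]:
    # y has shape (a, b, r); balanced two-way ANOVA sums of squares.
    a, b, r = y.shape
    grand = y.mean()
    mi = y.mean(axis=(1, 2))
    mj = y.mean(axis=(0, 2))
    mij = y.mean(axis=2)
    ss_a = b * r * float(np.sum((mi - grand) ** 2))
    ss_b = a * r * float(np.sum((mj - grand) ** 2))
    ss_ab = r * float(np.sum((mij - mi[:, None] - mj[None, :] + grand) ** 2))
    ss_err = float(np.sum((y - mij[:, :, None]) ** 2))
    return [
        ("T", ss_a, a - 1),
        ("RH", ss_b, b - 1),
        ("T:RH", ss_ab, (a - 1) * (b - 1)),
        ("Residual", ss_err, a * b * (r - 1)),
    ]


def _anova_tukey_nonadditivity(y: np.ndarray) -> list[tuple[str, float, int]]:
    # y has shape (a, b), one observation per cell: additive two-way ANOVA
    # with Tukey's one-degree-of-freedom test for nonadditivity.
    a, b = y.shape
    grand = y.mean()
    ai = y.mean(axis=1) - grand
    bj = y.mean(axis=0) - grand
    ss_a = b * float(np.sum(ai**2))
    ss_b = a * float(np.sum(bj**2))
    ss_tot = float(np.sum((y - grand) ** 2))
    ss_resid = ss_tot - ss_a - ss_b
    d = np.outer(ai, bj)
    denom = float(np.sum(d**2))
    ss_nonadd = 0.0 if denom == 0 else float(np.sum(y * d)) ** 2 / denom
    ss_rem = max(ss_resid - ss_nonadd, 0.0)
    return [
        ("T", ss_a, a - 1),
        ("RH", ss_b, b - 1),
        ("T:RH", ss_nonadd, 1),
        ("Residual", ss_rem, (a - 1) * (b - 1) - 1),
    ]


def effect_anova(auc_by_condition: pd.DataFrame, response: str = "auc") -> EffectTable:
    """Temperature x humidity ANOVA on a per-condition response table.

    Expects columns ``temperature_C``, ``rh_pct`` and the response (default
    ``auc``), with one or more rows per factorial cell.  With replicates the
    interaction is the usual two-way interaction term; with a single
    observation per cell it is Tukey's one-degree-of-freedom nonadditivity
    test.  The design must be balanced (equal counts per cell) and each
    factor must have at least two levels.
    """
    df = auc_by_condition
    for col in ("temperature_C", "rh_pct", response):
        if col not in df.columns:
            raise DesignError(f"missing column {col!r} in effect table")
    Ts = np.sort(df["temperature_C"].unique())
    RHs = np.sort(df["rh_pct"].unique())
    if len(Ts) < 2 or len(RHs) < 2:
        raise DesignError("each factor needs at least two levels")
    counts = df.groupby(["temperature_C", "rh_pct"]).size()
    if len(counts) != len(Ts) * len(RHs) or counts.nunique() != 1:
        raise DesignError("effect analysis requires a complete, balanced factorial")
    r = int(counts.iloc[0])
    cube = (
        df.sort_values(["temperature_C", "rh_pct"])[response]
        .to_numpy(dtype=float)
        .reshape(len(Ts), len(RHs), r)
    )
    if r > 1:
        rows = _anova_replicated(cube)
        method = "two-way ANOVA with interaction"
    else:
        rows = _anova_tukey_nonadditivity(cube[:, :, 0])
        method = "additive two-way ANOVA, Tukey 1-df nonadditivity"
    ss_err, df_err = rows[-1][1], rows[-1][2]
    if df_err < 1:
        raise DesignError("no residual degrees of freedom for the effect tests")
    mse = ss_err / df_err
    records = []
    for name, ss, dfree in rows[:-1]:
        ms = ss / dfree
        if mse > 0:
            F = ms / mse
            p = float(stats.f.sf(F, dfree, df_err))
        elif ms == 0:  # no variance anywhere: nothing to detect
            F, p = 0.0, 1.0
        else:
            F, p = float("inf"), 0.0
        records.append({"term": name, "ss": ss, "df": dfree, "F": F, "p_value": p})
    records.append({"term": "Residual", "ss": ss_err, "df": df_err, "F": np.nan, "p_value": np.nan})
    table = pd.DataFrame(records)
    pvals = {rec["term"]: rec["p_value"] for rec in records}
    return EffectTable(
        response=response,
        p_T=pvals["T"],
        p_RH=pvals["RH"],
        p_TxRH=pvals["T:RH"],
        table=table,
        method=method,
    )
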