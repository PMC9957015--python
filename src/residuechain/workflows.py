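"""Study-level workflows composing kinetics, surface fitting and effect analysis.

These are the table-in/table-out steps the command-line interface exposes;
they operate on lists of :class:`~residuechain.kinetics.ResidueTimeCourse`
grouped from a tidy study table.
"""

from __future__ import annotations

import pandas as pd

from .errors import FitError
from .kinetics import ResidueTimeCourse, auc_trapezoid, fit_first_order, to_ratios
from .rsm import COEFFICIENT_NAMES, EffectTable, SurfaceFitResult, effect_anova, fit_quadratic_surface

__all__ = [
    "auc_by_condition",
    "effects_table",
    "fit_all_surfaces",
    "kinetics_summary",
    "surface_coefficient_table",
]


def kinetics_summary(courses: list[ResidueTimeCourse]) -> pd.DataFrame:
    """Per-course first-order rate, half-life, log-linear R^2 and AUC."""
    rows = []
    for tc in courses:
        fit = fit_first_order(tc)
        auc = auc_trapezoid(tc)
        rows.append(
            {
                "pesticide": tc.pesticide,
                "matrix": tc.matrix,
                "temperature_C": tc.temperature_C,
                "rh_pct": tc.rh_pct,
                "replicate": tc.replicate,
                "k_per_day": fit.k,
                "half_life_days": fit.half_life_days,
                "r2_loglinear": fit.r2_loglinear,
                "auc": auc.value,
                "n_points": auc.n_points,
            }
        )
    return pd.DataFrame(rows)


def fit_all_surfaces(courses: list[ResidueTimeCourse]) -> dict[tuple[str, str], SurfaceFitResult]:
    """Fit one ratio surface per pesticide x matrix, pooling all conditions/replicates."""
    groups: dict[tuple[str, str], list[ResidueTimeCourse]] = {}
    for tc in courses:
        groups.setdefault((tc.pesticide, tc.matrix), []).append(tc)
    results = {}
    for (pesticide, matrix), tcs in sorted(groups.items()):
        points, ratios = [], []
        for tc in tcs:
            rt = to_ratios(tc)
            for day, ratio in zip(rt.days, rt.concentrations):
                points.append((day, tc.temperature_C, tc.rh_pct))
                ratios.append(ratio)
        if len(points) <= 10:
            raise FitError(
                f"{pesticide}/{matrix}: only {len(points)} observations; "
                "need more than 10 for the ten-term surface"
            )
        results[(pesticide, matrix)] = fit_quadratic_surface(
            points, ratios, pesticide=pesticide, matrix=matrix
        )
    return results


def surface_coefficient_table(results: dict[tuple[str, str], SurfaceFitResult]) -> pd.DataFrame:
    """One row per pesticide x matrix: ten coefficients plus fit R^2."""
    rows = []
    for (pesticide, matrix), res in sorted(results.items()):
        rows.append(
            {
                "pesticide": pesticide,
                "matrix": matrix,
                **dict(zip(COEFFICIENT_NAMES, res.model.coefficients)),
                "r2": res.r2,
                "r2_adj": res.r2_adj,
                "n_obs": res.n_obs,
            }
        )
    return pd.DataFrame(rows)


def auc_by_condition(courses: list[ResidueTimeCourse], ratio: bool = False) -> pd.DataFrame:
    """Trapezoidal AUC per pesticide x condition x replicate.

    By default the AUC of raw concentrations; with ``ratio=True`` the course
    is day-0 normalised first (AUC then has units of days).
    """
    rows = []
    for tc in courses:
        series = to_ratios(tc) if ratio else tc
        auc = auc_trapezoid(series)
        rows.append(
            {
                "pesticide": tc.pesticide,
                "matrix": tc.matrix,
                "temperature_C": tc.temperature_C,
                "rh_pct": tc.rh_pct,
                "replicate": tc.replicate,
                "auc": auc.value,
            }
        )
    return pd.DataFrame(rows)


def effects_table(courses: list[ResidueTimeCourse], ratio: bool = False) -> pd.DataFrame:
    """AUC effect ANOVA per pesticide: p-values for T, RH and their interaction."""
    auc = auc_by_condition(courses, ratio=ratio)
    rows = []
    for (pesticide, matrix), grp in sorted(auc.groupby(["pesticide", "matrix"])):
        effect: EffectTable = effect_anova(grp)
        rows.append(
            {
                "pesticide": pesticide,
                "matrix": matrix,
                "p_T": effect.p_T,
                "p_RH": effect.p_RH,
                "p_TxRH": effect.p_TxRH,
                "method": effect.method,
            }
        )
    return pd.DataFrame(rows)
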