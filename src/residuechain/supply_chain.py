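"""Chained residue prediction across the wheat-to-flour supply chain.

The chain has three critical points: wheat storage (residue degrades from C0
to C1 following the wheat surface model), milling (C2 = PF * C1, where PF is
the processing factor — the fraction of residue carried from grain into
flour; PF < 1 means milling removes residue), and flour storage (C2 to C3
following the flour surface model).  Milling itself is treated as
zero-duration: any degradation during processing is folded into PF.

Surface-model ratios are clamped into [0, 1] before chaining so predicted
concentrations stay physical even where the polynomials leave that range;
every clamp is surfaced in the prediction's ``clamp_events``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .models import QuadraticSurfaceModel, _evaluate_clamped_flag, builtin_model

__all__ = [
    "StageConditions",
    "SupplyChainPrediction",
    "SupplyChainScenario",
    "predict_chain",
    "scan_conditions",
]


@dataclass(frozen=True)
class StageConditions:
    """Storage duration (days), temperature (degrees C) and humidity (%RH) for one stage."""

    t: float
    T: float
    RH: float

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.t, self.T, self.RH))):
            raise ValidationError("stage conditions must be finite")
        if self.t < 0:
            raise ValidationError(f"stage duration must be non-negative, got {self.t!r}")


@dataclass(frozen=True)
class SupplyChainScenario:
    """Initial concentration plus the two storage stages and the milling factor.

    ``pf`` defaults to 1.0 (milling neither removes nor concentrates
    residue); values above 1 are physically unusual and trigger a warning.
    """

    pesticide: str
    c0: float
    wheat_stage: StageConditions
    flour_stage: StageConditions
    pf: float = 1.0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.c0) and self.c0 > 0):
            raise ValidationError(f"c0 must be positive and finite, got {self.c0!r}")
        if not (math.isfinite(self.pf) and self.pf >= 0):
            raise ValidationError(f"pf must be non-negative and finite, got {self.pf!r}")
        if self.pf > 1:
            warnings.warn(
                f"processing factor {self.pf} > 1: milling is predicted to "
                "concentrate residue",
                UserWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class SupplyChainPrediction:
    """Predicted concentrations after each critical point (mg/kg)."""

    c0: float
    c1: float
    c2: float
    c3: float
    clamp_events: tuple[str, ...] = field(default=())
    models_used: tuple[str, ...] = field(default=())


def predict_chain(
    scenario: SupplyChainScenario,
    wheat_model: QuadraticSurfaceModel | None = None,
    flour_model: QuadraticSurfaceModel | None = None,
) -> SupplyChainPrediction:
    """Predict C1 (after wheat storage), C2 (after milling) and C3 (after flour storage).

    ``c1 = c0 * ratio_wheat(t_w, T_w, RH_w)``, ``c2 = pf * c1``,
    ``c3 = c2 * ratio_flour(t_f, T_f, RH_f)``, with each ratio clamped to
    [0, 1].  Models default to the built-in registry entries for the
    scenario's pesticide and must match its pesticide and their matrices.
    """
    if wheat_model is None:
        wheat_model = builtin_model(scenario.pesticide, "wheat")
    if flour_model is None:
        flour_model = builtin_model(scenario.pesticide, "flour")
    for model, matrix in ((wheat_model, "wheat"), (flour_model, "flour")):
        if model.matrix != matrix:
            raise ValidationError(
                f"expected a {matrix} model, got matrix {model.matrix!r}"
            )
        if model.pesticide != scenario.pesticide:
            raise ValidationError(
                f"model pesticide {model.pesticide!r} does not match scenario "
                f"pesticide {scenario.pesticide!r}"
            )
    clamps: list[str] = []
    w = scenario.wheat_stage
    ratio_w, clamped_w = _evaluate_clamped_flag(wheat_model, w.t, w.T, w.RH)
    if clamped_w:
        clamps.append(f"wheat ratio clamped to {ratio_w}")
    c1 = scenario.c0 * ratio_w
    c2 = scenario.pf * c1
    f = scenario.flour_stage
    ratio_f, clamped_f = _evaluate_clamped_flag(flour_model, f.t, f.T, f.RH)
    if clamped_f:
        clamps.append(f"flour ratio clamped to {ratio_f}")
    c3 = c2 * ratio_f
    return SupplyChainPrediction(
        c0=scenario.c0,
        c1=c1,
        c2=c2,
        c3=c3,
        clamp_events=tuple(clamps),
        models_used=(
            f"{wheat_model.pesticide}/{wheat_model.matrix}",
            f"{flour_model.pesticide}/{flour_model.matrix}",
        ),
    )


def scan_conditions(
    pesticide: str,
    c0: float,
    pf: float,
    wheat_grid: list[StageConditions],
    flour_grid: list[StageConditions],
    wheat_model: QuadraticSurfaceModel | None = None,
    flour_model: QuadraticSurfaceModel | None = None,
) -> pd.DataFrame:
    """Predict the chain over every combination of wheat and flour stage conditions.

    Returns one row per grid cell with the stage conditions, predicted
    c1/c2/c3 and a flag for clamped evaluations; row count equals
    ``len(wheat_grid) * len(flour_grid)``.
    """
    from .errors import DesignError

    if not wheat_grid or not flour_grid:
        raise DesignError("condition grids must be non-empty")
    rows = []
    for w in wheat_grid:
        for f in flour_grid:
            scenario = SupplyChainScenario(
                pesticide=pesticide, c0=c0, pf=pf, wheat_stage=w, flour_stage=f
            )
            pred = predict_chain(scenario, wheat_model=wheat_model, flour_model=flour_model)
            rows.append(
                {
                    "pesticide": pesticide,
                    "t_w": w.t, "T_w": w.T, "RH_w": w.RH,
                    "t_f": f.t, "T_f": f.T, "RH_f": f.RH,
                    "pf": pf,
                    "c0": c0, "c1": pred.c1, "c2": pred.c2, "c3": pred.c3,
                    "clamped": bool(pred.clamp_events),
                }
            )
    return pd.DataFrame(rows)
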