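"""Published second-order residue-degradation models for wheat and flour storage.

Each model predicts the residue ratio (concentration after storage divided by
the concentration entering storage: C1/C0 for wheat, C3/C2 for flour) as a
full second-order polynomial in storage time ``t`` (days), temperature ``T``
(degrees C) and relative humidity ``RH`` (percentage points):

    ratio = b0 + b_t*t + b_T*T + b_RH*RH
          + b_tt*t^2 + b_TT*T^2 + b_RHRH*RH^2
          + b_tT*t*T + b_tRH*t*RH + b_TRH*T*RH

The registry stores the ten published coefficients for five pesticides
(carbendazim, bensulfuron-methyl, triazophos, chlorpyrifos, carbosulfan) in
each of the two matrices, exactly as printed, so the table is auditable
against its source.  No refitting or correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import ClampWarning, ModelLookupError, ValidationError

__all__ = [
    "COEFFICIENT_NAMES",
    "MATRICES",
    "PESTICIDES",
    "QuadraticSurfaceModel",
    "builtin_model",
    "evaluate",
    "evaluate_clamped",
    "registry_table",
]

#: Canonical coefficient order, matching the design-matrix columns in
#: :mod:`residuechain.rsm`.
COEFFICIENT_NAMES = (
    "b0", "b_t", "b_T", "b_RH",
    "b_tt", "b_TT", "b_RHRH",
    "b_tT", "b_tRH", "b_TRH",
)

PESTICIDES = (
    "carbendazim",
    "bensulfuron-methyl",
    "triazophos",
    "chlorpyrifos",
    "carbosulfan",
)

MATRICES = ("wheat", "flour")


@dataclass(frozen=True)
class QuadraticSurfaceModel:
    """A ten-coefficient second-order surface for the residue ratio.

    Coefficient units follow the raw-variable parameterization: ``b_t`` is
    per day, ``b_T`` per degree C, ``b_RH`` per %RH, the quadratic and cross
    terms per the corresponding products.  ``r2_reported`` is the published
    coefficient of determination, or ``None`` for models fitted locally.
    """

    pesticide: str
    matrix: str
    b0: float
    b_t: float
    b_T: float
    b_RH: float
    b_tt: float
    b_TT: float
    b_RHRH: float
    b_tT: float
    b_tRH: float
    b_TRH: float
    r2_reported: float | None = None
    notes: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        for name in COEFFICIENT_NAMES:
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ValidationError(f"coefficient {name} is not finite: {value!r}")
        if self.r2_reported is not None and not 0.0 <= self.r2_reported <= 1.0:
            raise ValidationError(f"r2_reported outside [0, 1]: {self.r2_reported!r}")

    @property
    def coefficients(self) -> tuple[float, ...]:
        """The ten coefficients in canonical order."""
        return tuple(getattr(self, name) for name in COEFFICIENT_NAMES)

    def __call__(self, t: float, T: float, RH: float) -> float:
        return evaluate(self, t, T, RH)


def _require_finite(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value):
            raise ValidationError(f"argument {name} is not finite: {value!r}")


def evaluate(model: QuadraticSurfaceModel, t: float, T: float, RH: float) -> float:
    """Evaluate the raw (unclamped) polynomial at time, temperature, humidity.

    ``t`` in days (must be >= 0), ``T`` in degrees C, ``RH`` in percentage
    points (50 means 50 %).  Returns a dimensionless residue ratio; the
    polynomial is not constrained to [0, 1].
    """
    _require_finite(t=t, T=T, RH=RH)
    if t < 0:
        raise ValidationError(f"storage time must be non-negative, got {t!r}")
    return (
        model.b0
        + model.b_t * t + model.b_T * T + model.b_RH * RH
        + model.b_tt * t * t + model.b_TT * T * T + model.b_RHRH * RH * RH
        + model.b_tT * t * T + model.b_tRH * t * RH + model.b_TRH * T * RH
    )


def evaluate_clamped(
    model: QuadraticSurfaceModel, t: float, T: float, RH: float
) -> float:
    """Evaluate the polynomial and clamp the result into the physical [0, 1] range.

    A :class:`~residuechain.errors.ClampWarning` is emitted whenever clamping
    actually fires; the raw value is available via :func:`evaluate`.
    """
    value, clamped = _evaluate_clamped_flag(model, t, T, RH)
    if clamped:
        warnings.warn(
            f"{model.pesticide}/{model.matrix} ratio at (t={t}, T={T}, RH={RH}) "
            f"left [0, 1] and was clamped to {value}",
            ClampWarning,
            stacklevel=2,
        )
    return value


def _evaluate_clamped_flag(
    model: QuadraticSurfaceModel, t: float, T: float, RH: float
) -> tuple[float, bool]:
    raw = evaluate(model, t, T, RH)
    clamped = min(1.0, max(0.0, raw))
    return clamped, clamped != raw


# Coefficients kept verbatim as printed strings and parsed exactly once at
# import, so the registry can be proofread digit-for-digit against its source.
# Order per row: b0, b_t, b_T, b_RH, b_tt, b_TT, b_RHRH, b_tT, b_tRH, b_TRH.
_CARBENDAZIM_WHEAT_NOTE = (
    "The published carbendazim/wheat row prints its three cross terms with "
    "inconsistent subscripts (two apparent T*RH terms and no t*RH term); the "
    "three coefficients are mapped, in printed order, to the canonical "
    "(t*T, t*RH, T*RH) slots used by every other row."
)

_REGISTRY_ROWS: tuple[tuple[str, str, tuple[str, ...], str, str], ...] = (
    (
        "carbendazim", "wheat",
        ("0.438", "-0.00246", "0.0217", "-0.00184", "0.0000736", "-0.000312",
         "-0.00004015", "0.0000674", "0.00000585", "0.00005695"),
        "0.830", _CARBENDAZIM_WHEAT_NOTE,
    ),
    (
        "bensulfuron-methyl", "wheat",
        ("0.5", "-0.034575", "0.035875", "-0.007", "0.000285", "-0.00047",
         "0.000035", "0.000025", "-0.00003", "0.000001"),
        "0.817", "",
    ),
    (
        "triazophos", "wheat",
        ("0.298", "-0.02986", "0.046", "-0.00346", "0.000244", "-0.000666",
         "-0.000004", "-0.000008", "0.000002", "0.000036"),
        "0.852", "",
    ),
    (
        "chlorpyrifos", "wheat",
        ("0.586", "-0.03286", "0.02572", "-0.00434", "0.000276", "-0.000328",
         "0.000016", "-0.000028", "0.00001", "0.000006"),
        "0.868", "",
    ),
    (
        "carbosulfan", "wheat",
        ("0.728", "-0.02008", "0.01628", "-0.00171", "0.000157", "-0.000259",
         "-0.000007", "0.000019", "-0.000025", "-0.000017"),
        "0.863", "",
    ),
    (
        "carbendazim", "flour",
        ("1.756", "-0.05176", "-0.0042", "-0.01902", "0.000575", "0.000043",
         "0.0001", "0.0000412", "0.0000768", "-0.0000162"),
        "0.796", "",
    ),
    (
        "bensulfuron-methyl", "flour",
        ("1.738", "-0.05116", "0.0033", "0.0185", "0.000549", "-0.000095",
         "0.00007", "0.000006", "0.000116", "0.000081"),
        "0.802", "",
    ),
    (
        "triazophos", "flour",
        ("1.253", "-0.0411", "-0.0022", "-0.006", "0.000491", "0.00021",
         "-0.0000165", "0.0000065", "0.0000115", "0.0001"),
        "0.878", "",
    ),
    (
        "chlorpyrifos", "flour",
        ("0.968", "-0.05488", "-0.0106", "-0.00196", "0.00063", "-0.000192",
         "0.00002", "0.000018", "0.0000656", "0.000005"),
        "0.840", "",
    ),
    (
        "carbosulfan", "flour",
        ("1.314", "-0.03604", "0.01218", "-0.01", "0.000467", "0.000225",
         "0.0000344", "0.000023", "-0.000045", "-0.000008"),
        "0.863", "",
    ),
)

_REGISTRY: dict[tuple[str, str], QuadraticSurfaceModel] = {
    (pesticide, matrix): QuadraticSurfaceModel(
        pesticide=pesticide,
        matrix=matrix,
        **dict(zip(COEFFICIENT_NAMES, (float(c) for c in coeffs))),
        r2_reported=float(r2),
        notes=note,
    )
    for pesticide, matrix, coeffs, r2, note in _REGISTRY_ROWS
}


def builtin_model(pesticide: str, matrix: str) -> QuadraticSurfaceModel:
    """Look up a published degradation model by pesticide and matrix.

    Pesticide identifiers are lowercase hyphenated (e.g.
    ``"bensulfuron-methyl"``); matrices are ``"wheat"`` or ``"flour"``.
    """
    key = (pesticide, matrix)
    if key not in _REGISTRY:
        raise ModelLookupError(
            f"no built-in model for {pesticide!r}/{matrix!r}; "
            f"valid pesticides: {', '.join(PESTICIDES)}; "
            f"valid matrices: {', '.join(MATRICES)}"
        )
    return _REGISTRY[key]


def registry_table() -> pd.DataFrame:
    """The full registry as a tidy table: one row per pesticide x matrix.

    Columns: pesticide, matrix, the ten coefficients in canonical order and
    the published R^2.  Suitable for export as delimited text.
    """
    rows = [
        {
            "pesticide": m.pesticide,
            "matrix": m.matrix,
            **dict(zip(COEFFICIENT_NAMES, m.coefficients)),
            "r2_reported": m.r2_reported,
        }
        for m in _REGISTRY.values()
    ]
    return pd.DataFrame(rows)
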