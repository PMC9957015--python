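"""Delimited-text input/output for time-course tables and run artifacts.

All tables are comma-delimited UTF-8 with a header row; metadata (package
version, seed, units, free-form key-values) travels in ``#``-prefixed
comment lines before the header so every artifact records how it was
produced.  Matrix labels are lowercase {wheat, flour}; pesticide identifiers
lowercase hyphenated.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError, ValidationError
from .kinetics import ResidueTimeCourse

__all__ = [
    "STUDY_COLUMNS",
    "read_table",
    "read_timecourses",
    "table_to_timecourses",
    "timecourses_to_table",
    "write_table",
    "write_timecourses",
    "load_config",
    "dump_config",
]

STUDY_COLUMNS = (
    "pesticide",
    "matrix",
    "temperature_C",
    "rh_pct",
    "replicate",
    "day",
    "concentration_mg_kg",
    "censored",
)

_GROUP_KEY = ["pesticide", "matrix", "temperature_C", "rh_pct", "replicate"]


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a table as CSV with ``#`` metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    from . import __version__

    lines = [f"# residuechain {__version__}"]
    for key, value in (metadata or {}).items():
        lines.append(f"# {key}: {value}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\n".join(lines) + "\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (metadata lines are skipped)."""
    return pd.read_csv(path, comment="#")


def write_timecourses(table: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """Write a tidy study table, validating the schema first."""
    _check_schema(table)
    write_table(table[list(STUDY_COLUMNS)], path, metadata=metadata)


def _check_schema(df: pd.DataFrame) -> None:
    missing = [c for c in STUDY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")


def table_to_timecourses(df: pd.DataFrame) -> list[ResidueTimeCourse]:
    """Group a tidy study table into validated :class:`ResidueTimeCourse` objects."""
    _check_schema(df)
    courses = []
    for key, grp in df.groupby(_GROUP_KEY, sort=True):
        pesticide, matrix, T, RH, rep = key
        days = grp["day"].to_numpy(dtype=float)
        if days.size > 1 and not (pd.Series(days).diff().iloc[1:] > 0).all():
            raise ValidationError(
                f"days not strictly increasing within group {key}"
            )
        courses.append(
            ResidueTimeCourse(
                pesticide=str(pesticide),
                matrix=str(matrix),
                temperature_C=float(T),
                rh_pct=float(RH),
                replicate=int(rep),
                days=days,
                concentrations=grp["concentration_mg_kg"].to_numpy(dtype=float),
                censored=grp["censored"].to_numpy(dtype=bool),
            )
        )
    return courses


def timecourses_to_table(courses: list[ResidueTimeCourse]) -> pd.DataFrame:
    frames = []
    for tc in courses:
        frames.append(
            pd.DataFrame(
                {
                    "pesticide": tc.pesticide,
                    "matrix": tc.matrix,
                    "temperature_C": tc.temperature_C,
                    "rh_pct": tc.rh_pct,
                    "replicate": tc.replicate,
                    "day": tc.days,
                    "concentration_mg_kg": tc.concentrations,
                    "censored": tc.censored,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def read_timecourses(path) -> list[ResidueTimeCourse]:
    """Read a study CSV into validated, grouped time courses."""
    return table_to_timecourses(read_table(path))


def load_config(path) -> dict:
    """Load a nestable key-value (YAML) configuration file."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"config {path} must be a mapping at top level")
    return data


def dump_config(config: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
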