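"""Readers, writers and provenance-stamped summaries.

Draw-level output goes to CSV and machine-readable summaries to JSON; every
summary embeds the originating configuration, seed and package version so a
run can be reproduced from its artifacts alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .catch_curve import AgeComposition
from .growth import LengthAtAgeRecord

__all__ = [
    "read_length_at_age",
    "write_length_at_age",
    "read_age_composition",
    "read_species_table",
    "write_summary_json",
    "write_draws_csv",
]

LENGTH_AT_AGE_COLUMNS = ("age_years", "disc_width_mm")


class ValidationError(ValueError):
    """Raised for malformed input files; the message names the offending row."""


def read_length_at_age(path) -> list[LengthAtAgeRecord]:
    """Read and validate a length-at-age CSV (``age_years,disc_width_mm``).

    Row numbers in error messages are 1-based data rows (the header is row 0).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = set(LENGTH_AT_AGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: missing required columns {sorted(missing)}; "
            f"expected header {','.join(LENGTH_AT_AGE_COLUMNS)}"
        )
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        age, dw = row.age_years, row.disc_width_mm
        try:
            age_f = float(age)
            dw_f = float(dw)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {i}: non-numeric cell ({age!r}, {dw!r})")
        if not np.isfinite(age_f) or not np.isfinite(dw_f):
            raise ValidationError(f"{path} row {i}: non-finite value")
        if age_f < 0 or age_f != int(age_f):
            raise ValidationError(
                f"{path} row {i}: age_years must be a non-negative integer, got {age!r}"
            )
        if dw_f <= 0:
            raise ValidationError(
                f"{path} row {i}: disc_width_mm must be > 0, got {dw!r}"
            )
        records.append(LengthAtAgeRecord(int(age_f), dw_f))
    return records


def write_length_at_age(records, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "age_years": [r.age for r in records],
            "disc_width_mm": [r.disc_width for r in records],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def read_age_composition(path) -> AgeComposition:
    """Read a pre-tabulated composition CSV (``age_class,count``)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = {"age_class", "count"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    counts = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            age = int(row.age_class)
            n = float(row.count)
        except (TypeError, ValueError):
            raise ValidationError(f"{path} row {i}: non-numeric cell")
        if age < 0 or n < 0:
            raise ValidationError(f"{path} row {i}: negative age or count")
        counts[age] = n
    return AgeComposition(counts=counts)


def read_species_table(path) -> pd.DataFrame:
    """Read a species life-history table for the batch r_max mode."""
    path = Path(path)
    df = pd.read_csv(path)
    required = {
        "species", "b_low", "b_high",
        "alpha_mat_low", "alpha_mat_high", "alpha_max_low", "alpha_max_high",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    return df


def write_summary_json(summary: dict, path, *, config: dict | None = None,
                       seed: int | None = None) -> Path:
    """Write a summary dict with provenance (config, seed, package version)."""
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "summary": _jsonable(summary),
        "provenance": {
            "config": _jsonable(config or {}),
            "seed": seed,
            "package": "elasmodemo",
            "version": __version__,
        },
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def write_draws_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (bool, int, float, str)) or obj is None:
        return obj
    return str(obj)
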