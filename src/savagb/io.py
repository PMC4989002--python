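"""Schema-validated CSV exchange for the pipeline's tables.

Each table kind has a documented header; readers check required columns,
warn on unknown ones (which are preserved on pass-through), and collect
row-level validation failures with their 1-based data line numbers rather
than aborting on the first bad row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import pandas as pd


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    # column -> predicate on the column Series returning a boolean mask of
    # VALID rows, plus a message for invalid ones
    row_checks: tuple[tuple[str, Callable[[pd.Series], pd.Series], str], ...] = ()


def _positive(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col, errors="coerce") > 0


def _non_negative(col: pd.Series) -> pd.Series:
    return pd.to_numeric(col, errors="coerce") >= 0


SCHEMAS: dict[str, TableSchema] = {
    "inventory": TableSchema(
        "inventory",
        ("tree_id", "plot_id", "luca", "species", "dbh_cm", "height_m", "density"),
        (
            ("dbh_cm", _positive, "DBH must be positive"),
            ("height_m", _positive, "height must be positive"),
            ("density", _positive, "wood density must be positive"),
        ),
    ),
    "cores": TableSchema(
        "cores",
        ("core_id", "species", "dry_mass_g", "bit_diameter_cm", "core_length_cm"),
        (
            ("dry_mass_g", _non_negative, "dry mass must be non-negative"),
            ("bit_diameter_cm", _positive, "bit diameter must be positive"),
            ("core_length_cm", _positive, "core length must be positive"),
        ),
    ),
    "destructive_components": TableSchema(
        "destructive_components",
        ("tree_id", "component", "fresh_mass_kg", "sample_fresh_kg", "sample_dry_kg"),
        (
            ("fresh_mass_kg", _non_negative, "fresh mass must be non-negative"),
            ("sample_fresh_kg", _positive, "subsample fresh mass must be positive"),
            ("sample_dry_kg", _non_negative, "subsample dry mass must be non-negative"),
        ),
    ),
    "density_summary": TableSchema(
        "density_summary",
        ("species", "n", "mean_density", "se", "min_density", "max_density"),
    ),
    "ivi": TableSchema(
        "ivi",
        ("species", "rd", "rf", "rdom", "ivi", "rank", "selected_main_species"),
    ),
    "lulc_summary": TableSchema(
        "lulc_summary",
        (
            "lulc", "n_plots", "mean_density", "se_density", "pct_error",
            "area_ha", "total_stock", "se_stock", "min_density", "max_density",
        ),
    ),
    "plot_densities": TableSchema(
        "plot_densities",
        ("plot_id", "lulc", "plot_area_ha", "agb_density"),
        (
            ("plot_area_ha", _positive, "plot area must be positive"),
            ("agb_density", _non_negative, "density must be non-negative"),
        ),
    ),
}


def read_table(
    path: str | Path, schema_name: str
) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Read and validate a CSV table.

    Returns ``(valid_rows, errors)`` where errors is a list of
    ``(line_number, message)`` for rejected rows (line 1 is the first data
    row after the header).  Missing required columns raise; unknown
    columns warn and are preserved.
    """
    schema = SCHEMAS[schema_name]
    df = pd.read_csv(path)
    missing = set(schema.required) - set(df.columns)
    if missing:
        raise ValueError(f"{schema.name}: missing required columns {sorted(missing)}")
    extra = set(df.columns) - set(schema.required)
    if extra:
        warnings.warn(
            f"{schema.name}: unknown columns {sorted(extra)} preserved",
            stacklevel=2,
        )
    errors: list[tuple[int, str]] = []
    keep = pd.Series(True, index=df.index)
    for col, check, message in schema.row_checks:
        ok = check(df[col]).fillna(False)
        for idx in df.index[~ok]:
            errors.append((int(idx) + 1, f"{col}: {message}"))
        keep &= ok
    return df[keep].reset_index(drop=True), errors


def write_table(df: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a table, verifying its header matches the schema."""
    schema = SCHEMAS[schema_name]
    missing = set(schema.required) - set(df.columns)
    if missing:
        raise ValueError(f"{schema.name}: missing required columns {sorted(missing)}")
    df.to_csv(path, index=False)
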