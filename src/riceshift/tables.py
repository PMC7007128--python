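"""CSV schemas and validated table I/O.

Every table that crosses the package boundary is a UTF-8, comma-separated
CSV with a mandatory header, "." decimal point and one fixed column order
per schema.  ``read_table`` rejects headers that do not match exactly and
rows that violate the domain invariants; ``write_table`` writes values at
12 significant digits with a deterministic row sort so that write-read is
an identity to that precision and reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    AGE_BINS,
    FOODS,
    MEASURES,
    NUTRIENTS,
    SEXES,
    STATES,
    UNITS,
    VEHICLES,
    SchemaError,
    ValidationError,
)

_FLOAT_FMT = "%.12g"


def _check_range(df: pd.DataFrame, col: str, lo=None, hi=None, strict_lo=False) -> None:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & df[col].notna()
    if lo is not None:
        bad |= (s < lo) if not strict_lo else (s <= lo)
    if hi is not None:
        bad |= s > hi
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"column {col!r} out of range at row {i}: {df[col].iloc[i]!r}")


def _check_enum(df: pd.DataFrame, col: str, allowed) -> None:
    bad = ~df[col].isin(allowed)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"unknown {col} code {df[col].iloc[i]!r} at row {i}")


def _check_units(df: pd.DataFrame) -> None:
    expect = df["nutrient"].map(UNITS)
    bad = df["unit"] != expect
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"unit {df['unit'].iloc[i]!r} at row {i} does not match nutrient "
            f"{df['nutrient'].iloc[i]!r} (expected {expect.iloc[i]!r})"
        )


def _v_supplies(df: pd.DataFrame) -> None:
    _check_enum(df, "sex", SEXES)
    _check_enum(df, "nutrient", NUTRIENTS)
    _check_enum(df, "age_low", AGE_BINS)
    _check_range(df, "supply", lo=0)
    _check_range(df, "se", lo=0)
    _check_units(df)


def _v_population(df: pd.DataFrame) -> None:
    _check_enum(df, "sex", SEXES)
    _check_enum(df, "age_low", AGE_BINS)
    _check_range(df, "population", lo=0)


def _v_fertility(df: pd.DataFrame) -> None:
    _check_enum(df, "age_low", AGE_BINS)
    _check_range(df, "asfr", lo=0)


def _v_breastfeeding(df: pd.DataFrame) -> None:
    _check_range(df, "mean_duration_months", lo=0)


def _v_requirements(df: pd.DataFrame) -> None:
    _check_enum(df, "nutrient", NUTRIENTS)
    _check_enum(df, "sex", SEXES)
    _check_enum(df, "state", STATES)
    _check_range(df, "rni", lo=0, strict_lo=True)
    _check_range(df, "ear_factor", lo=0, strict_lo=True)
    _check_units(df)
    bad = df["age_low"] >= df["age_high"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"age_low >= age_high at row {i}")


def _v_fortification(df: pd.DataFrame) -> None:
    _check_enum(df, "vehicle", VEHICLES)
    _check_enum(df, "nutrient", NUTRIENTS)
    _check_range(df, "level_mg_per_kg", lo=0)
    _check_range(df, "standardization_factor", lo=0, hi=1, strict_lo=True)
    _check_range(df, "pct_processed", lo=0, hi=1)
    _check_range(df, "pct_processed_fortified", lo=0, hi=1)


def _v_interval(df: pd.DataFrame) -> None:
    bad = (df["lo95"] > df["mean"]) | (df["mean"] > df["hi95"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"interval does not bracket mean at row {i}")


def _v_loss_factors(df: pd.DataFrame) -> None:
    _check_enum(df, "nutrient", NUTRIENTS)
    _check_range(df, "mean_frac_change", lo=-1, hi=1)
    bad = (df["lo95"] > df["mean_frac_change"]) | (df["mean_frac_change"] > df["hi95"])
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"interval does not bracket mean at row {i}")


def _v_burden(df: pd.DataFrame) -> None:
    _check_enum(df, "measure", MEASURES)
    _check_range(df, "mean", lo=0)
    _v_interval(df)


def _v_dose_response(df: pd.DataFrame) -> None:
    _check_range(df, "risk_per_1000", lo=0, strict_lo=True)
    d = np.diff(df["intake"].to_numpy(dtype=float))
    if len(d) and (d <= 0).any():
        raise ValidationError("dose-response intakes must be strictly increasing")


def _v_vehicle_intake(df: pd.DataFrame) -> None:
    _check_enum(df, "food", FOODS)
    _check_range(df, "grams_per_day", lo=0)


#: schema name -> (column order, key columns for the deterministic sort,
#: row validator or None)
SCHEMAS: dict[str, tuple[list[str], list[str], object]] = {
    "supplies": (
        ["country", "year", "sex", "age_low", "food", "nutrient", "supply", "unit", "se"],
        ["country", "year", "sex", "age_low", "food", "nutrient"],
        _v_supplies,
    ),
    "population": (
        ["country", "year", "sex", "age_low", "population"],
        ["country", "year", "sex", "age_low"],
        _v_population,
    ),
    "fertility": (["country", "age_low", "asfr"], ["country", "age_low"], _v_fertility),
    "breastfeeding": (
        ["country", "mean_duration_months"],
        ["country"],
        _v_breastfeeding,
    ),
    "requirements": (
        ["nutrient", "sex", "age_low", "age_high", "state", "rni", "unit", "ear_factor"],
        ["nutrient", "sex", "state", "age_low"],
        _v_requirements,
    ),
    "fortification": (
        ["country", "vehicle", "nutrient", "fortificant", "level_mg_per_kg",
         "standardization_factor", "pct_processed", "pct_processed_fortified"],
        ["country", "vehicle", "nutrient"],
        _v_fortification,
    ),
    "loss_factors": (
        ["nutrient", "mean_frac_change", "lo95", "hi95"],
        ["nutrient"],
        _v_loss_factors,
    ),
    "burden": (["country", "measure", "mean", "lo95", "hi95"], ["country", "measure"], _v_burden),
    "dose_response": (["intake", "risk_per_1000"], ["intake"], _v_dose_response),
    "regions": (["country", "region"], ["country"], None),
    "vehicle_intake": (
        ["country", "food", "grams_per_day"],
        ["country", "food"],
        _v_vehicle_intake,
    ),
    # outputs
    "ear": (
        ["country", "sex", "age_low", "nutrient", "ear"],
        ["country", "sex", "age_low", "nutrient"],
        None,
    ),
    "added_nutrient": (
        ["country", "sex", "age_low", "nutrient", "added"],
        ["country", "sex", "age_low", "nutrient"],
        None,
    ),
    "adequacy": (
        ["country", "sex", "age_low", "nutrient", "scenario", "prevalence", "population_at_risk"],
        ["country", "sex", "age_low", "nutrient", "scenario"],
        None,
    ),
    "scenario": (
        ["country", "sex", "age_low", "nutrient", "ratio", "prev_current", "prev_eco2",
         "delta_points", "newly_at_risk", "already_deficient"],
        ["country", "sex", "age_low", "nutrient"],
        None,
    ),
    "burden_out": (
        ["country", "pif", "attributable_deaths", "attributable_dalys",
         "deaths_rate_per_million", "dalys_rate_per_million"],
        ["country"],
        None,
    ),
    "results": (
        ["scope", "nutrient", "metric", "point", "lo95", "hi95", "n_draws", "seed"],
        ["scope", "nutrient", "metric"],
        None,
    ),
}

_INT_COLUMNS = {"year", "age_low", "age_high", "n_draws", "seed"}


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    """Read and validate one CSV against a named schema.

    Raises :class:`SchemaError` on a header mismatch (naming the offending
    columns) and :class:`ValidationError` on the first invariant-violating
    row.  Row order is preserved.
    """
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    columns, _, validator = SCHEMAS[schema_name]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype={"country": str, "region": str})
    if list(df.columns) != columns:
        missing = [c for c in columns if c not in df.columns]
        extra = [c for c in df.columns if c not in columns]
        raise SchemaError(
            f"{path.name}: header does not match schema {schema_name!r}"
            f" (missing {missing}, unexpected {extra}, order must be {columns})"
        )
    for col in df.columns:
        if col in _INT_COLUMNS:
            df[col] = df[col].astype(int)
    if validator is not None and len(df):
        validator(df)
    return df


def write_table(df: pd.DataFrame, path: str | Path, schema_name: str) -> None:
    """Write a table in its schema's column order with a deterministic sort."""
    if schema_name not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema_name!r}")
    columns, sort_keys, _ = SCHEMAS[schema_name]
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"records lack columns {missing} required by {schema_name!r}")
    out = df.loc[:, columns]
    if len(out) and sort_keys:
        out = out.sort_values(sort_keys, kind="mergesort").reset_index(drop=True)
    out.to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_results(df: pd.DataFrame, path: str | Path, schema_name: str = "results") -> None:
    """Write a result table (sorted, re-readable by :func:`read_table`)."""
    write_table(df, path, schema_name)


def tables_equal(a: pd.DataFrame, b: pd.DataFrame, rel: float = 1e-11) -> bool:
    """Compare two tables column-wise, numerics to a relative tolerance."""
    if list(a.columns) != list(b.columns) or len(a) != len(b):
        return False
    for col in a.columns:
        x, y = a[col], b[col]
        if pd.api.types.is_numeric_dtype(x) and pd.api.types.is_numeric_dtype(y):
            xv, yv = x.to_numpy(dtype=float), y.to_numpy(dtype=float)
            both_nan = np.isnan(xv) & np.isnan(yv)
            ok = both_nan | np.isclose(xv, yv, rtol=rel, atol=0.0)
            if not ok.all():
                return False
        else:
            if not (x.fillna("").astype(str) == y.fillna("").astype(str)).all():
                return False
    return True


def checksum(path: str | Path) -> str:
    import hashlib

    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
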