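"""Validated table I/O: schema checks, invariant rejection, round trips."""

import numpy as np
import pandas as pd
import pytest

from riceshift import pipeline, read_table, write_table
from riceshift.model import SchemaError, ValidationError
from riceshift.tables import SCHEMAS, tables_equal


def test_round_trip_identity_on_world_tables(small_world, tmp_path):
    """write then read reproduces every bundled input table."""
    for name, df in small_world.items():
        path = tmp_path / f"{name}.csv"
        write_table(df, path, name)
        back = read_table(path, name)
        # write_table sorts rows; compare against the sorted original
        cols, keys, _ = SCHEMAS[name]
        expected = df.loc[:, cols].sort_values(keys, kind="mergesort").reset_index(drop=True)
        assert tables_equal(expected, back), name


def test_round_trip_preserves_12_significant_digits(tmp_path):
    rng = np.random.default_rng(5)
    df = pd.DataFrame(
        {
            "country": ["A"] * 20,
            "measure": ["deaths"] * 10 + ["dalys"] * 10,
            "mean": rng.uniform(10, 1e6, 20),
        }
    )
    df["lo95"] = df["mean"] * 0.8
    df["hi95"] = df["mean"] * 1.3
    path = tmp_path / "burden.csv"
    write_table(df, path, "burden")
    back = read_table(path, "burden")
    merged = df.sort_values(["country", "measure"], kind="mergesort").reset_index(drop=True)
    for col in ("mean", "lo95", "hi95"):
        assert np.allclose(merged[col], back[col], rtol=1e-11, atol=0)


def test_empty_collection_writes_header_only(tmp_path):
    cols, _, _ = SCHEMAS["burden"]
    write_table(pd.DataFrame(columns=cols), tmp_path / "b.csv", "burden")
    text = (tmp_path / "b.csv").read_text().strip()
    assert text == ",".join(cols)


def test_rows_written_in_sorted_order(tmp_path):
    df = pd.DataFrame(
        {
            "country": ["B", "A"],
            "measure": ["deaths", "deaths"],
            "mean": [2.0, 1.0],
            "lo95": [1.5, 0.5],
            "hi95": [2.5, 1.5],
        }
    )
    write_table(df, tmp_path / "b.csv", "burden")
    back = read_table(tmp_path / "b.csv", "burden")
    assert list(back["country"]) == ["A", "B"]


def test_header_mismatch_names_columns(tmp_path):
    (tmp_path / "bad.csv").write_text("country,measure,mean,lo95\nA,deaths,1,0.5\n")
    with pytest.raises(SchemaError, match="hi95"):
        read_table(tmp_path / "bad.csv", "burden")


@pytest.mark.parametrize(
    ("column", "bad_value", "match"),
    [
        ("supply", -1.0, "supply"),
        ("se", -0.5, "se"),
        ("sex", "unknown", "sex"),
        ("nutrient", "vitamin-x", "nutrient"),
        ("age_low", 3, "age_low"),
        ("unit", "mg", "unit"),  # folate rows must carry ug
    ],
)
def test_single_field_violations_rejected(tmp_path, column, bad_value, match):
    """Mutating any one validated field of a good row triggers rejection."""
    df = pd.DataFrame(
        [
            {
                "country": "A", "year": 2010, "sex": "female", "age_low": 20,
                "food": "rice", "nutrient": "folate", "supply": 100.0,
                "unit": "ug", "se": 5.0,
            }
        ]
    )
    df[column] = bad_value
    path = tmp_path / "supplies.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match=match):
        read_table(path, "supplies")


def test_validation_error_reports_row_index(tmp_path):
    df = pd.DataFrame(
        {
            "country": ["A", "A"], "year": [2010, 2010], "sex": ["female"] * 2,
            "age_low": [20, 25], "food": ["rice"] * 2, "nutrient": ["folate"] * 2,
            "supply": [100.0, -3.0], "unit": ["ug"] * 2, "se": [0.0, 0.0],
        }
    )
    path = tmp_path / "supplies.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="row 1"):
        read_table(path, "supplies")


def test_world_save_load_round_trip(small_world, tmp_path):
    pipeline.save_world(small_world, tmp_path)
    back = pipeline.load_world(tmp_path)
    assert set(back) == set(pipeline.INPUT_SCHEMAS)
    for name in pipeline.INPUT_SCHEMAS:
        assert len(back[name]) == len(small_world[name])
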