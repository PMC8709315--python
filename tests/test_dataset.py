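"""Container, CSV round trips and mask algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from misurv.dataset import (ColumnSpec, MissingnessMask, SchemaError,
                            TabularDataset, apply_mask, extract_mask,
                            load_schema, make_schema, read_mask, read_table,
                            save_schema, write_mask, write_table)

from conftest import make_mvn_dataset


def test_na_tokens_read_as_missing(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("EGFR,KRAS,time_at_risk,event\n"
                    "NA,1,10,1\n0,n.a.,20,0\n1,,30,1\n")
    ds = read_table(path, make_schema(["EGFR", "KRAS"], "binary"))
    assert ds.features["EGFR"].isna().tolist() == [True, False, False]
    assert ds.features["KRAS"].isna().tolist() == [False, True, True]
    assert ds.survival["time_at_risk"].tolist() == [10, 20, 30]


def test_roundtrip_bitwise(tmp_path):
    ds = make_mvn_dataset(n=10, p=3, seed=1, miss_frac=0.3)
    path = write_table(ds, tmp_path / "rt.csv")
    back = read_table(path, ds.schema)
    pd.testing.assert_frame_equal(ds.features, back.features)
    pd.testing.assert_frame_equal(ds.survival, back.survival)


def test_written_file_has_na_exactly_at_masked_cells(tmp_path):
    ds = make_mvn_dataset(n=8, p=2, seed=2)
    mask = MissingnessMask(np.eye(8, 2, dtype=int), ds.feature_names)
    masked = apply_mask(ds, mask)
    text = (tmp_path / "m.csv")
    write_table(masked, text)
    rows = text.read_text().strip().splitlines()[1:]
    na_cells = [(i, j) for i, row in enumerate(rows)
                for j, cell in enumerate(row.split(",")[:2]) if cell == "NA"]
    assert na_cells == [(0, 0), (1, 1)]


def test_read_errors(tmp_path):
    no_surv = tmp_path / "a.csv"
    no_surv.write_text("x0\n1\n")
    with pytest.raises(SchemaError, match="survival"):
        read_table(no_surv, make_schema(["x0"], "continuous"))
    bad = tmp_path / "b.csv"
    bad.write_text("x0,time_at_risk,event\nfoo,1,1\n2,2,0\n")
    with pytest.raises(SchemaError, match="x0"):
        read_table(bad, make_schema(["x0"], "continuous"))


def test_write_requires_survival_and_features():
    ds = make_mvn_dataset(n=5, p=2, with_survival=False)
    with pytest.raises(SchemaError):
        write_table(ds, "/tmp/nope.csv")


def test_schema_yaml_roundtrip(tmp_path):
    schema = [ColumnSpec("a", "continuous"), ColumnSpec("b", "binary"),
              ColumnSpec("c", "categorical", ("lo", "mid", "hi"))]
    save_schema(schema, tmp_path / "s.yaml")
    assert load_schema(tmp_path / "s.yaml") == schema


def test_mask_roundtrip(tmp_path):
    ds = make_mvn_dataset(n=12, p=3, seed=7, miss_frac=0.4)
    mask = extract_mask(ds)
    write_mask(mask, tmp_path / "m.csv")
    back = read_mask(tmp_path / "m.csv")
    assert np.array_equal(back.grid, mask.grid)
    assert back.column_names == mask.column_names


def test_extract_mask_identity_cases():
    complete = make_mvn_dataset(n=6, p=2, seed=0)
    assert extract_mask(complete).grid.sum() == 0
    one = complete.copy()
    one.features.iloc[2, 1] = np.nan
    m = extract_mask(one)
    assert m.grid.sum() == 1 and m.grid[2, 1] == 1


def test_apply_mask_contract():
    ds = make_mvn_dataset(n=10, p=3, seed=4)
    zero = MissingnessMask(np.zeros((10, 3), dtype=int), ds.feature_names)
    assert apply_mask(ds, zero).equals(ds)
    ones = MissingnessMask(np.ones((10, 3), dtype=int), ds.feature_names)
    assert apply_mask(ds, ones).features.isna().all().all()
    with pytest.raises(ValueError):
        apply_mask(ds, MissingnessMask(np.zeros((9, 3), dtype=int),
                                       ds.feature_names))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(seed=st.integers(0, 10_000), frac=st.floats(0.0, 0.6))
def test_mask_union_property(seed, frac):
    """extract_mask(apply_mask(d, m)) == elementwise OR of both masks."""
    rng = np.random.default_rng(seed)
    ds = make_mvn_dataset(n=20, p=5, seed=seed, miss_frac=0.2)
    m = MissingnessMask((rng.uniform(size=(20, 5)) < frac).astype(int),
                        ds.feature_names)
    combined = extract_mask(apply_mask(ds, m))
    expected = np.maximum(extract_mask(ds).grid, m.grid)
    assert np.array_equal(combined.grid, expected)


def test_invariant_violations_rejected():
    feats = pd.DataFrame({"b": [0.0, 2.0]})
    with pytest.raises(SchemaError, match="binary"):
        TabularDataset(feats, None, make_schema(["b"], "binary"))
    good = pd.DataFrame({"x": [1.0, 2.0]})
    surv = pd.DataFrame({"time_at_risk": [-1.0, 2.0], "event": [1.0, 0.0]})
    with pytest.raises(SchemaError, match="non-negative"):
        TabularDataset(good, surv, make_schema(["x"], "continuous"))
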