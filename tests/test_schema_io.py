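"""Schema validation, CSV parsing, filtering, shape transform, summaries."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import morphodist as md
from morphodist.schema_io import DomainError, SchemaError, ValidationError

HEADER = (
    "PHASE,RMA,CPE,LEN,WID,THI,EPA,SHA,BUL,ESC,LIP,HCO,PTY,PWI,PTH,NNU,NOR"
)
ROW = "1,1,10,30,25,8,80,2,3,0,0,1,2,15,5,3,1"


def _csv(rows):
    return io.StringIO(HEADER + "\n" + "\n".join(rows) + "\n")


class TestSchema:
    def test_default_schema_structure(self, schema):
        assert len(schema) == 16
        assert schema.geometry_names == ["LEN", "WID", "THI", "PWI", "PTH"]
        assert schema.ordinal_names == ["BUL", "NNU"]
        assert len(schema.continuous_names) == 7
        assert len(schema.nominal_names) == 7

    def test_ordinal_needs_levels(self):
        with pytest.raises(SchemaError):
            md.Variable(name="X", scale="ordinal")

    def test_geometry_must_be_continuous(self):
        with pytest.raises(SchemaError):
            md.Variable(name="X", scale="nominal", levels=("0", "1"), geometry=True)

    def test_duplicate_names_rejected(self, schema):
        with pytest.raises(SchemaError):
            md.Schema(variables=(schema.variables[0], schema.variables[0]))


class TestReadTable:
    def test_identity_parse(self, schema):
        t = md.read_table(_csv([ROW, ROW, ROW]), schema)
        assert t.n == 3
        assert int(t.missing_mask.to_numpy().sum()) == 0
        assert list(t.group) == ["1", "1", "1"]

    def test_empty_cell_is_missing(self, schema):
        row = ROW.split(",")
        row[3] = ""  # LEN
        t = md.read_table(_csv([",".join(row)]), schema)
        assert bool(t.missing_mask.loc[0, "LEN"])

    @pytest.mark.parametrize("token", ["NA", "na", "N/A", "NaN", "NA´s"])
    def test_na_tokens_are_missing(self, schema, token):
        row = ROW.split(",")
        row[8] = token  # BUL
        t = md.read_table(_csv([",".join(row)]), schema)
        assert bool(t.missing_mask.loc[0, "BUL"])

    def test_out_of_level_value_rejected(self, schema):
        row = ROW.split(",")
        row[12] = "7"  # PTY has levels 1..6
        with pytest.raises(ValidationError, match="PTY"):
            md.read_table(_csv([",".join(row)]), schema)

    def test_missing_column_named(self, schema):
        buf = io.StringIO("PHASE,RMA\n1,1\n")
        with pytest.raises(SchemaError, match="CPE"):
            md.read_table(buf, schema)

    def test_labels_accepted_as_codes(self, schema):
        row = ROW.split(",")
        row[1] = "Dolerite"
        t = md.read_table(_csv([",".join(row)]), schema)
        assert t.data.loc[0, "RMA"] == "1"


class TestFilter:
    @pytest.mark.parametrize(
        "n_vars,frac,expect", [(16, 0.20, 3), (16, 0.0, 0), (10, 0.25, 2), (16, 1.0, 16)]
    )
    def test_max_missing_count(self, n_vars, frac, expect):
        assert md.max_missing_count(n_vars, frac) == expect

    def test_threshold_application(self, schema):
        rows = []
        for k in (0, 3, 4, 16):  # missing counts
            row = ROW.split(",")
            for j in range(k):
                row[1 + j] = ""  # blank k attribute cells
            rows.append(",".join(row))
        t = md.read_table(_csv(rows), schema)
        out = md.filter_flakes(t, md.FilterConfig(max_missing_fraction=0.20))
        assert out.n == 2

    def test_requires_group_label(self, schema):
        row = ROW.split(",")
        row[0] = ""
        t = md.read_table(_csv([ROW, ",".join(row)]), schema)
        assert md.filter_flakes(t).n == 1

    def test_idempotent(self, small_assemblage):
        table, _ = small_assemblage
        t = md.inject_missing(table, 0.1, 0)
        once = md.filter_flakes(t)
        twice = md.filter_flakes(once)
        pd.testing.assert_frame_equal(once.data, twice.data)

    def test_empty_result_warns(self, schema):
        row = ",".join([""] * 17)
        t = md.read_table(_csv([row]), schema)
        with pytest.warns(UserWarning, match="empty"):
            md.filter_flakes(t)


class TestShapeTransform:
    def _table(self, schema, geo_vals):
        row = ROW.split(",")
        for name, v in zip(["LEN", "WID", "THI", "PWI", "PTH"], geo_vals):
            row[HEADER.split(",").index(name)] = str(v)
        return md.read_table(_csv([",".join(row)]), schema)

    def test_equal_values_map_to_one(self, schema):
        t = md.to_shape_variables(self._table(schema, [10, 10, 10, 10, 10]))
        assert np.allclose(t.data[schema.geometry_names].iloc[0], 1.0)

    def test_powers_of_two(self, schema):
        t = md.to_shape_variables(self._table(schema, [2, 4, 8, 16, 32]))
        got = t.data[["LEN", "WID", "THI", "PWI", "PTH"]].iloc[0].to_numpy()
        assert np.allclose(got, [0.25, 0.5, 1.0, 2.0, 4.0])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        vals=st.lists(st.floats(0.5, 200.0), min_size=5, max_size=5),
        c=st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, schema, vals, c):
        t1 = md.to_shape_variables(self._table(schema, vals))
        t2 = md.to_shape_variables(self._table(schema, [v * c for v in vals]))
        a = t1.data[schema.geometry_names].to_numpy()
        b = t2.data[schema.geometry_names].to_numpy()
        assert np.allclose(a, b, rtol=1e-9)

    def test_product_is_one(self, small_assemblage, schema):
        table, _ = small_assemblage
        t = md.to_shape_variables(table)
        prod = t.data[schema.geometry_names].to_numpy().prod(axis=1)
        assert np.allclose(prod, 1.0, atol=1e-10)

    def test_partial_record_uses_observed_subset(self, schema):
        t = self._table(schema, [2, 8, "", "", ""])
        out = md.to_shape_variables(t)
        got = out.data[["LEN", "WID"]].iloc[0].to_numpy()
        assert np.allclose(got, [0.5, 2.0])  # gm of {2, 8} is 4
        assert np.isnan(out.data.loc[0, "THI"])

    def test_strict_mode_leaves_partial_untouched(self, schema):
        t = self._table(schema, [2, 8, "", "", ""])
        out = md.to_shape_variables(t, mode="strict")
        assert out.data.loc[0, "LEN"] == 2.0

    def test_nonpositive_rejected(self, schema):
        with pytest.raises(DomainError):
            md.to_shape_variables(self._table(schema, [0, 1, 1, 1, 1]))


class TestSummarize:
    def test_level_counts_plus_na_equals_n(self, small_assemblage):
        table, _ = small_assemblage
        t = md.inject_missing(table, 0.15, 3)
        s = md.summarize(t)
        for var in t.schema.names:
            sub = s[s["variable"] == var]
            if sub["scale"].iloc[0] == "continuous":
                continue
            counts = sub[sub["statistic"] != "NA's"]["value"].sum()
            na = sub[sub["statistic"] == "NA's"]["value"].iloc[0]
            assert counts + na == t.n

    def test_constant_column(self, schema):
        rows = []
        for _ in range(4):
            row = ROW.split(",")
            row[2] = "5"  # CPE
            rows.append(",".join(row))
        s = md.summarize(md.read_table(_csv(rows), schema))
        sub = s[s["variable"] == "CPE"].set_index("statistic")["value"]
        assert sub["Min."] == sub["Max."] == sub["Mean"] == 5

    def test_fully_missing_column_flagged(self, schema):
        row = ROW.split(",")
        row[2] = ""
        s = md.summarize(md.read_table(_csv([",".join(row)]), schema))
        sub = s[s["variable"] == "CPE"].set_index("statistic")["value"]
        assert sub["NA's"] == 1
        assert np.isnan(sub["Mean"])
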