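"""Import/export: four dialects, NA/negative policy, merging, results CSV."""

import numpy as np
import pytest

from toxpi.data import DataError, DataTable
from toxpi.data_io import merge_tables, read_table, write_model_file, write_results_csv
from toxpi.fixtures import (
    default_model,
    generate_dataset,
    write_column_annotated_csv,
    write_complete_csv,
    write_matrix_csv,
    write_row_annotated_csv,
)
from toxpi.model import SliceDef, ToxPiModel
from toxpi.scoring import score


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadTable:
    def test_basic_matrix(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a,b\nr1,1,2\nr2,3,4\n")
        table, model, rep = read_table(p)
        assert rep.dialect == "matrix" and model is None
        assert table.entity_ids == ["r1", "r2"]
        assert table.metric_ids == ["a", "b"]
        np.testing.assert_array_equal(table.values, [[1.0, 2.0], [3.0, 4.0]])
        assert not table.missing_mask.any()

    def test_negative_becomes_missing(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a,b\nr1,-5,2\n")
        table, _, rep = read_table(p)
        assert table.missing_mask[0, 0] and not table.missing_mask[0, 1]
        assert rep.n_negative_dropped == 1 and rep.n_missing_na == 0

    def test_na_token_is_missing(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a,b\nr1,NA,2\n")
        table, _, rep = read_table(p)
        assert table.missing_mask[0, 0]
        assert rep.n_missing_na == 1 and rep.n_negative_dropped == 0

    def test_zero_is_retained(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a\nr1,0\n")
        table, _, rep = read_table(p)
        assert not table.missing_mask.any() and table.values[0, 0] == 0.0

    @pytest.mark.parametrize("token", ["na", "n/a", "", "null", "NaN", "x"])
    def test_other_tokens_hard_error(self, tmp_path, token):
        p = _write(tmp_path, "m.csv", f"id,a\nr1,{token}\n")
        with pytest.raises(DataError, match="non-numeric|ragged"):
            read_table(p)

    def test_error_locates_bad_cell(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a,b\nr1,1,2\nr2,1,oops\n")
        with pytest.raises(DataError, match=r"row 3.*'b'"):
            read_table(p)

    def test_duplicate_names_error(self, tmp_path):
        with pytest.raises(DataError, match="duplicate entity.*r1"):
            read_table(_write(tmp_path, "a.csv", "id,a\nr1,1\nr1,2\n"))
        with pytest.raises(DataError, match="duplicate metric.*a"):
            read_table(_write(tmp_path, "b.csv", "id,a,a\nr1,1,2\n"))

    def test_ragged_rows_error(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a,b\nr1,1\n")
        with pytest.raises(DataError, match="ragged"):
            read_table(p)

    def test_scientific_notation(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,a\nr1,1.5e-3\n")
        table, _, _ = read_table(p)
        assert table.values[0, 0] == 1.5e-3

    def test_row_annotated_detection(self, tmp_path):
        p = _write(tmp_path, "m.csv", "id,class,a\nr1,Foo,1\nr2,Bar,2\n")
        table, _, rep = read_table(p)
        assert rep.dialect == "row_annotated"
        assert table.entity_class == ["Foo", "Bar"]

    def test_column_annotated_detection(self, tmp_path):
        p = _write(
            tmp_path, "m.csv",
            "slice,S1,S1\nweight,1.0,1.0\nid,a,b\nr1,1,2\n",
        )
        table, model, rep = read_table(p)
        assert rep.dialect == "column_annotated" and model is None
        assert rep.annotations["slice"] == ["S1", "S1"]
        assert table.metric_ids == ["a", "b"]


class TestDialectEquivalence:
    def test_four_dialects_parse_to_identical_data(self, tmp_path):
        data = generate_dataset(n_entities=15, n_metrics=8, missing_frac=0.1,
                                negative_frac=0.05, seed=11)
        model = default_model(data.to_table())
        write_matrix_csv(data, tmp_path / "matrix.csv")
        write_row_annotated_csv(data, tmp_path / "row.csv")
        write_column_annotated_csv(data, tmp_path / "col.csv", model)
        write_complete_csv(data, tmp_path / "complete.csv", model)
        tables = {}
        for name, dialect in [("matrix", "matrix"), ("row", "row_annotated"),
                              ("col", "column_annotated"), ("complete", "complete")]:
            t, _, rep = read_table(tmp_path / f"{name}.csv")
            assert rep.dialect == dialect
            tables[name] = t
        ref = tables["matrix"]
        for t in tables.values():
            assert t.entity_ids == ref.entity_ids
            assert t.metric_ids == ref.metric_ids
            np.testing.assert_array_equal(t.missing_mask, ref.missing_mask)
            keep = ~ref.missing_mask
            np.testing.assert_array_equal(t.values[keep], ref.values[keep])

    def test_import_report_reconciles_with_mask(self, tmp_path):
        data = generate_dataset(n_entities=20, n_metrics=6, missing_frac=0.2,
                                negative_frac=0.1, seed=3)
        write_matrix_csv(data, tmp_path / "m.csv")
        table, _, rep = read_table(tmp_path / "m.csv")
        assert rep.n_missing_na + rep.n_negative_dropped == table.missing_mask.sum()
        assert rep.n_missing_na == data.na_mask.sum()
        assert rep.n_negative_dropped == data.neg_mask.sum()


class TestModelFileRoundTrip:
    def test_round_trip_identity(self, small_table, small_model, tmp_path):
        p = tmp_path / "model.csv"
        write_model_file(small_table, small_model, p)
        t2, m2, rep = read_table(p)
        assert rep.dialect == "complete"
        assert small_table.equals(t2)
        assert m2 == small_model

    def test_weights_survive_exactly(self, small_table, tmp_path):
        model = ToxPiModel((
            SliceDef("A", ("m1", "m2"), weight=3.0),
            SliceDef("B", ("m3", "m4"), weight=1.0),
        ))
        write_model_file(small_table, model, tmp_path / "m.csv")
        _, m2, _ = read_table(tmp_path / "m.csv")
        assert [s.weight for s in m2.slices] == [3.0, 1.0]

    def test_awkward_weight_decimal_bit_for_bit(self, small_table, tmp_path):
        w = 0.1 + 0.2  # not exactly representable; repr must round-trip
        model = ToxPiModel((SliceDef("A", ("m1", "m2", "m3", "m4"), weight=w),))
        write_model_file(small_table, model, tmp_path / "m.csv")
        _, m2, _ = read_table(tmp_path / "m.csv")
        assert m2.slices[0].weight == w

    def test_quoted_names_round_trip(self, tmp_path):
        table = DataTable(["a,b", "c"], ['m "q"', "m2"],
                          np.ones((2, 2)), np.zeros((2, 2), bool))
        model = ToxPiModel((SliceDef("S", ('m "q"', "m2")),))
        write_model_file(table, model, tmp_path / "m.csv")
        t2, _, _ = read_table(tmp_path / "m.csv")
        assert t2.entity_ids == ["a,b", "c"]
        assert t2.metric_ids == ['m "q"', "m2"]

    def test_random_tables_round_trip(self, tmp_path):
        from conftest import random_table_and_model

        rng = np.random.default_rng(5)
        for trial in range(20):
            table, model = random_table_and_model(rng)
            p = tmp_path / f"m{trial}.csv"
            write_model_file(table, model, p)
            t2, m2, _ = read_table(p)
            assert table.equals(t2) and m2 == model


class TestMergeTables:
    def test_single_table_identity(self, small_table):
        merged = merge_tables([small_table])
        assert merged.equals(small_table)

    def test_metric_intersection(self, tmp_path):
        a = DataTable(["e1"], ["a", "b"], [[1.0, 2.0]], [[False, False]])
        b = DataTable(["e2"], ["b", "c"], [[2.0, 3.0]], [[False, False]])
        merged = merge_tables([a, b])
        assert merged.metric_ids == ["b"]
        assert merged.entity_ids == ["e1", "e2"]

    def test_subset_order_preserved(self, medium_table):
        ids = [medium_table.entity_ids[i] for i in (7, 2, 11)]
        merged = merge_tables([medium_table], entity_subset=ids)
        assert merged.entity_ids == ids

    def test_conflicting_values_error(self):
        a = DataTable(["e1"], ["a"], [[1.0]], [[False]])
        b = DataTable(["e1"], ["a"], [[2.0]], [[False]])
        with pytest.raises(DataError, match="conflicting"):
            merge_tables([a, b])

    def test_present_fills_missing(self):
        a = DataTable(["e1"], ["a", "b"], [[np.nan, 2.0]], [[True, False]])
        b = DataTable(["e1"], ["a", "b"], [[5.0, 2.0]], [[False, False]])
        merged = merge_tables([a, b])
        assert merged.values[0, 0] == 5.0 and not merged.missing_mask.any()

    def test_empty_intersection_error(self):
        a = DataTable(["e1"], ["a"], [[1.0]], [[False]])
        b = DataTable(["e2"], ["b"], [[1.0]], [[False]])
        with pytest.raises(DataError, match="common"):
            merge_tables([a, b])

    def test_intersection_is_order_insensitive(self, tmp_path):
        rng = np.random.default_rng(0)
        a = DataTable(["e1"], ["a", "b", "c"], rng.random((1, 3)), np.zeros((1, 3), bool))
        b = DataTable(["e2"], ["c", "b"], rng.random((1, 2)), np.zeros((1, 2), bool))
        m1 = merge_tables([a, b])
        m2 = merge_tables([b, a])
        assert set(m1.metric_ids) == set(m2.metric_ids) == {"b", "c"}


class TestResultsCsv:
    def test_row_per_entity_and_columns(self, small_table, small_model, tmp_path):
        s = score(small_table, small_model)
        p = tmp_path / "r.csv"
        write_results_csv(s, p)
        lines = p.read_text().splitlines()
        assert lines[0] == "id,class,overall_score,rank,cluster,S1,S2"
        assert len(lines) == 1 + 4

    def test_selection_order_and_unknown_id(self, small_table, small_model, tmp_path):
        s = score(small_table, small_model)
        p = tmp_path / "r.csv"
        write_results_csv(s, p, selection=["e3", "e1"])
        lines = p.read_text().splitlines()
        assert [ln.split(",")[0] for ln in lines[1:]] == ["e3", "e1"]
        with pytest.raises(DataError, match="nope"):
            write_results_csv(s, p, selection=["nope"])

    def test_cluster_column_populated(self, small_table, small_model, tmp_path):
        from toxpi.hier_cluster import cut_dendrogram, euclidean_distances, linkage

        s = score(small_table, small_model)
        dend = linkage(euclidean_distances(s.slice_scores), "average")
        clusters = cut_dendrogram(dend, k=2)
        p = tmp_path / "r.csv"
        write_results_csv(s, p, clusters=clusters)
        for ln in p.read_text().splitlines()[1:]:
            assert ln.split(",")[4] in {"1", "2"}

    def test_ci_columns_appended(self, small_table, small_model, tmp_path):
        from toxpi.uncertainty import bootstrap_ci

        s = score(small_table, small_model)
        ci = bootstrap_ci(small_table, small_model, n_boot=50, seed=1, point=s)
        p = tmp_path / "r.csv"
        write_results_csv(s, p, ci=ci)
        header = p.read_text().splitlines()[0].split(",")
        for col in ("overall_lo", "overall_hi", "rank_lo", "rank_hi",
                    "S1_lo", "S1_hi", "S2_lo", "S2_hi"):
            assert col in header
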