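"""Ingestion, replicate averaging, detection/gene-set filtering, normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from circsync.datasets import (
    StudyDataset,
    TableLayout,
    TimeSeriesExpression,
    average_replicates,
    filter_detected,
    filter_gene_set,
    minmax_normalize,
    read_dataset,
    read_expression_table,
    write_dataset,
    write_expression_table,
)
from circsync.errors import (
    EmptyResultError,
    TableFormatError,
    TableParseError,
    ValidationError,
)
from circsync.intra import pearson_r

from conftest import ZT12, make_series


class TestReadWrite:
    def test_round_trip_preserves_matrix_exactly(self, tmp_path, rng):
        series = make_series(rng.uniform(0, 50, (3, 12)), timepoints=ZT12)
        path = tmp_path / "t.tsv"
        write_expression_table(series, path)
        back = read_expression_table(path, TableLayout(tissue_id="liver"))
        assert back.genes == series.genes
        np.testing.assert_array_equal(back.values, series.values)
        np.testing.assert_array_equal(back.timepoints_h, series.timepoints_h)
        assert back.replicate_averaged

    def test_duplicate_gene_symbols_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("gene\tZT0\tZT2\tZT4\nactb\t1\t2\t3\nactb\t4\t5\t6\n")
        with pytest.raises(ValidationError, match="actb"):
            read_expression_table(path)

    def test_replicate_columns_recognized_and_left_unaveraged(self, tmp_path):
        header = ["gene"]
        for t in range(0, 24, 2):
            header += [f"ZT{t}_rep1", f"ZT{t}_rep2"]
        rows = ["\t".join(header)]
        for g in range(3):
            rows.append("\t".join([f"g{g}"] + [str(float(i)) for i in range(24)]))
        path = tmp_path / "reps.tsv"
        path.write_text("\n".join(rows) + "\n")
        ts = read_expression_table(path)
        assert ts.n_timepoints == 12
        assert ts.values.shape == (3, 24)
        assert not ts.replicate_averaged

    def test_missing_gene_column_is_format_error(self, tmp_path):
        path = tmp_path / "nogene.tsv"
        path.write_text("symbol\tZT0\tZT2\tZT4\na\t1\t2\t3\n")
        with pytest.raises(TableFormatError, match="gene"):
            read_expression_table(path)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tZT0\tZT2\tZT4\na\t1\t2\t3\nb\t4\toops\t6\n")
        with pytest.raises(TableParseError, match="'b'.*ZT2"):
            read_expression_table(path)

    def test_long_layout_pivots_to_wide(self, tmp_path):
        lines = ["gene\ttimepoint_h\treplicate\tvalue"]
        for g in ("a", "b"):
            for t in (0, 2, 4):
                for r in (1, 2):
                    lines.append(f"{g}\t{t}\t{r}\t{t + r / 10}")
        path = tmp_path / "long.tsv"
        path.write_text("\n".join(lines) + "\n")
        ts = read_expression_table(path, TableLayout(orientation="long"))
        assert ts.n_timepoints == 3
        assert not ts.replicate_averaged
        avg = average_replicates(ts)
        np.testing.assert_allclose(avg.values, [[0.15, 2.15, 4.15]] * 2)

    def test_dataset_directory_round_trip(self, tmp_path, two_tissue_dataset):
        write_dataset(two_tissue_dataset, tmp_path / "ds")
        back = read_dataset(tmp_path / "ds")
        assert back.conditions == two_tissue_dataset.conditions
        for key, ts in two_tissue_dataset.series.items():
            np.testing.assert_array_equal(back.series[key].values, ts.values)


class TestAverageReplicates:
    def _rep_series(self, values, n_tp):
        values = np.asarray(values, dtype=float)
        n_rep = values.shape[1] // n_tp
        idx = np.repeat(np.arange(n_tp), n_rep)
        return TimeSeriesExpression(
            tissue_id="t", condition_id="c",
            genes=tuple(f"g{i}" for i in range(values.shape[0])),
            timepoints_h=np.arange(n_tp) * 2.0,
            values=values, replicate_averaged=False, column_timepoint_idx=idx,
        )

    def test_arithmetic_mean_per_timepoint(self):
        ts = self._rep_series([[1, 3, 2, 4, 0, 2]], 3)
        avg = average_replicates(ts)
        np.testing.assert_allclose(avg.values, [[2.0, 3.0, 1.0]])
        assert avg.replicate_averaged

    def test_single_replicate_is_identity(self):
        ts = self._rep_series([[1.0, 2.0, 3.0]], 3)
        avg = average_replicates(ts)
        np.testing.assert_array_equal(avg.values, ts.values)

    def test_three_replicates(self):
        ts = self._rep_series([[0, 0, 6, 1, 1, 1, 2, 2, 2]], 3)
        np.testing.assert_allclose(average_replicates(ts).values, [[2.0, 1.0, 2.0]])

    def test_zero_replicate_timepoint_rejected(self):
        idx = np.array([0, 0, 2, 2])  # timepoint 1 has no columns
        with pytest.raises(ValidationError, match="zero replicates"):
            average_replicates(
                TimeSeriesExpression(
                    tissue_id="t", condition_id="c", genes=("g0",),
                    timepoints_h=np.array([0.0, 2.0, 4.0]),
                    values=np.ones((1, 4)), replicate_averaged=False,
                    column_timepoint_idx=idx,
                )
            )


class TestFilters:
    def test_gene_undetected_at_one_timepoint_removed(self):
        ts = make_series([[5, 0, 5, 5], [1, 1, 1, 2]])
        out = filter_detected(ts)
        assert out.genes == ("g1",)

    def test_all_positive_genes_all_kept(self, random_series):
        out = filter_detected(random_series)
        assert out.genes == random_series.genes

    def test_seeded_zero_planting_count(self, rng):
        values = rng.uniform(1.0, 10.0, (100, 12))
        hit = rng.choice(100, size=7, replace=False)
        for g in hit:
            values[g, rng.integers(12)] = 0.0
        out = filter_detected(make_series(values, timepoints=ZT12))
        assert out.n_genes == 93
        survivors = {f"g{i}" for i in range(100)} - {f"g{i}" for i in hit}
        assert set(out.genes) == survivors

    def test_filter_detected_idempotent(self, rng):
        ts = make_series(rng.uniform(-1, 5, (30, 12)), timepoints=ZT12)
        once = filter_detected(ts)
        twice = filter_detected(once)
        assert once.genes == twice.genes

    def test_all_removed_raises_empty_result(self):
        with pytest.raises(EmptyResultError):
            filter_detected(make_series([[0, 1, 1], [1, 0, 1]]))

    def test_gene_set_filter_preserves_order(self, two_tissue_dataset):
        out = filter_gene_set(two_tissue_dataset, {"g1", "g3", "g5"})
        for ts in out.series.values():
            assert ts.genes == ("g1", "g3", "g5")

    def test_gene_set_superset_is_identity(self, two_tissue_dataset):
        universe = {f"g{i}" for i in range(100)}
        out = filter_gene_set(two_tissue_dataset, universe)
        for key, ts in out.series.items():
            assert ts.genes == two_tissue_dataset.series[key].genes

    def test_gene_set_filter_idempotent_and_counts(self, rng):
        genes = [f"g{i:03d}" for i in range(500)]
        universe = set(rng.choice(genes, size=120, replace=False))
        ts = make_series(rng.uniform(1, 5, (500, 12)), genes=genes, timepoints=ZT12)
        ds = StudyDataset(("ALF",), ("liver",), {("ALF", "liver"): ts})
        once = filter_gene_set(ds, universe)
        assert once.get("ALF", "liver").n_genes == 120
        twice = filter_gene_set(once, universe)
        assert twice.get("ALF", "liver").genes == once.get("ALF", "liver").genes

    def test_zero_overlap_names_tissue(self, two_tissue_dataset):
        with pytest.raises(EmptyResultError, match="liver|heart|lung"):
            filter_gene_set(two_tissue_dataset, {"nope"})


class TestMinMax:
    def test_profile_mapped_to_unit_interval(self):
        out = minmax_normalize(make_series([[2, 4, 6]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])

    def test_already_normalized_profile_unchanged(self):
        out = minmax_normalize(make_series([[0.0, 0.25, 1.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.25, 1.0]])

    def test_constant_gene_dropped_with_warning(self, caplog):
        ts = make_series([[1, 1, 1], [0, 1, 2]])
        with caplog.at_level("WARNING"):
            out = minmax_normalize(ts)
        assert out.genes == ("g1",)
        assert "constant" in caplog.text

    def test_pearson_invariant_under_normalization(self, random_series):
        normed = minmax_normalize(random_series)
        for i in range(0, 20, 3):
            for j in range(1, 20, 5):
                if i == j:
                    continue
                r_raw = pearson_r(random_series.values[i], random_series.values[j])
                r_norm = pearson_r(normed.values[i], normed.values[j])
                assert abs(r_raw - r_norm) < 1e-10

    @settings(max_examples=40, derandomize=True)
    @given(
        hnp.arrays(
            np.float64,
            (4, 6),
            elements=st.floats(0.0, 100.0, allow_nan=False, width=32),
        )
    )
    def test_minmax_bounds_property(self, values):
        values = values + np.arange(6) * 1e-6  # avoid all-constant rows
        ts = make_series(values, timepoints=np.arange(6) * 2.0)
        out = minmax_normalize(ts)
        if out.n_genes == 0:
            return
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        np.testing.assert_allclose(out.values.min(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.values.max(axis=1), 1.0, atol=1e-12)


class TestInvariants:
    def test_timepoints_must_be_strictly_increasing_in_day(self):
        with pytest.raises(ValidationError):
            make_series([[1, 2, 3]], timepoints=[0.0, 2.0, 2.0])
        with pytest.raises(ValidationError):
            make_series([[1, 2, 3]], timepoints=[0.0, 12.0, 24.0])

    def test_condition_time_grids_must_match(self, rng):
        a = make_series(rng.uniform(1, 2, (3, 12)), tissue="liver", timepoints=ZT12)
        b = make_series(
            rng.uniform(1, 2, (3, 6)), tissue="heart", timepoints=np.arange(6) * 4.0
        )
        with pytest.raises(ValidationError, match="time grids"):
            StudyDataset(
                ("ALF",), ("liver", "heart"),
                {("ALF", "liver"): a, ("ALF", "heart"): b},
            )
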