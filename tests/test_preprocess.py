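"""LLOD policy, complete-case filtering, design-matrix construction, I/O."""

import numpy as np
import pandas as pd
import pytest

from stablasso.preprocess import (
    ClassError,
    CohortTable,
    DegenerateColumnError,
    EmptyDataError,
    apply_llod_policy,
    build_design,
    complete_cases,
    read_subject_spreadsheet,
    subset_variables,
)


class TestLlodPolicy:
    def _table(self, make_table, n_censored, n=10, llod=1.6):
        mask = [i < n_censored for i in range(n)]
        return make_table(
            {"A": list(np.linspace(2.0, 9.0, n)), "group": ["MIA", "Control"] * (n // 2)},
            censored={"A": mask},
            llods={"A": llod},
        )

    def test_over_threshold_excluded(self, make_table):
        table = self._table(make_table, n_censored=3)  # 30% > 20%
        out, excluded = apply_llod_policy(table)
        assert excluded == ["A"]
        assert "A" not in out.data.columns and "A" not in out.meta

    def test_exactly_at_threshold_retained_and_imputed(self, make_table):
        table = self._table(make_table, n_censored=2, llod=1.6)  # exactly 20%
        out, excluded = apply_llod_policy(table)
        assert excluded == []
        assert (out.data["A"].iloc[:2] == 0.8).all()  # half the LLOD
        assert not out.censored["A"].any()

    def test_no_censoring_is_identity(self, make_table):
        table = self._table(make_table, n_censored=0)
        out, excluded = apply_llod_policy(table)
        assert excluded == []
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_fraction_uses_all_assayed_samples_before_complete_case(self, make_table):
        """A missing value in another variable must not change the censored
        fraction: the rule is applied at assay level, pre-filtering."""
        table = make_table(
            {
                "A": [2.0] * 10,
                "other": [1.0] * 9 + [np.nan],
                "group": ["MIA", "Control"] * 5,
            },
            censored={"A": [True, True] + [False] * 8},
            llods={"A": 1.0},
        )
        out, excluded = apply_llod_policy(table)  # 2/10 = 20%, not 2/9
        assert excluded == []

    def test_exclusion_independent_of_observed_magnitudes(self, make_table):
        t1 = self._table(make_table, n_censored=3)
        t2 = self._table(make_table, n_censored=3)
        t2.data["A"] = t2.data["A"] * 1000
        _, e1 = apply_llod_policy(t1)
        _, e2 = apply_llod_policy(t2)
        assert e1 == e2 == ["A"]


class TestCompleteCases:
    def test_drops_rows_with_any_missing(self, make_table):
        table = make_table(
            {"A": [1.0, 2.0, np.nan, 4.0, 5.0], "group": ["MIA"] * 3 + ["Control"] * 2}
        )
        out = complete_cases(table)
        assert len(out.data) == 4
        assert list(out.data.index) == ["s1", "s2", "s4", "s5"]  # order preserved

    def test_no_missing_is_identity(self, make_table):
        table = make_table({"A": [1.0, 2.0], "group": ["MIA", "Control"]})
        out = complete_cases(table)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_all_rows_missing_raises(self, make_table):
        table = make_table({"A": [np.nan, np.nan], "group": ["MIA", "Control"]})
        with pytest.raises(EmptyDataError):
            complete_cases(table)


class TestBuildDesign:
    def test_population_variance_standardization(self, make_table):
        table = make_table({"A": [1.0, 2.0, 3.0], "group": ["MIA", "Control", "MIA"]})
        d = build_design(table)  # divisor n: scale = sqrt(2/3)
        np.testing.assert_allclose(
            d.X[:, 0], [-1.224745, 0.0, 1.224745], atol=1e-6
        )
        assert d.scaling["A"] == (2.0, pytest.approx(np.sqrt(2.0 / 3.0)))

    def test_sample_variance_switch(self, make_table):
        table = make_table({"A": [1.0, 2.0, 3.0], "group": ["MIA", "Control", "MIA"]})
        d = build_design(table, ddof=1)
        np.testing.assert_allclose(d.X[:, 0], [-1.0, 0.0, 1.0], atol=1e-12)

    def test_binary_encoded_not_standardized(self, make_table):
        table = make_table(
            {"multiparity": ["No", "Yes", "No"], "A": [1.0, 2.0, 3.0],
             "group": ["MIA", "Control", "MIA"]},
            kinds={"multiparity": "binary"},
        )
        d = build_design(table)
        j = d.column_names.index("multiparity")
        np.testing.assert_array_equal(d.X[:, j], [0.0, 1.0, 0.0])
        assert d.scaling["multiparity"] == (0.0, 1.0)
        assert d.outcome_coding == {"Control": 0, "MIA": 1}
        np.testing.assert_array_equal(d.y, [1.0, 0.0, 1.0])

    def test_constant_column_raises_with_name(self, make_table):
        table = make_table({"A": [4.0, 4.0, 4.0], "group": ["MIA", "Control", "MIA"]})
        with pytest.raises(DegenerateColumnError, match="'A'"):
            build_design(table)

    def test_single_class_outcome_raises(self, make_table):
        table = make_table({"A": [1.0, 2.0, 3.0], "group": ["MIA", "MIA", "MIA"]})
        with pytest.raises(ClassError):
            build_design(table)

    def test_standardized_columns_have_zero_mean_unit_variance(self, make_table):
        rng = np.random.default_rng(0)
        table = make_table(
            {"A": rng.normal(5, 2, 40).tolist(), "B": rng.lognormal(1, 1, 40).tolist(),
             "group": ["MIA", "Control"] * 20}
        )
        d = build_design(table)
        assert np.abs(d.X.mean(axis=0)).max() < 1e-10
        np.testing.assert_allclose(d.X.var(axis=0), 1.0, atol=1e-8)

    def test_unstandardize_round_trip(self, make_table):
        rng = np.random.default_rng(1)
        vals = rng.normal(10, 3, 25)
        table = make_table(
            {"A": vals.tolist(), "group": ["MIA", "Control"] * 12 + ["MIA"]}
        )
        d = build_design(table)
        np.testing.assert_allclose(d.unstandardize()[:, 0], vals, atol=1e-10)

    def test_row_permutation_equivariance(self, make_table):
        rng = np.random.default_rng(2)
        vals = rng.normal(size=20)
        groups = ["MIA", "Control"] * 10
        table = make_table({"A": vals.tolist(), "group": groups})
        perm = rng.permutation(20)
        table_p = make_table(
            {"A": vals[perm].tolist(), "group": [groups[i] for i in perm]}
        )
        d = build_design(table)
        d_p = build_design(table_p)
        np.testing.assert_allclose(d.X[perm, 0], d_p.X[:, 0], atol=1e-12)
        np.testing.assert_array_equal(d.y[perm], d_p.y)


class TestIO:
    def test_tsv_round_trip_with_sentinels(self, make_table, tmp_path):
        table = make_table(
            {"A": [1.0, 5.0, np.nan], "B": [1.0, 2.0, 3.0],
             "group": ["MIA", "Control", "MIA"]},
            censored={"A": [True, False, False]},
            llods={"A": 2.0},
        )
        table.to_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        text = (tmp_path / "c.tsv").read_text()
        assert "<LLOD" in text
        back = CohortTable.from_tsv(tmp_path / "c.tsv", tmp_path / "m.tsv")
        assert back.censored["A"].tolist() == [True, False, False]
        assert np.isnan(back.data["A"].iloc[2])
        assert back.meta["A"].llod == 2.0
        pd.testing.assert_frame_equal(back.data[["B"]], table.data[["B"]])

    def test_subset_variables_keeps_outcome(self, make_table):
        table = make_table({"A": [1.0, 2.0], "B": [3.0, 4.0],
                            "group": ["MIA", "Control"]})
        sub = subset_variables(table, ["B"])
        assert list(sub.data.columns) == ["B", "group"]

    def test_spreadsheet_adapter_round_trip(self, tmp_path):
        """Synthetic spreadsheet in the supplementary-table layout."""
        df = pd.DataFrame(
            {
                "Group": ["MIA", "Control", "MIA", "Control"],
                "Maternal age": [20.0, 21.0, 19.0, 22.0],
                "TNF-a": [5.0, "<LLOD", 4.0, 3.0],
            }
        )
        path = tmp_path / "synthetic_subjects.xlsx"
        df.to_excel(path, index=False)
        table = read_subject_spreadsheet(
            path, cytokine_columns=["TNF-a"], llods={"TNF-a": 1.0}
        )
        assert table.outcome == "Group"
        assert table.censored["TNF-a"].tolist() == [False, True, False, False]
        assert table.meta["TNF-a"].llod == 1.0
        assert len(table.data) == 4
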