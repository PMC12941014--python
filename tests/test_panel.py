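"""Panels and covariate tables: aggregation, IO round trips, COVID split."""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd
import pytest

from stcar import (CountPanel, CovariateTable, build_panel, covid_split_table,
                   make_grid_lattice, split_tally)
from stcar.categories import VisitRecord


def rec(codes, tract, day):
    return VisitRecord(tract_id=tract, date=day, icd_codes=tuple(codes))


@pytest.fixture()
def lat2():
    return make_grid_lattice(1, 2)  # tracts r0c0, r0c1


POPS = {"r0c0": 100, "r0c1": 200}


class TestBuildPanel:
    def test_counts_land_in_right_cell(self, lat2):
        records = [rec(["F32.9"], "r0c0", date(2019, m, 5)) for m in (1, 2, 3)]
        panel = build_panel(records, lat2, POPS, category="Depression")
        assert panel.Y[0, 1] == 3
        assert panel.Y.sum() == 3

    def test_multi_diagnosis_in_both_category_panels(self, lat2):
        records = [rec(["F32.9", "F41.1"], "r0c0", date(2019, 1, 5))]
        dep = build_panel(records, lat2, POPS, category="Depression")
        anx = build_panel(records, lat2, POPS, category="Anxiety")
        assert dep.Y.sum() == 1 and anx.Y.sum() == 1

    def test_monthly_t48(self, lat2):
        panel = build_panel([], lat2, POPS, granularity="month")
        assert panel.T == 48
        assert panel.period_labels[0] == "2018-01"
        assert panel.period_labels[-1] == "2021-12"

    def test_outside_window_excluded(self, lat2, caplog):
        records = [rec(["F32.9"], "r0c0", date(2017, 5, 1)),
                   rec(["F32.9"], "r0c0", date(2019, 5, 1))]
        with caplog.at_level("INFO"):
            panel = build_panel(records, lat2, POPS)
        assert panel.Y.sum() == 1
        assert "outside study window" in caplog.text

    def test_unknown_tract_raises(self, lat2):
        with pytest.raises(ValueError, match="not in lattice"):
            build_panel([rec(["F32.9"], "zzz", date(2019, 1, 1))], lat2, POPS)

    def test_category_additivity(self, lat2):
        # one multi-category record makes per-category totals exceed ALL
        records = [
            rec(["F32.9", "F41.1"], "r0c0", date(2019, 1, 5)),
            rec(["F43.10"], "r0c1", date(2020, 3, 2)),
        ]
        total_all = build_panel(records, lat2, POPS, category="ALL").Y.sum()
        per_cat = sum(
            build_panel(records, lat2, POPS, category=c).Y.sum()
            for c in ("Depression", "Anxiety", "PTSD")
        )
        assert total_all == 2 and per_cat == 3


class TestPanelIO:
    def test_round_trip_exact(self, tiny_panel, tmp_path):
        cp, pp = tmp_path / "panel.csv", tmp_path / "pops.csv"
        tiny_panel.write(cp, pp)
        back = CountPanel.read(cp, pp)
        assert np.array_equal(back.Y, tiny_panel.Y)
        assert np.array_equal(back.P, tiny_panel.P)
        assert back.period_labels == tiny_panel.period_labels
        assert back.tract_ids == tiny_panel.tract_ids
        assert back.granularity == "year"

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(Y=np.array([[-1]])), "non-negative"),
            (dict(P=np.array([0])), "positive"),
            (dict(period_labels=("2018-01",)), "bad year label"),
        ],
    )
    def test_validation(self, kwargs, msg):
        base = dict(Y=np.array([[1]]), P=np.array([10]), tract_ids=("a",),
                    period_labels=("2018",), granularity="year")
        base.update(kwargs)
        with pytest.raises(ValueError, match=msg):
            CountPanel(**base)


class TestCovariateTable:
    def _table(self, vals):
        idx = pd.MultiIndex.from_product(
            [["a", "b"], [2018, 2019]], names=["tract_id", "year"]
        )
        return CovariateTable(pd.DataFrame({"pct_x": vals}, index=idx))

    def test_percentage_bounds_enforced(self):
        with pytest.raises(ValueError, match="outside"):
            self._table([10.0, 20.0, 150.0, 30.0])

    def test_incomplete_grid_rejected(self):
        idx = pd.MultiIndex.from_tuples(
            [("a", 2018), ("b", 2019)], names=["tract_id", "year"]
        )
        with pytest.raises(ValueError, match="incomplete"):
            CovariateTable(pd.DataFrame({"x": [1.0, 2.0]}, index=idx))

    def test_round_trip(self, tmp_path):
        tab = self._table([10.0, 12.0, 20.0, 22.0])
        p = tmp_path / "cov.csv"
        tab.write(p)
        back = CovariateTable.read(p)
        pd.testing.assert_frame_equal(back.values, tab.values)

    def test_matrix_orientation(self):
        tab = self._table([10.0, 12.0, 20.0, 22.0])
        M = tab.matrix(["b", "a"], [2019, 2018])
        assert M[0, 0, 0] == 22.0  # tract b, year 2019
        assert M[1, 1, 0] == 10.0  # tract a, year 2018


class TestCovidSplit:
    def test_split_counts_and_percentages(self):
        records = [
            rec(["F32.9"], "t", date(2019, 6, 1)),
            rec(["F32.9"], "t", date(2020, 6, 1)),
            rec(["F41.1"], "t", date(2019, 7, 1)),
            rec(["F41.1", "F32.9"], "t", date(2021, 1, 1)),
        ]
        df = covid_split_table(records).set_index("category")
        assert df.loc["Depression", "before_n"] == 1
        assert df.loc["Depression", "during_n"] == 2
        assert df.loc["Anxiety", "total_n"] == 2
        assert df.loc["Total", "before_n"] == 2
        assert df.loc["Total", "during_n"] == 3
        assert df.loc["Depression", "before_pct"] == 50.0

    def test_empty_records_zero_percentages(self):
        df = covid_split_table([]).set_index("category")
        assert (df["before_pct"] == 0).all()
        assert df.loc["Total", "total_n"] == 0

    def test_split_tally_column_percentages_sum_to_100(self):
        before = {"Depression": 3, "Anxiety": 1}
        during = {"Depression": 2, "Anxiety": 2}
        df = split_tally(before, during, ["Depression", "Anxiety"])
        body = df[df["category"] != "Total"]
        assert body["before_pct"].sum() == pytest.approx(100.0, abs=0.02)
        assert body["during_pct"].sum() == pytest.approx(100.0, abs=0.02)
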