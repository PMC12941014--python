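"""Count panels and covariate tables for areal spatio-temporal models.

A :class:`CountPanel` holds visit counts ``Y[i, t]`` for ``n`` tracts over
``T`` periods (calendar years or months) together with the population at
risk ``P_i`` per tract, held constant over the study window.  A
:class:`CovariateTable` holds ``k`` tract-level covariates that step at
calendar-year boundaries (ACS-style yearly estimates); percentage covariates
are on the raw 0-100 scale.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .categories import CategoryMap, DEFAULT_CATEGORY_MAP, VisitRecord
from .lattice import TractLattice

__all__ = [
    "CountPanel",
    "CovariateTable",
    "build_panel",
    "covid_split_table",
    "split_tally",
]

log = logging.getLogger(__name__)

DEFAULT_STUDY_WINDOW = (date(2018, 1, 1), date(2021, 12, 31))


def year_labels(years: Iterable[int]) -> list[str]:
    return [str(y) for y in years]


def month_labels(years: Iterable[int]) -> list[str]:
    return [f"{y}-{m:02d}" for y in years for m in range(1, 13)]


@dataclass(frozen=True)
class CountPanel:
    """Counts ``Y`` (n x T), populations ``P`` (n,), and period labels.

    ``granularity`` is ``"year"`` (labels like ``"2019"``) or ``"month"``
    (labels like ``"2019-07"``).  An optional observation mask marks cells
    that contribute to the likelihood (all observed by default).
    """

    Y: np.ndarray
    P: np.ndarray
    tract_ids: tuple[str, ...]
    period_labels: tuple[str, ...]
    granularity: str
    category: str = "ALL"
    observed: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        Y = np.asarray(self.Y)
        P = np.asarray(self.P)
        object.__setattr__(self, "Y", Y.astype(np.int64))
        object.__setattr__(self, "P", P.astype(np.int64))
        if self.granularity not in ("year", "month"):
            raise ValueError("granularity must be 'year' or 'month'")
        if Y.ndim != 2:
            raise ValueError("Y must be 2-D (tracts x periods)")
        n, T = Y.shape
        if len(self.tract_ids) != n or len(self.period_labels) != T:
            raise ValueError("Y shape inconsistent with labels")
        if (Y < 0).any():
            raise ValueError("counts must be non-negative")
        if (P <= 0).any():
            raise ValueError("populations must be positive")
        if list(self.period_labels) != sorted(self.period_labels):
            raise ValueError("period_labels must be strictly increasing")
        if len(set(self.period_labels)) != T:
            raise ValueError("duplicate period labels")
        for lab in self.period_labels:
            ok = (self.granularity == "year" and len(lab) == 4) or (
                self.granularity == "month" and len(lab) == 7 and lab[4] == "-"
            )
            if not ok:
                raise ValueError(f"bad {self.granularity} label {lab!r}")
        if self.observed is not None:
            obs = np.asarray(self.observed, dtype=bool)
            if obs.shape != Y.shape:
                raise ValueError("observed mask shape mismatch")
            object.__setattr__(self, "observed", obs)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def T(self) -> int:
        return self.Y.shape[1]

    def period_years(self) -> np.ndarray:
        """Calendar year of each period column."""
        return np.array([int(lab[:4]) for lab in self.period_labels])

    def rates(self) -> np.ndarray:
        """Raw rates ``Y_it / P_i``."""
        return self.Y / self.P[:, None]

    def obs_mask(self) -> np.ndarray:
        if self.observed is None:
            return np.ones(self.Y.shape, dtype=bool)
        return self.observed

    # -- IO ----------------------------------------------------------------

    def write(self, counts_path, populations_path) -> None:
        """Write long-format counts CSV and a populations CSV."""
        with open(counts_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tract_id", "period", "category", "count"])
            for i, t_id in enumerate(self.tract_ids):
                for t, lab in enumerate(self.period_labels):
                    w.writerow([t_id, lab, self.category, int(self.Y[i, t])])
        with open(populations_path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["tract_id", "population"])
            for i, t_id in enumerate(self.tract_ids):
                w.writerow([t_id, int(self.P[i])])

    @classmethod
    def read(cls, counts_path, populations_path, category: str = "ALL") -> "CountPanel":
        df = pd.read_csv(counts_path, dtype={"tract_id": str, "period": str})
        df = df[df["category"] == category]
        if df.empty:
            raise ValueError(f"no rows for category {category!r}")
        pop = pd.read_csv(populations_path, dtype={"tract_id": str})
        tracts = tuple(sorted(df["tract_id"].unique()))
        periods = tuple(sorted(df["period"].unique()))
        gran = "year" if len(periods[0]) == 4 else "month"
        wide = df.pivot_table(
            index="tract_id", columns="period", values="count", fill_value=0
        ).reindex(index=list(tracts), columns=list(periods), fill_value=0)
        P = pop.set_index("tract_id")["population"].reindex(list(tracts))
        if P.isna().any():
            missing = P[P.isna()].index.tolist()
            raise ValueError(f"missing populations for {missing}")
        return cls(
            Y=wide.to_numpy(),
            P=P.to_numpy(),
            tract_ids=tracts,
            period_labels=periods,
            granularity=gran,
            category=category,
        )


@dataclass(frozen=True)
class CovariateTable:
    """Tract-by-year covariates, stepping at calendar-year boundaries.

    ``values`` is a DataFrame indexed by (tract_id, year) with one column
    per covariate; complete over the tract x year grid.  Covariates whose
    name contains ``pct`` or ``%`` must lie in [0, 100].
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.names != ["tract_id", "year"]:
            raise ValueError("values must be indexed by (tract_id, year)")
        tracts = df.index.get_level_values("tract_id").unique()
        years = df.index.get_level_values("year").unique()
        if len(df) != len(tracts) * len(years):
            raise ValueError("covariate table incomplete over tract x year grid")
        if df.isna().any().any():
            raise ValueError("covariate table contains missing values")
        for c in self.percentage_covariates():
            col = df[c]
            if (col < 0).any() or (col > 100).any():
                raise ValueError(f"percentage covariate {c!r} outside [0, 100]")

    @property
    def covariate_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def k(self) -> int:
        return len(self.values.columns)

    def years(self) -> tuple[int, ...]:
        return tuple(sorted(self.values.index.get_level_values("year").unique()))

    def percentage_covariates(self) -> tuple[str, ...]:
        return tuple(
            c for c in self.values.columns if "pct" in c.lower() or "%" in c
        )

    def matrix(
        self, tract_ids: Sequence[str], years: Sequence[int],
        names: Sequence[str] | None = None,
    ) -> np.ndarray:
        """Covariate array of shape (n, len(years), k) in tract order."""
        names = list(names or self.covariate_names)
        idx = pd.MultiIndex.from_product(
            [list(tract_ids), list(years)], names=["tract_id", "year"]
        )
        try:
            sub = self.values.loc[idx, names]
        except KeyError as e:
            raise ValueError(f"covariates missing for requested tracts/years: {e}")
        return sub.to_numpy().reshape(len(tract_ids), len(years), len(names))

    def long_frame(self, names: Sequence[str] | None = None) -> pd.DataFrame:
        """Tract-year rows (one per (tract, year)) with a numeric Year column."""
        df = self.values.reset_index()
        df = df.rename(columns={"year": "Year"})
        if names is not None:
            df = df[["tract_id", "Year", *names]]
        return df

    def write(self, path) -> None:
        long = self.values.reset_index().melt(
            id_vars=["tract_id", "year"], var_name="covariate", value_name="value"
        )
        long.sort_values(["tract_id", "year", "covariate"]).to_csv(path, index=False)

    @classmethod
    def read(cls, path) -> "CovariateTable":
        df = pd.read_csv(path, dtype={"tract_id": str})
        wide = df.pivot_table(
            index=["tract_id", "year"], columns="covariate", values="value"
        )
        wide.columns.name = None
        # preserve first-appearance covariate order from the file
        order = list(dict.fromkeys(df["covariate"]))
        return cls(values=wide[order].sort_index())


def read_populations(path) -> pd.Series:
    pop = pd.read_csv(path, dtype={"tract_id": str})
    return pop.set_index("tract_id")["population"]


def _period_label(d: date, granularity: str) -> str:
    return str(d.year) if granularity == "year" else f"{d.year}-{d.month:02d}"


def build_panel(
    records: Sequence[VisitRecord],
    lattice: TractLattice,
    populations: Mapping[str, int] | pd.Series,
    category: str = "ALL",
    granularity: str = "year",
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
) -> CountPanel:
    """Aggregate visit records into a :class:`CountPanel`.

    ``Y_it`` counts the records in tract ``i`` and period ``t`` whose
    category set contains ``category`` (``"ALL"`` accepts any record with a
    non-empty category set, i.e. any mental-health diagnosis).  Records
    outside the study window are excluded with a logged count, as are
    records with no mappable diagnosis.
    """
    start, end = study_window
    if granularity == "year":
        labels = year_labels(range(start.year, end.year + 1))
    else:
        labels = month_labels(range(start.year, end.year + 1))
    tracts = lattice.tract_ids
    pos = {t: i for i, t in enumerate(tracts)}
    lab_pos = {lab: t for t, lab in enumerate(labels)}
    Y = np.zeros((len(tracts), len(labels)), dtype=np.int64)
    n_outside = n_unmapped = 0
    for r in records:
        if r.tract_id not in pos:
            raise ValueError(f"record tract {r.tract_id!r} not in lattice")
        if not (start <= r.date <= end):
            n_outside += 1
            continue
        cats = category_map.categorize(r.icd_codes)
        if not cats:
            n_unmapped += 1
            continue
        if category != "ALL" and category not in cats:
            continue
        Y[pos[r.tract_id], lab_pos[_period_label(r.date, granularity)]] += 1
    if n_outside:
        log.info("excluded %d records outside study window", n_outside)
    if n_unmapped:
        log.info("excluded %d records with no mappable diagnosis", n_unmapped)
    P = np.array([int(populations[t]) for t in tracts])
    return CountPanel(
        Y=Y, P=P, tract_ids=tracts, period_labels=tuple(labels),
        granularity=granularity, category=category,
    )


def split_tally(
    before: Mapping[str, int], during: Mapping[str, int],
    category_names: Sequence[str],
) -> pd.DataFrame:
    """Two-period tally with column percentages (the COVID split summary).

    Percentages are 100 * count / column total, rounded to 2 decimals; a
    ``Total`` row closes the table.  Empty columns report 0 percentages.
    """
    rows = []
    tot_b = sum(before.get(c, 0) for c in category_names)
    tot_d = sum(during.get(c, 0) for c in category_names)
    tot = tot_b + tot_d

    def pct(x: int, denom: int) -> float:
        return round(100.0 * x / denom, 2) if denom else 0.0

    for c in category_names:
        b, d = before.get(c, 0), during.get(c, 0)
        rows.append(
            {"category": c, "before_n": b, "before_pct": pct(b, tot_b),
             "during_n": d, "during_pct": pct(d, tot_d),
             "total_n": b + d, "total_pct": pct(b + d, tot)}
        )
    rows.append(
        {"category": "Total", "before_n": tot_b, "before_pct": pct(tot_b, tot_b),
         "during_n": tot_d, "during_pct": pct(tot_d, tot_d),
         "total_n": tot, "total_pct": pct(tot, tot)}
    )
    return pd.DataFrame(rows)


def covid_split_table(
    records: Sequence[VisitRecord],
    category_map: CategoryMap = DEFAULT_CATEGORY_MAP,
    covid_start: date = date(2020, 1, 1),
    study_window: tuple[date, date] = DEFAULT_STUDY_WINDOW,
) -> pd.DataFrame:
    """Per-category visit tallies before vs during the pandemic period.

    A multi-diagnosis record is tallied in every matching category, so
    column totals count category assignments, not distinct visits.
    """
    names = category_map.category_names
    before = {c: 0 for c in names}
    during = {c: 0 for c in names}
    start, end = study_window
    for r in records:
        if not (start <= r.date <= end):
            continue
        bucket = before if r.date < covid_start else during
        for c in category_map.categorize(r.icd_codes):
            bucket[c] += 1
    return split_tally(before, during, names)
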