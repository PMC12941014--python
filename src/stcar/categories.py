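"""ICD-10 visit categorization for mental-health ED surveillance.

Eight clinically coherent categories (Depression, Bipolar Disorder, Anxiety,
PTSD, OCD, Psychosis, Substance Abuse, Other) following the grouping
conventions of ED-based mental-health surveillance.  A visit carrying several
diagnoses is counted once in every category it matches, so per-category
totals can exceed the all-category total.

Most entries match by exact code string.  The substance-use entries F10-F19
are three-character stems covering whole code families and are matched by
prefix (F10 matches F10.10, F10.20, ...).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Mapping, Sequence

__all__ = [
    "VisitRecord",
    "CategoryMap",
    "DEFAULT_CATEGORY_MAP",
    "CATEGORY_NAMES",
    "categorize_visit",
]

# letter + two digits + optional alphanumeric (e.g. F32A) + optional .suffix
_ICD10_RE = re.compile(r"^[A-Z]\d{2}[A-Z0-9]?(\.[A-Z0-9]{1,4})?$")

CATEGORY_NAMES = (
    "Depression",
    "Bipolar Disorder",
    "Anxiety",
    "PTSD",
    "OCD",
    "Psychosis",
    "Substance Abuse",
    "Other",
)

_EXACT_CODES: Mapping[str, tuple[str, ...]] = {
    "Depression": (
        "F32.0", "F32.1", "F32.2", "F32.3", "F32.4", "F32.5", "F32.8",
        "F32.89", "F32.9", "F32A",
        "F33.0", "F33.1", "F33.2", "F33.3", "F33.4", "F33.40", "F33.41",
        "F33.42", "F33.8", "F33.9",
        "F34.1", "F53.0", "O90.6", "O99.34",
    ),
    "Bipolar Disorder": (
        "F30.10", "F30.11", "F30.12", "F30.13", "F30.2", "F30.3", "F30.4",
        "F30.8", "F30.9",
        "F31.0", "F31.10", "F31.11", "F31.1", "F31.13", "F31.2", "F31.30",
        "F31.31", "F31.32", "F31.4", "F31.5", "F31.60", "F31.61", "F31.62",
        "F31.63", "F31.64", "F31.70", "F31.71", "F31.72", "F31.73", "F31.74",
        "F31.75", "F31.76", "F31.78", "F31.81", "F31.89", "F31.9",
        "F34.0", "F34.81", "F34.89", "F39",
    ),
    "Anxiety": (
        "F06.4", "F40.9", "F40.00", "F40.01", "F40.10", "F40.11", "F40.218",
        "F40.240", "F40.241", "F40.8", "F41.0", "F41.1", "F41.3", "F41.8",
        "F41.9", "F43.0", "F45.8", "F48.8", "F48.9", "F93.8", "F99", "R45.7",
    ),
    "PTSD": ("F43.10", "F43.11", "F43.12"),
    "OCD": ("F42.2", "F42.3", "F42.4", "F42.8", "F42.9", "R46.81"),
    "Psychosis": (
        "F06.0", "F06.2", "F20.0", "F20.1", "F20.2", "F20.3", "F20.5",
        "F20.81", "F20.89", "F20.9", "F21", "F22", "F23", "F24", "F25.0",
        "F25.1", "F25.8", "F25.9", "F28", "F29", "F53.1", "F44.0", "F44.1",
        "F44.2", "F44.81", "F44.89", "F44.9", "F48.1", "F48.2",
    ),
    "Substance Abuse": (
        "O99.320", "O99.321", "O99.322", "O99.323", "O99.324", "O99.325",
    ),
    "Other": (
        "R45.850", "R45.851", "F06.1", "F06.30", "F06.31", "F06.32", "F06.33",
        "F06.34", "F34.9", "F43.20", "F43.21", "F43.22", "F43.23", "F43.24",
        "F43.25", "F43.29", "F43.81", "F43.89", "F43.9", "F44.4", "F44.5",
        "F44.6", "F44.7", "F45.0", "F45.1", "F45.20", "F45.21", "F45.22",
        "F45.29", "F45.41", "F45.42", "F45.9", "F51.01", "F51.02", "F51.03",
        "F51.04", "F51.05", "F51.09", "F51.11", "F51.12", "F51.13", "F51.19",
        "F51.8", "F51.9", "F54", "F59", "O99.340", "O99.341", "O99.342",
        "O99.343", "O99.344", "O99.345",
    ),
}

_PREFIX_STEMS: Mapping[str, tuple[str, ...]] = {
    "Substance Abuse": (
        "F10", "F11", "F12", "F13", "F14", "F15", "F16", "F17", "F18", "F19",
    ),
}


@dataclass(frozen=True)
class VisitRecord:
    """A single ED visit already linked to a census tract."""

    tract_id: str
    date: date
    icd_codes: tuple[str, ...]
    age: float | None = None
    sex: str | None = None

    def __post_init__(self) -> None:
        if not self.icd_codes:
            raise ValueError("icd_codes must be non-empty")
        for c in self.icd_codes:
            if not _ICD10_RE.match(c):
                raise ValueError(f"not an ICD-10 code: {c!r}")


@dataclass(frozen=True)
class CategoryMap:
    """Mapping from ICD-10 codes to disease categories.

    ``code_sets`` are exact-match codes; ``prefix_stems`` are stems matched
    by prefix.  Every code belongs to exactly one category.
    """

    code_sets: Mapping[str, frozenset[str]]
    prefix_stems: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cat, codes in list(self.code_sets.items()) + list(
            self.prefix_stems.items()
        ):
            if cat not in self.code_sets:
                raise ValueError(f"prefix stems for unknown category {cat!r}")
            for c in codes:
                if c in seen and seen[c] != cat:
                    raise ValueError(f"code {c!r} in two categories")
                seen[c] = cat

    @property
    def category_names(self) -> tuple[str, ...]:
        return tuple(self.code_sets)

    def categorize(self, codes: Iterable[str]) -> set[str]:
        """Categories matched by any of ``codes`` (possibly empty)."""
        out: set[str] = set()
        codes = list(codes)
        for cat, exact in self.code_sets.items():
            stems = self.prefix_stems.get(cat, ())
            for c in codes:
                if c in exact or any(c.startswith(s) for s in stems):
                    out.add(cat)
                    break
        return out


DEFAULT_CATEGORY_MAP = CategoryMap(
    code_sets={k: frozenset(v) for k, v in _EXACT_CODES.items()},
    prefix_stems={k: frozenset(v) for k, v in _PREFIX_STEMS.items()},
)


def categorize_visit(
    record: VisitRecord, category_map: CategoryMap = DEFAULT_CATEGORY_MAP
) -> set[str]:
    """All categories with at least one matching diagnosis code.

    A record with several diagnoses lands in each matching category; a record
    with no mappable code yields the empty set.
    """
    return category_map.categorize(record.icd_codes)


def parse_codes(cell: str) -> tuple[str, ...]:
    """Split a semicolon-delimited ICD-code cell."""
    return tuple(c.strip() for c in cell.split(";") if c.strip())


def read_visits(path) -> list[VisitRecord]:
    """Read a visit CSV with header ``tract_id,date,icd_codes,age,sex``."""
    import csv

    out: list[VisitRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"tract_id", "date", "icd_codes"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError("visit CSV must have columns tract_id,date,icd_codes")
        for row in reader:
            out.append(
                VisitRecord(
                    tract_id=row["tract_id"],
                    date=date.fromisoformat(row["date"]),
                    icd_codes=parse_codes(row["icd_codes"]),
                    age=float(row["age"]) if row.get("age") else None,
                    sex=row.get("sex") or None,
                )
            )
    return out


def write_visits(path, records: Sequence[VisitRecord]) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tract_id", "date", "icd_codes", "age", "sex"])
        for r in records:
            w.writerow(
                [r.tract_id, r.date.isoformat(), ";".join(r.icd_codes),
                 "" if r.age is None else r.age, r.sex or ""]
            )
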