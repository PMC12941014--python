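"""ICD-10 categorization of ED visit records and the pandemic split table.

Builds a handful of visit records, maps their diagnosis codes into the
eight mental-health categories (a visit with several diagnoses counts in
every matching category), aggregates a per-tract count panel, and prints
the before/during-pandemic tally with column percentages.
"""

from datetime import date

from stcar import (VisitRecord, build_panel, categorize_visit,
                   covid_split_table, make_grid_lattice)

records = [
    VisitRecord("r0c0", date(2019, 3, 5), ("F32.9",)),            # depression
    VisitRecord("r0c0", date(2019, 7, 9), ("F32.9", "F41.1")),    # dep + anx
    VisitRecord("r0c1", date(2020, 4, 2), ("F10.10",)),           # substance
    VisitRecord("r0c1", date(2021, 1, 20), ("F43.10",)),          # PTSD
    VisitRecord("r1c0", date(2020, 11, 3), ("F20.0",)),           # psychosis
    VisitRecord("r1c0", date(2019, 5, 5), ("Z00.0",)),            # unmapped
]

for r in records:
    codes = ";".join(r.icd_codes)
    cats = categorize_visit(r)
    print(f"{r.date}  {codes:<14s} -> {sorted(cats) or '(no category)'}")

lattice = make_grid_lattice(2, 2)
pops = {t: 500 for t in lattice.tract_ids}
panel = build_panel(records, lattice, pops, category="Depression")
print(f"\nDepression panel counts by (tract, year):\n{panel.Y}")

print("\nBefore/during pandemic split (column percentages):")
df = covid_split_table(records)
print(df[df["total_n"] > 0].to_string(index=False))
print("\nNote the multi-diagnosis visit appears in both the Depression and "
      "Anxiety rows, so category tallies exceed the number of visits.")
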