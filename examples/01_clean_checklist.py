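"""Clean a raw checklist: filters, authority parsing, surname variants.

Builds a small synthetic checklist export with injected author misspellings,
adds a few rows that the inclusion rules must reject, and runs the cleaning
step. The drop log says why each rejected row was removed; the variant
report lists surname pairs a curator should inspect.
"""

import io

import pandas as pd

from descurve import SyntheticConfig, build_checklist, clean_checklist
from descurve.checklist_io import suggest_variant_candidates

config = SyntheticConfig(
    N_total=800.0, alpha=1950.0, beta=0.06, start_year=1900, end_year=2023,
    author_pool_size=800, misspelling_rate=0.05, seed=7,
)
frame, truth = build_checklist(config)

# rows the filters must reject: a fossil, a subspecies, an unaccepted name
noise = pd.DataFrame(
    [
        {**frame.iloc[0].to_dict(), "scientific_name": "Fossilis extinctus",
         "is_fossil": True},
        {**frame.iloc[1].to_dict(), "scientific_name": "Sub species minor",
         "rank": "Subspecies"},
        {**frame.iloc[2].to_dict(), "scientific_name": "Dubium nomen",
         "status": "unaccepted"},
    ]
)
raw = pd.concat([frame, noise], ignore_index=True)

buf = io.StringIO()
raw.to_csv(buf, index=False)
buf.seek(0)
records, drop_log = clean_checklist(buf, variants=truth.variant_map)

print(f"input rows:          {len(raw)}")
print(f"clean species kept:  {len(records)}")
print(f"drop log:            {drop_log}")
# without the variant map, misspelled surnames would inflate the author count
names = {r.first_author for r in records}
pairs = suggest_variant_candidates(sorted(names)[:120])
print(f"near-duplicate surname pairs in first 120 names: {len(pairs)}")
print("example record:", records[0])
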