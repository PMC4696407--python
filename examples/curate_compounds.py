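"""Curate a toy assay table: calls, counts, categories and exclusions.

Builds a synthetic table of compounds with per-isoform AC50 / activity-score
evidence, classifies each piece of evidence into inhibitor / non-inhibitor /
indeterminate, then runs the structure curation pass (salt stripping, hydrate
water removal, inorganic/mixture rejection, strict MW<800 filter).
"""

from p450nnc import (
    CompoundRecord,
    InhibitionCall,
    IsoformEvidence,
    classify_call,
    curate,
    generate_assay_table,
)

table = generate_assay_table(12, seed=7)
print("evidence -> call")
for _, row in table.iterrows():
    call = classify_call(IsoformEvidence(row["isoform"], row["measure_kind"], row["value"]))
    print(f"  {row['id']}: {row['measure_kind']}={row['value']:.2f} -> {call.value}")

records = [CompoundRecord(r["id"], r["smiles"]) for _, r in table.iterrows()]
kept, report = curate(records)
print(f"\nkept {report.kept} of {len(records)} compounds")
print(f"excluded: mw>=800 Da: {report.excluded_by_mw}, inorganic: {report.excluded_inorganic}, "
      f"mixtures: {report.excluded_mixture}")
print("Each kept compound now has a standardized single-fragment structure and a")
print("computed molecular weight below 800 Da, ready for descriptor calculation.")
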