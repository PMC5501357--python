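"""Membrane/secreted classification of differential calls.

Loads the packaged transmembrane/signal-peptide annotation set (a
transcription of the published membrane-and-secreted protein table),
treats its reported response directions as consensus calls, and
partitions them into membrane, secreted and other proteins.
"""

import csv

from lfqpair import ConsensusCall, classify_membrane_secreted, load_packaged_membrane_table
from lfqpair.annotation import packaged_membrane_table_path

with open(packaged_membrane_table_path(), newline="", encoding="utf-8") as fh:
    rows = list(csv.DictReader(fh, delimiter="\t"))

calls = [
    ConsensusCall(r["accession"], "increased" if r["ri"] == "I" else "decreased", 3, ())
    for r in rows
]
annotations = load_packaged_membrane_table()
categories = classify_membrane_secreted(calls, annotations)

for name in ("membrane", "secreted", "other", "unannotated"):
    group = categories[name]
    up = sum(c.direction == "increased" for c in group)
    down = len(group) - up
    print(f"{name:12} {len(group):3}  (increased {up}, decreased {down})")

genes = {r["accession"]: r["gene"] for r in rows}
examples = [genes[c.accession] for c in categories["secreted"][:6]]
print(f"\nfirst secreted proteins: {', '.join(examples)}")
print("\nA protein with any transmembrane region counts as membrane; a "
      "signal peptide without one marks a secreted protein.")
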