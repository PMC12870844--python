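"""Best-hit ortholog assignment from tabular homology-search output.

Reproductive-protein gene sets are defined by mapping annotated proteins
from a related species onto the study transcriptome: keep hits with >=90%
identity, then per query the lowest-e-value hit (ties: higher bitscore,
then subject id).
"""

import pandas as pd

import sexseldiv as sd

hits = pd.DataFrame(
    [
        # query, subject, %identity, evalue, bitscore
        ("SFP_001", "transcript_0007", 96.5, 1e-80, 310.0),
        ("SFP_001", "transcript_0042", 91.0, 1e-12, 88.0),
        ("SFP_002", "transcript_0013", 89.2, 1e-60, 250.0),   # below identity cutoff
        ("FRP_010", "transcript_0099", 93.8, 1e-35, 140.0),
        ("FRP_010", "transcript_0100", 93.8, 1e-35, 160.0),   # same e-value, higher bitscore
    ],
    columns=["query_id", "subject_id", "percent_identity", "evalue", "bitscore"],
)

mapping = sd.ortholog_best_hit_filter(hits, min_identity=90.0)
for query, subject in sorted(mapping.items()):
    print(f"{query} -> {subject}")
print(f"\n{len(mapping)} of {hits['query_id'].nunique()} query proteins got an ortholog; "
      "queries whose best hits fall under 90% identity are dropped, so the\n"
      "resulting gene sets only contain confidently mapped transcripts.")
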