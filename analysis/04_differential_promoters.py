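#!/usr/bin/env python
"""Differential promoter expression between the two conditions.

Chi-square test of each promoter's weighted tag count against the library
remainder, then regulation classing: condition-specific (zero tags in the
other library, >= 10 tpm, p <= 0.01), up / down (fold change >= 3, p <= 0.01),
else common.
"""

import json
from pathlib import Path

import pandas as pd

from cagemap import differential
from cagemap.pipeline import _tsv

ROOT = Path(__file__).resolve().parents[1] / "results"

ann = pd.read_csv(ROOT / "annotated.tsv", sep="\t", comment="#",
                  keep_default_na=False, na_values=[])
totals = json.loads((ROOT / "library_totals.json").read_text())
calls = differential.classify_regulation(ann, totals)
_tsv(calls, ROOT / "promoter_calls.tsv", {"alpha": 0.01, "fc": 3})

counts = calls["regulation"].value_counts()
print("regulation classes:")
print(counts.to_string())
sig = calls[calls["p_value"] <= 0.01]
print(f"significant at p<=0.01: {len(sig)} of {len(calls)}")
unann = calls.groupby("regulation")["gene_id"].apply(lambda s: (s == "").mean())
print("unannotated fraction by class:")
print(unann.round(3).to_string())
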