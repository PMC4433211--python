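#!/usr/bin/env python
"""Chromatin-state classification and promoter epigenetic transitions.

Classifies H3K4me3/H3K4me1 islands into promoter vs enhancer regions via the
log-ratio rule, flags bivalent (H3K4me3+/H3K27me3+) promoter regions, and
crosses each CAGE promoter's condition-1 epigenetic state (active vs poised)
with its regulation class to extract the poised-to-active population.
"""

import json
from pathlib import Path

import pandas as pd

from cagemap import chromatin, synthetic
from cagemap.pipeline import _tsv
from cagemap.synthetic import CONDITIONS

ROOT = Path(__file__).resolve().parents[1] / "results"
FIXTURE = ROOT / "fixture"

totals = {tuple(k.split(":")): v
          for k, v in json.loads((FIXTURE / "island_totals.json").read_text()).items()}
regions = {}
for cond in CONDITIONS:
    isl = {m: synthetic.read_islands_bed(FIXTURE / f"islands_{m}_{cond}.bed")
           for m in ("H3K4me3", "H3K4me1", "H3K27me3")}
    reg = chromatin.classify_regions(isl["H3K4me3"], isl["H3K4me1"],
                                     totals[("H3K4me3", cond)], totals[("H3K4me1", cond)])
    reg = chromatin.call_bivalent(reg, isl["H3K27me3"])
    regions[cond] = reg
    _tsv(reg, ROOT / f"regions_{cond}.tsv", {})
    print(f"{cond}: {len(reg)} regions -> "
          f"{(reg['label'] == 'promoter').sum()} promoter / "
          f"{(reg['label'] == 'enhancer').sum()} enhancer, "
          f"{reg['bivalent'].sum()} bivalent")

calls = pd.read_csv(ROOT / "promoter_calls.tsv", sep="\t", comment="#",
                    keep_default_na=False, na_values=[])
calls, table, p2a = chromatin.classify_transitions(calls, regions["cond1"])
_tsv(calls, ROOT / "promoter_calls.tsv", {"alpha": 0.01, "fc": 3})
_tsv(table.rename_axis("state").reset_index(), ROOT / "transitions.tsv", {})
_tsv(p2a, ROOT / "poised_to_active.tsv", {})
print("condition-1 epigenetic state x regulation class:")
print(table.to_string())
print(f"poised-to-active promoters (poised in condition 1, up or "
      f"condition-2-specific): {len(p2a)}")
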