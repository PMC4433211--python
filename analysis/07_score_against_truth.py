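#!/usr/bin/env python
"""Score the whole analysis against the planted ground truth.

Reports promoter recall, regulation-class macro-F1, poised-to-active recall
and transcribed-enhancer recall/precision, and writes the combined scores to
results/recovery.json.
"""

import json
from pathlib import Path

import pandas as pd

from cagemap import cage, scoring, synthetic

ROOT = Path(__file__).resolve().parents[1] / "results"
FIXTURE = ROOT / "fixture"

truth = synthetic.read_truth_json(FIXTURE / "truth.json")
promoters = cage.read_promoters(ROOT / "promoters.tsv")
calls = pd.read_csv(ROOT / "promoter_calls.tsv", sep="\t", comment="#",
                    keep_default_na=False, na_values=[])
p2a = pd.read_csv(ROOT / "poised_to_active.tsv", sep="\t", comment="#",
                  keep_default_na=False, na_values=[])
enh = pd.read_csv(ROOT / "cage_enhancers.tsv", sep="\t", comment="#")

matches = scoring.match_promoters(truth, promoters)
rec = scoring.enhancer_recovery(truth, enh)
scores = {
    "promoter_recall": scoring.promoter_recall(matches),
    "regulation_macro_f1": scoring.regulation_macro_f1(matches, calls),
    "poised_to_active_recall": scoring.poised_to_active_recall(matches, p2a),
    "transcribed_enhancer_recall": rec["recall"],
    "transcribed_enhancer_precision": rec["precision"],
}
(ROOT / "recovery.json").write_text(json.dumps(scores, indent=1))
for k, v in scores.items():
    print(f"{k}: {v:.3f}")
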