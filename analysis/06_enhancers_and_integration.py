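#!/usr/bin/env python
"""Transcribed enhancers: bidirectional CAGE loci and the enhancer cross-tab.

Builds the TSS/exon exclusion mask, scans the pooled Level-1 signal for
balanced divergent tag-cluster pairs (>= 2 tags in one sample) outside the
mask, tests them for differential expression with the fixed-dispersion NB
exact test, and cross-tabulates eRNA-like CAGE promoters against the
condition-specificity of epigenetically defined enhancer regions.
"""

import json
from pathlib import Path

import pandas as pd

from cagemap import cage, chromatin, differential, integrate
from cagemap.genome import read_chrom_sizes, read_gtf
from cagemap.pipeline import _tsv
from cagemap.synthetic import CONDITIONS

ROOT = Path(__file__).resolve().parents[1] / "results"
FIXTURE = ROOT / "fixture"

model = read_gtf(FIXTURE / "genes.gtf", read_chrom_sizes(FIXTURE / "chrom.sizes"))
level1 = cage.read_level1_tsv(ROOT / "level1.tsv")
totals = json.loads((ROOT / "library_totals.json").read_text())
calls = pd.read_csv(ROOT / "promoter_calls.tsv", sep="\t", comment="#",
                    keep_default_na=False, na_values=[])
regions = {c: pd.read_csv(ROOT / f"regions_{c}.tsv", sep="\t", comment="#")
           for c in CONDITIONS}

mask = integrate.build_mask(model)
enh = integrate.call_cage_enhancers(level1, mask)
enh = differential.call_differential_enhancers(enh, totals)
_tsv(enh, ROOT / "cage_enhancers.tsv", {"min_tags": 2, "alpha": 0.05, "fc": 2,
                                        "dispersion": 0.09})
print(f"mask covers {int((mask['end'] - mask['start']).sum())} bp; "
      f"{len(enh)} bidirectional CAGE-enhancers called "
      f"({(enh['call'] != 'ns').sum()} differential)")

catalog = chromatin.enhancer_specificity(regions["cond1"], regions["cond2"])
table1, selected = integrate.find_transcribed_enhancers(calls, catalog)
_tsv(catalog, ROOT / "enhancer_catalog.tsv", {})
_tsv(table1.rename_axis("activity").reset_index(), ROOT / "table1.tsv", {})
print("eRNA-like CAGE promoters inside enhancer regions "
      "(activity x enhancer specificity):")
print(table1.to_string())

for cond in CONDITIONS:
    ov = integrate.overlap_promoters_islands(calls, regions[cond])
    _, distal = integrate.enhancer_promoter_distance_filter(regions[cond], calls)
    print(f"{cond}: {ov['promoter_fraction_matched']:.1%} of CAGE promoters within "
          f"2 kb of a promoter region; {distal:.1%} of enhancer regions "
          f"> 2 kb from any CAGE promoter")
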