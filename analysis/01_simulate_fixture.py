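#!/usr/bin/env python
"""Simulate the two-condition study inputs with planted ground truth.

Writes a demo-scale synthetic data set (3 chromosomes, 500 genes, two CAGE
libraries of 1e6 tags with 15% multimapping tags, H3K4me3/H3K4me1/H3K27me3
islands, 200 planted promoters, 100 enhancers of which 20 transcribed) to
results/fixture/, together with the truth JSON used for scoring.
"""

import sys
from pathlib import Path

from cagemap import make_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "fixture"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

fixture = make_fixture("demo", seed=SEED, outdir=OUT)
n_tags = {c: df["tag_id"].nunique() for c, df in fixture.alignments.items()}
print(f"fixture written to {OUT}")
print(f"  genes: {len(fixture.model.genes)} on {len(fixture.model.chrom_sizes)} chromosomes")
print(f"  CAGE tags per condition: {n_tags}")
print(f"  planted promoters: {len(fixture.truth.promoters)} "
      f"({sum(p.bivalent for p in fixture.truth.promoters)} bivalent)")
print(f"  planted enhancers: {len(fixture.truth.enhancers)} "
      f"({len(fixture.truth.transcribed_enhancers)} transcribed)")
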