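#!/usr/bin/env python
"""Annotate promoters: genomic context, gene assignment, motif windows.

Places each promoter's dominant TSS in its genomic context (promoter window,
UTRs, exons, introns, noncoding transcripts, antisense, intergenic), assigns
promoters to same-strand genes within 400 bp, counts alternative promoter
usage per gene and exports the -300/+100 bp windows for motif analysis.
"""

from pathlib import Path

from cagemap import annotate, cage
from cagemap.genome import read_chrom_sizes, read_gtf
from cagemap.pipeline import _tsv

ROOT = Path(__file__).resolve().parents[1] / "results"
FIXTURE = ROOT / "fixture"

model = read_gtf(FIXTURE / "genes.gtf", read_chrom_sizes(FIXTURE / "chrom.sizes"))
promoters = cage.read_promoters(ROOT / "promoters.tsv")
ann = annotate.annotate_promoters(promoters, model)
_tsv(ann, ROOT / "annotated.tsv", {"gene_dist": 400})

tfbs = annotate.export_tfbs_regions(ann, model.chrom_sizes)
tfbs.to_csv(ROOT / "tfbs_regions.bed", sep="\t", header=False, index=False)
alt, frac = annotate.count_alternative_promoters(ann)
_tsv(alt, ROOT / "alternative_promoters.tsv", {})

print("context fractions:")
print((ann["context"].value_counts(normalize=True).round(3)).to_string())
print(f"annotated to a gene within 400 bp: {(ann['gene_id'] != '').mean():.1%}")
print(f"genes with >= 2 alternative promoters: "
      f"{ {c: round(f, 3) for c, f in frac.items()} }")
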