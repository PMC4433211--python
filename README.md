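# cagemap

Genome-wide definition of **active promoters and transcribed enhancers** from
CAGE-seq and histone-modification data across two cell states (a
pluripotent-like condition 1 and a committed condition 2, as in embryonic
stem cells induced to neuroepithelial-like stem cells).

CAGE (Cap Analysis of Gene Expression) sequences the 5′ ends of capped RNAs,
mapping transcription start sites (TSSs) at single-base resolution and
quantifying promoter activity in tags per million (tpm). `cagemap`
re-implements, as a tested and reusable pipeline, the analysis that joins
CAGE tag clusters with SICER-style H3K4me1/H3K4me3/H3K27me3 islands:

1. **Multimap rescue.** A tag mapping to several locations gets per-candidate
   weights `w_i = u_i / Σ_j u_j`, where `u_i` counts uniquely mapped
   same-strand tags in the 200-bp window around candidate `i` (equal weights
   when every window is empty).
2. **Promoter calling.** Weighted tags are summed per base and strand
   (Level-1 TSSs), normalized to tpm, and chained into Level-2 CAGE
   promoters when closer than 20 bp on one strand; promoters are kept at
   ≥ 10 tpm in at least one condition.
3. **Annotation.** Each promoter's dominant TSS is placed in genomic context
   (annotated TSS ± 500 bp, 5′ UTR, exon, intron, 3′ UTR, noncoding
   transcript, antisense, intergenic) and assigned to a same-strand gene
   whose TSS lies within 400 bp of either promoter end.
4. **Differential expression.** A χ² test on the 2×2 table
   `[[count, library − count], …]` per promoter; classes are
   condition-specific (zero tags in the other library, p ≤ 0.01), up / down
   (fold change ≥ 3, p ≤ 0.01), else common.
5. **Chromatin states.** Overlapping H3K4me3/H3K4me1 islands merge into
   regions labelled promoter or enhancer by the sign of
   `log2(me3 / me1)` of per-million-normalized counts; promoter regions
   intersecting H3K27me3 are bivalent (poised). Crossing condition-1 states
   with the CAGE classes yields the poised→active population.
6. **Transcribed enhancers (eRNAs).** Outside a mask of TSSs ± 500 bp and
   exons ± 200 bp, balanced divergent tag-cluster pairs (minus-strand
   cluster 5′ of the plus-strand cluster, directionality
   `(plus − minus)/(plus + minus)` within ± 0.8) with ≥ 2 pooled tags in one
   sample are called CAGE-enhancers and tested with a fixed-dispersion
   (φ = 0.3² = 0.09) conditional negative-binomial exact test.

A first-class **synthetic-data module** generates the toy genome, the two
CAGE libraries (with planted multimapping tags, divergent eRNA loci and
background noise) and the histone islands with a planted truth set, so every
stage is testable without any external download.

## Worked example

```bash
cagemap simulate --size tiny --seed 5 --outdir fixture/
cagemap run-all --fixture-dir fixture/ --outdir out/
cagemap report --outdir out/
```

prints (tiny fixture, seed 5):

```
promoters: 67 (expressed {'cond1': 42, 'cond2': 45})
regulation: {'common': 56, 'cond1_specific': 4, 'cond2_specific': 3, 'down': 3, 'up': 1}
regions: {'cond1': 29, 'cond2': 31} | bivalent {'cond1': 3, 'cond2': 0}
...
CAGE-enhancers: 4 calls {'down': 1, 'ns': 2, 'up': 1}
```

On a 50k-tag library a single background tag already exceeds 10 tpm, so the
tiny fixture deliberately shows the promoter caller's behaviour under noise;
the demo fixture (1M tags per condition) is the calibrated study scale. The
same run as a library call:

```python
from cagemap import make_fixture, run_fixture, scoring

fx = make_fixture("demo", seed=1)      # 500 genes, 200 planted promoters
res = run_fixture(fx)                  # the whole pipeline, in memory
m = scoring.match_promoters(fx.truth, res.promoters)
print(scoring.promoter_recall(m))      # 1.0
print(res.summary["regulation_counts"])
# {'cond1_specific': 23, 'cond2_specific': 25, 'up': 30, 'down': 31, 'common': 106}
```

The numbered scripts under `analysis/` run the same study step by step
(simulate → promoters → annotation → differential → chromatin → enhancers →
scoring), each writing its tables under `results/` and printing what it
found.

## Layout

- `src/cagemap/` — the library: `synthetic` (generator + truth),
  `cage` (weights, Level-1/2), `annotate`, `differential` (χ², NB exact
  test), `chromatin`, `integrate`, `scoring`, `pipeline`, `config`, `cli`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property (hypothesis) and end-to-end recovery tests.
- `docs/methods.md` — model, parameters and design notes.
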