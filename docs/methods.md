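# Methods

`cagemap` maps active promoters and transcribed enhancers in a two-condition
design (condition 1 → condition 2, e.g. a pluripotent state induced towards a
committed one) from two kinds of input: strand-specific 1-bp CAGE tag
alignments with multi-mapping candidates, and broad histone-mark islands
(SICER-style BED with per-island tag counts) for H3K4me3, H3K4me1 and
H3K27me3. Peak calling, read alignment, motif discovery and microarray
processing are out of scope: islands and alignments are consumed, not
computed.

## CAGE promoter model

**Multimap rescue.** Each tag contributes total weight 1. For a tag with
candidates `i = 1..n`, the weight of candidate `i` is `u_i / Σ_j u_j`, where
`u_i` is the number of *uniquely* mapped tags of the same library on the same
strand within the 200-bp window `[pos − 100, pos + 100)`. When all `u_j = 0`
the tag gets equal weights `1/n`. The window is read as symmetric around the
candidate and half-open for determinism. Weighting is a single pass (one
rescue step, not an EM): unique-tag counts are computed once from
single-candidate tags and never re-estimated. Whether the neighbourhood
should be strand-restricted is a genuinely open convention; we restrict to
the same strand, consistent with CAGE's strand-specific signal, and the
choice is visible in `assign_multimap_weights`.

**Level-1 / Level-2.** Level-1 TSSs sum candidate weights per
(chromosome, base, strand); positions whose weighted count is exactly zero
(pure decoy candidates) are dropped, so `Σ counts = library size` exactly.
tpm is `count / total mapped tags × 1e6`, computed at Level-1; a promoter's
tpm is its member sum. Level-2 promoters chain same-strand positions at
distance `< 20 bp` (strictly: a 19-bp gap merges, a 20-bp gap splits) by
single-linkage, and are retained at ≥ 10 tpm in at least one condition. The
dominant TSS is the member with maximal pooled (both-condition) tpm, ties
broken to the 5′-most position on the promoter's strand; per-condition
selection is available through `select_dominant_tss`.

Coordinates are 0-based half-open everywhere, including BED output; a CTSS
is a 1-bp interval.

## Annotation

A TSS receives exactly one context by precedence over same-strand features:
promoter window (annotated TSS ± 500 bp) > 5′ UTR > coding exon > intron >
3′ UTR > noncoding transcript. If nothing matches on the TSS's strand the
same precedence is applied to the opposite strand and the hit is reported
with `orientation = antisense`; otherwise the TSS is intergenic. The
annotation does not state a resolution order for overlapping features, so
the precedence mirrors the mutual exclusivity of the reported categories.
"Bidirectional" promoters are defined operationally as divergent pairs whose
dominant TSSs lie within 500 bp, minus-strand partner upstream; this is a
declared convention, not an established definition.

Gene assignment: the nearest same-strand gene whose annotated TSS is within
400 bp of either promoter end (distance 0 when the TSS falls inside the
promoter); everything else is "unannotated". Alternative promoters are
counted per gene per condition (a promoter counts where its tpm > 0). Motif
windows are exported as `[TSS − 300, TSS + 100]`, strand-mirrored, clipped
at chromosome bounds.

## Differential statistics

**Promoters.** Pearson χ² (1 df, no continuity correction) on
`[[count1, lib1 − count1], [count2, lib2 − count2]]`; the correction is
immaterial at library-scale denominators and can be enabled by flag.
Degenerate tables return statistic 0, p = 1. Classes: condition-specific
requires *zero* weighted tags in the other library (the strictest reading of
exclusive expression), ≥ 10 tpm in its own, and p ≤ 0.01; up / down requires
|log2 FC| ≥ log2 3 and p ≤ 0.01; the remainder is common. The five classes
are mutually exclusive and exhaustive. No multiple-testing correction is
applied to the classing (the filter is on raw p ≤ 0.01); a
Benjamini–Hochberg column is emitted for information.

**Enhancers.** Lowly expressed eRNA loci need an overdispersion-aware test:
we use a conditional negative-binomial exact test with fixed dispersion
φ = 0.3² = 0.09. Counts are rescaled to the geometric mean of the two
library sizes and rounded (a stated simplification of quantile adjustment);
conditioned on the scaled total `n`, both sides are NB with mean `n/2` and
dispersion φ under the null, and the p-value sums the probabilities of every
split `(a, n − a)` whose probability does not exceed the observed one
(ties included with a 1e-8 relative tolerance in log space), normalized by
the probability of the total. At φ = 0 the null reduces to Poisson and the
test to the exact binomial split test. An enhancer is up/down at p ≤ 0.05
and library-scaled fold change ≥ 2.

## Chromatin states

Islands of the two H3K4 marks are grouped by transitive ≥ 1-bp overlap;
each maximal group becomes one region spanning the union. A region with only
H3K4me3 is a promoter, only H3K4me1 an enhancer; mixed groups are labelled by
the sign of `log2(me3_norm / me1_norm)` with tag counts summed per mark over
the group and normalized per million (no per-kb normalization — both marks
are measured on the same merged region, so length cancels from the ratio;
whether the original workflow summed island counts or per-bp pileup is not
recoverable, and summed counts are the simpler region-level reading). A
ratio of exactly 0 goes to promoter (configurable tie label); the log base
never affects the sign test. Promoter regions intersecting ≥ 1 bp of
H3K27me3 in the same condition are bivalent (poised); enhancer regions are
never flagged.

Each CAGE promoter is matched to its condition-1 epigenetic state within
± 2 kb (base distance: a region base exactly 2,000 bp from a promoter base
matches; 2,001 does not). When both an active and a poised promoter region
are in reach, the poised one wins — the bivalent signature is the
informative one. Promoters with no region in reach land in a `no_island`
bucket outside the state × class table. The poised→active list is: poised in
condition 1 and CAGE class up or condition-2-specific.

## Transcribed enhancers (CAGE-enhancers)

The mask is the union of annotated TSSs ± 500 bp ("1 kb around TSSs", read
symmetric; a ± 1 kb reading is available by flag) and exons ± 200 bp. The
two libraries are pooled (per-base, per-strand weighted counts summed).
Strand clusters are built with the Level-2 chaining rule at min_tpm 0; a
candidate locus pairs a minus-strand cluster whose 5′ end (rightmost base)
lies at most 400 bp left of a plus-strand cluster's 5′ end (leftmost base) —
divergent geometry. Filters: summed pair count ≥ 2 tags in at least one
sample (the locus total, not per strand), pooled directionality
`(plus − minus)/(plus + minus)` within ± 0.8, and no mask intersection
(hard assertion on all output). Overlapping candidates are merged keeping
the highest pooled total; the midpoint is the centre between the two cluster
summits. The 400-bp pairing window and the 0.8 directionality bound are
declared conventions (the original bidirectional-pairing procedure's
internals are not recoverable from its description); every constant is in
`RunConfig`.

The transcribed-enhancer cross-tab selects CAGE promoters that are
unannotated or annotated to noncoding biotypes and lie fully inside an
epigenetically defined enhancer region, tabulated by activity (condition 1 /
condition 2 / both, zero-count rule) × enhancer specificity (specific when a
region overlaps no enhancer region of the other condition, else common).

## Synthetic data: what it emulates, and what it does not

The generator plants ground truth and emits inputs with the statistical
structure the analysis assumes:

- **Genome**: 1–3 chromosomes, genes with 2–5 exons and a CDS (so UTR
  contexts exist), separated by ≥ 10 kb so masks never merge by accident.
- **Promoters** at gene TSSs with per-condition mean tpm drawn log-normally
  and per-promoter counts negative-binomial (Gamma multipliers with size 10
  inside a multinomial allocation, i.e. Gamma–Poisson conditioned on the
  library total) — the overdispersed count structure the NB test assumes.
  Regulation classes: common, condition-specific (mean 0 in the other
  condition), up/down at a planted fold change of 6 (log2 ≈ 2.6, within the
  1–12 log2-FC range such experiments report, and far enough from the
  FC ≥ 3 calling threshold that class identity survives NB sampling noise).
- **Positional jitter**: discretized Gaussian, σ = 4 bp truncated at ± 20 bp,
  guaranteeing single-cluster recovery under the < 20 bp rule.
- **Multimapping**: a configurable share of tags (default 15%) carries 2–4
  candidates; decoys are ≥ 1 kb from every planted promoter TSS so the
  unique-neighbourhood weighting can resolve them.
- **eRNA loci**: divergent cluster pairs (minus 5′ of plus, 300 bp apart)
  with per-strand counts ≥ 2 and bounded imbalance, so planted loci satisfy
  the caller's declared balance filter — the recovery guarantee is part of
  the generator's contract.
- **Islands**: H3K4me3 spanning each planted TSS (both conditions), H3K4me1
  over each enhancer in the condition(s) of its specificity, H3K27me3 over
  bivalent promoters in condition 1 only, plus optional random noise islands.
- **Background**: `round(noise_rate × genome length)` uniform tags; the
  emitted library size equals the requested depth exactly.

One seeded generator drives everything; the seed is recorded in the truth
JSON and fixtures are byte-reproducible.

What it does **not** emulate: promoter shape classes (broad vs sharp), CAGE
artifacts (G-addition), sequence content (no reads, no FASTQ), mappability
structure (decoys are uniform, not repeat-driven), correlated biological
replicates, or chromatin signal gradients within islands. Passing the
recovery tests therefore shows the pipeline's rules are implemented
correctly and are mutually consistent at realistic depths — not that the
thresholds are optimal for any particular real library.

## Fixture scales

`tiny` (1 chromosome / 2 Mb / 50 genes / 50k tags) builds and runs in ~2 s
and is used for smoke and determinism tests; at this depth one background
tag exceeds 10 tpm, which the tests treat as expected behaviour, not noise
robustness. `demo` (3 chromosomes / 30 Mb / 500 genes / 200 promoters with
20+20 condition-specific, 30 up, 30 down / 30 bivalent / 100 enhancers with
20 transcribed / 1e6 tags per condition / background 1e-5 tags per bp) is
the calibrated study scale used by the recovery tests and the acceptance
script; a full run takes a few seconds on one CPU.

## Numerical choices and degenerate inputs

- Weights: exact conservation (`Σ w = 1` per tag) by construction; zero-sum
  neighbourhoods fall back to `1/n`.
- χ²: zero-margin tables → statistic 0, p = 1; counts above library totals
  raise.
- NB exact test: p computed in log space, max-subtracted; dispersion < 0 and
  non-positive libraries raise; total 0 → p = 1.
- Clustering requires sorted input and raises otherwise (no silent
  re-sorting).
- Correlation with a zero-variance vector returns NaN with a warning rather
  than raising.
- All interval logic is half-open; "within ± w" matching uses base distance,
  inclusive at exactly w.

## Known limitations

- The χ² table construction (promoter vs library remainder, weighted
  non-integer counts) is one of several defensible readings; counts are not
  rounded before testing.
- Enhancer condition-specificity is overlap-based (≥ 1 bp), not
  reciprocal-fraction-based.
- The per-condition activity call in the cross-tab reuses the zero-count
  exclusivity rule; borderline loci with a single stray tag in the other
  condition move from "specific" to "both".
- The pipeline holds Level-1 tables in memory; libraries far beyond ~1e7
  tags would need chunked processing.
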