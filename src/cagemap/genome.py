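"""Toy genome annotation: gene models with exon structure, GTF/BED12 round trip.

The genome model stands in for a RefSeq/Gencode-style annotation: each gene is
a single-transcript model with ordered, non-overlapping exons, a strand, a TSS
at the 5'-most exon boundary and a coding/noncoding biotype.  Coding genes
carry a CDS nested inside the exonic sequence so that 5'/3' UTR intervals are
well defined for TSS context classification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np


class GenomeSizingError(ValueError):
    """Requested gene count cannot be placed at the required spacing."""


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str  # "+" or "-"
    exons: tuple  # tuple of (start, end), 0-based half-open, sorted, disjoint
    biotype: str = "coding"  # "coding" | "noncoding"
    cds: Optional[tuple] = None  # (start, end) genomic span of the CDS, coding only

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """5'-most transcribed base (position of the first transcribed bp)."""
        return self.start if self.strand == "+" else self.end - 1

    def utr5_intervals(self):
        """Exonic intervals 5' of the CDS (empty for noncoding genes)."""
        return self._utr(five_prime=True)

    def utr3_intervals(self):
        return self._utr(five_prime=False)

    def _utr(self, five_prime: bool):
        if self.cds is None:
            return []
        cs, ce = self.cds
        upstream = five_prime == (self.strand == "+")
        out = []
        for s, e in self.exons:
            if upstream:
                lo, hi = s, min(e, cs)
            else:
                lo, hi = max(s, ce), e
            if lo < hi:
                out.append((lo, hi))
        return out

    def cds_exon_intervals(self):
        if self.cds is None:
            return list(self.exons)
        cs, ce = self.cds
        return [(max(s, cs), min(e, ce)) for s, e in self.exons if max(s, cs) < min(e, ce)]

    def intron_intervals(self):
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]


@dataclass
class GenomeModel:
    chrom_sizes: dict
    genes: list = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise ValueError(f"{g.gene_id}: unknown chromosome {g.chrom}")
            if not (0 <= g.start < g.end <= self.chrom_sizes[g.chrom]):
                raise ValueError(f"{g.gene_id}: gene outside chromosome bounds")
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                if not (s1 < e1 <= s2 < e2):
                    raise ValueError(f"{g.gene_id}: exons unsorted or overlapping")
            if g.strand not in "+-":
                raise ValueError(f"{g.gene_id}: bad strand {g.strand!r}")


def build_genome_model(
    n_chroms: int,
    n_genes: int,
    seed: int,
    chrom_length: int = 10_000_000,
    min_spacing: int = 10_000,
    coding_fraction: float = 0.9,
) -> GenomeModel:
    """Place ``n_genes`` gene models on ``n_chroms`` chromosomes.

    Genes are separated by at least ``min_spacing`` bp of intergenic space so
    promoter/exon masks of neighbouring genes never merge by accident.
    Deterministic for a fixed seed.  Raises :class:`GenomeSizingError` when the
    genes cannot fit.
    """
    if n_chroms < 1 or chrom_length < 1_000_000:
        raise ValueError("need >= 1 chromosome of >= 1 Mb")
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}
    genes: list[GeneModel] = []
    # round-robin allocation of genes to chromosomes
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    max_span = 8_000
    edge = 5_000
    gi = 0
    for ci, (chrom, n_c) in enumerate(zip(chrom_sizes, per_chrom)):
        if n_c == 0:
            continue
        usable = chrom_length - 2 * edge
        if n_c * (max_span + min_spacing) > usable:
            raise GenomeSizingError(
                f"{n_c} genes x (span {max_span} + spacing {min_spacing}) bp "
                f"exceed the {usable} usable bp of {chrom}"
            )
        spans = rng.integers(2_000, max_span + 1, size=n_c)
        slack = usable - int(spans.sum()) - n_c * min_spacing
        # distribute leftover space into n_c + 1 random gaps
        extra = rng.multinomial(slack, np.full(n_c + 1, 1.0 / (n_c + 1)))
        pos = edge
        for k in range(n_c):
            pos += int(extra[k]) + (min_spacing if k > 0 else 0)
            span = int(spans[k])
            strand = "+" if rng.random() < 0.5 else "-"
            biotype = "coding" if rng.random() < coding_fraction else "noncoding"
            exons = _random_exons(pos, pos + span, rng)
            cds = _place_cds(exons, rng) if biotype == "coding" else None
            genes.append(
                GeneModel(
                    gene_id=f"G{gi:05d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    biotype=biotype,
                    cds=cds,
                )
            )
            gi += 1
            pos += span
    model = GenomeModel(chrom_sizes=chrom_sizes, genes=genes)
    model.validate()
    return model


def _random_exons(start: int, end: int, rng) -> tuple:
    """Split [start, end) into 2-5 exons separated by introns (>= 100 bp each)."""
    span = end - start
    n_ex = int(rng.integers(2, 6))
    n_seg = 2 * n_ex - 1
    min_seg = 100
    while n_seg * min_seg > span:
        n_ex -= 1
        n_seg = 2 * n_ex - 1
        if n_ex == 1:
            return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, span // min_seg), size=n_seg - 1, replace=False)) * min_seg
    bounds = np.concatenate([[0], cuts, [span]]) + start
    return tuple((int(bounds[2 * i]), int(bounds[2 * i + 1])) for i in range(n_ex))


def _place_cds(exons, rng) -> tuple:
    """CDS spanning the middle ~60% of the exonic length, mapped to genomic coords."""
    lens = np.array([e - s for s, e in exons])
    total = int(lens.sum())
    lo = max(1, int(0.2 * total))
    hi = max(lo + 1, int(0.8 * total))
    gs = _exonic_to_genomic(exons, lo)
    ge = _exonic_to_genomic(exons, hi)
    return (gs, ge)


def _exonic_to_genomic(exons, offset: int) -> int:
    for s, e in exons:
        if offset < e - s:
            return s + offset
        offset -= e - s
    return exons[-1][1]


# ---------------------------------------------------------------------------
# serialization


def write_gtf(model: GenomeModel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in model.genes:
            attrs = (
                f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.1"; '
                f'gene_biotype "{"protein_coding" if g.biotype == "coding" else "lncRNA"}";'
            )
            fh.write(
                f"{g.chrom}\tcagemap\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tcagemap\ttranscript\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exons:
                fh.write(f"{g.chrom}\tcagemap\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
            if g.cds is not None:
                for s, e in g.cds_exon_intervals():
                    fh.write(f"{g.chrom}\tcagemap\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{attrs}\n")


def write_bed12(model: GenomeModel, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in model.genes:
            block_sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            block_starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            cds = g.cds if g.cds is not None else (g.start, g.start)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{cds[0]}\t{cds[1]}\t0\t{len(g.exons)}\t{block_sizes}\t{block_starts}\n"
            )


def write_chrom_sizes(model: GenomeModel, path) -> None:
    with Path(path).open("w") as fh:
        for chrom, size in model.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path) -> dict:
    sizes = {}
    for line in Path(path).read_text().splitlines():
        if line.strip():
            chrom, size = line.split("\t")
            sizes[chrom] = int(size)
    return sizes


def read_gtf(path, chrom_sizes: dict) -> GenomeModel:
    """Load a GTF annotation into a :class:`GenomeModel` via :mod:`gffutils`."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for gene in db.features_of_type("gene"):
        gid = gene.attributes["gene_id"][0]
        exons = sorted(
            (f.start - 1, f.end)
            for f in db.region(region=(gene.seqid, gene.start, gene.end), featuretype="exon")
            if f.attributes.get("gene_id", [None])[0] == gid
        )
        cds_parts = [
            (f.start - 1, f.end)
            for f in db.region(region=(gene.seqid, gene.start, gene.end), featuretype="CDS")
            if f.attributes.get("gene_id", [None])[0] == gid
        ]
        biotype = gene.attributes.get("gene_biotype", ["protein_coding"])[0]
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                biotype="coding" if biotype == "protein_coding" else "noncoding",
                cds=(min(s for s, _ in cds_parts), max(e for _, e in cds_parts)) if cds_parts else None,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    model = GenomeModel(chrom_sizes=dict(chrom_sizes), genes=genes)
    model.validate()
    return model
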