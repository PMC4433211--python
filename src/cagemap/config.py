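"""Run configuration: every numeric threshold of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

CONFIG_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    # input paths (None when running from an in-memory fixture)
    alignments: dict = field(default_factory=dict)  # condition -> BED path
    islands: dict = field(default_factory=dict)  # "mark:condition" -> BED path
    annotation_gtf: str | None = None
    chrom_sizes: str | None = None
    truth: str | None = None
    outdir: str = "results"
    seed: int = 0
    # CAGE promoter calling
    weight_window: int = 200
    max_gap: int = 20
    min_tpm: float = 10.0
    # annotation
    gene_dist: int = 400
    promoter_halfwidth: int = 500
    tfbs_upstream: int = 300
    tfbs_downstream: int = 100
    # differential promoters
    fc_log2: float = float(np.log2(3.0))
    alpha_promoter: float = 0.01
    # chromatin / integration
    overlap_window: int = 2000
    transition_window: int = 2000
    distal_min_dist: int = 2000
    mask_tss_halfwidth: int = 500
    mask_exon_pad: int = 200
    # CAGE-enhancers
    enhancer_window: int = 400
    enhancer_min_tags: float = 2.0
    enhancer_max_directionality: float = 0.8
    alpha_enhancer: float = 0.05
    fc_enhancer: float = 2.0
    dispersion: float = 0.09
    schema_version: int = CONFIG_SCHEMA_VERSION

    def validate(self) -> None:
        positive = (
            "weight_window", "max_gap", "min_tpm", "gene_dist", "promoter_halfwidth",
            "overlap_window", "transition_window", "distal_min_dist", "enhancer_window",
            "enhancer_min_tags", "alpha_promoter", "alpha_enhancer", "fc_enhancer",
            "fc_log2", "enhancer_max_directionality",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**doc)
        cfg.validate()
        return cfg

    def thresholds(self) -> dict:
        d = asdict(self)
        for k in ("alignments", "islands", "annotation_gtf", "chrom_sizes", "truth", "outdir"):
            d.pop(k, None)
        return d
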