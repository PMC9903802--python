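"""Run configuration: every tunable threshold with its documented default."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class Config:
    # clustering
    proximity_distance: int = 5_000        # breakends closer than this merge (strict <)
    long_variant_threshold: int = 1_000_000  # DEL/DUP length to qualify for the overlap rule
    ploidy: float = 2.0
    high_major_offset: float = 2.0         # high-major run: major CN >= ploidy + offset
    # annotation
    foldback_max_distance: int = 5_000
    loh_threshold: float = 0.5             # minor CN below this is LOH
    homdel_threshold: float = 0.5          # total CN below this is homozygous deletion
    polya_min_length: int = 11
    polya_purity: float = 0.9
    line_window: int = 5_000               # window for suspected LINE source loci
    transduction_distance: int = 5_000     # transduced interval within this downstream of source
    phase_max_separation: int = 1_000
    # classification
    shard_max_length: int = 1_000
    ecdna_jcn_min: float = 5.0
    ecdna_adjacency_ratio: float = 2.3
    ecdna_closure_min: float = 0.5         # "predominantly closed" score
    high_amp_jcn: float = 8.0
    pseudogene_tolerance: int = 5          # bases around intron splice boundaries
    pseudogene_min_introns: int = 2
    pseudogene_min_fraction: float = 0.8
    # gene impact
    fusion_promoter_window: int = 100_000
    disruption_upstream_window: int = 10_000
    readthrough_distance: int = 1_000_000
    max_fusion_links: int = 4
    enrichment_fdr: float = 0.1
    # validation
    consistency_tolerance: float = 0.15
    # misc
    seed: int = 0

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "Config":
        values: dict[str, object] = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, raw = line.partition("=")
                key = key.strip()
                if key not in types:
                    raise KeyError(f"unknown config key {key!r}")
                ftype = types[key]
                values[key] = int(raw) if ftype in ("int", int) else float(raw)
        return cls(**values)
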