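"""Pipeline configuration: every tunable threshold with its default."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import ClassVar


@dataclass
class PipelineConfig:
    # alignment / placement filtering
    min_identity: float = 0.90
    min_coverage: float = 0.80
    min_anchor_len: int = 20
    contig_min_len: int = 500
    # BES anchoring
    bes_contig_min_identity: float = 0.90
    bes_contig_min_coverage: float = 0.95
    bes_ref_min_identity: float = 0.90
    bes_ref_min_coverage: float = 0.90
    bes_max_pair_dist: int = 300_000
    # paired-end anchoring
    min_links: int = 3
    # large-indel classification
    indel_min_size: int = 100
    indel_max_size: int = 50_000
    min_flank: int = 200
    min_span_reads: int = 5
    # polishing
    polish_min_qual: int = 30
    polish_min_depth: int = 10
    polish_min_freq: float = 0.70
    polish_rounds: int = 2
    polish_min_map_qual: int = 20
    polish_min_base_qual: int = 20
    # gene analysis
    gene_absent_cov: float = 0.05
    transcript_min_identity: float = 0.90
    transcript_min_coverage: float = 0.70
    transcript_unique_max_cov: float = 0.50
    seed: int = 0

    _RANGES: ClassVar[dict[str, tuple[float, float]]] = {
        "min_identity": (0.0, 1.0),
        "min_coverage": (0.0, 1.0),
        "bes_contig_min_identity": (0.0, 1.0),
        "bes_contig_min_coverage": (0.0, 1.0),
        "bes_ref_min_identity": (0.0, 1.0),
        "bes_ref_min_coverage": (0.0, 1.0),
        "polish_min_freq": (0.0, 1.0),
        "gene_absent_cov": (0.0, 1.0),
        "transcript_min_identity": (0.0, 1.0),
        "transcript_min_coverage": (0.0, 1.0),
        "transcript_unique_max_cov": (0.0, 1.0),
    }

    def validate(self) -> "PipelineConfig":
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        for name in ("contig_min_len", "indel_min_size", "indel_max_size", "min_flank",
                     "polish_rounds", "min_links", "bes_max_pair_dist", "min_span_reads"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.indel_min_size >= self.indel_max_size:
            raise ValueError("indel size window is empty")
        return self

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        data = json.loads(p.read_text() if p.exists() else str(source))
        return cls(**data).validate()
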