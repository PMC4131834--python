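"""Unique-mapping-rate reports for read sets against multiple references.

The unique mapping rate is uniquely mapped reads / total reads x 100 for a
read set against a given reference.  A read counts as unique when its
primary alignment is mapped with mapping quality at or above the floor and
the aligner reported no secondary or supplementary record for it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
import pysam


@dataclass
class MappingReport:
    read_set_id: str
    reference_id: str
    total_reads: int
    uniquely_mapped: int
    multi_mapped: int
    unmapped: int

    @property
    def unique_rate_pct(self) -> float:
        return 100.0 * self.uniquely_mapped / self.total_reads if self.total_reads else 0.0

    def __post_init__(self) -> None:
        if self.uniquely_mapped + self.multi_mapped + self.unmapped != self.total_reads:
            raise ValueError("read classification does not partition the total")


def unique_mapping_rate(
    sam_per_reference: dict[tuple[str, str], str | Path],
    manifest: dict[str, set[str]] | None = None,
    min_mapq: int = 20,
) -> list[MappingReport]:
    """One report per (read set, reference) SAM.

    Keys of ``sam_per_reference`` are (read_set_id, reference_id).  Pairs
    count as two reads (mate 1 and mate 2 classified independently).  An
    optional manifest maps read_set_id to the expected read-name set; SAM
    reads missing from it are still counted, with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    reports = []
    for (rs_id, ref_id), path in sam_per_reference.items():
        state: dict[tuple[str, bool, bool], list] = {}
        # per read key: [mapped, mapq_ok, has_extra_alignment]
        with pysam.AlignmentFile(str(path), "r") as sam:
            for rec in sam:
                key = (rec.query_name, rec.is_read1, rec.is_read2)
                st = state.setdefault(key, [False, False, False])
                if rec.is_secondary or rec.is_supplementary:
                    st[2] = True
                    continue
                if not rec.is_unmapped:
                    st[0] = True
                    st[1] = rec.mapping_quality >= min_mapq
        if manifest is not None and rs_id in manifest:
            names = {k[0] for k in state}
            extra = names - manifest[rs_id]
            if extra:
                logger.warning("%d reads in SAM missing from manifest for %s", len(extra), rs_id)
        unique = sum(1 for st in state.values() if st[0] and st[1] and not st[2])
        unmapped = sum(1 for st in state.values() if not st[0])
        total = len(state)
        reports.append(
            MappingReport(
                read_set_id=rs_id,
                reference_id=ref_id,
                total_reads=total,
                uniquely_mapped=unique,
                multi_mapped=total - unique - unmapped,
                unmapped=unmapped,
            )
        )
    return reports


def report_table(reports: Iterable[MappingReport]) -> pd.DataFrame:
    """Accession x reference layout of unique mapping rates."""
    df = pd.DataFrame(
        [
            dict(
                read_set=r.read_set_id,
                reference=r.reference_id,
                total=r.total_reads,
                unique=r.uniquely_mapped,
                multi=r.multi_mapped,
                unmapped=r.unmapped,
                unique_rate_pct=round(r.unique_rate_pct, 1),
            )
            for r in reports
        ]
    )
    return df
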